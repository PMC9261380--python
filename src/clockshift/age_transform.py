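"""Piecewise log-linear age transformation used by epigenetic clocks.

Chronological ages are mapped onto a scale that is logarithmic during
development and linear in adulthood, with the knot at 20 years:

    f(x) = ln((x + 1) / 21)      if x <= 20
    f(x) = (x + 1) / 21 - 1      if x >  20

so that f(20) = 0 and f is continuous and strictly increasing on
(-1, inf). Regressions on transformed ages weight errors in childhood
on a relative rather than absolute scale, which matters for cohorts
spanning infancy to old age. The inverse maps model output back to
years:

    f_inv(y) = 21 * exp(y) - 1   if y < 0
    f_inv(y) = 21 * y + 20       if y >= 0

The knot (20) and scale (21) are fixed constants of the transform.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

ADULT_AGE = 20.0
_SCALE = ADULT_AGE + 1.0


def transform_age(age: ArrayLike) -> float | NDArray[np.float64]:
    """Map age in years to the transformed (log/linear) scale.

    Parameters
    ----------
    age
        Scalar or array of ages in years; every value must be > -1.

    Returns
    -------
    Transformed value(s); scalar input yields a Python float.

    Raises
    ------
    ValueError
        If any age is <= -1 or non-finite.
    """
    x = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("age must be finite")
    if np.any(x <= -1.0):
        raise ValueError("age transformation is undefined for age <= -1")
    ratio = (x + 1.0) / _SCALE
    out = np.where(x > ADULT_AGE, ratio - 1.0, np.log(ratio))
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def inverse_transform_age(value: ArrayLike) -> float | NDArray[np.float64]:
    """Map a transformed age back to years (inverse of :func:`transform_age`)."""
    y = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("transformed age must be finite")
    out = np.where(y < 0.0, _SCALE * np.exp(y) - 1.0, _SCALE * y + ADULT_AGE)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out
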
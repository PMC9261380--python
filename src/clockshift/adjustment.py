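"""Cell-composition adjustment of clock predictions via elastic net.

A blood-trained methylation clock applied to saliva/buccal samples makes
composition-dependent errors: the larger the epithelial fraction, the more
the clock over-ages the sample. Four correction schemes are supported,
each a small linear model fitted with elastic net and selected by
leave-one-study-out (LOSO) cross-validated grid search:

``none``
    Identity; raw clock output is used as-is.
``simple``
    Chronological age regressed on the raw prediction alone (no
    composition information).
``delta``
    The clock residual ``delta = prediction - age`` regressed on the
    epithelial (Epi) and immune-cell (IC) fractions; the fitted delta is
    subtracted from the raw prediction.
``total``
    Chronological age regressed jointly on the prediction and the Epi/IC
    fractions.

The ``simple`` and ``total`` schemes can operate in transformed-age space
(see :mod:`clockshift.age_transform`): both the prediction feature and the
age response pass through ``f``, and the fitted output returns through
``f^-1``. Fibroblast fractions are excluded from the default feature set
(Epi + Fib + IC is close to 1, so including all three is collinear) but
can be opted in.

Features are deliberately *not* standardized before fitting: the published
coefficient sets are on natural scales and reproducing their magnitudes
requires unstandardized fits. A flag enables standardization for
exploration.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LinearRegression

from .age_transform import inverse_transform_age, transform_age
from .io_formats import CellFractions, ClockPrediction, SampleAnnotation

__all__ = [
    "AdjustmentModel",
    "HyperparamGrid",
    "Scheme",
    "fit_adjuster",
    "apply_adjuster",
    "published_total_age_model",
    "loso_folds",
    "median_baseline",
    "align_inputs",
]

Scheme = Literal["none", "simple", "delta", "total"]

SCHEMES: tuple[Scheme, ...] = ("none", "simple", "delta", "total")

#: coefficients of the published total-age adjustment in transformed-age space
PUBLISHED_TRANSFORMED = {
    "prediction": 0.93,
    "Epi": -1.14,
    "IC": 1.05,
    "intercept": -1.18,
}
#: coefficients of the published total-age adjustment in years
PUBLISHED_UNTRANSFORMED = {
    "prediction": 0.85,
    "Epi": -11.54,
    "IC": 10.56,
    "intercept": -15.76,
}


@dataclass
class HyperparamGrid:
    """Elastic-net search grid: every (alpha, l1_ratio) pair is tried.

    Defaults are ``l1_ratio in {0.00, 0.01, ..., 0.99}`` (the pure-lasso
    endpoint 1.0 is intentionally absent) and ``alpha`` spanning five
    decades plus 0 (fitted as ordinary least squares).
    """

    l1_ratios: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.01), 2))
    alphas: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.0, 1.0, 10.0, 100.0)

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 1 for r in self.l1_ratios):
            raise ValueError("l1_ratio values must lie in [0, 1]")
        if any(a < 0 for a in self.alphas):
            raise ValueError("alpha values must be >= 0")

    def candidates(self) -> list[tuple[float, float]]:
        """Deterministic candidate order; alpha = 0 appears once (OLS)."""
        out: list[tuple[float, float]] = []
        for alpha in self.alphas:
            if alpha == 0.0:
                out.append((0.0, self.l1_ratios[0] if self.l1_ratios else 0.0))
            else:
                out.extend((alpha, r) for r in self.l1_ratios)
        return out


@dataclass
class AdjustmentModel:
    """One fitted (or published) adjustment regression."""

    scheme: Scheme
    transformed: bool = False
    coefficients: dict[str, float] = field(default_factory=dict)
    alpha: float | None = None
    l1_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "none" and self.coefficients:
            raise ValueError("scheme 'none' carries no coefficients")
        if self.transformed and self.scheme not in ("simple", "total"):
            raise ValueError(
                "transformed-age fitting is only defined for the 'simple' "
                "and 'total' schemes"
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "transformed": self.transformed,
            "coefficients": dict(self.coefficients),
            "alpha": self.alpha,
            "l1_ratio": self.l1_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdjustmentModel":
        return cls(
            scheme=d["scheme"],
            transformed=bool(d.get("transformed", False)),
            coefficients={k: float(v) for k, v in d.get("coefficients", {}).items()},
            alpha=d.get("alpha"),
            l1_ratio=d.get("l1_ratio"),
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "AdjustmentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def published_total_age_model(transformed: bool) -> AdjustmentModel:
    """The published total-age adjustment with its printed coefficients.

    ``transformed=True`` returns the model operating in transformed-age
    space; ``transformed=False`` the model in plain years.
    """
    coeffs = PUBLISHED_TRANSFORMED if transformed else PUBLISHED_UNTRANSFORMED
    return AdjustmentModel(
        scheme="total", transformed=transformed, coefficients=dict(coeffs)
    )


# ---------------------------------------------------------------------------
# data alignment and folds

def align_inputs(
    predictions: Sequence[ClockPrediction],
    annotations: Sequence[SampleAnnotation],
    fractions: CellFractions | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, CellFractions | None]:
    """Align predictions/annotations/fractions on sample_id.

    Returns (sample_ids, predicted ages, chronological ages, study ids,
    reordered fractions). Order follows ``predictions``.
    """
    ann = {a.sample_id: a for a in annotations}
    ids = [p.sample_id for p in predictions]
    missing = [s for s in ids if s not in ann]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    pred = np.array([p.predicted_age for p in predictions], dtype=float)
    ages = np.array([ann[s].age for s in ids], dtype=float)
    studies = np.array([ann[s].study_id for s in ids], dtype=object)
    frac = None
    if fractions is not None:
        absent = [s for s in ids if s not in set(fractions.sample_ids)]
        if absent:
            raise ValueError(f"samples without cell fractions: {absent[:5]}")
        frac = fractions.reindex(ids)
    return ids, pred, ages, studies, frac


def loso_folds(
    annotations: Sequence[SampleAnnotation],
) -> list[tuple[list[str], list[str]]]:
    """Leave-one-study-out folds: one fold per study, sorted by study id.

    Each fold is (train sample ids, test sample ids); the test sets
    partition the cohort.
    """
    by_study: dict[str, list[str]] = {}
    for a in annotations:
        by_study.setdefault(a.study_id, []).append(a.sample_id)
    if len(by_study) < 2:
        raise ValueError(
            "leave-one-study-out folds require at least 2 distinct studies"
        )
    folds = []
    for study in sorted(by_study):
        test = by_study[study]
        train = [a.sample_id for a in annotations if a.study_id != study]
        folds.append((train, test))
    return folds


def median_baseline(train_ages: Sequence[float]) -> float:
    """Constant baseline predictor: the median of the training ages."""
    ages = np.asarray(list(train_ages), dtype=float)
    if ages.size == 0:
        raise ValueError("median baseline requires a non-empty training set")
    return float(np.median(ages))


# ---------------------------------------------------------------------------
# design matrices and fitting

def _feature_names(scheme: Scheme, include_fib: bool) -> list[str]:
    if scheme == "simple":
        return ["prediction"]
    if scheme == "delta":
        return ["Epi", "IC"] + (["Fib"] if include_fib else [])
    if scheme == "total":
        return ["prediction", "Epi", "IC"] + (["Fib"] if include_fib else [])
    return []


def _design(
    scheme: Scheme,
    transformed: bool,
    pred: np.ndarray,
    ages: np.ndarray,
    frac: CellFractions | None,
    names: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, y) for a scheme. y is the regression response."""
    cols = []
    for name in names:
        if name == "prediction":
            cols.append(transform_age(pred) if transformed else pred)
        else:
            if frac is None or name not in frac.cell_types:
                raise ValueError(f"cell fraction column {name!r} is required but absent")
            cols.append(frac.column(name))
    X = np.column_stack(cols) if cols else np.empty((len(pred), 0))
    if scheme == "delta":
        y = pred - ages
    else:
        y = transform_age(ages) if transformed else ages
    return X, np.asarray(y, dtype=float)


def _fit_linear(
    X: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float
) -> tuple[np.ndarray, float]:
    """Elastic-net fit (OLS when alpha == 0); returns (coefs, intercept)."""
    if alpha == 0.0:
        est = LinearRegression()
        est.fit(X, y)
    else:
        est = ElasticNet(
            alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True, max_iter=50_000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
    return np.atleast_1d(est.coef_).astype(float), float(est.intercept_)


def _model_from_fit(
    scheme: Scheme,
    transformed: bool,
    names: list[str],
    coefs: np.ndarray,
    intercept: float,
    alpha: float,
    l1_ratio: float,
) -> AdjustmentModel:
    coeffs = {n: float(c) for n, c in zip(names, coefs)}
    coeffs["intercept"] = intercept
    return AdjustmentModel(
        scheme=scheme,
        transformed=transformed,
        coefficients=coeffs,
        alpha=alpha,
        l1_ratio=l1_ratio,
    )


def apply_adjuster(
    model: AdjustmentModel,
    predictions: Sequence[ClockPrediction],
    fractions: CellFractions | None = None,
    delta_sign: Literal["subtract", "add"] = "subtract",
) -> np.ndarray:
    """Apply a fitted or published adjustment; returns adjusted ages in years.

    For the ``delta`` scheme the fitted residual is subtracted from the
    raw prediction by default (an over-estimating clock is pulled down);
    ``delta_sign="add"`` flips the convention for sensitivity analysis.
    """
    pred = np.array([p.predicted_age for p in predictions], dtype=float)
    if model.scheme == "none":
        return pred.copy()
    ids = [p.sample_id for p in predictions]
    coeffs = model.coefficients
    out = np.full(len(pred), float(coeffs.get("intercept", 0.0)))
    frac = None
    if any(k in coeffs for k in ("Epi", "IC", "Fib")):
        if fractions is None:
            raise ValueError(
                f"model for scheme {model.scheme!r} requires cell fractions"
            )
        frac = fractions.reindex(ids)
    for name, c in coeffs.items():
        if name == "intercept":
            continue
        if name == "prediction":
            feat = transform_age(pred) if model.transformed else pred
        else:
            if frac is None or name not in frac.cell_types:
                raise ValueError(f"model requires feature {name!r} which is absent")
            feat = frac.column(name)
        out = out + c * np.asarray(feat, dtype=float)
    if model.scheme == "delta":
        return pred - out if delta_sign == "subtract" else pred + out
    if model.transformed:
        return np.asarray(inverse_transform_age(out), dtype=float)
    return out


def _cv_mae(
    scheme: Scheme,
    transformed: bool,
    alpha: float,
    l1_ratio: float,
    ids: list[str],
    pred: np.ndarray,
    ages: np.ndarray,
    frac: CellFractions | None,
    folds: list[tuple[list[str], list[str]]],
    names: list[str],
) -> float:
    """Pooled LOSO mean absolute error (years) at one hyperparameter point."""
    pos = {s: i for i, s in enumerate(ids)}
    abs_err: list[np.ndarray] = []
    for train, test in folds:
        tr = np.array([pos[s] for s in train])
        te = np.array([pos[s] for s in test])
        frac_tr = frac.reindex([ids[i] for i in tr]) if frac is not None else None
        X, y = _design(scheme, transformed, pred[tr], ages[tr], frac_tr, names)
        coefs, intercept = _fit_linear(X, y, alpha, l1_ratio)
        model = _model_from_fit(
            scheme, transformed, names, coefs, intercept, alpha, l1_ratio
        )
        test_preds = [ClockPrediction(ids[i], pred[i]) for i in te]
        adj = apply_adjuster(model, test_preds, frac)
        abs_err.append(np.abs(adj - ages[te]))
    return float(np.mean(np.concatenate(abs_err)))


def fit_adjuster(
    scheme: Scheme,
    transformed: bool,
    predictions: Sequence[ClockPrediction],
    annotations: Sequence[SampleAnnotation],
    fractions: CellFractions | None = None,
    grid: HyperparamGrid | None = None,
    include_fib: bool = False,
    standardize: bool = False,
) -> AdjustmentModel:
    """Fit one adjustment scheme with LOSO-CV elastic-net grid search.

    Hyperparameters minimize the pooled mean absolute error (in years)
    over leave-one-study-out folds; the returned model is refit on all
    samples at the selected (alpha, l1_ratio). Requires at least two
    distinct studies. ``scheme="none"`` returns the empty identity model.
    """
    if scheme == "none":
        return AdjustmentModel(scheme="none")
    if grid is None:
        grid = HyperparamGrid()
    names = _feature_names(scheme, include_fib)
    needs_frac = any(n in ("Epi", "IC", "Fib") for n in names)
    if needs_frac:
        if fractions is None:
            raise ValueError(f"scheme {scheme!r} requires cell fractions")
        for col in names:
            if col != "prediction" and col not in fractions.cell_types:
                raise ValueError(f"fractions are missing the {col!r} column")
    ids, pred, ages, _, frac = align_inputs(predictions, annotations, fractions)
    folds = loso_folds([a for a in annotations if a.sample_id in set(ids)])

    mu = sigma = None
    if standardize:
        X_full, _ = _design(scheme, transformed, pred, ages, frac, names)
        mu, sigma = X_full.mean(axis=0), X_full.std(axis=0)
        sigma[sigma == 0] = 1.0

    def fit_at(X: np.ndarray, y: np.ndarray, alpha: float, l1r: float):
        if standardize:
            coefs_s, icept_s = _fit_linear((X - mu) / sigma, y, alpha, l1r)
            coefs = coefs_s / sigma
            return coefs, icept_s - float(coefs @ mu)
        return _fit_linear(X, y, alpha, l1r)

    # grid search on pooled LOSO MAE; ties resolved by candidate order
    best = None
    if standardize:
        # score the standardized pipeline fold-by-fold
        pos = {s: i for i, s in enumerate(ids)}
        for alpha, l1r in grid.candidates():
            abs_err = []
            for train, test in folds:
                tr = np.array([pos[s] for s in train])
                te = np.array([pos[s] for s in test])
                frac_tr = frac.reindex([ids[i] for i in tr]) if frac is not None else None
                X, y = _design(scheme, transformed, pred[tr], ages[tr], frac_tr, names)
                coefs, icept = fit_at(X, y, alpha, l1r)
                model = _model_from_fit(scheme, transformed, names, coefs, icept, alpha, l1r)
                adj = apply_adjuster(
                    model, [ClockPrediction(ids[i], pred[i]) for i in te], frac
                )
                abs_err.append(np.abs(adj - ages[te]))
            score = float(np.mean(np.concatenate(abs_err)))
            if best is None or score < best[0] - 1e-12:
                best = (score, alpha, l1r)
    else:
        for alpha, l1r in grid.candidates():
            score = _cv_mae(
                scheme, transformed, alpha, l1r, ids, pred, ages, frac, folds, names
            )
            if best is None or score < best[0] - 1e-12:
                best = (score, alpha, l1r)
    assert best is not None
    _, alpha, l1r = best

    X, y = _design(scheme, transformed, pred, ages, frac, names)
    coefs, intercept = fit_at(X, y, alpha, l1r)
    return _model_from_fit(scheme, transformed, names, coefs, intercept, alpha, l1r)


def fit_adjuster_at(
    scheme: Scheme,
    transformed: bool,
    predictions: Sequence[ClockPrediction],
    annotations: Sequence[SampleAnnotation],
    fractions: CellFractions | None = None,
    alpha: float = 0.0,
    l1_ratio: float = 0.0,
    include_fib: bool = False,
) -> AdjustmentModel:
    """Fit one scheme at fixed hyperparameters, without any grid search.

    Used for refitting inside cross-validation folds once the
    hyperparameters have been selected; works with a single study.
    """
    if scheme == "none":
        return AdjustmentModel(scheme="none")
    names = _feature_names(scheme, include_fib)
    _, pred, ages, _, frac = align_inputs(predictions, annotations, fractions)
    X, y = _design(scheme, transformed, pred, ages, frac, names)
    coefs, intercept = _fit_linear(X, y, alpha, l1_ratio)
    return _model_from_fit(scheme, transformed, names, coefs, intercept, alpha, l1_ratio)
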
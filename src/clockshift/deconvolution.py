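"""Reference-based cell-type deconvolution of bulk methylation profiles.

Two standard estimators are provided, both operating per sample on the
marker probes shared between the bulk matrix and the reference:

``rpc`` (robust partial correlation)
    A robust linear model (Huber loss, iteratively reweighted least
    squares, intercept included) of the bulk beta vector on the reference
    columns. Negative coefficients are truncated to zero and the vector is
    renormalized onto the unit simplex.

``cp`` (constrained projection)
    The quadratic program ``min ||y - H w||^2  s.t.  w >= 0, sum(w) <= 1``
    solved exactly by enumerating KKT active sets (the problem has few
    cell types, so enumeration is both exact and fast), followed by
    renormalization to sum 1.

Missing beta values are dropped per sample (row-wise deletion over
probes): deconvolution is an independent regression per sample, so
deletion is unbiased under missing-at-random and avoids imputation.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import statsmodels.api as sm

from .io_formats import BetaMatrix, CellFractions, ReferenceMatrix

__all__ = [
    "intersect_probes",
    "estimate_fractions_rpc",
    "estimate_fractions_cp",
    "estimate_fractions",
    "InsufficientOverlapError",
    "DegenerateReferenceError",
]

#: default Huber tuning constant (95% efficiency under Gaussian errors)
HUBER_TUNING = 1.345


class InsufficientOverlapError(ValueError):
    """Bulk matrix and reference share too few probes for deconvolution."""


class DegenerateReferenceError(ValueError):
    """Reference columns are collinear; fractions are not identifiable."""


def _min_overlap(n_cell_types: int) -> int:
    return max(10, 2 * n_cell_types)


def intersect_probes(
    beta: BetaMatrix,
    ref: ReferenceMatrix,
    min_overlap: int | None = None,
) -> tuple[BetaMatrix, ReferenceMatrix]:
    """Restrict both matrices to their shared probes, in the reference's order.

    Raises :class:`InsufficientOverlapError` when fewer than
    ``max(10, 2 * n_cell_types)`` probes are shared (override with
    ``min_overlap``).
    """
    if min_overlap is None:
        min_overlap = _min_overlap(len(ref.cell_types))
    beta_probes = set(beta.probe_ids)
    shared = [p for p in ref.probe_ids if p in beta_probes]
    if len(shared) < min_overlap:
        raise InsufficientOverlapError(
            f"only {len(shared)} probes shared between bulk matrix and "
            f"reference; need at least {min_overlap}"
        )
    beta_idx = {p: i for i, p in enumerate(beta.probe_ids)}
    ref_idx = {p: i for i, p in enumerate(ref.probe_ids)}
    b_rows = [beta_idx[p] for p in shared]
    r_rows = [ref_idx[p] for p in shared]
    return (
        BetaMatrix(shared, list(beta.sample_ids), beta.values[b_rows]),
        ReferenceMatrix(shared, list(ref.cell_types), ref.values[r_rows]),
    )


def _check_reference_rank(H: np.ndarray) -> None:
    if np.linalg.matrix_rank(H) < H.shape[1]:
        raise DegenerateReferenceError(
            "reference columns are collinear; cell fractions are not identifiable"
        )


def _to_simplex(coef: np.ndarray) -> tuple[np.ndarray, bool]:
    """Truncate negatives and normalize to sum 1; flag all-nonpositive input."""
    w = np.where(coef > 0, coef, 0.0)
    total = w.sum()
    if total <= 0:
        k = len(coef)
        return np.full(k, 1.0 / k), True
    return w / total, False


def estimate_fractions_rpc(
    beta: BetaMatrix,
    ref: ReferenceMatrix,
    max_iter: int = 100,
    huber_tuning: float = HUBER_TUNING,
) -> CellFractions:
    """Robust-partial-correlation deconvolution.

    Per sample, fits a Huber-loss robust regression (IRLS, with intercept)
    of the sample's beta vector on the reference columns, truncates
    negative coefficients to zero, and renormalizes onto the simplex.
    Samples whose coefficients are all non-positive receive uniform
    fractions and are recorded in ``CellFractions.flagged``.
    """
    H = ref.values
    _check_reference_rank(H)
    X = sm.add_constant(H)
    min_ok = _min_overlap(len(ref.cell_types))
    out = np.empty((len(beta.sample_ids), len(ref.cell_types)))
    flagged: list[str] = []
    for j, sid in enumerate(beta.sample_ids):
        y = beta.values[:, j]
        keep = ~np.isnan(y)
        if keep.sum() < min_ok:
            raise InsufficientOverlapError(
                f"sample {sid!r} has only {int(keep.sum())} non-missing marker "
                f"probes; need at least {min_ok}"
            )
        model = sm.RLM(y[keep], X[keep], M=sm.robust.norms.HuberT(t=huber_tuning))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            fit = model.fit(maxiter=max_iter, tol=1e-8)
        if not getattr(fit, "converged", True) and fit.fit_history.get("deviance"):
            warnings.warn(
                f"robust fit for sample {sid!r} did not converge in "
                f"{max_iter} iterations; using last iterate",
                RuntimeWarning,
                stacklevel=2,
            )
        coef = fit.params[1:]  # drop intercept
        out[j], was_flagged = _to_simplex(coef)
        if was_flagged:
            flagged.append(sid)
    return CellFractions(list(beta.sample_ids), list(ref.cell_types), out, flagged)


def _solve_cp_qp(H: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact solution of min ||y - Hw||^2 s.t. w >= 0, sum(w) <= 1.

    The QP is convex with K nonnegativity constraints plus one sum
    constraint; the global optimum is found by enumerating candidate
    active sets and keeping the feasible candidate with the smallest
    objective.
    """
    K = H.shape[1]
    G = H.T @ H
    b = H.T @ y
    best_w, best_obj = None, np.inf
    eps = 1e-9
    for zero_set in itertools.chain.from_iterable(
        itertools.combinations(range(K), r) for r in range(K + 1)
    ):
        free = [i for i in range(K) if i not in zero_set]
        if not free:
            obj = float(y @ y)  # w = 0 candidate
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, np.zeros(K)
            continue
        Gf = G[np.ix_(free, free)]
        bf = b[free]
        for sum_active in (False, True):
            try:
                if sum_active:
                    # KKT system with equality sum(w_free) = 1
                    n = len(free)
                    kkt = np.zeros((n + 1, n + 1))
                    kkt[:n, :n] = Gf
                    kkt[:n, n] = 1.0
                    kkt[n, :n] = 1.0
                    rhs = np.concatenate([bf, [1.0]])
                    sol = np.linalg.solve(kkt, rhs)[:n]
                else:
                    sol = np.linalg.solve(Gf, bf)
            except np.linalg.LinAlgError:
                continue
            w = np.zeros(K)
            w[free] = sol
            if np.any(w < -eps) or w.sum() > 1.0 + eps:
                continue
            w = np.clip(w, 0.0, None)
            r = y - H @ w
            obj = float(r @ r)
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    if best_w is None:  # w = 0 is always feasible, so this cannot trigger
        raise RuntimeError("constrained projection failed to find a feasible point")
    return best_w


def estimate_fractions_cp(beta: BetaMatrix, ref: ReferenceMatrix) -> CellFractions:
    """Constrained-projection deconvolution.

    Per sample solves the non-negative, sum-at-most-one least-squares
    projection onto the reference columns, then renormalizes to sum
    exactly 1. Samples whose constrained coefficients summed to < 0.5
    before renormalization are recorded in ``CellFractions.flagged``.
    """
    H = ref.values
    _check_reference_rank(H)
    min_ok = _min_overlap(len(ref.cell_types))
    out = np.empty((len(beta.sample_ids), len(ref.cell_types)))
    flagged: list[str] = []
    for j, sid in enumerate(beta.sample_ids):
        y = beta.values[:, j]
        keep = ~np.isnan(y)
        if keep.sum() < min_ok:
            raise InsufficientOverlapError(
                f"sample {sid!r} has only {int(keep.sum())} non-missing marker "
                f"probes; need at least {min_ok}"
            )
        try:
            w = _solve_cp_qp(H[keep], y[keep])
        except Exception as exc:
            raise RuntimeError(
                f"constrained projection failed for sample {sid!r}: {exc}"
            ) from exc
        total = w.sum()
        if total < 0.5:
            flagged.append(sid)
        out[j], uniform = _to_simplex(w)
        if uniform and sid not in flagged:
            flagged.append(sid)
    return CellFractions(list(beta.sample_ids), list(ref.cell_types), out, flagged)


def estimate_fractions(
    beta: BetaMatrix,
    ref: ReferenceMatrix,
    method: str = "rpc",
    **kwargs,
) -> CellFractions:
    """Dispatch to :func:`estimate_fractions_rpc` or :func:`estimate_fractions_cp`."""
    if method == "rpc":
        return estimate_fractions_rpc(beta, ref, **kwargs)
    if method == "cp":
        return estimate_fractions_cp(beta, ref, **kwargs)
    raise ValueError(f"unknown deconvolution method {method!r}; use 'rpc' or 'cp'")
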
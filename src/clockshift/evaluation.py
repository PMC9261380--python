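"""Error metrics and scheme comparison for adjusted clock predictions.

Provides the core metrics (MAE in years, coefficient of determination,
Pearson correlation), the accuracy-gain-versus-immune-fraction analysis,
and :func:`evaluate_schemes`, which scores every adjustment variant plus
the median-age baseline by leave-one-study-out cross-validation on the
training studies and by refit-and-apply on held-out verification studies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adjustment import (
    AdjustmentModel,
    HyperparamGrid,
    align_inputs,
    apply_adjuster,
    fit_adjuster,
    fit_adjuster_at,
    loso_folds,
    median_baseline,
)
from .io_formats import CellFractions, ClockPrediction, SampleAnnotation

__all__ = [
    "mae",
    "r_squared",
    "pearson_r",
    "accuracy_gain_analysis",
    "evaluate_schemes",
    "EvaluationReport",
    "SchemeResult",
    "GainAnalysis",
    "composition_summary",
    "SCHEME_VARIANTS",
]

#: the six adjustment variants reported side by side, plus the baseline
SCHEME_VARIANTS: tuple[tuple[str, bool], ...] = (
    ("none", False),
    ("simple", False),
    ("simple", True),
    ("delta", False),
    ("total", False),
    ("total", True),
)


def mae(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Mean absolute error in years."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted and actual must be equal-length and non-empty")
    return float(np.mean(np.abs(p - a)))


def r_squared(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about mean(actual)."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 2:
        raise ValueError("need at least two aligned values")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for constant actual values")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.size < 2:
        raise ValueError("need at least two aligned values")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    return float(stats.pearsonr(xv, yv).statistic)


@dataclass
class GainAnalysis:
    """OLS of per-sample accuracy gain on immune-cell fraction."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    fraction_worsened: float
    gains: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
            "fraction_worsened": self.fraction_worsened,
        }


def accuracy_gain_analysis(
    raw_pred: Sequence[float],
    adjusted_pred: Sequence[float],
    ages: Sequence[float],
    ic_fractions: Sequence[float],
    absolute_shift: bool = False,
) -> GainAnalysis:
    """Relate the per-sample accuracy gain to immune-cell content.

    The gain for sample *i* is the drop in distance to chronological age,
    ``|raw - age| - |adjusted - age|`` (positive = improvement). An
    ordinary least-squares line of gain on IC fraction is reported along
    with the Pearson correlation and the share of samples the adjustment
    made worse. With ``absolute_shift=True`` the response is instead the
    absolute adjustment magnitude ``|adjusted - raw|``.
    """
    raw = np.asarray(raw_pred, dtype=float)
    adj = np.asarray(adjusted_pred, dtype=float)
    age = np.asarray(ages, dtype=float)
    ic = np.asarray(ic_fractions, dtype=float)
    if not (raw.shape == adj.shape == age.shape == ic.shape) or raw.size < 3:
        raise ValueError("need at least three aligned samples")
    gain = np.abs(raw - age) - np.abs(adj - age)
    response = np.abs(adj - raw) if absolute_shift else gain
    if np.std(response) == 0 or np.std(ic) == 0:
        raise ValueError(
            "gain analysis undefined: response or IC fraction is constant"
        )
    fit = stats.linregress(ic, response)
    return GainAnalysis(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        pearson_r=float(fit.rvalue),
        fraction_worsened=float(np.mean(gain < 0)),
        gains=gain,
    )


@dataclass
class SchemeResult:
    """CV and holdout errors for one adjustment variant."""

    scheme: str
    transformed: bool
    cv_mae: float
    holdout_mae: float | None
    r_squared: float | None
    per_study_mae: dict[str, float]
    model: AdjustmentModel | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "transformed": self.transformed,
            "cv_mae": self.cv_mae,
            "holdout_mae": self.holdout_mae,
            "r_squared": self.r_squared,
            "per_study_mae": dict(self.per_study_mae),
        }


@dataclass
class EvaluationReport:
    """Per-scheme errors plus the gain-vs-IC analysis for the best variant."""

    results: list[SchemeResult]
    gain_analysis: GainAnalysis | None = None

    def best(self) -> SchemeResult:
        scored = [r for r in self.results if r.scheme != "baseline"]
        return min(scored, key=lambda r: r.cv_mae)

    def result_for(self, scheme: str, transformed: bool) -> SchemeResult:
        for r in self.results:
            if r.scheme == scheme and r.transformed == transformed:
                return r
        raise KeyError(f"no result for scheme={scheme!r} transformed={transformed}")

    def to_dict(self) -> dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "gain_analysis": self.gain_analysis.to_dict() if self.gain_analysis else None,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results]).drop(
            columns=["per_study_mae"]
        )

    def save_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def save_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def _per_study_mae(
    adj: np.ndarray, ages: np.ndarray, studies: np.ndarray
) -> dict[str, float]:
    out = {}
    for s in sorted(set(studies)):
        m = studies == s
        out[str(s)] = float(np.mean(np.abs(adj[m] - ages[m])))
    return out


def evaluate_schemes(
    predictions: Sequence[ClockPrediction],
    annotations: Sequence[SampleAnnotation],
    fractions: CellFractions,
    grid: HyperparamGrid | None = None,
    holdout_studies: Sequence[str] = (),
    per_fold_average: bool = False,
) -> EvaluationReport:
    """Score every adjustment variant and the median-age baseline.

    Training studies are everything outside ``holdout_studies``. For each
    variant, hyperparameters are selected by LOSO grid search on the
    training studies; ``cv_mae`` is the pooled LOSO error at the selected
    point (``per_fold_average=True`` averages fold MAEs instead), and
    ``holdout_mae`` comes from refitting on all training studies and
    applying to the holdout. The gain analysis is computed for the
    variant with the lowest CV MAE, on pooled CV predictions.
    """
    if grid is None:
        grid = HyperparamGrid()
    holdout = set(holdout_studies)
    train_ann = [a for a in annotations if a.study_id not in holdout]
    hold_ann = [a for a in annotations if a.study_id in holdout]
    if holdout and not hold_ann:
        raise ValueError(f"no samples found for holdout studies {sorted(holdout)}")
    pred_by_id = {p.sample_id: p for p in predictions}
    train_preds = [pred_by_id[a.sample_id] for a in train_ann]
    hold_preds = [pred_by_id[a.sample_id] for a in hold_ann]

    ids, pred, ages, studies, frac = align_inputs(train_preds, train_ann, fractions)
    folds = loso_folds(train_ann)
    pos = {s: i for i, s in enumerate(ids)}

    def cv_predictions(
        scheme: str, transformed: bool, alpha: float | None, l1_ratio: float | None
    ) -> np.ndarray:
        """Out-of-study adjusted predictions at the selected hyperparameters."""
        if scheme == "none":
            return pred.copy()
        out = np.empty(len(ids))
        for train, test in folds:
            tr_ann = [a for a in train_ann if a.sample_id in set(train)]
            tr_preds = [pred_by_id[s] for s in train]
            model = fit_adjuster_at(
                scheme, transformed, tr_preds, tr_ann, fractions,
                alpha=alpha, l1_ratio=l1_ratio,
            )
            te = [pos[s] for s in test]
            adj = apply_adjuster(
                model, [pred_by_id[ids[i]] for i in te], fractions
            )
            out[te] = adj
        return out

    results: list[SchemeResult] = []

    # median-age baseline: per-fold constant predictor
    base_cv = np.empty(len(ids))
    for train, test in folds:
        med = median_baseline([ages[pos[s]] for s in train])
        for s in test:
            base_cv[pos[s]] = med
    fold_maes = [
        mae(base_cv[[pos[s] for s in test]], ages[[pos[s] for s in test]])
        for _, test in folds
    ]
    base_cv_mae = float(np.mean(fold_maes)) if per_fold_average else mae(base_cv, ages)
    base_hold = None
    if hold_ann:
        med = median_baseline(ages)
        base_hold = mae([med] * len(hold_ann), [a.age for a in hold_ann])
    results.append(
        SchemeResult(
            scheme="baseline",
            transformed=False,
            cv_mae=base_cv_mae,
            holdout_mae=base_hold,
            r_squared=None,
            per_study_mae=_per_study_mae(base_cv, ages, studies),
        )
    )

    cv_adjusted: dict[tuple[str, bool], np.ndarray] = {}
    for scheme, transformed in SCHEME_VARIANTS:
        final_model = fit_adjuster(
            scheme, transformed, train_preds, train_ann, fractions, grid
        )
        adj_cv = cv_predictions(
            scheme, transformed, final_model.alpha, final_model.l1_ratio
        )
        cv_adjusted[(scheme, transformed)] = adj_cv
        if per_fold_average:
            fold_maes = [
                mae(adj_cv[[pos[s] for s in test]], ages[[pos[s] for s in test]])
                for _, test in folds
            ]
            cv_mae = float(np.mean(fold_maes))
        else:
            cv_mae = mae(adj_cv, ages)
        hold_mae = None
        if hold_ann:
            hold_adj = apply_adjuster(final_model, hold_preds, fractions)
            hold_mae = mae(hold_adj, [a.age for a in hold_ann])
        results.append(
            SchemeResult(
                scheme=scheme,
                transformed=transformed,
                cv_mae=cv_mae,
                holdout_mae=hold_mae,
                r_squared=r_squared(adj_cv, ages),
                per_study_mae=_per_study_mae(adj_cv, ages, studies),
                model=final_model,
            )
        )

    report = EvaluationReport(results=results)
    best = report.best()
    best_cv = cv_adjusted[(best.scheme, best.transformed)]
    try:
        report.gain_analysis = accuracy_gain_analysis(
            pred, best_cv, ages, frac.column("IC")
        )
    except ValueError:
        report.gain_analysis = None  # degenerate (e.g. identity best scheme)
    return report


def composition_summary(
    fractions: CellFractions, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Tidy per-study composition table: mean and IQR of each cell fraction."""
    study = {a.sample_id: a.study_id for a in annotations}
    df = fractions.to_frame()
    df["study_id"] = [study[s] for s in fractions.sample_ids]
    rows = []
    for sid, grp in df.groupby("study_id"):
        for ct in fractions.cell_types:
            q1, q3 = grp[ct].quantile([0.25, 0.75])
            rows.append(
                {
                    "study_id": sid,
                    "cell_type": ct,
                    "mean": grp[ct].mean(),
                    "q1": q1,
                    "q3": q3,
                    "n": len(grp),
                }
            )
    return pd.DataFrame(rows)
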
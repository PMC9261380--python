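"""Tabular readers/writers for methylation matrices, annotations and fractions.

All formats are plain delimited text (comma for ``.csv``, tab otherwise,
overridable). Beta matrices are stored with probe ids in the first column
and sample ids in the header by default; the ``orientation`` flag accepts
transposed files. Missing beta values may appear as empty fields or ``NA``
and are carried internally as NaN.

Probe identifiers are opaque strings: no Illumina ``cg``-prefix syntax is
assumed, so synthetic probe sets are first-class citizens.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleAnnotation",
    "ReferenceMatrix",
    "ClockPrediction",
    "CellFractions",
    "ValidationError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotations",
    "write_annotations",
    "read_reference",
    "write_reference",
    "read_fractions",
    "write_fractions",
    "read_predictions",
    "write_predictions",
]

#: absolute tolerance for clamping beta values that exceed [0, 1] by rounding
BETA_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _sep_for(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))[:5]}")


def _clamp_unit_interval(values: np.ndarray, probe_ids, sample_ids, what: str) -> np.ndarray:
    """Clamp values within BETA_TOL of [0,1]; anything further out is an error."""
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        low = v < -BETA_TOL
        high = v > 1.0 + BETA_TOL
    bad = (low | high) & ~np.isnan(v)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} value out of [0,1]: {v[r, c]!r} at probe "
            f"{probe_ids[r]!r}, column {sample_ids[c]!r}"
        )
    return np.clip(v, 0.0, 1.0)


@dataclass
class BetaMatrix:
    """Bulk methylation beta values, probes x samples, entries in [0, 1].

    Missing entries are NaN (detection-p-filtered holes are routine on
    27K/450K arrays).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        self.values = _clamp_unit_interval(
            self.values, self.probe_ids, self.sample_ids, "beta"
        )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass
class ReferenceMatrix:
    """Pure-cell-type beta signatures over marker probes (probes x cell types)."""

    probe_ids: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.cell_types = [str(c) for c in self.cell_types]
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.cell_types, "cell type")
        if len(self.cell_types) < 2:
            raise ValidationError("reference needs at least 2 cell types")
        if len(self.probe_ids) < len(self.cell_types):
            raise ValidationError("reference needs at least as many probes as cell types")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.cell_types)):
            raise ValidationError("reference matrix shape does not match id lists")
        if np.isnan(self.values).any():
            raise ValidationError("reference matrix must have no missing entries")
        self.values = _clamp_unit_interval(
            self.values, self.probe_ids, self.cell_types, "reference"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.cell_types)


@dataclass
class SampleAnnotation:
    """One sample's metadata: id, chronological age (years), study, tissue."""

    sample_id: str
    age: float
    study_id: str
    tissue: str = ""
    sex: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age = float(self.age)
        if not np.isfinite(self.age) or self.age < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age must be finite and >= 0, got {self.age}"
            )
        if not str(self.study_id).strip():
            raise ValidationError(
                f"sample {self.sample_id!r}: study_id must be non-empty "
                "(leave-one-study-out folds are keyed on it)"
            )
        self.sample_id = str(self.sample_id)
        self.study_id = str(self.study_id)


@dataclass
class ClockPrediction:
    """Raw clock output for one sample, in years (blood-domain scale)."""

    sample_id: str
    predicted_age: float

    def __post_init__(self) -> None:
        self.predicted_age = float(self.predicted_age)
        if not np.isfinite(self.predicted_age):
            raise ValidationError(
                f"sample {self.sample_id!r}: predicted age must be finite"
            )
        self.sample_id = str(self.sample_id)


@dataclass
class CellFractions:
    """Per-sample cell-type proportions (samples x cell types), rows on the simplex."""

    sample_ids: list[str]
    cell_types: list[str]
    values: np.ndarray
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cell_types = [str(c) for c in self.cell_types]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.cell_types, "cell type")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValidationError("fractions shape does not match id lists")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValidationError("cell fractions must lie in [0,1]")
        sums = self.values.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-4
        if off.any():
            i = int(np.argmax(off))
            raise ValidationError(
                f"fractions for sample {self.sample_ids[i]!r} sum to "
                f"{sums[i]:.6f}, expected 1"
            )
        self.values = np.clip(self.values, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cell_types)

    def column(self, cell_type: str) -> np.ndarray:
        return self.values[:, self.cell_types.index(cell_type)]

    def reindex(self, sample_ids: Sequence[str]) -> "CellFractions":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CellFractions(
            list(sample_ids), list(self.cell_types), self.values[idx],
            [s for s in self.flagged if s in set(sample_ids)],
        )


# ---------------------------------------------------------------------------
# readers / writers

def read_beta_matrix(
    path: str | os.PathLike,
    orientation: Literal["probes_in_rows", "samples_in_rows"] = "probes_in_rows",
    delimiter: str | None = None,
) -> BetaMatrix:
    """Read a beta matrix from delimited text.

    The on-disk layout is declared by ``orientation``; the returned matrix
    is always probes x samples. Empty fields and ``NA`` become missing
    values; entries outside [0, 1] by more than ``BETA_TOL`` raise.
    """
    sep = _sep_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed beta matrix file {path}: {exc}") from exc
    for col in df.columns:
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValidationError(
                    f"non-numeric beta value in column {col!r} of {path}: {exc}"
                ) from exc
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "probes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return BetaMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_beta_matrix(
    beta: BetaMatrix,
    path: str | os.PathLike,
    orientation: Literal["probes_in_rows", "samples_in_rows"] = "probes_in_rows",
    delimiter: str | None = None,
) -> None:
    df = beta.to_frame()
    if orientation == "samples_in_rows":
        df = df.T
    df.index.name = "probe_id" if orientation == "probes_in_rows" else "sample_id"
    df.to_csv(path, sep=_sep_for(path, delimiter), na_rep="NA", float_format="%.6f")


_REQUIRED_ANNOT = ("sample_id", "age", "study_id", "tissue")


def read_annotations(
    path: str | os.PathLike, delimiter: str | None = None
) -> list[SampleAnnotation]:
    """Read a sample annotation table (sample_id, age, study_id, tissue[, sex])."""
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    missing = [c for c in _REQUIRED_ANNOT if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file {path} missing column(s): {missing}")
    known = set(_REQUIRED_ANNOT) | {"sex"}
    out: list[SampleAnnotation] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            age = float(rec["age"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path} line {row_no}: non-numeric age {rec['age']!r}"
            ) from exc
        out.append(
            SampleAnnotation(
                sample_id=rec["sample_id"],
                age=age,
                study_id=rec["study_id"] if rec["study_id"] is not None else "",
                tissue=rec.get("tissue") or "",
                sex=rec.get("sex"),
                extra={k: v for k, v in rec.items() if k not in known},
            )
        )
    _check_unique([a.sample_id for a in out], "sample")
    return out


def write_annotations(
    annotations: Sequence[SampleAnnotation],
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> None:
    rows = []
    for a in annotations:
        row = {
            "sample_id": a.sample_id,
            "age": a.age,
            "study_id": a.study_id,
            "tissue": a.tissue,
        }
        if a.sex is not None:
            row["sex"] = a.sex
        row.update(a.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, delimiter), index=False)


def read_reference(
    path: str | os.PathLike, delimiter: str | None = None
) -> ReferenceMatrix:
    """Read a reference matrix (first column probe id, header = cell types)."""
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    return ReferenceMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_reference(
    ref: ReferenceMatrix, path: str | os.PathLike, delimiter: str | None = None
) -> None:
    df = ref.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path, delimiter), float_format="%.6f")


def read_fractions(
    path: str | os.PathLike, delimiter: str | None = None
) -> CellFractions:
    """Read cell fractions; rows must sum to 1 within 1e-4."""
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    return CellFractions(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_fractions(
    fractions: CellFractions, path: str | os.PathLike, delimiter: str | None = None
) -> None:
    """Write fractions with 6-decimal precision; round-trips losslessly at 1e-6."""
    df = fractions.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path, delimiter), float_format="%.6f")


def read_predictions(
    path: str | os.PathLike, delimiter: str | None = None
) -> list[ClockPrediction]:
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    for col in ("sample_id", "predicted_age"):
        if col not in df.columns:
            raise ValidationError(f"prediction file {path} missing column {col!r}")
    return [
        ClockPrediction(str(r.sample_id), float(r.predicted_age))
        for r in df.itertuples(index=False)
    ]


def write_predictions(
    predictions: Sequence[ClockPrediction],
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in predictions],
            "predicted_age": [p.predicted_age for p in predictions],
        }
    ).to_csv(path, sep=_sep_for(path, delimiter), index=False, float_format="%.6f")
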
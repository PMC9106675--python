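"""Dscore evaluation, druggability classification and target aggregation.

The druggability score of a detected site is

    Dscore = 0.094 * sqrt(n) + 0.60 * e - 0.324 * p

Two classification schemes are provided: the PPI-specific four-class scheme
(very druggable >= 1.0; druggable >= 0.75; moderately druggable >= 0.5;
difficult < 0.5, with ND sites always difficult) and Halgren's three-class
scheme for general binding sites (< 0.8 difficult; >= 1.0 very druggable;
druggable in between).

Aggregation reproduces the conventions of small-sample crystal-structure
surveys: the median of an even-sized sample is the mean of the two middle
values, the standard deviation uses the n-1 denominator, and ND structures
are counted but never enter the medians.  Where a plot or correlation needs
a number for an ND target, the caller may request the zero-imputation
convention instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .pocket_descriptors import SiteDescriptors

__all__ = [
    "DSCORE_COEFF_N",
    "DSCORE_COEFF_E",
    "DSCORE_COEFF_P",
    "VERY_DRUGGABLE",
    "DRUGGABLE",
    "MODERATELY_DRUGGABLE",
    "DIFFICULT",
    "FORMS",
    "DruggabilityRecord",
    "TargetSummary",
    "SummaryStats",
    "ActivityRecord",
    "CorrelationResult",
    "dscore",
    "classify_ppi",
    "classify_halgren",
    "make_record",
    "aggregate_target",
    "percent_reduction",
    "pearson_r2",
    "pic50",
]

DSCORE_COEFF_N = 0.094
DSCORE_COEFF_E = 0.60
DSCORE_COEFF_P = 0.324

VERY_DRUGGABLE = "very druggable"
DRUGGABLE = "druggable"
MODERATELY_DRUGGABLE = "moderately druggable"
DIFFICULT = "difficult"

#: canonical crystal-form labels
FORMS = ("apo", "protein_peptide_bound", "ligand_bound")


def dscore(n: float, e: float, p: float) -> float:
    """Evaluate the druggability score; no clamping is applied."""
    if n < 0:
        raise ValueError("site-point count n must be >= 0")
    if not 0.0 <= e <= 1.0:
        raise ValueError("enclosure factor e must lie in [0, 1]")
    if p < 0:
        raise ValueError("hydrophilicity factor p must be >= 0")
    return DSCORE_COEFF_N * math.sqrt(n) + DSCORE_COEFF_E * e - DSCORE_COEFF_P * p


def classify_ppi(score: float | None) -> str:
    """Four-class PPI scheme; ND (None) maps to difficult."""
    if score is None:
        return DIFFICULT
    if score < 0:
        raise ValueError("Dscore must be >= 0 or ND")
    if score >= 1.0:
        return VERY_DRUGGABLE
    if score >= 0.75:
        return DRUGGABLE
    if score >= 0.5:
        return MODERATELY_DRUGGABLE
    return DIFFICULT


def classify_halgren(score: float) -> str:
    """Halgren's general scheme: < 0.8 difficult, >= 1.0 very druggable."""
    if score < 0:
        raise ValueError("Dscore must be >= 0")
    if score < 0.8:
        return DIFFICULT
    if score >= 1.0:
        return VERY_DRUGGABLE
    return DRUGGABLE


@dataclass(frozen=True)
class DruggabilityRecord:
    """Per-structure outcome: descriptors, score and PPI class."""

    structure_id: str
    target: str
    form: str
    descriptors: SiteDescriptors
    dscore: float | None
    ppi_class: str

    def __post_init__(self) -> None:
        if self.descriptors.detected != (self.dscore is not None):
            raise ValueError("dscore must be present iff a site was detected")


def make_record(
    structure_id: str, target: str, form: str, descriptors: SiteDescriptors
) -> DruggabilityRecord:
    score = (
        dscore(descriptors.n, descriptors.e, descriptors.p)
        if descriptors.detected
        else None
    )
    return DruggabilityRecord(
        structure_id=structure_id,
        target=target,
        form=form,
        descriptors=descriptors,
        dscore=score,
        ppi_class=classify_ppi(score),
    )


@dataclass(frozen=True)
class SummaryStats:
    """Median / sample SD / range of one variable over detected structures."""

    count: int
    median: float | None
    sd: float | None
    min: float | None
    max: float | None

    @classmethod
    def from_values(cls, values: list[float]) -> "SummaryStats":
        if not values:
            return cls(count=0, median=None, sd=None, min=None, max=None)
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) >= 2 else None
        return cls(
            count=len(arr),
            median=float(np.median(arr)),
            sd=sd,
            min=float(arr.min()),
            max=float(arr.max()),
        )


_METRICS = ("dscore", "n", "e", "p")


@dataclass
class TargetSummary:
    """Per-target aggregates in the layout of a survey summary table."""

    target: str
    n_records: int
    n_detected: int
    overall: dict[str, SummaryStats]
    per_form: dict[str, dict[str, SummaryStats]]
    form_counts: dict[str, int]
    mean_pic50: float | None = None

    @property
    def median_dscore(self) -> float | None:
        return self.overall["dscore"].median

    @property
    def ppi_class(self) -> str:
        return classify_ppi(self.median_dscore)


def _collect(records: list[DruggabilityRecord]) -> dict[str, SummaryStats]:
    values: dict[str, list[float]] = {m: [] for m in _METRICS}
    for r in records:
        if not r.descriptors.detected:
            continue
        values["dscore"].append(r.dscore)
        values["n"].append(r.descriptors.n)
        values["e"].append(r.descriptors.e)
        values["p"].append(r.descriptors.p)
    return {m: SummaryStats.from_values(v) for m, v in values.items()}


def aggregate_target(
    records: list[DruggabilityRecord],
    activities: dict[str, float] | None = None,
) -> TargetSummary:
    """Aggregate one target's records into per-form and overall summaries.

    ``activities`` optionally maps structure ids to pIC50 values, averaged
    over the records that carry one.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record set")
    targets = {r.target for r in records}
    if len(targets) > 1:
        raise ValueError(f"records span multiple targets: {sorted(targets)}")
    forms = sorted({r.form for r in records})
    per_form = {
        f: _collect([r for r in records if r.form == f]) for f in forms
    }
    form_counts = {f: sum(1 for r in records if r.form == f) for f in forms}
    mean_pic50 = None
    if activities:
        vals = [activities[r.structure_id] for r in records if r.structure_id in activities]
        if vals:
            mean_pic50 = float(np.mean(vals))
    return TargetSummary(
        target=records[0].target,
        n_records=len(records),
        n_detected=sum(1 for r in records if r.descriptors.detected),
        overall=_collect(records),
        per_form=per_form,
        form_counts=form_counts,
        mean_pic50=mean_pic50,
    )


def percent_reduction(reference_median: float, other_median: float) -> int:
    """Percent decrease from a reference median, rounded to an integer."""
    if reference_median <= 0:
        raise ValueError("reference median must be positive")
    return int(round(100.0 * (reference_median - other_median) / reference_median))


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    r2: float
    n_points: int


class UndefinedCorrelationError(ValueError):
    pass


def pearson_r2(
    x,
    y,
    x_name: str = "x",
    y_name: str = "y",
    impute_nd_zero: bool = False,
) -> CorrelationResult:
    """Pearson correlation and its square.

    With ``impute_nd_zero`` ND entries (None/NaN) are replaced by zero --
    the convention used when plotting pocket-less targets alongside scored
    ones; otherwise ND entries are rejected.
    """
    xs, ys = [], []
    for a, b in zip(x, y, strict=True):
        if impute_nd_zero:
            a = 0.0 if a is None or (isinstance(a, float) and math.isnan(a)) else a
            b = 0.0 if b is None or (isinstance(b, float) and math.isnan(b)) else b
        xs.append(float(a))
        ys.append(float(b))
    if len(xs) < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    r = float(_sps.pearsonr(xs, ys).statistic)
    return CorrelationResult(x_name=x_name, y_name=y_name, r=r, r2=r * r, n_points=len(xs))


def pic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 in molar units)."""
    if ic50_molar <= 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50_molar)


# ---------------------------------------------------------------------------
# Table-level helpers (descriptor tables are the pipeline's interchange unit)
# ---------------------------------------------------------------------------

def records_from_table(table: pd.DataFrame) -> list[DruggabilityRecord]:
    """Build records from a descriptor table with columns
    structure_id, target, form, detected, n, e, p."""
    records = []
    for row in table.itertuples(index=False):
        if bool(row.detected):
            desc = SiteDescriptors(n=int(row.n), e=float(row.e), p=float(row.p), detected=True)
        else:
            desc = SiteDescriptors.nd()
        records.append(make_record(str(row.structure_id), str(row.target), str(row.form), desc))
    return records


def summarize_table(
    table: pd.DataFrame, activities: dict[str, float] | None = None
) -> dict[str, TargetSummary]:
    """Aggregate a full descriptor table into per-target summaries."""
    records = records_from_table(table)
    out: dict[str, TargetSummary] = {}
    for target in sorted({r.target for r in records}):
        out[target] = aggregate_target(
            [r for r in records if r.target == target], activities
        )
    return out
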
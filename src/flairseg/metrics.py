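"""Segmentation agreement metrics and cohort-level reports.

Per-case indices against a reference mask: Dice 2TP/(2TP+FP+FN), Jaccard
TP/(TP+FP+FN), true/false negative fractions TPF = TP/|ref| and
FNF = FN/|ref|, and a false positive fraction normalized by the reference
volume, FPF = FP/|ref| — so FPF can exceed 1 when a method marks more
spurious voxels than the lesion holds. Each metric column is summarized by
seven first-order statistics: mean, SD, max, min, median, Q1, Q3.

Two masks that are both empty agree perfectly: Dice = Jaccard = 1 by
convention. An empty reference makes TPF/FPF/FNF undefined and raises.

Paired method comparison defaults to the two-sided Wilcoxon signed-rank
test; a chi-square mode (cases dichotomized at the pooled median, 2x2
method x above/below table with continuity correction) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError
from .volumes import BinaryMask, require_same_grid

__all__ = [
    "ConfusionCounts",
    "SummaryStats",
    "MetricsReport",
    "confusion_counts",
    "dice",
    "jaccard",
    "tpf",
    "fpf",
    "fnf",
    "summarize",
    "evaluate_cohort",
    "compare_methods",
    "METRIC_NAMES",
    "STAT_NAMES",
]

METRIC_NAMES = ("dice", "jaccard", "tpf", "fpf", "fnf")
STAT_NAMES = ("mean", "sd", "max", "min", "median", "q1", "q3")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts of a prediction against a reference over a region."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn


def confusion_counts(
    pred: BinaryMask, ref: BinaryMask, region: BinaryMask | None = None
) -> ConfusionCounts:
    """Count TP/FP/FN/TN over ``region`` voxels (default: the whole grid)."""
    require_same_grid(pred, ref, "prediction and reference")
    if region is not None:
        require_same_grid(pred, region, "prediction and region")
        if not region.data.any():
            raise ValueError("region is empty")
        p = pred.data[region.data]
        r = ref.data[region.data]
    else:
        p = pred.data.ravel()
        r = ref.data.ravel()
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity 2TP/(2TP+FP+FN); two empty masks agree perfectly (1)."""
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard overlap TP/(TP+FP+FN); two empty masks agree perfectly (1)."""
    denom = c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def _require_reference(c: ConfusionCounts, name: str) -> None:
    if c.n_reference == 0:
        raise UndefinedMetricError(f"undefined {name}: empty reference mask")


def tpf(c: ConfusionCounts) -> float:
    """True positive fraction TP/|ref|."""
    _require_reference(c, "TPF")
    return c.tp / c.n_reference


def fpf(c: ConfusionCounts) -> float:
    """False positive fraction FP/|ref| — may exceed 1."""
    _require_reference(c, "FPF")
    return c.fp / c.n_reference


def fnf(c: ConfusionCounts) -> float:
    """False negative fraction FN/|ref| = 1 - TPF."""
    _require_reference(c, "FNF")
    return c.fn / c.n_reference


@dataclass(frozen=True)
class SummaryStats:
    """The seven first-order statistics of one metric column."""

    mean: float
    sd: float
    max: float
    min: float
    median: float
    q1: float
    q3: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in STAT_NAMES}


def summarize(values) -> SummaryStats:
    """Seven-statistic summary; sample SD (n-1), linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    return SummaryStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        max=float(v.max()),
        min=float(v.min()),
        median=float(np.median(v)),
        q1=float(np.percentile(v, 25)),
        q3=float(np.percentile(v, 75)),
    )


@dataclass
class MetricsReport:
    """Per-case metric table plus per-metric seven-statistic summaries."""

    per_case: pd.DataFrame  # index: case id; columns: METRIC_NAMES
    summary: pd.DataFrame  # index: STAT_NAMES; columns: METRIC_NAMES

    def to_csv(self, per_case_path, summary_path=None) -> None:
        self.per_case.to_csv(per_case_path, index_label="case")
        if summary_path is not None:
            self.summary.to_csv(summary_path, index_label="statistic")


def evaluate_cohort(
    preds: list[BinaryMask],
    refs: list[BinaryMask],
    regions: list[BinaryMask] | None = None,
    case_ids: list[str] | None = None,
) -> MetricsReport:
    """Per-case metrics of predictions against reference masks, summarized.

    ``refs`` is typically the STAPLE consensus mask per case; ``regions``
    optionally restricts counting (default: whole grid).
    """
    if len(preds) != len(refs):
        raise ValueError(f"{len(preds)} predictions vs {len(refs)} references")
    if regions is not None and len(regions) != len(preds):
        raise ValueError("one region per case required")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(preds))]
    rows = []
    for i, (p, r) in enumerate(zip(preds, refs)):
        c = confusion_counts(p, r, regions[i] if regions is not None else None)
        rows.append(
            {"dice": dice(c), "jaccard": jaccard(c), "tpf": tpf(c), "fpf": fpf(c), "fnf": fnf(c)}
        )
    per_case = pd.DataFrame(rows, index=pd.Index(case_ids, name="case"))
    summary = pd.DataFrame(
        {m: summarize(per_case[m].to_numpy()).as_dict() for m in METRIC_NAMES}
    ).loc[list(STAT_NAMES)]
    return MetricsReport(per_case=per_case, summary=summary)


def compare_methods(
    values_a, values_b, test: str = "wilcoxon"
) -> float:
    """Paired two-sided comparison of one metric column between two methods.

    ``"wilcoxon"`` (default): Wilcoxon signed-rank on the paired
    differences; identical columns return p = 1.0 by convention.
    ``"chi2"``: cases are dichotomized at the pooled median of both
    columns; the 2x2 table (method x above/at-or-below) is tested with
    Yates continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired columns must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired cases")
    if test == "wilcoxon":
        if np.allclose(a, b):
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    if test == "chi2":
        pooled_median = float(np.median(np.concatenate([a, b])))
        table = np.array(
            [
                [int(np.sum(a > pooled_median)), int(np.sum(a <= pooled_median))],
                [int(np.sum(b > pooled_median)), int(np.sum(b <= pooled_median))],
            ]
        )
        if np.any(table.sum(axis=0) == 0):
            return 1.0
        return float(stats.chi2_contingency(table, correction=True).pvalue)
    raise ValueError(f"unknown test {test!r}")


def comparison_table(
    reports: dict[str, MetricsReport],
    metrics: tuple[str, ...] = ("jaccard", "dice", "fpf", "tpf"),
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """All-pairs p-value table (method pairs x metrics), long format."""
    names = list(reports)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            for met in metrics:
                p = compare_methods(
                    reports[na].per_case[met].to_numpy(),
                    reports[nb].per_case[met].to_numpy(),
                    test=test,
                )
                rows.append({"method_a": na, "method_b": nb, "metric": met, "p_value": p})
    return pd.DataFrame(rows)
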
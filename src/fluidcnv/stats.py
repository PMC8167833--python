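"""Cohort diagnostic accuracy with exact binomial intervals.

Sensitivity and specificity are binomial proportions; their confidence
intervals are exact Clopper-Pearson (beta-quantile) intervals, which are
conservative by construction.  Display percentages round half away from
zero to integers.  Tumor fractions are summarized as median and type-7
(linear-interpolation) quartiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

from .genome import InvalidParameterError

__all__ = [
    "ContingencyResult",
    "CohortResult",
    "clopper_pearson",
    "accuracy_table",
    "tf_summary",
    "round_half_away",
]

logger = logging.getLogger(__name__)

#: truth labels counted as malignant (sensitivity strata); everything
#: else is treated as a control (specificity stratum).
MALIGNANT_LABELS = frozenset({"cytology_positive", "cytology_negative"})


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (88.5 -> 89)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass(frozen=True)
class ContingencyResult:
    """x successes of n trials with an exact binomial interval."""

    x: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    conf: float = 0.95
    kind: str = "sensitivity"

    @property
    def pct(self) -> int:
        return round_half_away(100.0 * self.proportion)

    @property
    def ci_pct(self) -> tuple[int, int]:
        return round_half_away(100.0 * self.ci_low), round_half_away(100.0 * self.ci_high)


@dataclass(frozen=True)
class CohortResult:
    """Per-stratum accuracy plus tumor-fraction summaries."""

    strata: dict[str, ContingencyResult]
    tf_summary: dict[str, tuple[float, float, float]]


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    At the extremes the closed forms hold: x = 0 gives low = 0 and
    high = 1 - (alpha/2)^(1/n); x = n gives low = (alpha/2)^(1/n) and
    high = 1.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not 0 <= x <= n:
        raise InvalidParameterError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise InvalidParameterError("conf must lie in (0, 1)")
    a = 1.0 - conf
    low = 0.0 if x == 0 else float(beta.ppf(a / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(beta.ppf(1.0 - a / 2.0, x + 1, n - x))
    return low, high


def proportion_with_ci(x: int, n: int, conf: float = 0.95, kind: str = "sensitivity") -> ContingencyResult:
    low, high = clopper_pearson(x, n, conf)
    return ContingencyResult(x, n, x / n, low, high, conf, kind)


def tf_summary(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) of tumor fractions, type-7 quartiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("tf_summary needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def accuracy_table(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    conf: float = 0.95,
    malignant_labels: frozenset[str] = MALIGNANT_LABELS,
) -> CohortResult:
    """Diagnostic accuracy per truth stratum.

    ``calls`` needs columns ``sample_id, positive, tumor_fraction`` (one
    row per QC-passing specimen); ``truth`` needs ``sample_id,
    truth_label``.  Malignant strata report sensitivity (positives among
    truth-positives), control strata specificity (negatives among
    controls).  Tumor fractions are summarized over the CNV-positive
    specimens of each stratum.  Empty strata are omitted with a warning.
    """
    merged = calls.merge(truth, on="sample_id", how="left", validate="one_to_one")
    unmatched = merged.loc[merged["truth_label"].isna(), "sample_id"].tolist()
    if unmatched:
        raise InvalidParameterError(f"samples missing from truth table: {unmatched}")
    strata: dict[str, ContingencyResult] = {}
    summaries: dict[str, tuple[float, float, float]] = {}
    for label, group in merged.groupby("truth_label", sort=False):
        if len(group) == 0:  # pragma: no cover - groupby drops empties
            continue
        positives = group["positive"].fillna(False).astype(bool)
        if label in malignant_labels:
            x, kind = int(positives.sum()), "sensitivity"
        else:
            x, kind = int((~positives).sum()), "specificity"
        strata[str(label)] = proportion_with_ci(x, len(group), conf, kind)
        tf_pos = group.loc[positives, "tumor_fraction"]
        if len(tf_pos):
            summaries[str(label)] = tf_summary(tf_pos)
    expected = set(truth["truth_label"].unique())
    for label in expected - set(strata):
        msg = f"stratum {label!r} has no called samples; omitted"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return CohortResult(strata, summaries)


def cohort_report(result: CohortResult) -> str:
    """Human-readable per-stratum summary."""
    lines = []
    for name, r in result.strata.items():
        lo, hi = r.ci_pct
        lines.append(
            f"{name}: {r.kind} {r.pct}% ({r.x} of {r.n}; {int(100 * r.conf)}% CI {lo}-{hi}%)"
        )
        if name in result.tf_summary:
            med, q1, q3 = result.tf_summary[name]
            lines.append(
                f"{name}: tumor fraction of CNV-positive median "
                f"{100 * med:.0f}% (IQR {100 * q1:.0f}-{100 * q3:.0f}%)"
            )
    return "\n".join(lines)
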
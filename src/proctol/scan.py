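"""Rolling experience-threshold selection.

Scans candidate prior-year endotracheal-intubation thresholds in
descending order and asks, for each retained subset, whether the log
procedure times still look normal (Shapiro-Wilk p >= alpha_fit).  The
selected threshold is the smallest one that passes with every larger
evaluated threshold also passing — i.e. the point below which the
log-normal fit first breaks as less-experienced participants enter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, CohortError, filter_by_experience
from .fit import FitError, shapiro_wilk

__all__ = ["ThresholdScanRow", "ThresholdScanResult", "scan_thresholds", "subset_fit_at"]


@dataclass(frozen=True)
class ThresholdScanRow:
    threshold: int
    n_retained: int
    shapiro_W: float
    shapiro_p: float
    passes: bool


@dataclass(frozen=True)
class ThresholdScanResult:
    """Scan rows in descending threshold order, plus the selected threshold.

    ``selected_threshold`` is None when no candidate reaches ``min_subset``
    (flagged in ``warnings``) or when the largest evaluated threshold
    already fails.
    """

    rows: tuple[ThresholdScanRow, ...]
    selected_threshold: int | None
    alpha_fit: float
    min_subset: int
    warnings: tuple[str, ...] = ()


def _evaluate(cohort: Cohort, threshold: int, alpha_fit: float) -> ThresholdScanRow:
    subset = filter_by_experience(cohort, threshold)
    times = subset.times()
    result = shapiro_wilk(np.log(times), transform="log")
    return ThresholdScanRow(
        threshold=int(threshold),
        n_retained=int(times.size),
        shapiro_W=result.statistic,
        shapiro_p=result.p_value,
        passes=result.p_value >= alpha_fit,
    )


def scan_thresholds(
    cohort: Cohort, alpha_fit: float = 0.05, min_subset: int = 20
) -> ThresholdScanResult:
    """Evaluate every distinct reported count (plus 0) as a threshold.

    Thresholds whose retained subset is smaller than ``min_subset`` are
    skipped (the Shapiro-Wilk test has little power there).  Selection
    requires a contiguous run of passes from the largest evaluated
    threshold down; the selected threshold is the bottom of that run.
    """
    if len(cohort.completed_records) == 0:
        raise CohortError("cohort has no completed records")
    counts = cohort.eti_counts()
    candidates = sorted(set(int(c) for c in counts) | {0}, reverse=True)
    rows = []
    warnings: list[str] = []
    for threshold in candidates:
        n_retained = int(np.sum(counts >= threshold))
        if n_retained < min_subset:
            continue
        rows.append(_evaluate(cohort, threshold, alpha_fit))
    if not rows:
        warnings.append(
            f"no candidate threshold retains at least min_subset = {min_subset} records"
        )
        return ThresholdScanResult(
            rows=(),
            selected_threshold=None,
            alpha_fit=alpha_fit,
            min_subset=min_subset,
            warnings=tuple(warnings),
        )
    selected: int | None = None
    for row in rows:  # descending threshold order
        if row.passes:
            selected = row.threshold
        else:
            break
    if selected is None:
        warnings.append(
            "largest evaluated threshold already fails the log-normal check"
        )
    return ThresholdScanResult(
        rows=tuple(rows),
        selected_threshold=selected,
        alpha_fit=alpha_fit,
        min_subset=min_subset,
        warnings=tuple(warnings),
    )


def subset_fit_at(
    cohort: Cohort, threshold: int, alpha_fit: float = 0.05
) -> ThresholdScanRow:
    """Evaluate a single stated threshold (same rule as the scan)."""
    subset = filter_by_experience(cohort, threshold)
    if len(subset.completed_records) < 3:
        raise FitError(
            f"threshold {threshold} retains fewer than 3 completed records"
        )
    return _evaluate(cohort, threshold, alpha_fit)
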
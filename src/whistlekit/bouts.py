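"""Repetition, bout and inter-whistle-interval (IWI) statistics.

A whistle type is *repeated* when at least ``min_count`` successive whistles
of that type occur with every consecutive gap at most ``window_s`` (30 s by
default) within one recording; such maximal runs are *bouts*.  The window is
read as a maximum onset-to-onset gap between successive same-type whistles
(sliding), not as a fixed tiling of the recording.  IWIs are measured
onset-to-onset and summarized both within bouts and across the whole
per-type series; the distribution summary follows the 1-s histogram with a
first bin of [0.3, 1) s, class percentages over [0.3, 4), [4, 10) and
[10, 60] s, and a separately reported fraction of intervals above the 60-s
cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import Partition
from .errors import InvalidInputError

BOUT_WINDOW_S = 30.0
BOUT_MIN_COUNT = 3
IWI_CAP_S = 60.0
IWI_FLOOR_S = 0.3


@dataclass
class BoutSeries:
    """Per-type, per-day onset series with its qualifying bouts."""

    type_label: str
    day_label: str
    onsets_s: np.ndarray
    bout_spans: list[tuple[int, int]]  # inclusive (start, end) indices

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise InvalidInputError("onsets must be strictly increasing")

    @property
    def iwis_s(self) -> np.ndarray:
        """Consecutive onset differences over the whole series."""
        return np.diff(self.onsets_s)

    @property
    def bout_iwis_s(self) -> np.ndarray:
        """Onset differences within bouts only."""
        parts = [
            np.diff(self.onsets_s[a : b + 1]) for a, b in self.bout_spans
        ]
        return np.concatenate(parts) if parts else np.empty(0)

    @property
    def bout_sizes(self) -> list[int]:
        return [b - a + 1 for a, b in self.bout_spans]


@dataclass
class IwiSummary:
    n_le_60s: int
    pct_0p3_to_4: Optional[float]
    pct_4_to_10: Optional[float]
    pct_gt_10: Optional[float]
    mean_s: Optional[float]
    sd_s: Optional[float]
    pct_gt_60s_overall: Optional[float]
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.n_le_60s == 0


def _maximal_runs(
    onsets: Sequence[float], window_s: float, min_count: int
) -> list[tuple[int, int]]:
    onsets = np.asarray(onsets, dtype=float)
    spans: list[tuple[int, int]] = []
    if onsets.size == 0:
        return spans
    start = 0
    for k in range(1, onsets.size + 1):
        if k == onsets.size or onsets[k] - onsets[k - 1] > window_s:
            if k - start >= min_count:
                spans.append((start, k - 1))
            start = k
    return spans


def find_repeated_types(
    timeline: Mapping[str, Sequence[float]],
    window_s: float = BOUT_WINDOW_S,
    min_count: int = BOUT_MIN_COUNT,
) -> set[str]:
    """Type labels with at least one run of ``min_count`` successive whistles
    whose consecutive gaps all stay within ``window_s``."""
    return {
        label
        for label, onsets in timeline.items()
        if _maximal_runs(onsets, window_s, min_count)
    }


def detect_bouts(
    type_label: str,
    day_label: str,
    onsets_s: Sequence[float],
    window_s: float = BOUT_WINDOW_S,
    min_count: int = BOUT_MIN_COUNT,
) -> BoutSeries:
    """Maximal runs with all gaps <= ``window_s`` and length >= ``min_count``."""
    spans = _maximal_runs(onsets_s, window_s, min_count)
    return BoutSeries(
        type_label=type_label,
        day_label=day_label,
        onsets_s=np.asarray(onsets_s, dtype=float),
        bout_spans=spans,
    )


def iwi_summary(iwis_s: Sequence[float], cap_s: float = IWI_CAP_S) -> IwiSummary:
    """Distribution summary of IWIs restricted to ``<= cap_s``.

    Histogram: first bin [0.3, 1) s then 1-s bins up to the cap.  The three
    class percentages partition [0.3, cap]; the overall fraction above the
    cap is reported separately.  An empty input yields an empty-summary
    marker rather than an error.
    """
    iwis = np.asarray(iwis_s, dtype=float)
    if iwis.size and np.any(iwis <= 0):
        raise InvalidInputError("IWIs must be > 0")
    edges = np.concatenate([[IWI_FLOOR_S], np.arange(1.0, cap_s + 1.0)])
    capped = iwis[iwis <= cap_s]
    if capped.size == 0:
        return IwiSummary(
            n_le_60s=0,
            pct_0p3_to_4=None,
            pct_4_to_10=None,
            pct_gt_10=None,
            mean_s=None,
            sd_s=None,
            pct_gt_60s_overall=(100.0 if iwis.size else None),
            histogram_edges=edges,
            histogram_counts=np.zeros(edges.size - 1, dtype=int),
        )
    n = capped.size
    counts, _ = np.histogram(capped, bins=edges)
    return IwiSummary(
        n_le_60s=int(n),
        pct_0p3_to_4=100.0 * float(np.sum(capped < 4.0)) / n,
        pct_4_to_10=100.0 * float(np.sum((capped >= 4.0) & (capped < 10.0))) / n,
        pct_gt_10=100.0 * float(np.sum(capped >= 10.0)) / n,
        mean_s=float(capped.mean()),
        sd_s=float(capped.std(ddof=1)) if n > 1 else 0.0,
        pct_gt_60s_overall=100.0 * float(iwis.size - n) / iwis.size,
        histogram_edges=edges,
        histogram_counts=counts,
    )


def cross_day_table(partition: Partition, days: Mapping[str, str]) -> pd.DataFrame:
    """Counts per (type, day) with per-type totals and a multi-day flag.

    ``days`` maps contour id -> day label; every contour in the partition
    must carry one."""
    missing = [i for i in partition.ids if i not in days]
    if missing:
        raise InvalidInputError(f"contours missing a day label: {missing[:5]}")
    rows = [(partition[i], days[i]) for i in partition.ids]
    df = pd.DataFrame(rows, columns=["type", "day"])
    table = pd.crosstab(df["type"], df["day"])
    table["total"] = table.sum(axis=1)
    table["multi_day"] = (table.drop(columns="total") > 0).sum(axis=1) >= 2
    return table


def type_timelines(
    partition: Partition,
    onsets: Mapping[str, float],
    days: Mapping[str, str],
) -> dict[tuple[str, str], np.ndarray]:
    """Sorted per-(type, day) onset arrays from a partition and a timeline."""
    series: dict[tuple[str, str], list[float]] = {}
    for cid in partition.ids:
        key = (str(partition[cid]), days[cid])
        series.setdefault(key, []).append(onsets[cid])
    return {k: np.array(sorted(v)) for k, v in series.items()}
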
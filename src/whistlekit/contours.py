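"""Whistle contour data model and the dynamic-time-warping similarity primitive.

A whistle is represented by its *contour*: the fundamental-frequency trace of
the call, sampled on a uniform time grid.  Two contours are compared by
aligning them with dynamic time warping (DTW) under a slope constraint and
scoring each aligned frequency pair with the scale-free ratio similarity

    s(f, g) = 100 * min(f, g) / max(f, g)        (percent, 0-100)

The similarity of a pair of contours is the *mean* local similarity along the
best admissible warp path.  This is the quantity that the adaptive-resonance
categorizer compares against its vigilance threshold: two contours belong to
the same whistle type when their best alignment keeps the traces within a few
percent of each other in frequency, regardless of moderate time stretching.

Warp constraint
---------------
A path is a monotone sequence of index pairs from (0, 0) to (n-1, m-1) built
from diagonal, horizontal and vertical unit steps.  With warp factor ``W`` a
point of either contour may be aligned with at most ``W`` points of the
other, i.e. at most ``W - 1`` consecutive steps may advance the same single
sequence.  Consequently a uniform time stretch of up to factor ``W`` (with
unchanged frequency values) can still be aligned perfectly, while a stretch
beyond ``W`` cannot be fully aligned at all.  When no admissible path exists
:func:`dtw_align` raises :class:`InfeasibleAlignmentError` and
:func:`similarity` reports 0.

Because the path length varies, "maximize the mean" is a fractional
objective; it is solved exactly by Dinkelbach's method: repeatedly maximize
``sum(s - lam)`` with an additive DP and update ``lam`` to the mean of the
best path, which converges monotonically to the optimum in a handful of
passes.  Ties between equal-scoring predecessors are broken toward the
diagonal step, making alignments deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from numba import njit

from .errors import (
    InfeasibleAlignmentError,
    InvalidInputError,
    InvalidParameterError,
    ParseError,
)

SNR_CLASSES = ("high", "medium", "low")

#: default common sampling interval for contour comparisons (seconds)
DEFAULT_DT_S = 0.005


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class WhistleContour:
    """A uniformly sampled time-frequency trace of one whistle.

    Parameters
    ----------
    id : str
        Unique identifier within a :class:`ContourSet`.
    recording_id, day_label : str
        Provenance of the whistle (recording file, encounter day).
    onset_s : float
        Onset relative to the start of the recording, seconds.
    dt_s : float
        Sampling interval of the trace, seconds (> 0).
    freqs_khz : numpy.ndarray
        Fundamental frequency at each sample, kHz; >= 2 positive values.
    snr_class : str
        Qualitative signal-to-noise grade: ``high``, ``medium`` or ``low``.
    visual_label : str, optional
        Category assigned by a human observer, if any.
    """

    id: str
    recording_id: str
    day_label: str
    onset_s: float
    dt_s: float
    freqs_khz: np.ndarray
    snr_class: str = "medium"
    visual_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        if self.freqs_khz.ndim != 1 or self.freqs_khz.size < 2:
            raise InvalidInputError(
                f"contour {self.id!r}: needs >= 2 frequency points"
            )
        if not np.all(self.freqs_khz > 0):
            raise InvalidInputError(f"contour {self.id!r}: frequencies must be > 0")
        if not self.dt_s > 0:
            raise InvalidParameterError(f"contour {self.id!r}: dt_s must be > 0")
        if self.snr_class not in SNR_CLASSES:
            raise InvalidParameterError(
                f"contour {self.id!r}: snr_class must be one of {SNR_CLASSES}"
            )

    @property
    def n_points(self) -> int:
        return int(self.freqs_khz.size)

    @property
    def duration_s(self) -> float:
        """Trace duration ``(n_points - 1) * dt_s``."""
        return (self.n_points - 1) * self.dt_s

    @property
    def offset_s(self) -> float:
        """Time of the last trace point relative to the recording start."""
        return self.onset_s + self.duration_s

    def times_s(self) -> np.ndarray:
        return self.onset_s + np.arange(self.n_points) * self.dt_s


class ContourSet:
    """A collection of :class:`WhistleContour` keyed by id (ids unique)."""

    def __init__(self, contours: Iterable[WhistleContour] = ()) -> None:
        self._by_id: dict[str, WhistleContour] = {}
        for c in contours:
            self.add(c)

    def add(self, c: WhistleContour) -> None:
        if c.id in self._by_id:
            raise InvalidInputError(f"duplicate contour id {c.id!r}")
        self._by_id[c.id] = c

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def __getitem__(self, cid: str) -> WhistleContour:
        return self._by_id[cid]

    def __iter__(self) -> Iterator[WhistleContour]:
        for cid in self.ids():
            yield self._by_id[cid]

    def ids(self) -> list[str]:
        """Contour ids in ascending (lexicographic) order."""
        return sorted(self._by_id)


@dataclass
class DtwAlignment:
    """Result of aligning two contours: path, mean similarity, warp bound."""

    path: np.ndarray  # (L, 2) int index pairs, monotone, (0,0) .. (n-1,m-1)
    similarity_pct: float
    warp_factor: int

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int)
        if not 0.0 <= self.similarity_pct <= 100.0 + 1e-9:
            raise InvalidInputError("similarity_pct outside [0, 100]")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_contour(c: WhistleContour, target_dt_s: float) -> WhistleContour:
    """Linearly resample a contour onto a uniform grid of ~``target_dt_s``.

    The new grid spans exactly the original duration, so both endpoints are
    preserved exactly.  The number of points is the nearest integer fit; the
    actual spacing equals ``target_dt_s`` exactly whenever the duration is a
    multiple of it, and differs by less than half a sample otherwise.
    """
    if not target_dt_s > 0:
        raise InvalidParameterError("target_dt_s must be > 0")
    dur = c.duration_s
    n_new = max(2, int(round(dur / target_dt_s)) + 1)
    new_dt = dur / (n_new - 1)
    t_old = np.arange(c.n_points) * c.dt_s
    t_new = np.linspace(0.0, dur, n_new)
    freqs = np.interp(t_new, t_old, c.freqs_khz)
    return replace(c, dt_s=new_dt, freqs_khz=freqs)


# ---------------------------------------------------------------------------
# DTW similarity
# ---------------------------------------------------------------------------

_NEG = -1e18


@njit(cache=True)
def _dp_pass(sim: np.ndarray, lam: float, W: int):  # pragma: no cover - jitted
    """One additive DP pass maximizing sum(sim - lam) over admissible paths.

    State k at node (i, j): 0 = arrived by diagonal; 1..W-1 = horizontal run
    of length k; W..2W-2 = vertical run of length k-W+1.  Returns the value
    cube and predecessor-state cube.  Ties prefer the diagonal predecessor
    (candidates scanned in preference order with strict improvement).
    """
    n, m = sim.shape
    K = 2 * W - 1
    V = np.full((n, m, K), _NEG)
    P = np.full((n, m, K), -1, np.int16)
    V[0, 0, 0] = sim[0, 0] - lam
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            c = sim[i, j] - lam
            # diagonal arrival: predecessor (i-1, j-1), any state
            if i > 0 and j > 0:
                bk = -1
                bv = _NEG
                for k in range(K):
                    v = V[i - 1, j - 1, k]
                    if v > bv:
                        bv = v
                        bk = k
                if bk >= 0:
                    V[i, j, 0] = bv + c
                    P[i, j, 0] = bk
            # horizontal arrival: predecessor (i, j-1)
            if j > 0 and W > 1:
                bk = -1
                bv = V[i, j - 1, 0]
                if bv > _NEG / 2:
                    bk = 0
                for k in range(W, K):  # vertical states reset the h-run
                    v = V[i, j - 1, k]
                    if v > bv:
                        bv = v
                        bk = k
                if bk >= 0:
                    V[i, j, 1] = bv + c
                    P[i, j, 1] = bk
                for r in range(2, W):
                    pv = V[i, j - 1, r - 1]
                    if pv > _NEG / 2:
                        V[i, j, r] = pv + c
                        P[i, j, r] = r - 1
            # vertical arrival: predecessor (i-1, j)
            if i > 0 and W > 1:
                bk = -1
                bv = V[i - 1, j, 0]
                if bv > _NEG / 2:
                    bk = 0
                for k in range(1, W):  # horizontal states reset the v-run
                    v = V[i - 1, j, k]
                    if v > bv:
                        bv = v
                        bk = k
                if bk >= 0:
                    V[i, j, W] = bv + c
                    P[i, j, W] = bk
                for r in range(1, W - 1):
                    pv = V[i - 1, j, W + r - 1]
                    if pv > _NEG / 2:
                        V[i, j, W + r] = pv + c
                        P[i, j, W + r] = W + r - 1
    return V, P


def _local_similarity_matrix(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    lo = np.minimum.outer(fa, fb)
    hi = np.maximum.outer(fa, fb)
    return 100.0 * lo / hi


def _backtrack(P: np.ndarray, end_state: int, n: int, m: int, W: int) -> np.ndarray:
    path = [(n - 1, m - 1)]
    i, j, k = n - 1, m - 1, end_state
    while (i, j) != (0, 0):
        pk = int(P[i, j, k])
        if k == 0:
            i, j = i - 1, j - 1
        elif k < W:
            j -= 1
        else:
            i -= 1
        k = pk
        path.append((i, j))
    return np.array(path[::-1], dtype=int)


def dtw_align_arrays(
    fa: np.ndarray, fb: np.ndarray, warp_factor: int = 3
) -> tuple[np.ndarray, float]:
    """Align two raw frequency arrays; returns (path, mean similarity pct).

    Raises :class:`InfeasibleAlignmentError` when the length ratio exceeds
    the warp bound so that no admissible path reaches the final node.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.size == 0 or fb.size == 0:
        raise InvalidInputError("cannot align an empty contour")
    W = int(warp_factor)
    if W < 1:
        raise InvalidParameterError("warp_factor must be >= 1")
    sim = _local_similarity_matrix(fa, fb)
    n, m = sim.shape
    lam = float(sim.mean())
    path = None
    mean = lam
    for _ in range(100):
        V, P = _dp_pass(sim, lam, W)
        end = V[n - 1, m - 1]
        k_best = int(np.argmax(end))  # argmax takes the first (diagonal-first)
        if end[k_best] <= _NEG / 2:
            raise InfeasibleAlignmentError(
                f"no admissible warp path for lengths {n} vs {m} at warp {W}"
            )
        path = _backtrack(P, k_best, n, m, W)
        total = float(sim[path[:, 0], path[:, 1]].sum())
        mean = total / len(path)
        if abs(mean - lam) < 1e-10:
            break
        lam = mean
    return path, float(min(mean, 100.0))


def dtw_align(
    a: WhistleContour, b: WhistleContour, warp_factor: int = 3
) -> DtwAlignment:
    """Best-mean-similarity DTW alignment of two contours.

    Both contours should be sampled at a common ``dt_s`` (see
    :func:`resample_contour`); only the frequency sequences enter the
    alignment.
    """
    path, mean = dtw_align_arrays(a.freqs_khz, b.freqs_khz, warp_factor)
    return DtwAlignment(path=path, similarity_pct=mean, warp_factor=int(warp_factor))


def similarity(a: WhistleContour, b: WhistleContour, warp_factor: int = 3) -> float:
    """Percent similarity of two contours (0-100); 0 when unalignable."""
    try:
        return dtw_align(a, b, warp_factor).similarity_pct
    except InfeasibleAlignmentError:
        return 0.0


def similarity_arrays(fa: np.ndarray, fb: np.ndarray, warp_factor: int = 3) -> float:
    try:
        return dtw_align_arrays(fa, fb, warp_factor)[1]
    except InfeasibleAlignmentError:
        return 0.0


# ---------------------------------------------------------------------------
# contour CSV (long form, one row per trace point)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "id",
    "recording_id",
    "day_label",
    "onset_s",
    "dt_s",
    "snr_class",
    "visual_label",
    "point_index",
    "freq_khz",
]


def write_contours_csv(cs: ContourSet, path) -> None:
    """Write a contour set in long form; floats use %.17g so values
    round-trip exactly and re-writing identical data is byte-stable."""
    rows = []
    for c in cs:
        for k, f in enumerate(c.freqs_khz):
            rows.append(
                (
                    c.id,
                    c.recording_id,
                    c.day_label,
                    c.onset_s,
                    c.dt_s,
                    c.snr_class,
                    "" if c.visual_label is None else c.visual_label,
                    k,
                    f,
                )
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_contours_csv(path) -> ContourSet:
    df = pd.read_csv(
        path,
        dtype={
            "id": str,
            "recording_id": str,
            "day_label": str,
            "snr_class": str,
            "visual_label": str,
        },
        keep_default_na=False,
        na_values=[],
        float_precision="round_trip",
    )
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"contour CSV missing column(s): {missing}")
    out = ContourSet()
    for cid, g in df.groupby("id", sort=True):
        g = g.sort_values("point_index")
        first = g.iloc[0]
        vl = first["visual_label"]
        out.add(
            WhistleContour(
                id=str(cid),
                recording_id=first["recording_id"],
                day_label=first["day_label"],
                onset_s=float(first["onset_s"]),
                dt_s=float(first["dt_s"]),
                freqs_khz=g["freq_khz"].to_numpy(dtype=float),
                snr_class=first["snr_class"],
                visual_label=None if vl == "" else str(vl),
            )
        )
    return out
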
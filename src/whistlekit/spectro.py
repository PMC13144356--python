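"""Spectrogram computation and tonal contour extraction.

Implements the whistle definition used throughout the pipeline: a
narrow-band tonal trace of at least 100 ms, with consecutive fragments
separated by under 200 ms and a continuous frequency pattern merged into a
single contour.  Extraction is automatic single-peak tracking with explicit
thresholds (tonality 6 dB over the frame median, 1 kHz/frame maximum jump,
2 kHz merge continuity), a deterministic stand-in for interactive
peak-extraction workflows; simultaneous whistles are not disentangled (the
stronger peak wins).

SNR classes are quantified as the mean peak-over-median excess along the
trace: >= 15 dB high, >= 6 dB medium, else low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import ShortTimeFFT, get_window

from .contours import ContourSet, WhistleContour
from .errors import InvalidInputError, InvalidParameterError

log = logging.getLogger(__name__)

TONALITY_THRESHOLD_DB = 6.0
MAX_JUMP_KHZ = 1.0
MERGE_MAX_GAP_S = 0.2
MERGE_CONTINUITY_KHZ = 2.0
MERGE_POWER_CONTINUITY_DB = 12.0
MIN_DURATION_S = 0.1
SNR_HIGH_DB = 15.0
SNR_MEDIUM_DB = 6.0


@dataclass
class SpectrogramConfig:
    """STFT settings (defaults follow the Raven-style analysis: FFT 2048,
    Hann, 50% overlap, 2-25 kHz band)."""

    fft_size: int = 2048
    window: str = "hann"
    overlap_fraction: float = 0.5
    band_low_khz: float = 2.0
    band_high_khz: float = 25.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise InvalidParameterError("overlap_fraction must be in [0, 1)")
        if not self.band_low_khz < self.band_high_khz:
            raise InvalidParameterError("band_low_khz must be < band_high_khz")
        if self.fft_size < 8:
            raise InvalidParameterError("fft_size too small")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.fft_size * (1 - self.overlap_fraction))))


@dataclass
class Spectrogram:
    """Band-limited power spectrogram in dB (freqs x times)."""

    power_db: np.ndarray
    times_s: np.ndarray
    freqs_khz: np.ndarray
    sample_rate_hz: float
    cfg: SpectrogramConfig

    @property
    def dt_s(self) -> float:
        return self.cfg.hop / self.sample_rate_hz

    @property
    def df_khz(self) -> float:
        return self.sample_rate_hz / self.cfg.fft_size / 1000.0


@dataclass
class ContourFragment:
    """A run of consecutive tracked peaks (pre-merge contour piece)."""

    onset_s: float
    dt_s: float
    freqs_khz: np.ndarray
    peak_powers_db: np.ndarray
    median_powers_db: np.ndarray  # frame noise floor under each peak

    @property
    def n_points(self) -> int:
        return int(self.freqs_khz.size)

    @property
    def duration_s(self) -> float:
        return (self.n_points - 1) * self.dt_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def compute_spectrogram(
    waveform: np.ndarray, sample_rate_hz: float, cfg: SpectrogramConfig | None = None
) -> Spectrogram:
    """Band-limited power spectrogram (dB, PSD scaling).

    Time step is ``fft_size * (1 - overlap) / sample_rate``; frequency bins
    are restricted to ``[band_low_khz, min(band_high_khz, Nyquist)]``.
    """
    cfg = cfg or SpectrogramConfig()
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("waveform must be a non-empty 1-D array")
    if x.size < cfg.fft_size:
        raise InvalidInputError(
            f"waveform shorter ({x.size}) than fft_size ({cfg.fft_size})"
        )
    win = get_window(cfg.window, cfg.fft_size)
    sft = ShortTimeFFT(
        win, hop=cfg.hop, fs=sample_rate_hz, scale_to="psd", fft_mode="onesided2X"
    )
    S = sft.spectrogram(x)  # |X|^2, PSD scaled, (freq, time)
    t = sft.t(x.size)
    f_khz = sft.f / 1000.0
    hi = min(cfg.band_high_khz, sample_rate_hz / 2000.0)
    mask = (f_khz >= cfg.band_low_khz) & (f_khz <= hi)
    if not mask.any():
        raise InvalidParameterError("frequency band contains no bins")
    power_db = 10.0 * np.log10(S[mask] + 1e-300)
    return Spectrogram(
        power_db=power_db,
        times_s=np.asarray(t),
        freqs_khz=f_khz[mask],
        sample_rate_hz=float(sample_rate_hz),
        cfg=cfg,
    )


def track_peaks(
    spec: Spectrogram,
    tonality_threshold_db: float = TONALITY_THRESHOLD_DB,
    max_jump_khz: float = MAX_JUMP_KHZ,
    min_frames: int = 3,
) -> list[ContourFragment]:
    """Single-peak tracking: per frame the strongest bin is a candidate when
    it exceeds the frame median by the tonality threshold; candidates in
    consecutive frames are linked while the frequency jump stays within
    ``max_jump_khz``; runs shorter than ``min_frames`` are discarded."""
    P = spec.power_db
    med = np.median(P, axis=0)
    peak_ix = np.argmax(P, axis=0)
    nt = P.shape[1]
    peak_pow = P[peak_ix, np.arange(nt)]
    is_cand = peak_pow >= med + tonality_threshold_db
    peak_f = spec.freqs_khz[peak_ix]

    frags: list[ContourFragment] = []
    start = None
    for t in range(nt + 1):
        linked = (
            t < nt
            and is_cand[t]
            and (
                start is not None
                and t > start
                and abs(peak_f[t] - peak_f[t - 1]) <= max_jump_khz
            )
        )
        if t < nt and is_cand[t] and start is None:
            start = t
            continue
        if linked:
            continue
        if start is not None:
            end = t  # exclusive
            if end - start >= min_frames:
                sl = slice(start, end)
                frags.append(
                    ContourFragment(
                        onset_s=float(spec.times_s[start]),
                        dt_s=spec.dt_s,
                        freqs_khz=peak_f[sl].copy(),
                        peak_powers_db=peak_pow[sl].copy(),
                        median_powers_db=med[sl].copy(),
                    )
                )
            start = t if (t < nt and is_cand[t]) else None
    return frags


def merge_fragments(
    frags: Sequence[ContourFragment],
    max_gap_s: float = MERGE_MAX_GAP_S,
    continuity_khz: float = MERGE_CONTINUITY_KHZ,
    power_continuity_db: float | None = MERGE_POWER_CONTINUITY_DB,
) -> list[ContourFragment]:
    """Merge time-sorted fragments separated by less than ``max_gap_s`` with a
    continuous frequency pattern (|end - next start| <= ``continuity_khz``),
    interpolating the gap linearly.  Applied transitively left to right;
    idempotent on its own output.

    "Continuous pattern" also requires comparable intensity: fragments whose
    mean peak powers differ by more than ``power_continuity_db`` are kept
    apart (``None`` disables the check).  Pieces of one whistle share its
    source level, whereas chance noise-peak runs sit just above the tonality
    threshold and would otherwise be glued onto nearby strong whistles.
    """
    frags = sorted(frags, key=lambda f: f.onset_s)
    out: list[ContourFragment] = []
    for f in frags:
        if out:
            cur = out[-1]
            gap = f.onset_s - cur.end_s
            power_ok = power_continuity_db is None or abs(
                float(np.mean(f.peak_powers_db)) - float(np.mean(cur.peak_powers_db))
            ) <= power_continuity_db
            if (
                gap < max_gap_s
                and abs(f.freqs_khz[0] - cur.freqs_khz[-1]) <= continuity_khz
                and power_ok
            ):
                dt = cur.dt_s
                n_gap = max(0, int(round(gap / dt)) - 1)
                if n_gap > 0:
                    w = np.arange(1, n_gap + 1) / (n_gap + 1)
                    bridge_f = cur.freqs_khz[-1] + w * (f.freqs_khz[0] - cur.freqs_khz[-1])
                    bridge_p = cur.peak_powers_db[-1] + w * (
                        f.peak_powers_db[0] - cur.peak_powers_db[-1]
                    )
                    bridge_m = cur.median_powers_db[-1] + w * (
                        f.median_powers_db[0] - cur.median_powers_db[-1]
                    )
                else:
                    bridge_f = bridge_p = bridge_m = np.empty(0)
                out[-1] = ContourFragment(
                    onset_s=cur.onset_s,
                    dt_s=dt,
                    freqs_khz=np.concatenate([cur.freqs_khz, bridge_f, f.freqs_khz]),
                    peak_powers_db=np.concatenate(
                        [cur.peak_powers_db, bridge_p, f.peak_powers_db]
                    ),
                    median_powers_db=np.concatenate(
                        [cur.median_powers_db, bridge_m, f.median_powers_db]
                    ),
                )
                continue
        out.append(f)
    return out


def _snr_class_from_excess(excess_db: float) -> str:
    if excess_db >= SNR_HIGH_DB:
        return "high"
    if excess_db >= SNR_MEDIUM_DB:
        return "medium"
    return "low"


def filter_contours(
    frags: Sequence[ContourFragment],
    min_duration_s: float = MIN_DURATION_S,
    recording_id: str = "",
    day_label: str = "",
    id_prefix: str = "x",
) -> ContourSet:
    """Promote fragments of duration >= ``min_duration_s`` (inclusive) to
    :class:`WhistleContour` with fresh sequential ids; drop shorter ones
    (the dropped count is logged).  SNR class comes from the fragment's mean
    peak-over-median excess."""
    out = ContourSet()
    dropped = 0
    k = 0
    for f in sorted(frags, key=lambda f: f.onset_s):
        if f.duration_s < min_duration_s:
            dropped += 1
            continue
        k += 1
        excess = float(np.mean(f.peak_powers_db - f.median_powers_db))
        out.add(
            WhistleContour(
                id=f"{id_prefix}{k:05d}",
                recording_id=recording_id,
                day_label=day_label,
                onset_s=f.onset_s,
                dt_s=f.dt_s,
                freqs_khz=f.freqs_khz,
                snr_class=_snr_class_from_excess(excess),
            )
        )
    log.info(
        "filter_contours: kept %d, dropped %d below %.3f s", len(out), dropped, min_duration_s
    )
    return out


def assess_snr(contour: WhistleContour, spec: Spectrogram) -> str:
    """Classify a contour's SNR from the spectrogram it lies in: the mean of
    (peak power - frame median) sampled along the trace is mapped through the
    15 dB / 6 dB class thresholds."""
    t = contour.times_s()
    if t[0] < spec.times_s[0] - spec.dt_s or t[-1] > spec.times_s[-1] + spec.dt_s:
        raise InvalidInputError("contour trace extends outside the spectrogram")
    if (
        contour.freqs_khz.min() < spec.freqs_khz[0] - spec.df_khz
        or contour.freqs_khz.max() > spec.freqs_khz[-1] + spec.df_khz
    ):
        raise InvalidInputError("contour frequencies outside the spectrogram band")
    ti = np.clip(
        np.searchsorted(spec.times_s, t), 0, spec.times_s.size - 1
    )
    fi = np.clip(
        np.round((contour.freqs_khz - spec.freqs_khz[0]) / spec.df_khz).astype(int),
        0,
        spec.freqs_khz.size - 1,
    )
    med = np.median(spec.power_db[:, ti], axis=0)
    excess = float(np.mean(spec.power_db[fi, ti] - med))
    return _snr_class_from_excess(excess)


def extract_contours(
    waveform: np.ndarray,
    sample_rate_hz: float,
    cfg: SpectrogramConfig | None = None,
    tonality_threshold_db: float = TONALITY_THRESHOLD_DB,
    max_jump_khz: float = MAX_JUMP_KHZ,
    max_gap_s: float = MERGE_MAX_GAP_S,
    continuity_khz: float = MERGE_CONTINUITY_KHZ,
    min_duration_s: float = MIN_DURATION_S,
    recording_id: str = "",
    day_label: str = "",
    id_prefix: str = "x",
) -> ContourSet:
    """Full extraction chain: spectrogram -> peak tracking -> fragment merge ->
    duration filter -> SNR classing."""
    spec = compute_spectrogram(waveform, sample_rate_hz, cfg)
    frags = track_peaks(spec, tonality_threshold_db, max_jump_khz)
    merged = merge_fragments(frags, max_gap_s, continuity_khz)
    return filter_contours(
        merged, min_duration_s, recording_id=recording_id, day_label=day_label,
        id_prefix=id_prefix,
    )
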
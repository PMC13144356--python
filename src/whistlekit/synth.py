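"""Synthetic whistle repertoires with known ground truth.

The generator emulates the structure of a multi-day recording effort on a
small delphinid group: a repertoire of stereotyped contour types (upsweeps,
downsweeps, stepped contours, multi-inflection shapes, near-flat tones),
each emitted in bouts with lognormal inter-whistle intervals, plus
non-repeated background whistles, three signal-to-noise classes, and
optional rendering to audio as frequency-modulated tones in white noise.

Every quantity is a pure function of the :class:`RepertoireSpec` (including
its seed), so downstream stages can be tested against exact ground truth.

Calibration contract: with the default jitter magnitudes, two exemplars of
one type stay above the categorizer's 96% vigilance under warp factor 3,
while exemplars of different types stay below it (templates are rejection
sampled until all pairwise noiseless similarities fall under a 94% margin).
That separation is what makes planted-category recovery a fair test of the
categorizer; real repertoires need not satisfy it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .agreement import Partition
from .contours import (
    DEFAULT_DT_S,
    ContourSet,
    WhistleContour,
    similarity_arrays,
)
from .errors import InvalidInputError, InvalidParameterError

SHAPE_TAGS = ("upsweep", "downsweep", "stepped", "multi_inflection", "flat")

FREQ_LOW_KHZ = 1.9
FREQ_HIGH_KHZ = 16.1

#: noiseless rendered exemplars of distinct templates must stay below this
#: DTW similarity (rejection-sampling margin under the 96 vigilance)
MAX_TEMPLATE_SIMILARITY = 94.0

#: synthesis spectrogram SNR targets per class, dB above the noise floor
SNR_CLASS_DB = {"high": 26.0, "medium": 13.0, "low": 5.0}

NOISE_LABEL = "noise"


@dataclass
class ContourTemplate:
    """A stereotyped whistle type: piecewise-linear frequency segments.

    ``segments`` is an ordered list of ``(start_khz, end_khz, duration_s,
    gap_after_s)``.  Temporal gaps are bridged linearly when the template is
    rendered to a contour trace, mirroring how fragmented whistles are merged
    into a single contour during extraction.
    """

    type_id: str
    segments: list[tuple[float, float, float, float]]
    shape_tag: str

    def __post_init__(self) -> None:
        if self.shape_tag not in SHAPE_TAGS:
            raise InvalidParameterError(f"unknown shape_tag {self.shape_tag!r}")
        if self.total_duration_s < 0.1:
            raise InvalidParameterError("template shorter than 0.1 s")
        for s, e, d, g in self.segments:
            if not (FREQ_LOW_KHZ <= s <= FREQ_HIGH_KHZ and FREQ_LOW_KHZ <= e <= FREQ_HIGH_KHZ):
                raise InvalidParameterError(
                    f"template {self.type_id}: frequencies outside "
                    f"[{FREQ_LOW_KHZ}, {FREQ_HIGH_KHZ}] kHz"
                )
            if d <= 0 or g < 0:
                raise InvalidParameterError("segment durations must be > 0, gaps >= 0")

    @property
    def total_duration_s(self) -> float:
        segs = self.segments
        dur = sum(d for _, _, d, _ in segs)
        dur += sum(g for _, _, _, g in segs[:-1])  # trailing gap ignored
        return dur


@dataclass
class RepertoireSpec:
    """Parameters of a synthetic repertoire (defaults: desk-scale emulation
    of a three-day encounter series; see the package methods note)."""

    n_types: int = 8
    exemplars_per_type: Union[int, tuple[int, int]] = (3, 20)
    duration_warp_sd: float = 0.08       # lognormal sigma of per-segment warp
    freq_jitter_sd_khz: float = 0.05     # sd of the smooth frequency offset
    background_whistle_rate: float = 1.0  # singleton whistles per minute
    iwi_log_mean: float = 1.42           # log-scale mean of IWI (s)
    iwi_log_sd: float = 1.01             # log-scale sd of IWI
    iwi_min_s: float = 0.3               # lower truncation of IWI
    bout_size_range: tuple[int, int] = (3, 20)
    interbout_gap_range_s: tuple[float, float] = (35.0, 90.0)
    snr_mix: tuple[float, float, float] = (0.115, 0.470, 0.415)  # high/med/low
    n_days: int = 3
    multi_day_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.snr_mix) - 1.0) > 1e-9:
            raise InvalidParameterError("snr_mix proportions must sum to 1")
        if min(self.duration_warp_sd, self.freq_jitter_sd_khz) < 0:
            raise InvalidParameterError("jitter SDs must be >= 0")
        if self.n_days < 1 or self.n_types < 1:
            raise InvalidParameterError("n_days and n_types must be >= 1")


@dataclass
class GeneratedDataset:
    """Ground-truth output of :func:`generate_repertoire`."""

    contours: ContourSet
    truth: Partition                     # id -> type label ('noise' for bg)
    timeline: dict[str, list[tuple[str, float]]]  # day -> [(id, onset_s)]
    templates: list[ContourTemplate]
    spec: RepertoireSpec

    @property
    def day_labels(self) -> list[str]:
        return sorted(self.timeline)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def render_template(t: ContourTemplate, dt_s: float = DEFAULT_DT_S) -> np.ndarray:
    """Noiseless frequency trace of a template (gaps bridged linearly)."""
    times = [0.0]
    freqs = [t.segments[0][0]]
    clock = 0.0
    for k, (s, e, d, g) in enumerate(t.segments):
        if times[-1] < clock - 1e-12 or abs(s - freqs[-1]) > 1e-12:
            times.append(clock)
            freqs.append(s)
        clock += d
        times.append(clock)
        freqs.append(e)
        if k < len(t.segments) - 1:
            clock += g  # bridged by interpolation across the gap
    dur = max(clock, 0.1)
    n = max(2, int(round(dur / dt_s)) + 1)
    grid = np.linspace(0.0, dur, n)
    return np.interp(grid, times, freqs)


def _random_template(type_id: str, shape_tag: str, rng: np.random.Generator) -> ContourTemplate:
    lo, hi = 2.4, 14.5

    def clip(f):
        return float(np.clip(f, lo, hi))

    segs: list[tuple[float, float, float, float]] = []
    if shape_tag == "flat":
        f0 = rng.uniform(2.8, 11.0)
        tilt = rng.uniform(0.97, 1.03)
        segs = [(clip(f0), clip(f0 * tilt), rng.uniform(0.25, 0.8), 0.0)]
    elif shape_tag in ("upsweep", "downsweep"):
        f0 = rng.uniform(2.8, 8.0)
        span = rng.uniform(1.35, 1.95)
        f1 = clip(f0 * span)
        fm = clip(f0 * rng.uniform(1.05, span * 0.85))
        d1, d2 = rng.uniform(0.12, 0.45, size=2)
        a, b, c = (f0, fm, f1) if shape_tag == "upsweep" else (f1, fm, f0)
        segs = [(clip(a), clip(b), d1, 0.0), (clip(b), clip(c), d2, 0.0)]
    elif shape_tag == "stepped":
        k = int(rng.integers(2, 5))
        f = rng.uniform(3.0, 8.5)
        direction = rng.choice([-1.0, 1.0])
        for _ in range(k):
            d = rng.uniform(0.10, 0.30)
            segs.append((clip(f), clip(f * rng.uniform(0.995, 1.005)), d, 0.0))
            # step stays below the 2 kHz merge-continuity bound so a split
            # at the discontinuity remains re-joinable after extraction
            step = min(f * (rng.uniform(1.12, 1.30) - 1.0), 1.8)
            f = clip(f + step if direction > 0 else f - step)
    else:  # multi_inflection
        k = int(rng.integers(3, 5))
        f = rng.uniform(3.5, 8.0)
        up = rng.choice([True, False])
        for _ in range(k):
            ratio = rng.uniform(1.2, 1.55)
            f2 = clip(f * ratio if up else f / ratio)
            segs.append((clip(f), f2, rng.uniform(0.10, 0.30), 0.0))
            f = f2
            up = not up
    t = ContourTemplate(type_id=type_id, segments=segs, shape_tag=shape_tag)
    if t.total_duration_s < 0.12:
        s, e, d, g = t.segments[-1]
        t.segments[-1] = (s, e, d + 0.12, g)
    return t


def make_default_templates(
    n_types: int, seed: int, warp_factor: int = 3
) -> list[ContourTemplate]:
    """Deterministic, mutually separable templates covering all shape families.

    Shape tags cycle so all five families appear once ``n_types >= 5``.
    Candidates are rejection sampled until every pairwise DTW similarity of
    the noiseless renders stays below :data:`MAX_TEMPLATE_SIMILARITY`.
    """
    if not 1 <= n_types <= 50:
        raise InvalidParameterError("n_types must be in [1, 50]")
    rng = _substream(seed, "templates")
    out: list[ContourTemplate] = []
    rendered: list[np.ndarray] = []
    for i in range(n_types):
        tag = SHAPE_TAGS[i % len(SHAPE_TAGS)]
        for attempt in range(500):
            cand = _random_template(f"T{i + 1:02d}", tag, rng)
            trace = render_template(cand)
            if all(
                similarity_arrays(trace, other, warp_factor) < MAX_TEMPLATE_SIMILARITY
                for other in rendered
            ):
                out.append(cand)
                rendered.append(trace)
                break
        else:
            raise RuntimeError(
                f"could not place {n_types} mutually separable templates"
            )
    return out


# ---------------------------------------------------------------------------
# exemplars
# ---------------------------------------------------------------------------

def _smooth_jitter(n: int, sd_khz: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean frequency offset: interpolation through 4 random knots."""
    if sd_khz == 0 or n < 2:
        return np.zeros(n)
    knots = rng.normal(0.0, sd_khz, size=4)
    return np.interp(np.linspace(0, 3, n), np.arange(4), knots)


def render_exemplar(
    t: ContourTemplate, spec: RepertoireSpec, rng: np.random.Generator
) -> WhistleContour:
    """One jittered realization of a template.

    Segment durations (and gaps) are multiplied by independent lognormal
    factors with log-sd ``duration_warp_sd``; the whole trace is offset by a
    smooth random curve with sd ``freq_jitter_sd_khz``.  With both SDs zero
    the exemplar equals the noiseless template rendering.
    """
    segs = []
    for s, e, d, g in t.segments:
        wd = d * float(np.exp(rng.normal(0.0, spec.duration_warp_sd)))
        wg = g * float(np.exp(rng.normal(0.0, spec.duration_warp_sd)))
        segs.append((s, e, wd, wg))
    warped = ContourTemplate(type_id=t.type_id, segments=segs, shape_tag=t.shape_tag)
    freqs = render_template(warped)
    freqs = freqs + _smooth_jitter(freqs.size, spec.freq_jitter_sd_khz, rng)
    freqs = np.clip(freqs, FREQ_LOW_KHZ, FREQ_HIGH_KHZ)
    return WhistleContour(
        id=f"{t.type_id}-x",
        recording_id="",
        day_label="",
        onset_s=0.0,
        dt_s=DEFAULT_DT_S,
        freqs_khz=freqs,
        snr_class="high",
        visual_label=t.type_id,
    )


# ---------------------------------------------------------------------------
# inter-whistle intervals
# ---------------------------------------------------------------------------

def draw_iwi(spec: RepertoireSpec, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Truncated-lognormal IWI draws (rejection below ``iwi_min_s``)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(spec.iwi_log_mean, spec.iwi_log_sd, size=size - filled)
        keep = draw[draw >= spec.iwi_min_s]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def truncated_lognormal_mean(mu: float, sigma: float, lower: float) -> float:
    """Analytic mean of a lognormal(mu, sigma) truncated to [lower, inf)."""
    a = (np.log(lower) - mu) / sigma
    return float(np.exp(mu + sigma**2 / 2) * norm.sf(a - sigma) / norm.sf(a))


# ---------------------------------------------------------------------------
# repertoire assembly
# ---------------------------------------------------------------------------

def _exemplar_count(spec: RepertoireSpec, rng: np.random.Generator) -> int:
    e = spec.exemplars_per_type
    if isinstance(e, int):
        return e
    lo, hi = e
    return int(rng.integers(lo, hi + 1))


def _split_bouts(n: int, spec: RepertoireSpec, rng: np.random.Generator) -> list[int]:
    lo, hi = spec.bout_size_range
    sizes: list[int] = []
    left = n
    while left > 0:
        s = int(min(left, rng.integers(lo, hi + 1)))
        sizes.append(s)
        left -= s
    if len(sizes) > 1 and sizes[-1] < lo:
        sizes[-2] += sizes[-1]
        sizes.pop()
    return sizes


def generate_repertoire(spec: RepertoireSpec) -> GeneratedDataset:
    """Build a full ground-truth dataset from a repertoire specification.

    Per day, bouts of same-type exemplars are scheduled sequentially with
    inter-bout gaps larger than the 30-s bout window, onset-to-onset IWIs
    drawn from the truncated lognormal (floored so consecutive whistles never
    overlap in time), and background singleton whistles inserted at the
    configured rate.  Output is fully reproducible from ``spec.seed``.
    """
    templates = make_default_templates(spec.n_types, spec.seed)
    rng_x = _substream(spec.seed, "exemplars")
    rng_t = _substream(spec.seed, "timeline")
    rng_s = _substream(spec.seed, "snr")
    rng_b = _substream(spec.seed, "background")

    days = [f"day{d + 1}" for d in range(spec.n_days)]

    # exemplars per type, split across that type's days
    per_day_bouts: dict[str, list[tuple[str, list[WhistleContour]]]] = {
        d: [] for d in days
    }
    n_exemplars_total = 0
    for t in templates:
        count = _exemplar_count(spec, rng_x)
        n_exemplars_total += count
        exemplars = [render_exemplar(t, spec, rng_x) for _ in range(count)]
        if spec.n_days > 1 and rng_t.random() < spec.multi_day_prob:
            k = int(rng_t.integers(2, spec.n_days + 1))
        else:
            k = 1
        type_days = list(rng_t.choice(spec.n_days, size=k, replace=False))
        shares = np.array_split(np.arange(count), k)
        for di, share in zip(type_days, shares):
            if share.size == 0:
                continue
            chunk = [exemplars[i] for i in share]
            for size in _split_bouts(len(chunk), spec, rng_t):
                per_day_bouts[days[di]].append((t.type_id, chunk[:size]))
                chunk = chunk[:0] if size >= len(chunk) else chunk[size:]

    # background singletons, count from the expected bout-schedule length
    bg_templates: list[ContourTemplate] = []
    for d in days:
        est_min = max(
            1.0,
            sum(len(b[1]) for b in per_day_bouts[d]) * 7.0 / 60.0
            + len(per_day_bouts[d]) * 60.0 / 60.0,
        )
        n_bg = int(rng_b.poisson(spec.background_whistle_rate * est_min))
        for k in range(n_bg):
            tag = SHAPE_TAGS[int(rng_b.integers(len(SHAPE_TAGS)))]
            bt = _random_template(f"BG-{d}-{k:03d}", tag, rng_b)
            bg_templates.append(bt)
            per_day_bouts[d].append((NOISE_LABEL, [render_exemplar(bt, spec, rng_b)]))

    # schedule each day sequentially
    contours = ContourSet()
    truth: dict[str, str] = {}
    timeline: dict[str, list[tuple[str, float]]] = {}
    counter = 0
    for d in days:
        bouts = per_day_bouts[d]
        order = rng_t.permutation(len(bouts))
        clock = float(rng_t.uniform(5.0, 15.0))
        events: list[tuple[str, float]] = []
        for bi in order:
            type_label, members = bouts[bi]
            for k, c in enumerate(members):
                counter += 1
                cid = f"w{counter:05d}"
                snr = str(rng_s.choice(SNR_CLASSES_ORDER, p=spec.snr_mix))
                placed = replace(
                    c,
                    id=cid,
                    recording_id=f"{d}-r1",
                    day_label=d,
                    onset_s=clock,
                    snr_class=snr,
                    visual_label=type_label if type_label != NOISE_LABEL else NOISE_LABEL,
                )
                contours.add(placed)
                truth[cid] = type_label
                events.append((cid, clock))
                if k < len(members) - 1:
                    iwi = float(draw_iwi(spec, rng_t, 1)[0])
                    clock += max(iwi, placed.duration_s + 0.25)
                else:
                    clock += placed.duration_s
            if type_label == NOISE_LABEL:
                # background singletons sit inside the recording texture;
                # only real bouts are separated by full inter-bout gaps
                clock += float(rng_t.uniform(5.0, 15.0))
            else:
                clock += float(rng_t.uniform(*spec.interbout_gap_range_s))
        timeline[d] = events

    return GeneratedDataset(
        contours=contours,
        truth=Partition(truth),
        timeline=timeline,
        templates=templates + bg_templates,
        spec=spec,
    )


SNR_CLASSES_ORDER = ("high", "medium", "low")


# ---------------------------------------------------------------------------
# audio rendering
# ---------------------------------------------------------------------------

def render_audio(
    d: GeneratedDataset,
    sample_rate_hz: int = 96_000,
    noise_db: float = -45.0,
) -> dict[str, np.ndarray]:
    """Render each day as an FM-tone-in-white-noise waveform (float32).

    Each contour becomes a phase-continuous frequency-modulated tone following
    its trace, with 5-ms cosine on/off ramps, embedded at its onset over white
    Gaussian noise of RMS ``10**(noise_db/20)``.  Tone amplitudes target the
    per-class spectrogram SNRs in :data:`SNR_CLASS_DB` (referred to a
    2048-point Hann analysis window).  Raises on aliasing.
    """
    fs = int(sample_rate_hz)
    max_f_hz = 1000.0 * max(
        (float(c.freqs_khz.max()) for c in d.contours), default=0.0
    )
    if fs < 2 * max_f_hz:
        raise InvalidParameterError(
            f"sample rate {fs} Hz below Nyquist for {max_f_hz:.0f} Hz content"
        )
    sigma = 10.0 ** (noise_db / 20.0)
    # noise power per Hann-window bin of the reference analysis FFT
    ref_fft = 2048
    noise_bin = sigma**2 * 1.5 / ref_fft
    rng = _substream(d.spec.seed, "audio")
    out: dict[str, np.ndarray] = {}
    for day in d.day_labels:
        events = d.timeline[day]
        dur = (events[-1][1] + 5.0) if events else 10.0
        dur = max(
            dur,
            max((d.contours[cid].offset_s for cid, _ in events), default=0.0) + 5.0,
        )
        n = int(round(dur * fs))
        wave = rng.normal(0.0, sigma, size=n)
        for cid in sorted(cid for cid, _ in events):
            c = d.contours[cid]
            i0 = int(round(c.onset_s * fs))
            ns = int(round(c.duration_s * fs))
            if ns < 2:
                continue
            tt = np.arange(ns) / fs
            f_hz = 1000.0 * np.interp(
                tt, np.arange(c.n_points) * c.dt_s, c.freqs_khz
            )
            phase = 2.0 * np.pi * np.cumsum(f_hz) / fs
            snr_db = SNR_CLASS_DB[c.snr_class]
            amp = float(np.sqrt(2.0 * noise_bin * 10.0 ** (snr_db / 10.0)))
            tone = amp * np.sin(phase)
            ramp = min(int(0.005 * fs), ns // 4)
            if ramp > 0:
                env = np.ones(ns)
                ramp_curve = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
                env[:ramp] = ramp_curve
                env[-ramp:] = ramp_curve[::-1]
                tone = tone * env
            wave[i0 : i0 + ns] += tone[: max(0, n - i0)]
        out[day] = wave.astype(np.float32)
    return out
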
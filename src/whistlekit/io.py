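"""File formats, run configuration, logging and packaged count-table fixtures.

Internal unit convention is kHz and seconds; Raven-style selection tables at
the boundary use Hz, per that format's convention.  All floats are written
with ``%.17g`` so that write -> read -> write is byte-stable.

The packaged fixtures carry the published per-encounter, photo-identification,
SNR-inventory, sequenced-agreement and cross-day count tables of the study
the pipeline re-implements; they drive the printed-table aggregation checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .artwarp import CategorizerConfig
from .contours import ContourSet, read_contours_csv, write_contours_csv
from .errors import InvalidInputError, ParseError
from .spectro import SpectrogramConfig
from .synth import RepertoireSpec

log = logging.getLogger("whistlekit")

SELECTION_COLUMNS = [
    "Selection",
    "View",
    "Channel",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
    "snr_class",
    "visual_label",
]


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped, machine-parseable log lines on stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s\t%(levelname)s\t%(name)s\t%(message)s")
    )
    root = logging.getLogger("whistlekit")
    root.handlers[:] = [handler]
    root.setLevel(level)
    logging.getLogger("whistlekit.stage").setLevel(level)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (JSON-serializable)."""

    generator: RepertoireSpec = field(default_factory=RepertoireSpec)
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    categorizer: CategorizerConfig = field(default_factory=CategorizerConfig)
    bout_window_s: float = 30.0
    bout_min_count: int = 3
    pca_standardize: bool = True
    sample_rate_hz: int = 96_000
    noise_db: float = -45.0
    prune_singletons: bool = True
    outdir: str = "whistlekit_out"
    seed: int = 0

    def __post_init__(self) -> None:
        # one config seed feeds every stage's named substream
        self.generator.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        for key in ("exemplars_per_type", "bout_size_range", "interbout_gap_range_s",
                    "snr_mix"):
            if key in gen and isinstance(gen[key], list):
                gen[key] = tuple(gen[key])
        spec = d.pop("spectrogram", {})
        cat = d.pop("categorizer", {})
        return cls(
            generator=RepertoireSpec(**gen),
            spectrogram=SpectrogramConfig(**spec),
            categorizer=CategorizerConfig(**cat),
            **d,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_stage_metadata(cfg: RunConfig, stage: str, path, **extra) -> None:
    meta = {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# WAV and tables
# ---------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sample_rate_hz: int) -> None:
    wavfile.write(path, int(sample_rate_hz), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, int]:
    fs, x = wavfile.read(path)
    return np.asarray(x, dtype=np.float32), int(fs)


def write_selection_table(cs: ContourSet, path) -> None:
    """Raven-compatible selection table (tab-separated, times s, freqs Hz)."""
    rows = []
    for k, cid in enumerate(cs.ids(), start=1):
        c = cs[cid]
        rows.append(
            (
                k,
                "Spectrogram 1",
                1,
                c.onset_s,
                c.offset_s,
                1000.0 * float(c.freqs_khz.min()),
                1000.0 * float(c.freqs_khz.max()),
                c.snr_class,
                "" if c.visual_label is None else c.visual_label,
            )
        )
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_selection_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=[],
        float_precision="round_trip",
    )
    missing = [c for c in SELECTION_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ParseError(f"selection table missing column(s): {missing}")
    return df


def write_truth_csv(truth, path) -> None:
    truth.to_frame().rename(columns={"label": "true_type"}).to_csv(path, index=False)


def write_timeline_csv(timeline: dict, path) -> None:
    rows = [
        (cid, day, onset)
        for day in sorted(timeline)
        for cid, onset in timeline[day]
    ]
    pd.DataFrame(rows, columns=["id", "day_label", "onset_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_timeline_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"id": str, "day_label": str}, float_precision="round_trip"
    )


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture(name: str) -> pd.DataFrame:
    with resources.files("whistlekit").joinpath(f"data/{name}").open() as fh:
        return pd.read_csv(fh)


def load_encounter_table() -> pd.DataFrame:
    df = _fixture("encounters.csv")
    if len(df) != 3:
        raise ParseError("encounter fixture must have 3 rows")
    return df


def load_photoid_table() -> pd.DataFrame:
    df = _fixture("photoid.csv")
    if len(df) != 3:
        raise ParseError("photo-ID fixture must have 3 rows")
    return df


def load_sequenced_agreement_table() -> pd.DataFrame:
    df = _fixture("sequenced_agreement.csv")
    if len(df) != 25:
        raise ParseError("sequenced-agreement fixture must have 25 rows")
    df["split_sizes"] = df["splits"].map(
        lambda s: tuple(int(x) for x in str(s).split("/"))
    )
    bad = df[[sum(s) != n for s, n in zip(df["split_sizes"], df["n"])]]
    if len(bad):
        raise ParseError(f"split sizes do not sum to n for {list(bad['category'])}")
    return df


def load_cross_day_counts() -> pd.DataFrame:
    df = _fixture("cross_day_counts.csv").set_index("category")
    if len(df) != 5:
        raise ParseError("cross-day fixture must have 5 multi-day categories")
    return df


def load_snr_inventory() -> pd.DataFrame:
    return _fixture("snr_inventory.csv").set_index("snr_class")


# ---------------------------------------------------------------------------
# fixture aggregations
# ---------------------------------------------------------------------------

def aggregate_encounters(df: pd.DataFrame) -> dict:
    """Column sums of the encounter table."""
    return {
        "encounter_min": int(df["encounter_min"].sum()),
        "n_recordings": int(df["n_recordings"].sum()),
        "recording_min": int(df["recording_min"].sum()),
    }


def photoid_percentages(df: pd.DataFrame) -> pd.Series:
    """Percent of the visually counted group photo-identified per event,
    rounded to integer (half away from zero)."""
    if (df["group_size"] <= 0).any():
        raise InvalidInputError("group size must be > 0")
    if (df["n_identified"] > df["group_size"]).any():
        raise InvalidInputError("identifications exceed group size")
    pct = 100.0 * df["n_identified"] / df["group_size"]
    return pct.map(lambda x: int(math.floor(x + 0.5)))


def snr_inventory_totals(df: pd.DataFrame) -> dict:
    return {
        "n_whistles_total": int(df["n_total"].sum()),
        "n_repeated_total": int(df["n_repeated"].sum()),
    }
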
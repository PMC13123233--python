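"""Domain types, units/conventions, and table readers/writers.

Conventions
-----------
* Voltages are in microvolts (µV), times in milliseconds.
* Sample ``k`` of a record maps to time ``(k - onset_index) / sampling_rate
  * 1000`` ms; the stimulus onset is at t = 0 and implicit times are
  reported relative to onset.
* Flash strengths are in log cd·s/m² and genotype labels form a closed
  vocabulary (see :class:`Genotype`).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, IntegrityError

__all__ = [
    "Adaptation",
    "Genotype",
    "StimulusCondition",
    "SweepSet",
    "AveragedWaveform",
    "FilteredPair",
    "ComponentMeasures",
    "OpSplitConfig",
    "ArtifactConfig",
    "RunConfig",
    "DA_PROTOCOL",
    "LA_PROTOCOL",
    "DA_FLASHES",
    "LA_FLASH",
    "read_waveforms",
    "write_waveforms",
    "read_measures",
    "write_measures",
    "MEASURES_COLUMNS",
    "WAVEFORM_COLUMNS",
]


class Adaptation(str, enum.Enum):
    """Adaptation state of the eye at recording time."""

    DA = "DA"  # dark-adapted (scotopic)
    LA = "LA"  # light-adapted (photopic)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(str, enum.Enum):
    """Closed genotype vocabulary; unknown labels are rejected at read time."""

    WT = "WT"
    mdx = "mdx"
    mdx5Cv = "mdx5Cv"
    mdx2Cv = "mdx2Cv"
    mdx52 = "mdx52"
    dmd_null = "dmd_null"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Dark-adapted protocol table: flash (log cd·s/m²) -> (nominal sweeps, ISI s).
DA_PROTOCOL: dict[float, tuple[int, float]] = {
    -3.7: (12, 1.0),
    -2.7: (10, 2.0),
    -1.7: (8, 5.0),
    -0.7: (8, 10.0),
    0.3: (4, 20.0),
}

#: Light-adapted protocol: single flash on a 25 cd/m² background.
LA_PROTOCOL: dict[float, tuple[int, float]] = {0.3: (24, 1.0)}

DA_FLASHES: tuple[float, ...] = tuple(sorted(DA_PROTOCOL))
LA_FLASH: float = 0.3
LA_BACKGROUND_CDM2: float = 25.0


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus condition of the flash protocol.

    The (sweeps, ISI) pairing is taken from the protocol table, which is
    the single source of truth; hand-built conditions that deviate from it
    are rejected.
    """

    adaptation: Adaptation
    flash_strength: float  # log cd·s/m²
    background_luminance: float  # cd/m²
    n_sweeps_nominal: int
    isi_s: float

    def __post_init__(self) -> None:
        flash = round(self.flash_strength, 1)
        table = DA_PROTOCOL if self.adaptation is Adaptation.DA else LA_PROTOCOL
        if flash not in table:
            raise ConfigurationError(
                f"flash strength {self.flash_strength} log cd·s/m² is not in the "
                f"{self.adaptation.value} protocol (valid: {sorted(table)})"
            )
        n_sweeps, isi = table[flash]
        if self.n_sweeps_nominal != n_sweeps or self.isi_s != isi:
            raise ConfigurationError(
                f"{self.adaptation.value} {flash} log: expected "
                f"{n_sweeps} sweeps / {isi} s ISI, got "
                f"{self.n_sweeps_nominal} / {self.isi_s}"
            )
        expected_bg = 0.0 if self.adaptation is Adaptation.DA else LA_BACKGROUND_CDM2
        if self.background_luminance != expected_bg:
            raise ConfigurationError(
                f"background luminance must be {expected_bg} cd/m² for "
                f"{self.adaptation.value}"
            )

    @classmethod
    def da(cls, flash_strength: float) -> "StimulusCondition":
        flash = round(flash_strength, 1)
        if flash not in DA_PROTOCOL:
            raise ConfigurationError(
                f"flash strength {flash_strength} log cd·s/m² is not in the DA "
                f"protocol (valid: {sorted(DA_PROTOCOL)})"
            )
        n, isi = DA_PROTOCOL[flash]
        return cls(Adaptation.DA, flash, 0.0, n, isi)

    @classmethod
    def la(cls) -> "StimulusCondition":
        n, isi = LA_PROTOCOL[LA_FLASH]
        return cls(Adaptation.LA, LA_FLASH, LA_BACKGROUND_CDM2, n, isi)


def _n_samples(sampling_rate: float, record_length_ms: float) -> int:
    return int(round(sampling_rate * record_length_ms / 1000.0))


@dataclass
class SweepSet:
    """Raw repeated stimulus-locked voltage traces for one eye × condition."""

    eye_id: str
    animal_id: str
    genotype: Genotype
    condition: StimulusCondition
    traces: np.ndarray  # [n_sweeps, n_samples] µV
    onset_index: int
    sampling_rate: float = 512.0
    record_length_ms: float = 250.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise IntegrityError("traces must be a 2-D [sweeps × samples] array")
        n_expected = _n_samples(self.sampling_rate, self.record_length_ms)
        if self.traces.shape[1] != n_expected:
            raise IntegrityError(
                f"expected {n_expected} samples per sweep "
                f"({self.sampling_rate} Hz × {self.record_length_ms} ms), "
                f"got {self.traces.shape[1]}"
            )
        if not (0 < self.onset_index < self.traces.shape[1]):
            raise ConfigurationError(
                f"onset_index {self.onset_index} outside record "
                f"(n_samples={self.traces.shape[1]})"
            )
        min_pre = math.ceil(0.016 * self.sampling_rate)
        if self.onset_index < min_pre:
            raise ConfigurationError(
                f"onset_index {self.onset_index} leaves less than 16 ms of "
                f"pre-onset record (need ≥ {min_pre} samples)"
            )

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


@dataclass
class AveragedWaveform:
    """Artifact-filtered mean trace with a stimulus-onset anchor."""

    eye_id: str
    animal_id: str
    genotype: Genotype
    condition: StimulusCondition
    trace: np.ndarray  # [n_samples] µV
    onset_index: int
    sampling_rate: float
    n_sweeps_used: int
    n_sweeps_rejected: int = 0

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 1:
            raise IntegrityError("averaged trace must be 1-D")
        if self.n_sweeps_used < 1:
            raise IntegrityError("n_sweeps_used must be ≥ 1")

    @property
    def n_samples(self) -> int:
        return self.trace.size

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        k = np.arange(self.n_samples)
        return (k - self.onset_index) / self.sampling_rate * 1000.0


@dataclass
class FilteredPair:
    """Additive split of an averaged trace into slow and OP components.

    Invariant: ``slow + ops`` reconstructs the input trace to within
    floating-point tolerance (the split is a partition of DFT bins and the
    removed mean is folded back into ``slow``).
    """

    source: AveragedWaveform
    slow: np.ndarray  # OP-removed waveform, µV
    ops: np.ndarray  # isolated OPs, µV
    cutoff_hz: float


@dataclass
class ComponentMeasures:
    """a-wave, b-wave, and OP measures for one eye × condition."""

    eye_id: str
    animal_id: str
    genotype: Genotype
    adaptation: Adaptation
    flash_strength: float
    baseline: float  # µV
    b_amplitude: float  # µV, ≥ 0
    b_implicit_time: float  # ms
    a_amplitude: float | None = None  # µV, ≥ 0; None when undetected / LA
    a_implicit_time: float | None = None  # ms
    op_spectral_amplitude: float | None = None  # µV; DA only
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.a_amplitude is not None:
            if not (0 < self.a_implicit_time <= 50.0 + 1e-9):
                raise IntegrityError(
                    f"a-wave implicit time {self.a_implicit_time} ms outside (0, 50]"
                )
            if self.b_implicit_time <= self.a_implicit_time:
                raise IntegrityError("b implicit time must exceed a implicit time")
            if self.a_amplitude < 0:
                raise IntegrityError("a amplitude must be ≥ 0")
        if self.b_amplitude < 0:
            raise IntegrityError("b amplitude must be ≥ 0")
        if self.op_spectral_amplitude is not None and self.op_spectral_amplitude < 0:
            raise IntegrityError("OP amplitude must be ≥ 0")
        self.flags = frozenset(self.flags)


@dataclass
class OpSplitConfig:
    mode: str = "fixed"  # "fixed" | "adaptive"
    fixed_cutoff_hz: float = 50.0
    adaptive_search_hz: tuple[float, float] = (30.0, 60.0)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ConfigurationError(f"unknown op_split mode {self.mode!r}")
        lo, hi = self.adaptive_search_hz
        if not (0 < lo < hi):
            raise ConfigurationError("adaptive_search_hz must be 0 < low < high")
        if self.fixed_cutoff_hz <= 0:
            raise ConfigurationError("fixed_cutoff_hz must be positive")


@dataclass
class ArtifactConfig:
    enabled: bool = False
    mad_k: float = 5.0

    def __post_init__(self) -> None:
        if self.mad_k <= 0:
            raise ConfigurationError("mad_k must be positive")


@dataclass
class RunConfig:
    """All tunable constants of the processing / quantification chain."""

    sampling_rate: float = 512.0
    record_length_ms: float = 250.0
    baseline_window_ms: float = 16.0
    a_search_ms: float = 50.0
    b_search_start_ms: float = 10.0
    a_detect_sd_mult: float = 3.0
    a_detect_min_uv: float = 5.0  # absolute floor of the detection threshold
    op_band_hz: tuple[float, float] = (60.0, 100.0)
    op_split: OpSplitConfig = field(default_factory=OpSplitConfig)
    artifact_rejection: ArtifactConfig = field(default_factory=ArtifactConfig)
    analysis_unit: str = "eye"  # "eye" | "animal"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        nyquist = self.sampling_rate / 2.0
        if self.baseline_window_ms <= 0 or self.a_search_ms <= 0:
            raise ConfigurationError("window lengths must be positive")
        lo, hi = self.op_band_hz
        if not (0 < lo < hi <= nyquist):
            raise ConfigurationError(
                f"op_band_hz {self.op_band_hz} outside (0, Nyquist={nyquist}]"
            )
        if self.op_split.mode == "fixed" and self.op_split.fixed_cutoff_hz >= nyquist:
            raise ConfigurationError("fixed cutoff must lie below Nyquist")
        if self.op_split.adaptive_search_hz[1] >= nyquist:
            raise ConfigurationError("adaptive search band must lie below Nyquist")
        if self.analysis_unit not in ("eye", "animal"):
            raise ConfigurationError(f"analysis_unit {self.analysis_unit!r} invalid")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["op_band_hz"] = list(self.op_band_hz)
        d["op_split"]["adaptive_search_hz"] = list(self.op_split.adaptive_search_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "op_split" in d and isinstance(d["op_split"], dict):
            sub = dict(d["op_split"])
            if "adaptive_search_hz" in sub:
                sub["adaptive_search_hz"] = tuple(sub["adaptive_search_hz"])
            d["op_split"] = OpSplitConfig(**sub)
        if "artifact_rejection" in d and isinstance(d["artifact_rejection"], dict):
            d["artifact_rejection"] = ArtifactConfig(**d["artifact_rejection"])
        if "op_band_hz" in d:
            d["op_band_hz"] = tuple(d["op_band_hz"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} does not hold a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise FormatError(f"bad config file {path}: {exc}") from exc

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Waveform tables (long format)
# ---------------------------------------------------------------------------

WAVEFORM_COLUMNS = [
    "animal_id",
    "eye_id",
    "genotype",
    "adaptation",
    "flash_strength",
    "sweep",
    "sample_index",
    "voltage_uv",
    "onset_index",
    "sampling_rate",
]


def _sep_for(path: Path) -> str:
    return "\t" if ".tsv" in path.suffixes or path.suffix == ".tsv" else ","


def read_waveforms(path: str | Path, config: RunConfig | None = None) -> list[SweepSet]:
    """Read a long-format waveform table into one SweepSet per eye × condition.

    The table must carry the columns in :data:`WAVEFORM_COLUMNS` (the
    ``onset_index`` and ``sampling_rate`` columns hold per-record metadata and
    must be constant within a record). Compressed variants (``.gz`` etc.) are
    handled by pandas transparently.
    """
    config = config or RunConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    required = [c for c in WAVEFORM_COLUMNS if c not in ("onset_index", "sampling_rate")]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"waveform table {path} is missing column {col!r}")
    bad = set(df["genotype"].astype(str)) - {g.value for g in Genotype}
    if bad:
        raise FormatError(f"unknown genotype label(s) {sorted(bad)!r} in {path}")
    if "onset_index" not in df.columns:
        raise ConfigurationError(
            f"waveform table {path} has no onset_index column; stimulus onset "
            "cannot be inferred from the data"
        )

    out: list[SweepSet] = []
    keys = ["animal_id", "eye_id", "adaptation", "flash_strength"]
    for (animal, eye, adapt, flash), grp in df.groupby(keys, sort=True):
        onsets = grp["onset_index"].unique()
        if len(onsets) != 1:
            raise IntegrityError(
                f"onset_index not constant for {animal}/{eye} {adapt} {flash}"
            )
        fs = (
            float(grp["sampling_rate"].iloc[0])
            if "sampling_rate" in grp.columns
            else config.sampling_rate
        )
        sweep_ids = sorted(grp["sweep"].unique())
        lengths = grp.groupby("sweep")["sample_index"].count()
        if lengths.nunique() != 1:
            raise IntegrityError(
                f"ragged sweep lengths for {animal}/{eye} {adapt} {flash}: "
                f"{sorted(set(lengths))}"
            )
        n_samples = int(lengths.iloc[0])
        mat = np.empty((len(sweep_ids), n_samples), dtype=float)
        for i, s in enumerate(sweep_ids):
            sub = grp[grp["sweep"] == s].sort_values("sample_index")
            if not np.array_equal(sub["sample_index"].to_numpy(), np.arange(n_samples)):
                raise IntegrityError(
                    f"sample indices of sweep {s} ({animal}/{eye}) are not 0..N-1"
                )
            mat[i] = sub["voltage_uv"].to_numpy()
        adaptation = Adaptation(str(adapt))
        cond = (
            StimulusCondition.da(float(flash))
            if adaptation is Adaptation.DA
            else StimulusCondition.la()
        )
        record_ms = n_samples / fs * 1000.0
        out.append(
            SweepSet(
                eye_id=str(eye),
                animal_id=str(animal),
                genotype=Genotype(str(grp["genotype"].iloc[0])),
                condition=cond,
                traces=mat,
                onset_index=int(onsets[0]),
                sampling_rate=fs,
                record_length_ms=record_ms,
            )
        )
    return out


def write_waveforms(sweepsets: Iterable[SweepSet], path: str | Path) -> None:
    """Write SweepSets to the long-format waveform table (inverse of read)."""
    path = Path(path)
    frames = []
    for ss in sorted(
        sweepsets,
        key=lambda s: (
            s.animal_id,
            s.eye_id,
            s.condition.adaptation.value,
            s.condition.flash_strength,
        ),
    ):
        n_sweeps, n_samples = ss.traces.shape
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(ss.animal_id, n_sweeps * n_samples),
                    "eye_id": ss.eye_id,
                    "genotype": ss.genotype.value,
                    "adaptation": ss.condition.adaptation.value,
                    "flash_strength": ss.condition.flash_strength,
                    "sweep": np.repeat(np.arange(n_sweeps), n_samples),
                    "sample_index": np.tile(np.arange(n_samples), n_sweeps),
                    "voltage_uv": ss.traces.ravel(),
                    "onset_index": ss.onset_index,
                    "sampling_rate": ss.sampling_rate,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Measures tables
# ---------------------------------------------------------------------------

MEASURES_COLUMNS = [
    "animal_id",
    "eye_id",
    "genotype",
    "adaptation",
    "flash_log_cdsm2",
    "baseline_uv",
    "a_amp_uv",
    "a_it_ms",
    "b_amp_uv",
    "b_it_ms",
    "op_amp_uv",
    "flags",
]


def measures_to_frame(measures: Sequence[ComponentMeasures]) -> pd.DataFrame:
    """Render measures as the canonical CSV frame (deterministic row order)."""
    rows = []
    for m in measures:
        rows.append(
            {
                "animal_id": m.animal_id,
                "eye_id": m.eye_id,
                "genotype": m.genotype.value,
                "adaptation": m.adaptation.value,
                "flash_log_cdsm2": m.flash_strength,
                "baseline_uv": m.baseline,
                "a_amp_uv": np.nan if m.a_amplitude is None else m.a_amplitude,
                "a_it_ms": np.nan if m.a_implicit_time is None else m.a_implicit_time,
                "b_amp_uv": m.b_amplitude,
                "b_it_ms": m.b_implicit_time,
                "op_amp_uv": np.nan
                if m.op_spectral_amplitude is None
                else m.op_spectral_amplitude,
                "flags": ";".join(sorted(m.flags)),
            }
        )
    df = pd.DataFrame(rows, columns=MEASURES_COLUMNS)
    df = df.sort_values(
        ["animal_id", "eye_id", "adaptation", "flash_log_cdsm2"]
    ).reset_index(drop=True)
    return df


def write_measures(measures: Sequence[ComponentMeasures], path: str | Path) -> None:
    if not len(measures):
        raise IntegrityError("refusing to write an empty measures table")
    df = measures_to_frame(measures)
    df.to_csv(Path(path), index=False)


def read_measures(path: str | Path) -> pd.DataFrame:
    """Read a measures CSV back into a frame (flags as strings, NaN = absent)."""
    df = pd.read_csv(Path(path), dtype={"flags": str}, float_precision="round_trip")
    for col in MEASURES_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"measures table {path} is missing column {col!r}")
    df["flags"] = df["flags"].fillna("")
    return df
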
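"""Seeded synthetic flash-ERG cohorts with calibrated genotype effect sizes.

The waveform model composes, for t ≥ 0 after stimulus onset (zero before):

* an a-component: a negative gamma-shaped transient with a sustained
  plateau (the photoreceptor response does not return to baseline within
  the record), absent at the two weakest dark-adapted flashes;
* a b-component: a positive gamma kernel;
* an OP component: a sinusoid under a Gaussian envelope riding the
  ascending limb of the b-wave, with its energy in the 60–100 Hz band.

Component amplitudes follow a Naka–Rushton saturation in linear flash
intensity; component peak latencies shorten linearly with log flash
strength. Genotype presets specify *measurement-scale* targets — the ratio
of measured mutant/WT amplitudes and the measured implicit-time shifts —
and :func:`calibrate_preset` solves for the internal multipliers/shifts
that make the pipeline's own noise-free measurements hit those targets.
This avoids bias from the trough-to-peak coupling between a- and
b-components and is the central correctness device of the generator.

Cohort structure: per-animal and per-eye log-normal amplitude factors plus
i.i.d. Gaussian sample noise per sweep; everything is reproducible from the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import optimize

from .data_model import (
    DA_FLASHES,
    Adaptation,
    AveragedWaveform,
    Genotype,
    RunConfig,
    StimulusCondition,
    SweepSet,
)
from .errors import CalibrationError, ConfigurationError
from .processing import isolate_ops
from .quantify import quantify_pair

__all__ = [
    "WaveformModelParams",
    "GenotypePreset",
    "CohortSpec",
    "InternalFactors",
    "PresetCalibration",
    "PRESETS",
    "PANEL_N_ANIMALS",
    "A_DETECTABLE_FLASHES",
    "waveform",
    "calibrate_preset",
    "generate_cohort",
    "generate_panel",
]

#: DA flashes at which an a-wave exists (and is measured)
A_DETECTABLE_FLASHES: tuple[float, ...] = (-1.7, -0.7, 0.3)

DEFAULT_ONSET_INDEX = 32


@dataclass(frozen=True)
class NakaRushton:
    """V(I) = Vmax · Iⁿ / (Iⁿ + σⁿ), I in linear cd·s/m²."""

    sigma: float  # semi-saturation, linear cd·s/m²
    exponent: float

    def fraction(self, log_intensity: float) -> float:
        i_n = (10.0 ** log_intensity) ** self.exponent
        return i_n / (i_n + self.sigma ** self.exponent)


@dataclass(frozen=True)
class WaveformModelParams:
    """Wild-type waveform model; absolute µV levels are plausible stand-ins
    (all downstream effect targets are relative, so they cancel)."""

    a_max: float = 280.0  # µV
    b_max: float = 300.0
    op_max: float = 45.0
    la_b_max: float = 120.0
    a_order: int = 3
    b_order: int = 7
    a_plateau: float = 0.55  # sustained fraction of the a-component
    nr_a: NakaRushton = field(default_factory=lambda: NakaRushton(10 ** -1.0, 0.8))
    nr_b: NakaRushton = field(default_factory=lambda: NakaRushton(10 ** -2.5, 0.6))
    nr_op: NakaRushton = field(default_factory=lambda: NakaRushton(10 ** -3.0, 0.55))
    # latency model: T(logI) = T0 − slope · (logI − ref), clipped at t_min
    a_t0_ms: float = 22.0  # at logI = −1.7
    a_latency_slope: float = 3.5  # ms per log unit
    b_t0_ms: float = 85.0  # at logI = −3.7
    b_latency_slope: float = 9.25
    t_min_ms: float = 5.0
    la_b_peak_ms: float = 45.0
    op_freq_hz: float = 76.0
    op_env_lead_ms: float = 10.0  # envelope centre = b-peak − lead
    op_env_sd_ms: float = 18.0
    shoulder_depth: float = 0.30  # fraction of b amplitude
    shoulder_lead_ms: float = 20.0
    shoulder_sd_ms: float = 6.0
    a_min_flash: float = -1.7  # a-component absent below this DA strength

    def __post_init__(self) -> None:
        if not (60.0 <= self.op_freq_hz <= 100.0):
            raise ConfigurationError("op_freq_hz must lie in the 60–100 Hz band")
        for name in ("a_max", "b_max", "op_max", "la_b_max"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be ≥ 0")

    def a_peak_ms(self, flash: float) -> float:
        return max(self.a_t0_ms - self.a_latency_slope * (flash + 1.7), self.t_min_ms)

    def b_peak_ms(self, flash: float) -> float:
        return max(self.b_t0_ms - self.b_latency_slope * (flash + 3.7), self.t_min_ms)


@dataclass(frozen=True)
class GenotypePreset:
    """Measurement-scale effect multipliers and latency shifts.

    ``k_*`` are target ratios of measured mutant/WT amplitudes; ``dt_*`` are
    target measured implicit-time differences in ms.
    """

    name: str
    k_a: float = 1.0
    k_b: float = 1.0
    k_op: float = 1.0
    k_b_la: float = 1.0
    dt_a_ms: float = 0.0
    dt_b_ms: float = 0.0
    electronegative_top_flash: bool = False
    shoulder: bool = False
    paper_anchored: bool = True

    def is_wildtype(self) -> bool:
        return (
            self.k_a == self.k_b == self.k_op == self.k_b_la == 1.0
            and self.dt_a_ms == self.dt_b_ms == 0.0
        )


PRESETS: dict[Genotype, GenotypePreset] = {
    Genotype.WT: GenotypePreset("WT"),
    Genotype.mdx: GenotypePreset(
        "mdx", k_a=0.87, k_b=0.83, dt_b_ms=-2.90
    ),
    Genotype.mdx5Cv: GenotypePreset("mdx5Cv", k_b=0.8442),
    Genotype.mdx2Cv: GenotypePreset(
        "mdx2Cv",
        k_b=0.767,
        k_op=0.6072,
        dt_a_ms=5.69,
        dt_b_ms=9.40,
        shoulder=True,
    ),
    # No effect sizes for mdx52 are anchored in this analysis; the default
    # preset interpolates between mdx2Cv and dmd_null and is excluded from
    # value-based validation.
    Genotype.mdx52: GenotypePreset(
        "mdx52",
        k_b=0.60,
        k_op=0.60,
        dt_a_ms=8.0,
        dt_b_ms=12.0,
        shoulder=True,
        paper_anchored=False,
    ),
    Genotype.dmd_null: GenotypePreset(
        "dmd_null",
        k_b=0.4549,
        k_op=0.5146,
        k_b_la=0.371,
        dt_a_ms=11.37,
        dt_b_ms=18.87,
        electronegative_top_flash=True,
        shoulder=True,
    ),
}

#: paper-scale group sizes: mutant genotype -> (n mutant animals, n WT animals)
PANEL_N_ANIMALS: dict[Genotype, tuple[int, int]] = {
    Genotype.mdx: (17, 16),
    Genotype.mdx5Cv: (17, 16),
    Genotype.mdx2Cv: (16, 16),
    Genotype.mdx52: (16, 16),
    Genotype.dmd_null: (14, 12),
}


@dataclass(frozen=True)
class InternalFactors:
    """Internal (pre-measurement) multipliers/shifts for one DA flash."""

    m_a: float = 1.0
    m_b: float = 1.0
    m_op: float = 1.0
    d_a_ms: float = 0.0
    d_b_ms: float = 0.0


@dataclass(frozen=True)
class PresetCalibration:
    da: dict[float, InternalFactors]
    m_b_la: float


@dataclass
class CohortSpec:
    """Sampling design of one synthetic cohort."""

    genotype: Genotype
    n_animals: int
    eyes_per_animal: int = 2
    noise_sd: float = 5.0  # µV per sample per sweep
    # Between-animal / between-eye log-normal amplitude variability. Kept
    # small enough that pooled normalized effects recover preset targets
    # within ±3 percentage points at paper-scale n.
    animal_effect_cv: float = 0.04
    eye_effect_cv: float = 0.02
    rng_seed: int = 0
    onset_index: int = DEFAULT_ONSET_INDEX
    id_prefix: str = ""

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be ≥ 1")
        if self.animal_effect_cv < 0 or self.eye_effect_cv < 0 or self.noise_sd < 0:
            raise ConfigurationError("variability parameters must be ≥ 0")


# ---------------------------------------------------------------------------
# Waveform composition
# ---------------------------------------------------------------------------


def _gamma_kernel(t_ms: np.ndarray, peak_ms: float, order: int) -> np.ndarray:
    """Unit-peak gamma kernel g(t) ∝ (t/τ)^n e^(−t/τ) with peak at n·τ."""
    out = np.zeros_like(t_ms)
    pos = t_ms > 0
    x = t_ms[pos] / peak_ms
    out[pos] = x ** order * np.exp(order * (1.0 - x))
    return out


def _a_kernel(t_ms: np.ndarray, peak_ms: float, order: int, plateau: float) -> np.ndarray:
    """Transient gamma plus a sustained plateau that persists to record end."""
    out = np.zeros_like(t_ms)
    pos = t_ms > 0
    x = t_ms[pos] / peak_ms
    transient = x ** order * np.exp(order * (1.0 - x))
    sustained = 1.0 - np.exp(-(x ** 3))
    out[pos] = (1.0 - plateau) * transient + plateau * sustained
    return out


def _time_axis(n_samples: int, onset_index: int, sampling_rate: float) -> np.ndarray:
    return (np.arange(n_samples) - onset_index) / sampling_rate * 1000.0


def waveform(
    model: WaveformModelParams,
    preset: GenotypePreset,
    flash: float,
    adaptation: Adaptation,
    factors: InternalFactors | None = None,
    m_b_la: float | None = None,
    sampling_rate: float = 512.0,
    n_samples: int = 128,
    onset_index: int = DEFAULT_ONSET_INDEX,
) -> np.ndarray:
    """Noise-free trace for one condition (µV, zero before stimulus onset).

    Without explicit ``factors`` the preset targets are applied directly as
    internal multipliers/shifts (adequate for WT; mutants should pass the
    output of :func:`calibrate_preset`).
    """
    flash = round(flash, 1)
    table = DA_FLASHES if adaptation is Adaptation.DA else (0.3,)
    if flash not in table:
        raise ConfigurationError(f"flash {flash} outside the {adaptation.value} protocol")
    t = _time_axis(n_samples, onset_index, sampling_rate)

    if adaptation is Adaptation.LA:
        m = m_b_la if m_b_la is not None else preset.k_b_la
        return m * model.la_b_max * _gamma_kernel(t, model.la_b_peak_ms, model.b_order)

    if factors is None:
        factors = InternalFactors(
            m_a=preset.k_a,
            m_b=preset.k_b,
            m_op=preset.k_op,
            d_a_ms=preset.dt_a_ms,
            d_b_ms=preset.dt_b_ms,
        )

    tp_a = model.a_peak_ms(flash)
    tp_b = model.b_peak_ms(flash)
    a_amp = (
        0.0
        if flash < model.a_min_flash - 1e-9
        else factors.m_a * model.a_max * model.nr_a.fraction(flash)
    )
    b_amp = factors.m_b * model.b_max * model.nr_b.fraction(flash)
    op_amp = factors.m_op * model.op_max * model.nr_op.fraction(flash)

    trace = np.zeros_like(t)
    if a_amp:
        trace -= a_amp * _a_kernel(t - factors.d_a_ms, tp_a, model.a_order, model.a_plateau)
    trace += b_amp * _gamma_kernel(t - factors.d_b_ms, tp_b, model.b_order)

    if op_amp:
        centre = tp_b - model.op_env_lead_ms + factors.d_b_ms
        env = np.exp(-0.5 * ((t - centre) / model.op_env_sd_ms) ** 2)
        carrier = np.sin(2.0 * np.pi * model.op_freq_hz * (t - centre) / 1000.0)
        trace += np.where(t > 0, op_amp * env * carrier, 0.0)

    if preset.shoulder and flash == 0.3:
        # cosmetic notch on the ascending limb at the top flash; never measured
        centre = tp_b + factors.d_b_ms - model.shoulder_lead_ms
        dip = np.exp(-0.5 * ((t - centre) / model.shoulder_sd_ms) ** 2)
        trace -= np.where(t > 0, model.shoulder_depth * b_amp * dip, 0.0)
    return trace


# ---------------------------------------------------------------------------
# Calibration against the pipeline's own measurements
# ---------------------------------------------------------------------------


def _measure_noise_free(
    trace: np.ndarray,
    flash: float,
    adaptation: Adaptation,
    config: RunConfig,
    onset_index: int,
):
    cond = (
        StimulusCondition.da(flash)
        if adaptation is Adaptation.DA
        else StimulusCondition.la()
    )
    w = AveragedWaveform(
        eye_id="cal",
        animal_id="cal",
        genotype=Genotype.WT,
        condition=cond,
        trace=trace,
        onset_index=onset_index,
        sampling_rate=config.sampling_rate,
        n_sweeps_used=1,
    )
    return quantify_pair(isolate_ops(w, config.op_split), config)


def _brentq_expand(fn, lo: float, hi: float, what: str) -> float:
    """brentq with bracket expansion; raises CalibrationError when no root."""
    flo, fhi = fn(lo), fn(hi)
    tries = 0
    while flo * fhi > 0 and tries < 6:
        lo, hi = max(lo * 0.5, 1e-9), hi * 1.6
        if what.startswith("d"):
            lo, hi = lo - 4.0, hi + 4.0
        flo, fhi = fn(lo), fn(hi)
        tries += 1
    if flo * fhi > 0:
        raise CalibrationError(
            f"cannot bracket a solution for {what}: f({lo})={flo:.4g}, "
            f"f({hi})={fhi:.4g}"
        )
    return float(optimize.brentq(fn, lo, hi, xtol=1e-6))


_CAL_CACHE: dict[tuple, PresetCalibration] = {}

RATIO_TOL = 0.002
TIME_TOL_MS = 0.25
_MAX_ROUNDS = 8


def calibrate_preset(
    model: WaveformModelParams,
    preset: GenotypePreset,
    config: RunConfig | None = None,
    onset_index: int = DEFAULT_ONSET_INDEX,
) -> PresetCalibration:
    """Solve internal factors so noise-free pipeline measurements hit the
    preset's measurement-scale targets at every flash strength.

    Per DA strength, coordinate-wise one-dimensional root finding alternates
    over (d_a, m_a, d_b, m_b, m_op) until measured mutant/WT amplitude
    ratios match ``k_*`` within 0.2 % and measured implicit-time shifts
    match ``dt_*`` within 0.25 ms. The LA multiplier is solved the same way.
    Results are cached per (model, preset, split-config) fingerprint.
    """
    config = config or RunConfig()
    key = (model, preset, config.op_split.mode, config.op_split.fixed_cutoff_hz,
           config.op_split.adaptive_search_hz, config.op_band_hz,
           config.sampling_rate, config.record_length_ms, onset_index)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    n_samples = int(round(config.sampling_rate * config.record_length_ms / 1000.0))

    def measure_da(flash: float, factors: InternalFactors):
        tr = waveform(
            model, preset, flash, Adaptation.DA, factors=factors,
            sampling_rate=config.sampling_rate, n_samples=n_samples,
            onset_index=onset_index,
        )
        return _measure_noise_free(tr, flash, Adaptation.DA, config, onset_index)

    wt_preset = PRESETS[Genotype.WT]

    def measure_wt(flash: float):
        tr = waveform(
            model, wt_preset, flash, Adaptation.DA,
            sampling_rate=config.sampling_rate, n_samples=n_samples,
            onset_index=onset_index,
        )
        return _measure_noise_free(tr, flash, Adaptation.DA, config, onset_index)

    da: dict[float, InternalFactors] = {}
    for flash in DA_FLASHES:
        wt = measure_wt(flash)
        has_a = flash >= model.a_min_flash - 1e-9
        f = InternalFactors(
            m_a=preset.k_a, m_b=preset.k_b, m_op=preset.k_op,
            d_a_ms=preset.dt_a_ms, d_b_ms=preset.dt_b_ms,
        )
        if preset.is_wildtype():
            da[flash] = f
            continue
        for _ in range(_MAX_ROUNDS):
            if has_a:
                if wt.a_amplitude is None:
                    raise CalibrationError(
                        f"WT a-wave undetected at {flash} log; model constants "
                        "are inconsistent with the detectability pattern"
                    )

                def res_da(d, f=f):
                    m = measure_da(flash, replace(f, d_a_ms=d))
                    if m.a_implicit_time is None:
                        return 1e3
                    return (m.a_implicit_time - wt.a_implicit_time) - preset.dt_a_ms

                d_a = _brentq_expand(
                    res_da, preset.dt_a_ms - 5.0, preset.dt_a_ms + 5.0, "d_a"
                )
                f = replace(f, d_a_ms=d_a)

                def res_ma(m, f=f):
                    meas = measure_da(flash, replace(f, m_a=m))
                    if meas.a_amplitude is None:
                        return -preset.k_a
                    return meas.a_amplitude / wt.a_amplitude - preset.k_a

                f = replace(f, m_a=_brentq_expand(res_ma, 0.05, 3.0, "m_a"))

            def res_db(d, f=f):
                m = measure_da(flash, replace(f, d_b_ms=d))
                return (m.b_implicit_time - wt.b_implicit_time) - preset.dt_b_ms

            d_b = _brentq_expand(
                res_db, preset.dt_b_ms - 5.0, preset.dt_b_ms + 5.0, "d_b"
            )
            f = replace(f, d_b_ms=d_b)

            def res_mb(m, f=f):
                return (
                    measure_da(flash, replace(f, m_b=m)).b_amplitude
                    / wt.b_amplitude
                    - preset.k_b
                )

            f = replace(f, m_b=_brentq_expand(res_mb, 0.02, 3.0, "m_b"))

            def res_mop(m, f=f):
                return (
                    measure_da(flash, replace(f, m_op=m)).op_spectral_amplitude
                    / wt.op_spectral_amplitude
                    - preset.k_op
                )

            f = replace(f, m_op=_brentq_expand(res_mop, 0.02, 3.0, "m_op"))

            final = measure_da(flash, f)
            errs = [
                abs(final.b_amplitude / wt.b_amplitude - preset.k_b),
                abs(
                    final.op_spectral_amplitude / wt.op_spectral_amplitude
                    - preset.k_op
                ),
                abs((final.b_implicit_time - wt.b_implicit_time) - preset.dt_b_ms)
                / (TIME_TOL_MS / RATIO_TOL),
            ]
            if has_a:
                if final.a_amplitude is None:
                    errs.append(1.0)
                else:
                    errs.append(abs(final.a_amplitude / wt.a_amplitude - preset.k_a))
                    errs.append(
                        abs(
                            (final.a_implicit_time - wt.a_implicit_time)
                            - preset.dt_a_ms
                        )
                        / (TIME_TOL_MS / RATIO_TOL)
                    )
            if max(errs) <= RATIO_TOL:
                break
        else:
            raise CalibrationError(
                f"calibration for {preset.name} did not converge at "
                f"{flash} log cd·s/m² (residuals {errs})"
            )
        da[flash] = f

    # LA: single multiplier, measured-from-baseline b-wave is linear in it
    def measure_la(m: float):
        tr = waveform(
            model, preset, 0.3, Adaptation.LA, m_b_la=m,
            sampling_rate=config.sampling_rate, n_samples=n_samples,
            onset_index=onset_index,
        )
        return _measure_noise_free(tr, 0.3, Adaptation.LA, config, onset_index)

    wt_la = measure_la(1.0).b_amplitude
    if preset.k_b_la == 1.0:
        m_la = 1.0
    else:
        m_la = _brentq_expand(
            lambda m: measure_la(m).b_amplitude / wt_la - preset.k_b_la,
            0.02, 3.0, "m_b_la",
        )

    cal = PresetCalibration(da=da, m_b_la=m_la)
    _CAL_CACHE[key] = cal
    return cal


# ---------------------------------------------------------------------------
# Cohorts and panels
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative factor with unit mean and the given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))


def _eye_conditions() -> list[StimulusCondition]:
    conds = [StimulusCondition.da(f) for f in DA_FLASHES]
    conds.append(StimulusCondition.la())
    return conds


def generate_cohort(
    spec: CohortSpec,
    model: WaveformModelParams | None = None,
    preset: GenotypePreset | None = None,
    config: RunConfig | None = None,
) -> list[SweepSet]:
    """Generate the full flash protocol for every eye of a seeded cohort.

    Each animal draws a log-normal amplitude factor, each eye a further
    factor; each sweep is the scaled noise-free eye waveform plus i.i.d.
    Gaussian sample noise. Identical (seed, spec) pairs give identical
    cohorts.
    """
    model = model or WaveformModelParams()
    preset = preset or PRESETS[spec.genotype]
    config = config or RunConfig()
    cal = calibrate_preset(model, preset, config, onset_index=spec.onset_index)

    n_samples = int(round(config.sampling_rate * config.record_length_ms / 1000.0))
    base: dict[tuple[str, float], np.ndarray] = {}
    for cond in _eye_conditions():
        if cond.adaptation is Adaptation.DA:
            tr = waveform(
                model, preset, cond.flash_strength, Adaptation.DA,
                factors=cal.da[cond.flash_strength],
                sampling_rate=config.sampling_rate, n_samples=n_samples,
                onset_index=spec.onset_index,
            )
        else:
            tr = waveform(
                model, preset, cond.flash_strength, Adaptation.LA,
                m_b_la=cal.m_b_la,
                sampling_rate=config.sampling_rate, n_samples=n_samples,
                onset_index=spec.onset_index,
            )
        base[(cond.adaptation.value, cond.flash_strength)] = tr

    rng = np.random.default_rng(spec.rng_seed)
    prefix = spec.id_prefix or f"{spec.genotype.value}-s{spec.rng_seed}"
    eye_labels = ["L", "R", "E3", "E4"][: spec.eyes_per_animal]

    out: list[SweepSet] = []
    for i in range(spec.n_animals):
        animal_id = f"{prefix}-a{i:02d}"
        f_animal = _lognormal_factor(rng, spec.animal_effect_cv)
        for eye in eye_labels:
            f_eye = f_animal * _lognormal_factor(rng, spec.eye_effect_cv)
            for cond in _eye_conditions():
                clean = base[(cond.adaptation.value, cond.flash_strength)] * f_eye
                noise = rng.normal(
                    0.0, spec.noise_sd, size=(cond.n_sweeps_nominal, n_samples)
                )
                out.append(
                    SweepSet(
                        eye_id=eye,
                        animal_id=animal_id,
                        genotype=spec.genotype,
                        condition=cond,
                        traces=clean[None, :] + noise,
                        onset_index=spec.onset_index,
                        sampling_rate=config.sampling_rate,
                        record_length_ms=config.record_length_ms,
                    )
                )
    return out


def generate_panel(
    seed: int,
    genotypes: Iterable[Genotype] | None = None,
    model: WaveformModelParams | None = None,
    config: RunConfig | None = None,
    noise_sd: float = 5.0,
    animal_effect_cv: float = 0.04,
    eye_effect_cv: float = 0.02,
) -> dict[Genotype, tuple[list[SweepSet], list[SweepSet]]]:
    """Generate each mutant cohort with its own WT littermate cohort.

    Returns ``{mutant genotype: (mutant sweepsets, matched WT sweepsets)}``
    with paper-scale group sizes and independent sub-seeds per cohort.
    """
    genotypes = list(genotypes) if genotypes is not None else list(PANEL_N_ANIMALS)
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(genotypes))
    out: dict[Genotype, tuple[list[SweepSet], list[SweepSet]]] = {}
    for j, g in enumerate(genotypes):
        n_mut, n_wt = PANEL_N_ANIMALS[g]
        mut_spec = CohortSpec(
            genotype=g, n_animals=n_mut, noise_sd=noise_sd,
            animal_effect_cv=animal_effect_cv, eye_effect_cv=eye_effect_cv,
            rng_seed=int(seeds[2 * j]), id_prefix=f"{g.value}-p{seed}",
        )
        wt_spec = CohortSpec(
            genotype=Genotype.WT, n_animals=n_wt, noise_sd=noise_sd,
            animal_effect_cv=animal_effect_cv, eye_effect_cv=eye_effect_cv,
            rng_seed=int(seeds[2 * j + 1]), id_prefix=f"WT-{g.value}-p{seed}",
        )
        out[g] = (
            generate_cohort(mut_spec, model=model, config=config),
            generate_cohort(wt_spec, model=model, config=config),
        )
    return out
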
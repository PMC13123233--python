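import numpy as np
import pytest

from ergflash.data_model import (
    Adaptation,
    AveragedWaveform,
    Genotype,
    RunConfig,
    StimulusCondition,
)
from ergflash.synth import PRESETS, CohortSpec, WaveformModelParams, generate_cohort, waveform

FS = 512.0
N_SAMPLES = 128
ONSET = 32


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def model() -> WaveformModelParams:
    return WaveformModelParams()


def make_waveform(trace, flash=0.3, adaptation=Adaptation.DA, onset=ONSET,
                  fs=FS, genotype=Genotype.WT, n_used=1):
    cond = (
        StimulusCondition.da(flash)
        if adaptation is Adaptation.DA
        else StimulusCondition.la()
    )
    return AveragedWaveform(
        eye_id="E", animal_id="A", genotype=genotype, condition=cond,
        trace=np.asarray(trace, dtype=float), onset_index=onset,
        sampling_rate=fs, n_sweeps_used=n_used,
    )


@pytest.fixture()
def sine80() -> np.ndarray:
    """Bin-aligned 80 Hz sinusoid, amplitude 10 µV, 128 samples @ 512 Hz."""
    t = np.arange(N_SAMPLES) / FS
    return 10.0 * np.sin(2 * np.pi * 80.0 * t)


@pytest.fixture(scope="session")
def wt_da_traces(model):
    """Noise-free WT traces for the five DA flash strengths."""
    return {
        flash: waveform(model, PRESETS[Genotype.WT], flash, Adaptation.DA)
        for flash in (-3.7, -2.7, -1.7, -0.7, 0.3)
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny noisy mdx cohort: 2 animals × 2 eyes × 6 conditions."""
    spec = CohortSpec(genotype=Genotype.mdx, n_animals=2, noise_sd=3.0, rng_seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, variability-free WT cohort (2 animals)."""
    spec = CohortSpec(
        genotype=Genotype.WT, n_animals=2, noise_sd=0.0,
        animal_effect_cv=0.0, eye_effect_cv=0.0, rng_seed=1,
    )
    return generate_cohort(spec)
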
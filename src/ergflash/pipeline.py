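"""End-to-end orchestration: sweeps → measures → normalized effects → stats.

This is the programmatic core behind the ``ergflash analyze`` command and
the parameter-recovery validation: generate (or read) cohorts, run artifact
rejection / averaging / OP isolation / component measurement, normalize to
the wild-type littermate group, and summarize pooled effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import (
    GroupComparisonResult,
    compare_groups_da,
    compare_groups_la,
    normalize_measures,
)
from .data_model import Genotype, RunConfig, SweepSet, measures_to_frame
from .errors import AnalysisError
from .processing import process_sweepset
from .quantify import quantify_pair
from .synth import (
    A_DETECTABLE_FLASHES,
    PANEL_N_ANIMALS,
    PRESETS,
    CohortSpec,
    WaveformModelParams,
    generate_cohort,
)

__all__ = ["measure_sweepsets", "RecoveryResult", "recover_effects", "EffectEstimates"]


def measure_sweepsets(sweepsets: list[SweepSet], config: RunConfig) -> pd.DataFrame:
    """Run the processing + quantification chain; one measures row per
    eye × condition, in the canonical column layout."""
    measures = [
        quantify_pair(process_sweepset(ss, config), config) for ss in sweepsets
    ]
    return measures_to_frame(measures)


@dataclass
class EffectEstimates:
    """Pooled normalized effect estimates for one mutant cohort vs its WT."""

    genotype: str
    b_amp_reduction_pct: float  # 100 − pooled % of WT, DA b-wave
    a_amp_reduction_pct: float | None
    op_reduction_pct: float
    la_b_amp_reduction_pct: float
    a_it_shift_ms: float | None  # pooled mutant − WT, detectable strengths
    b_it_shift_ms: float
    n_eyes_mutant: int
    n_eyes_wt: int


@dataclass
class RecoveryResult:
    estimates: EffectEstimates
    measures: pd.DataFrame


def _pooled(measures: pd.DataFrame, parameter: str, genotype: str,
            analysis_unit: str) -> float:
    res = normalize_measures(measures, parameter, analysis_unit=analysis_unit)
    return float(res.pooled.loc[genotype])


def estimate_effects(
    measures: pd.DataFrame, genotype: str, analysis_unit: str = "eye"
) -> EffectEstimates:
    """Pooled normalized effects for one mutant + WT measures table.

    a-wave parameters are pooled over the flash strengths where the a-wave
    is physiologically present (−1.7 log cd·s/m² and above); occasional
    spurious sub-threshold detections at weaker flashes are excluded.
    """
    da = measures["adaptation"] == "DA"
    a_ok = measures["flash_log_cdsm2"].round(1).isin([round(f, 1) for f in A_DETECTABLE_FLASHES])
    m_a = measures[~da | a_ok]

    b_pct = _pooled(measures, "b_amp", genotype, analysis_unit)
    op_pct = _pooled(measures, "op_amp", genotype, analysis_unit)
    la_pct = _pooled(measures, "la_b_amp", genotype, analysis_unit)
    b_it = _pooled(measures, "b_it", genotype, analysis_unit)
    try:
        a_pct = _pooled(m_a, "a_amp", genotype, analysis_unit)
        a_it = _pooled(m_a, "a_it", genotype, analysis_unit)
    except AnalysisError:
        a_pct = a_it = None

    eyes = measures.groupby("genotype").apply(
        lambda g: g[["animal_id", "eye_id"]].drop_duplicates().shape[0],
        include_groups=False,
    )
    return EffectEstimates(
        genotype=genotype,
        b_amp_reduction_pct=100.0 - b_pct,
        a_amp_reduction_pct=None if a_pct is None else 100.0 - a_pct,
        op_reduction_pct=100.0 - op_pct,
        la_b_amp_reduction_pct=100.0 - la_pct,
        a_it_shift_ms=a_it,
        b_it_shift_ms=b_it,
        n_eyes_mutant=int(eyes.get(genotype, 0)),
        n_eyes_wt=int(eyes.get("WT", 0)),
    )


def recover_effects(
    genotype: Genotype,
    seed: int,
    n_mutant: int | None = None,
    n_wt: int | None = None,
    noise_sd: float = 5.0,
    animal_effect_cv: float = 0.04,
    eye_effect_cv: float = 0.02,
    config: RunConfig | None = None,
    model: WaveformModelParams | None = None,
    analysis_unit: str = "eye",
) -> RecoveryResult:
    """Full parameter-recovery run for one mutant genotype at one seed.

    Generates a mutant cohort and a matched WT littermate cohort (paper-scale
    group sizes by default), runs the complete measurement pipeline on both,
    and returns pooled normalized effect estimates together with the raw
    measures table.
    """
    config = config or RunConfig()
    if n_mutant is None or n_wt is None:
        n_mutant, n_wt = PANEL_N_ANIMALS[genotype]
    seeds = __import__("numpy").random.SeedSequence(seed).generate_state(2)
    mut_spec = CohortSpec(
        genotype=genotype, n_animals=n_mutant, noise_sd=noise_sd,
        animal_effect_cv=animal_effect_cv, eye_effect_cv=eye_effect_cv,
        rng_seed=int(seeds[0]), id_prefix=f"{genotype.value}-s{seed}",
    )
    wt_spec = CohortSpec(
        genotype=Genotype.WT, n_animals=n_wt, noise_sd=noise_sd,
        animal_effect_cv=animal_effect_cv, eye_effect_cv=eye_effect_cv,
        rng_seed=int(seeds[1]), id_prefix=f"WT-{genotype.value}-s{seed}",
    )
    sweeps = generate_cohort(mut_spec, model=model, config=config)
    sweeps += generate_cohort(wt_spec, model=model, config=config)
    measures = measure_sweepsets(sweeps, config)
    est = estimate_effects(measures, genotype.value, analysis_unit=analysis_unit)
    return RecoveryResult(estimates=est, measures=measures)


def run_statistics(
    measures: pd.DataFrame, analysis_unit: str = "eye"
) -> dict[str, GroupComparisonResult]:
    """The statistical comparisons used in validation: DA b-wave two-way
    mixed ANOVA and LA b-wave one-way ANOVA."""
    return {
        "da_b_amp": compare_groups_da(measures, "b_amp", analysis_unit),
        "la_b_amp": compare_groups_la(measures, "la_b_amp", analysis_unit),
    }
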
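"""Littermate normalization, pooled effect summaries, and group statistics.

Amplitudes are expressed as percent of the wild-type littermate mean at the
same flash strength (WT mean = 100 % by construction); implicit times as the
difference in ms from the wild-type mean at the same strength. Per-strength
values are then averaged across flash strengths into a single pooled value
per genotype (and per analysis unit, for dispersion estimates).

The statistical decision tree mirrors standard repeated-measures practice:

* dark-adapted series → two-way mixed ANOVA (between: genotype, within:
  flash strength); Mauchly's test for sphericity; on violation the
  Greenhouse–Geisser correction is applied for severe violations
  (ε < 0.75) and Huynh–Feldt otherwise; post-hoc Bonferroni after a
  correction, Tukey without one;
* light-adapted single flash → Levene's test; homogeneous variances →
  one-way ANOVA + Tukey, otherwise Welch ANOVA + Games-Howell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import AnalysisError

__all__ = [
    "PARAMETERS",
    "SEVERITY_ORDER",
    "NormalizedResult",
    "GroupComparisonResult",
    "normalize_measures",
    "compare_groups_da",
    "compare_groups_la",
    "summarize_models",
]

#: parameter name -> (measures column, adaptation, normalization unit)
PARAMETERS: dict[str, tuple[str, str, str]] = {
    "a_amp": ("a_amp_uv", "DA", "percent_of_wt"),
    "b_amp": ("b_amp_uv", "DA", "percent_of_wt"),
    "op_amp": ("op_amp_uv", "DA", "percent_of_wt"),
    "la_b_amp": ("b_amp_uv", "LA", "percent_of_wt"),
    "a_it": ("a_it_ms", "DA", "delta_ms"),
    "b_it": ("b_it_ms", "DA", "delta_ms"),
    "la_b_it": ("b_it_ms", "LA", "delta_ms"),
}

#: genotype ordering by phenotype severity for model-comparison tables
SEVERITY_ORDER = ["mdx", "mdx5Cv", "mdx2Cv", "mdx52", "dmd_null"]

EPSILON_SEVERE = 0.75  # GG below, HF at/above


@dataclass
class NormalizedResult:
    """Normalized per-unit values plus pooled group summaries."""

    parameter: str
    unit: str  # percent_of_wt | delta_ms
    analysis_unit: str  # eye | animal
    values: pd.DataFrame  # per unit × flash: genotype, unit_id, flash, value
    per_strength: pd.DataFrame  # genotype × flash group means
    pooled_by_unit: pd.DataFrame  # genotype, unit_id, pooled value
    pooled: pd.Series  # genotype -> pooled group mean


def _unit_frame(measures: pd.DataFrame, parameter: str, analysis_unit: str) -> pd.DataFrame:
    """Select the parameter column and collapse to the analysis unit."""
    if parameter not in PARAMETERS:
        raise AnalysisError(f"unknown parameter {parameter!r}")
    col, adaptation, _ = PARAMETERS[parameter]
    df = measures[measures["adaptation"] == adaptation].copy()
    if df.empty:
        raise AnalysisError(f"no {adaptation} rows for parameter {parameter!r}")
    df = df.rename(columns={"flash_log_cdsm2": "flash"})
    df["value"] = df[col].astype(float)
    if analysis_unit == "animal":
        df = (
            df.groupby(["genotype", "animal_id", "flash"], as_index=False)["value"]
            .mean()
        )
        df["unit_id"] = df["animal_id"]
    elif analysis_unit == "eye":
        df["unit_id"] = df["animal_id"].astype(str) + "/" + df["eye_id"].astype(str)
    else:
        raise AnalysisError(f"unknown analysis unit {analysis_unit!r}")
    return df[["genotype", "unit_id", "flash", "value"]]


def normalize_measures(
    measures: pd.DataFrame,
    parameter: str,
    wt_genotype: str = "WT",
    analysis_unit: str = "eye",
) -> NormalizedResult:
    """Normalize a measures table to its wild-type group, per flash strength.

    Amplitude parameters become percent of the WT mean at the same strength;
    implicit-time parameters become the ms difference from that mean. Pooled
    values are means across flash strengths of the per-strength means.
    Missing values (e.g. undetected a-waves) are excluded stratum-wise.
    """
    _, _, unit = PARAMETERS[parameter]
    df = _unit_frame(measures, parameter, analysis_unit).dropna(subset=["value"])
    if wt_genotype not in set(df["genotype"]):
        raise AnalysisError(f"no {wt_genotype} rows available for normalization")
    wt = df[df["genotype"] == wt_genotype]
    wt_means = wt.groupby("flash")["value"].mean()
    out_rows = []
    for flash, grp in df.groupby("flash"):
        if flash not in wt_means.index:
            raise AnalysisError(
                f"no {wt_genotype} values at flash {flash} for {parameter}"
            )
        ref = wt_means.loc[flash]
        if unit == "percent_of_wt":
            if ref <= 0:
                raise AnalysisError(
                    f"{wt_genotype} mean at flash {flash} is {ref} µV; cannot "
                    f"normalize {parameter}"
                )
            vals = grp["value"] / ref * 100.0
        else:
            vals = grp["value"] - ref
        sub = grp.copy()
        sub["value"] = vals
        out_rows.append(sub)
    values = pd.concat(out_rows, ignore_index=True)
    per_strength = (
        values.groupby(["genotype", "flash"], as_index=False)["value"].mean()
    )
    pooled = per_strength.groupby("genotype")["value"].mean()
    pooled_by_unit = (
        values.groupby(["genotype", "unit_id"], as_index=False)["value"].mean()
    )
    return NormalizedResult(
        parameter=parameter,
        unit=unit,
        analysis_unit=analysis_unit,
        values=values,
        per_strength=per_strength,
        pooled_by_unit=pooled_by_unit,
        pooled=pooled,
    )


@dataclass
class GroupComparisonResult:
    design: str  # two_way_mixed | one_way
    p_genotype: float
    correction: str  # none | greenhouse_geisser | huynh_feldt | welch
    posthoc_method: str  # tukey | bonferroni | games_howell
    posthoc: pd.DataFrame
    p_within: float | None = None
    p_interaction: float | None = None
    sphericity_w: float | None = None
    sphericity_p: float | None = None
    epsilon: float | None = None
    levene_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in (self.p_genotype, self.p_within, self.p_interaction):
            if p is not None and not (0.0 <= p <= 1.0):
                raise AnalysisError(f"p-value {p} outside [0, 1]")


def _complete_cases(df: pd.DataFrame) -> pd.DataFrame:
    """Keep only units observed at every within level; error on empty cells."""
    levels = sorted(df["flash"].unique())
    counts = df.dropna(subset=["value"]).groupby("unit_id")["flash"].nunique()
    complete = counts[counts == len(levels)].index
    out = df[df["unit_id"].isin(complete)].dropna(subset=["value"])
    per_geno = out.groupby("genotype")["unit_id"].nunique()
    if out.empty or len(per_geno) < df["genotype"].nunique() or (per_geno < 2).any():
        raise AnalysisError(
            "incomplete within-factor design: a genotype retains fewer than 2 "
            "units with all flash strengths observed (no imputation is done)"
        )
    return out


def compare_groups_da(
    measures: pd.DataFrame, parameter: str, analysis_unit: str = "eye"
) -> GroupComparisonResult:
    """Two-way mixed ANOVA over the dark-adapted flash series.

    Between factor: genotype; within factor: flash strength; subject:
    analysis unit. Sphericity is assessed with Mauchly's test; on violation
    Greenhouse–Geisser degrees-of-freedom scaling is used when ε < 0.75 and
    Huynh–Feldt otherwise, and the post-hoc family switches from Tukey to
    Bonferroni.
    """
    df = _unit_frame(measures, parameter, analysis_unit)
    if df["genotype"].nunique() < 2:
        raise AnalysisError("need at least two genotypes for a group comparison")
    df = _complete_cases(df)

    aov = pg.mixed_anova(
        data=df,
        dv="value",
        within="flash",
        subject="unit_id",
        between="genotype",
        correction=False,
    ).set_index("Source")
    p_genotype = float(aov.loc["genotype", "p_unc"])
    f_within = float(aov.loc["flash", "F"])
    df1_w, df2_w = float(aov.loc["flash", "DF1"]), float(aov.loc["flash", "DF2"])
    f_inter = float(aov.loc["Interaction", "F"])
    df1_i, df2_i = (
        float(aov.loc["Interaction", "DF1"]),
        float(aov.loc["Interaction", "DF2"]),
    )

    spher = pg.sphericity(
        data=df, dv="value", within="flash", subject="unit_id", method="mauchly"
    )
    violated = bool(spher.pval < 0.05)
    correction = "none"
    epsilon = None
    p_within = float(stats.f.sf(f_within, df1_w, df2_w))
    p_interaction = float(stats.f.sf(f_inter, df1_i, df2_i))
    if violated:
        eps_gg = float(
            pg.epsilon(data=df, dv="value", within="flash", subject="unit_id",
                       correction="gg")
        )
        if eps_gg < EPSILON_SEVERE:
            correction, epsilon = "greenhouse_geisser", eps_gg
        else:
            eps_hf = float(
                pg.epsilon(data=df, dv="value", within="flash", subject="unit_id",
                           correction="hf")
            )
            correction, epsilon = "huynh_feldt", min(eps_hf, 1.0)
        p_within = float(stats.f.sf(f_within, df1_w * epsilon, df2_w * epsilon))
        p_interaction = float(stats.f.sf(f_inter, df1_i * epsilon, df2_i * epsilon))

    subject_means = df.groupby(["genotype", "unit_id"], as_index=False)["value"].mean()
    if correction == "none":
        posthoc_method = "tukey"
        posthoc = pg.pairwise_tukey(data=subject_means, dv="value", between="genotype")
    else:
        posthoc_method = "bonferroni"
        posthoc = pg.pairwise_tests(
            data=subject_means, dv="value", between="genotype", padjust="bonf"
        )

    return GroupComparisonResult(
        design="two_way_mixed",
        p_genotype=p_genotype,
        p_within=p_within,
        p_interaction=p_interaction,
        correction=correction,
        posthoc_method=posthoc_method,
        posthoc=posthoc,
        sphericity_w=float(spher.W),
        sphericity_p=float(spher.pval),
        epsilon=epsilon,
    )


def compare_groups_la(
    measures: pd.DataFrame, parameter: str = "la_b_amp", analysis_unit: str = "eye"
) -> GroupComparisonResult:
    """One-way ANOVA on the light-adapted flash, with the Levene → Welch →
    Games-Howell escalation on variance heterogeneity."""
    df = _unit_frame(measures, parameter, analysis_unit).dropna(subset=["value"])
    sizes = df.groupby("genotype")["value"].count()
    if len(sizes) < 2:
        raise AnalysisError("need at least two genotypes for a group comparison")
    if (sizes < 2).any():
        raise AnalysisError(f"group sizes below 2: {sizes.to_dict()}")

    lev = pg.homoscedasticity(data=df, dv="value", group="genotype", method="levene")
    levene_p = float(lev["pval"].iloc[0])
    homogeneous = bool(lev["equal_var"].iloc[0])
    if homogeneous:
        aov = pg.anova(data=df, dv="value", between="genotype")
        p = float(aov["p_unc"].iloc[0])
        correction = "none"
        posthoc_method = "tukey"
        posthoc = pg.pairwise_tukey(data=df, dv="value", between="genotype")
    else:
        aov = pg.welch_anova(data=df, dv="value", between="genotype")
        p = float(aov["p_unc"].iloc[0])
        correction = "welch"
        posthoc_method = "games_howell"
        posthoc = pg.pairwise_gameshowell(data=df, dv="value", between="genotype")

    return GroupComparisonResult(
        design="one_way",
        p_genotype=p,
        correction=correction,
        posthoc_method=posthoc_method,
        posthoc=posthoc,
        levene_p=levene_p,
    )


def summarize_models(
    arms: dict[str, pd.DataFrame],
    parameters: tuple[str, ...] = ("a_amp", "b_amp", "op_amp", "la_b_amp", "a_it", "b_it"),
    wt_genotype: str = "WT",
    analysis_unit: str = "eye",
) -> pd.DataFrame:
    """Cross-model comparison table of pooled normalized effects.

    ``arms`` maps mutant genotype name → measures frame holding that mutant
    together with its own WT littermate reference. One row per genotype ×
    parameter with the pooled value, SEM across analysis units, and n;
    rows are ordered by phenotype severity and the WT reference groups are
    not reported (they define the scale).
    """
    rows = []
    for genotype, measures in arms.items():
        for parameter in parameters:
            try:
                res = normalize_measures(
                    measures, parameter, wt_genotype=wt_genotype,
                    analysis_unit=analysis_unit,
                )
            except AnalysisError:
                continue
            per_unit = res.pooled_by_unit
            mut = per_unit[per_unit["genotype"] == genotype]["value"]
            if mut.empty:
                continue
            rows.append(
                {
                    "genotype": genotype,
                    "parameter": parameter,
                    "unit": res.unit,
                    "pooled": float(res.pooled.loc[genotype]),
                    "sem": float(mut.sem(ddof=1)) if len(mut) > 1 else np.nan,
                    "n_units": int(len(mut)),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    order = {g: i for i, g in enumerate(SEVERITY_ORDER)}
    table["_rank"] = table["genotype"].map(lambda g: order.get(g, len(order)))
    table = (
        table.sort_values(["_rank", "parameter"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return table
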
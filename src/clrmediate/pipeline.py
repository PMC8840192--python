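"""Grid orchestration: all genus x dietary-factor mediation models.

Runs one natural-effect mediation model per retained genus and dietary
factor, each with its own reference group (the group with the most
desirable adjusted intake of that factor), flags indirect effects at the
Bonferroni threshold for the full family of genus x factor x comparison
tests, and assembles the significant percent-mediated values into a
factor-by-genus matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as C
from .composition import clr_transform, prevalence_filter
from .diet import adjusted_group_means, select_reference_group
from .factors import DietFactorSpec
from .mediation import (
    MediationEstimate,
    bonferroni_threshold,
    bootstrap_mediation,
    transform_mediator,
)


@dataclass
class GridConfig:
    """Parameters of a full mediation-grid run."""

    prevalence_threshold: float = 0.5
    pseudocount: float = 1.0
    descriptive_covariates: tuple = C.DESCRIPTIVE_COVARIATES
    mediation_covariates: tuple = C.MEDIATION_COVARIATES
    n_boot: int = 100
    seed: int = 0
    alpha: float = 0.05
    hei_adjust: bool = False          # add diet-quality score as confounder
    hei_factor_name: str = "hei2015"
    clr_before_filter: bool = False   # CLR over all genera, then subset

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")


@dataclass(frozen=True)
class GridPlan:
    """Size and multiplicity bookkeeping of a mediation grid."""

    n_genera: int
    n_factors: int
    n_levels: int
    alpha: float

    @property
    def n_models(self) -> int:
        return self.n_genera * self.n_factors

    @property
    def n_comparisons(self) -> int:
        return self.n_levels - 1

    @property
    def n_nie_tests(self) -> int:
        return self.n_models * self.n_comparisons

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(
            self.alpha, self.n_genera, self.n_factors, self.n_comparisons)


def plan_grid(n_genera: int, n_factors: int, n_levels: int,
              alpha: float = 0.05) -> GridPlan:
    """Model/test counts and the Bonferroni threshold for a grid, without fitting."""
    if n_levels < 2:
        raise ValueError("need at least two exposure levels")
    return GridPlan(n_genera, n_factors, n_levels, alpha)


@dataclass
class MediationResult:
    """One fitted mediation model (one genus, one dietary factor)."""

    genus: str
    factor: str
    reference: str
    estimate: MediationEstimate
    threshold: float

    @property
    def effects(self) -> pd.DataFrame:
        out = self.estimate.effects.copy()
        out["significant"] = out["p_nie"] < self.threshold
        return out

    def to_rows(self) -> pd.DataFrame:
        out = self.effects.reset_index()
        out.insert(0, "reference", self.reference)
        out.insert(0, "factor", self.factor)
        out.insert(0, "genus", self.genus)
        return out


@dataclass
class GridResult:
    plan: GridPlan
    results: list[MediationResult]
    matrix: pd.DataFrame = field(repr=False)

    def to_long(self) -> pd.DataFrame:
        return pd.concat([r.to_rows() for r in self.results], ignore_index=True)


def run_grid(
    counts: pd.DataFrame,
    cohort: pd.DataFrame,
    factors: tuple[DietFactorSpec, ...],
    config: GridConfig = GridConfig(),
) -> GridResult:
    """Fit the full genus x dietary-factor mediation grid.

    For each factor: select its reference group from adjusted intake means,
    then for every retained genus decompose the group effect on the genus's
    CLR abundance into diet-mediated and direct components with bootstrap
    inference. NIE p-values are compared against the Bonferroni threshold
    for genera x factors x (levels - 1) tests; the returned matrix holds
    percent mediated for significant cells only ((factor, group) rows by
    genus columns).
    """
    C.validate_cohort(cohort)
    groups = cohort[C.GROUP]
    levels = sorted(groups.unique())

    kept = prevalence_filter(counts, groups, config.prevalence_threshold)
    if kept.shape[1] == 0:
        raise ValueError("no genus passed the prevalence filter")
    if config.clr_before_filter:
        clr = clr_transform(counts, config.pseudocount)[kept.columns]
    else:
        clr = clr_transform(kept, config.pseudocount)
    genera = list(clr.columns)

    plan = plan_grid(len(genera), len(factors), len(levels), config.alpha)
    seeds = np.random.SeedSequence(config.seed).spawn(plan.n_models)

    hei_model_scale = None
    if config.hei_adjust:
        hei_spec = next(f for f in factors if f.name == config.hei_factor_name)
        hei_model_scale = transform_mediator(
            cohort[hei_spec.name].to_numpy(), hei_spec)

    base_confounders = cohort[list(config.mediation_covariates)].to_numpy(float)
    results: list[MediationResult] = []
    model_idx = 0
    for spec in factors:
        means = adjusted_group_means(
            cohort, spec, config.descriptive_covariates)
        reference = select_reference_group(means, spec)
        mediator = transform_mediator(cohort[spec.name].to_numpy(), spec)
        confounders = base_confounders
        if config.hei_adjust and spec.name != config.hei_factor_name:
            confounders = np.column_stack([base_confounders, hei_model_scale])
        for genus in genera:
            seed = int(seeds[model_idx].generate_state(1)[0] & 0x7FFFFFFF)
            model_idx += 1
            est = bootstrap_mediation(
                clr[genus].to_numpy(), groups.to_numpy(), mediator,
                confounders, reference, n_boot=config.n_boot, seed=seed)
            results.append(MediationResult(
                genus=genus, factor=spec.name, reference=reference,
                estimate=est, threshold=plan.threshold))

    rows = pd.MultiIndex.from_tuples(
        [(spec.name, g) for spec in factors for g in levels],
        names=["factor", "group"])
    matrix = pd.DataFrame(np.nan, index=rows, columns=genera)
    for r in results:
        eff = r.effects
        for group, row in eff[eff["significant"]].iterrows():
            matrix.loc[(r.factor, group), r.genus] = row["percent_mediated"]
    matrix = matrix.dropna(how="all")
    return GridResult(plan=plan, results=results, matrix=matrix)


def adjusted_genus_means(
    clr: pd.DataFrame,
    cohort: pd.DataFrame,
    genera=None,
    covariates=C.GENUS_MEAN_COVARIATES,
) -> pd.DataFrame:
    """Covariate-adjusted per-group mean CLR abundance of each genus.

    Linear-model group means at the grand covariate means; the covariate set
    (age, sex, BMI, antibiotic use) deliberately differs from the diet
    descriptives, which adjust for energy instead of antibiotic use.
    Returns a long table (genus, group, estimate, lcl, ucl, p_value).
    """
    genera = list(clr.columns if genera is None else genera)
    missing = [g for g in genera if g not in clr.columns]
    if missing:
        raise ValueError(f"genera absent from the CLR matrix: {missing}")
    frames = []
    for genus in genera:
        temp = cohort.copy()
        temp["_outcome"] = clr[genus].reindex(cohort.index).to_numpy()
        spec = DietFactorSpec("_outcome", "adequacy", log_transform=False)
        means = adjusted_group_means(temp, spec, covariates)
        tab = means.table.reset_index(names="group")
        tab.insert(0, "genus", genus)
        tab["p_value"] = means.p_value
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def spearman_matrix(
    clr: pd.DataFrame,
    cohort: pd.DataFrame,
    genera=None,
    factor_names=None,
) -> pd.DataFrame:
    """Spearman rank correlation of each genus with each dietary factor.

    Returns genera x factors; a constant column yields NaN (not applicable).
    """
    genera = list(clr.columns if genera is None else genera)
    if factor_names is None:
        raise ValueError("factor_names is required")
    factor_names = list(factor_names)
    if len(clr) < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    G = clr[genera].to_numpy(float)
    F = cohort[factor_names].reindex(clr.index).to_numpy(float)
    out = np.full((len(genera), len(factor_names)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, _ in enumerate(factor_names):
            if np.ptp(F[:, j]) == 0:
                continue
            for i, _ in enumerate(genera):
                if np.ptp(G[:, i]) == 0:
                    continue
                out[i, j] = stats.spearmanr(G[:, i], F[:, j]).statistic
    return pd.DataFrame(out, index=pd.Index(genera, name="genus"),
                        columns=pd.Index(factor_names, name="factor"))


@dataclass
class FlowReport:
    """Participant-flow accounting through successive exclusion stages."""

    start: int
    stages: list[tuple[str, int, int]]  # (label, n_removed, n_remaining)

    @property
    def retained(self) -> int:
        return self.stages[-1][2] if self.stages else self.start

    def report(self) -> str:
        lines = [f"enrolled: {self.start}"]
        for label, removed, remaining in self.stages:
            lines.append(f"- {label}: removed {removed}, remaining {remaining}")
        lines.append(f"retained: {self.retained}")
        return "\n".join(lines)


def exclusion_cascade(removals, start: int) -> FlowReport:
    """Apply ordered (label, n_removed) exclusion stages to a starting count."""
    if start < 0:
        raise ValueError("start must be non-negative")
    remaining = start
    stages = []
    for label, removed in removals:
        if removed < 0:
            raise ValueError(f"stage {label!r}: negative removal count")
        remaining -= removed
        if remaining < 0:
            raise ValueError(f"stage {label!r}: removals exceed remaining participants")
        stages.append((str(label), int(removed), int(remaining)))
    return FlowReport(start=start, stages=stages)
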
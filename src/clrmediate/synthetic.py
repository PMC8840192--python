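"""Synthetic multi-group cohorts with known mediation ground truth.

The generator emulates the statistical structure the mediation analysis
assumes: five exposure groups with group-specific covariate distributions,
log-normal dietary intakes whose log-scale means shift by group, and genus
outcomes whose CLR-scale expectation is linear in group, diet and
covariates. Two modes are provided:

``sem``
    The CLR-scale outcome of each genus is produced directly by the linear
    structural equations, so estimator properties (bias, coverage, type-I
    error) can be checked against exact known natural effects.

``counts``
    The same linear structure produces a latent per-sample log-abundance
    vector, mapped through a softmax to multinomial genus counts at a fixed
    sequencing depth, so the full pipeline (prevalence filter -> CLR ->
    mediation) can be exercised end to end.

Structural equations (per participant i, factor f, genus g; z = fixed
standardized covariates):

    logM[i, f] = mu_f + alpha[f, group_i] + m'z_i + eps,   eps ~ N(0, sd_f)
    Y[i, g]    = beta[g, group_i] + sum_f gamma[g, f] * logM[i, f]
                 + o'z_i + eta,                            eta ~ N(0, noise_sd)

with alpha = beta = 0 for the reference group (the first configured group).
Because the outcome depends on the mediator through its log-scale value,
``alpha`` is the group effect on the modelled (log) mediator and
``gamma * alpha`` is the exact natural indirect effect of the group through
that factor; ``beta`` is the natural direct effect and the total effect is
their sum. These implied effects are carried in :class:`SimulationTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cohort as C

# Fixed centering/scaling used when covariates enter the structural
# equations; affine, so linear-model recovery of alpha/beta/gamma is exact.
_Z_CENTER = {C.AGE: 74.0, C.BMI: 26.5, C.ENERGY: 1900.0, C.SEX: 0.0, C.ANTIBIOTICS: 0.0}
_Z_SCALE = {C.AGE: 7.0, C.BMI: 5.0, C.ENERGY: 800.0, C.SEX: 1.0, C.ANTIBIOTICS: 1.0}

#: Default loadings of standardized covariates in the mediator equations.
DEFAULT_MEDIATOR_CONFOUNDER_COEFS = {
    C.AGE: 0.05, C.SEX: 0.10, C.BMI: -0.05, C.ENERGY: 0.15, C.ANTIBIOTICS: 0.0,
}
#: Default loadings of standardized covariates in the outcome equations.
DEFAULT_OUTCOME_CONFOUNDER_COEFS = {
    C.AGE: 0.10, C.SEX: -0.10, C.BMI: 0.05, C.ENERGY: 0.05, C.ANTIBIOTICS: -0.20,
}

_COVARIATE_KEYS = (
    "age_mean", "age_sd", "bmi_mean", "bmi_sd",
    "energy_mean", "energy_sd", "female_prop", "abx_prob",
)


@dataclass
class SimulationConfig:
    """Design of a synthetic cohort.

    Parameters
    ----------
    group_sizes:
        Ordered mapping of group label -> number of participants (>= 2
        each). The first group is the structural reference level.
    covariate_params:
        Per-group dict with keys ``age_mean, age_sd, bmi_mean, bmi_sd,
        energy_mean, energy_sd, female_prop, abx_prob``.
    diet_params:
        Per-factor dict with keys ``mean`` and ``sd`` (log-scale baseline
        intake for the reference group) and optional ``log`` (default True;
        set False for index-type factors generated on the raw scale, e.g. a
        0-100 diet-quality score).
    n_genera:
        Number of genus outcomes.
    sequencing_depth:
        Total counts per sample in counts mode (>= n_genera).
    noise_sd:
        SD of the outcome-equation residual (CLR units).
    seed:
        Global seed; sub-streams for covariates, diet, outcomes and counts
        are spawned from it so adding genera does not perturb covariate or
        diet draws.
    """

    group_sizes: dict[str, int]
    covariate_params: dict[str, dict[str, float]]
    diet_params: dict[str, dict[str, float]]
    n_genera: int
    sequencing_depth: int = 10_000
    noise_sd: float = 1.0
    base_logabund_sd: float = 1.0  # genus baseline spread in counts mode
    seed: int = 0
    mediator_confounder_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIATOR_CONFOUNDER_COEFS))
    outcome_confounder_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_CONFOUNDER_COEFS))

    def __post_init__(self) -> None:
        if len(self.group_sizes) < 2:
            raise ValueError("need at least two groups")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} must have size >= 2, got {n}")
        for g in self.group_sizes:
            if g not in self.covariate_params:
                raise ValueError(f"covariate_params missing for group {g!r}")
            missing = [k for k in _COVARIATE_KEYS if k not in self.covariate_params[g]]
            if missing:
                raise ValueError(f"covariate_params[{g!r}] missing {missing}")
            for k in ("age_sd", "bmi_sd", "energy_sd"):
                if self.covariate_params[g][k] <= 0:
                    raise ValueError(f"{k} must be > 0 for group {g!r}")
        for f, p in self.diet_params.items():
            if p.get("sd", 0) <= 0:
                raise ValueError(f"diet factor {f!r} must have sd > 0")
        if self.n_genera < 1:
            raise ValueError("n_genera must be positive")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.sequencing_depth < self.n_genera:
            raise ValueError("sequencing_depth must be >= n_genera")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.base_logabund_sd < 0:
            raise ValueError("base_logabund_sd must be >= 0")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)

    @property
    def reference_group(self) -> str:
        return next(iter(self.group_sizes))

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.diet_params)

    @property
    def genus_names(self) -> tuple[str, ...]:
        return tuple(f"genus_{i:03d}" for i in range(self.n_genera))

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def factor_is_log(self, factor: str) -> bool:
        return bool(self.diet_params[factor].get("log", True))

    # ---- serialization ------------------------------------------------
    def to_yaml(self, path) -> None:
        def _plain(d):  # numpy scalars -> YAML-safe builtins
            return {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                    for k, v in d.items()}

        payload = {
            "group_sizes": {g: int(n) for g, n in self.group_sizes.items()},
            "covariate_params": {g: _plain(p) for g, p in self.covariate_params.items()},
            "diet_params": {f: _plain(p) for f, p in self.diet_params.items()},
            "n_genera": self.n_genera,
            "sequencing_depth": self.sequencing_depth,
            "noise_sd": self.noise_sd,
            "base_logabund_sd": self.base_logabund_sd,
            "seed": self.seed,
            "mediator_confounder_coefs": dict(self.mediator_confounder_coefs),
            "outcome_confounder_coefs": dict(self.outcome_confounder_coefs),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class SimulationTruth:
    """Ground-truth coefficients and the natural effects they imply.

    ``alpha`` (factors x non-reference groups) is the group effect on the
    log-scale mediator; ``gamma`` (genera x factors) the mediator effect on
    the CLR outcome; ``beta`` (genera x non-reference groups) the direct
    group effect. For every (genus, factor, group) the implied natural
    indirect effect is ``gamma * alpha``, the direct effect is ``beta`` and
    the total effect is their sum, exactly.
    """

    groups: tuple[str, ...]
    alpha: pd.DataFrame
    gamma: pd.DataFrame
    beta: pd.DataFrame

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        nonref = list(self.groups[1:])
        if list(self.alpha.columns) != nonref or list(self.beta.columns) != nonref:
            raise ValueError("alpha/beta columns must equal the non-reference groups, in order")
        if list(self.gamma.columns) != list(self.alpha.index):
            raise ValueError("gamma columns must equal the alpha factor index")
        if list(self.beta.index) != list(self.gamma.index):
            raise ValueError("beta and gamma must share a genus index")

    @property
    def reference_group(self) -> str:
        return self.groups[0]

    @classmethod
    def zeros(cls, config: SimulationConfig) -> "SimulationTruth":
        groups, nonref = config.groups, list(config.groups[1:])
        factors, genera = list(config.factor_names), list(config.genus_names)
        return cls(
            groups=groups,
            alpha=pd.DataFrame(0.0, index=factors, columns=nonref),
            gamma=pd.DataFrame(0.0, index=genera, columns=factors),
            beta=pd.DataFrame(0.0, index=genera, columns=nonref),
        )

    def implied_effects(self) -> pd.DataFrame:
        """Long table of true NIE, NDE and TE per (genus, factor, group)."""
        rows = []
        for genus in self.gamma.index:
            for factor in self.alpha.index:
                for group in self.groups[1:]:
                    nie = self.gamma.loc[genus, factor] * self.alpha.loc[factor, group]
                    nde = self.beta.loc[genus, group]
                    rows.append((genus, factor, group, nie, nde, nde + nie))
        return pd.DataFrame(rows, columns=["genus", "factor", "group", "nie", "nde", "te"])

    def to_json(self, path) -> None:
        payload = {
            "groups": list(self.groups),
            "alpha": self.alpha.to_dict(orient="index"),
            "gamma": self.gamma.to_dict(orient="index"),
            "beta": self.beta.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        groups = tuple(payload["groups"])
        nonref = list(groups[1:])
        alpha = pd.DataFrame.from_dict(payload["alpha"], orient="index")[nonref]
        gamma = pd.DataFrame.from_dict(payload["gamma"], orient="index")
        gamma = gamma[list(alpha.index)]
        beta = pd.DataFrame.from_dict(payload["beta"], orient="index")[nonref]
        beta = beta.loc[list(gamma.index)]
        return cls(groups=groups, alpha=alpha, gamma=gamma, beta=beta)


def _check_dimensions(config: SimulationConfig, truth: SimulationTruth) -> None:
    if truth.groups != config.groups:
        raise ValueError(
            f"truth groups {truth.groups} do not match config groups {config.groups}")
    if tuple(truth.alpha.index) != config.factor_names:
        raise ValueError("truth factors do not match config diet_params")
    if tuple(truth.gamma.index) != config.genus_names:
        raise ValueError("truth genera do not match config n_genera")


def _standardized_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {k: (cov[k] - _Z_CENTER[k]) / _Z_SCALE[k] for k in _Z_CENTER},
        index=cov.index,
    )


def _generate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for g, n in config.group_sizes.items():
        p = config.covariate_params[g]
        frames.append(pd.DataFrame({
            C.GROUP: g,
            C.AGE: rng.normal(p["age_mean"], p["age_sd"], n),
            C.SEX: rng.binomial(1, p["female_prop"], n),
            C.BMI: rng.normal(p["bmi_mean"], p["bmi_sd"], n),
            C.ENERGY: np.maximum(rng.normal(p["energy_mean"], p["energy_sd"], n), 200.0),
            C.ANTIBIOTICS: rng.binomial(1, p["abx_prob"], n),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.index = pd.Index([f"S{i:05d}" for i in range(len(out))], name="sample_id")
    return out


def _generate_mediators(
    config: SimulationConfig,
    truth: SimulationTruth,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (raw-scale diet columns, model-scale mediator values)."""
    z = _standardized_covariates(covariates)
    conf_shift = sum(
        coef * z[k].to_numpy() for k, coef in config.mediator_confounder_coefs.items()
    )
    group_codes = covariates[C.GROUP].to_numpy()
    raw, model_scale = {}, {}
    for f in config.factor_names:
        p = config.diet_params[f]
        shift = np.zeros(len(covariates))
        for g in config.groups[1:]:
            shift[group_codes == g] = truth.alpha.loc[f, g]
        value = p["mean"] + shift + conf_shift + rng.normal(0.0, p["sd"], len(covariates))
        model_scale[f] = value
        raw[f] = np.exp(value) if config.factor_is_log(f) else value
    idx = covariates.index
    return (pd.DataFrame(raw, index=idx), pd.DataFrame(model_scale, index=idx))


def _linear_outcome_part(
    config: SimulationConfig,
    truth: SimulationTruth,
    covariates: pd.DataFrame,
    mediator_values: pd.DataFrame,
) -> np.ndarray:
    """n_samples x n_genera systematic component of the outcome equations."""
    z = _standardized_covariates(covariates)
    conf_shift = sum(
        coef * z[k].to_numpy() for k, coef in config.outcome_confounder_coefs.items()
    )
    group_codes = covariates[C.GROUP].to_numpy()
    n, G = len(covariates), config.n_genera
    eta = np.tile(conf_shift[:, None], (1, G))
    beta = truth.beta.to_numpy()  # genera x nonref groups
    for j, g in enumerate(config.groups[1:]):
        eta[group_codes == g] += beta[:, j]
    eta += mediator_values.to_numpy() @ truth.gamma.to_numpy().T
    return eta


def generate_sem_cohort(
    config: SimulationConfig, truth: SimulationTruth
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate a cohort whose genus outcomes follow the linear SEM directly.

    Returns ``(cohort, outcomes, truth)`` where ``cohort`` holds group,
    covariates and raw-scale diet columns, and ``outcomes`` holds one
    CLR-scale column per genus. Identical (config, truth) including the
    config seed give bit-identical output.
    """
    _check_dimensions(config, truth)
    ss = np.random.SeedSequence(config.seed).spawn(4)
    covariates = _generate_covariates(config, np.random.default_rng(ss[0]))
    raw_diet, model_diet = _generate_mediators(
        config, truth, covariates, np.random.default_rng(ss[1]))
    eta = _linear_outcome_part(config, truth, covariates, model_diet)
    noise = np.random.default_rng(ss[2]).normal(0.0, config.noise_sd, eta.shape)
    outcomes = pd.DataFrame(
        eta + noise, index=covariates.index, columns=list(config.genus_names))
    return pd.concat([covariates, raw_diet], axis=1), outcomes, truth


def generate_count_cohort(
    config: SimulationConfig, truth: SimulationTruth
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate a cohort with multinomial genus counts from the latent SEM.

    Latent per-sample log-abundances follow the same linear structure as sem
    mode plus a genus-specific baseline; counts are drawn multinomially at
    ``sequencing_depth`` from the row-wise softmax, so every row of the
    returned count matrix sums to the depth.
    """
    _check_dimensions(config, truth)
    ss = np.random.SeedSequence(config.seed).spawn(4)
    covariates = _generate_covariates(config, np.random.default_rng(ss[0]))
    raw_diet, model_diet = _generate_mediators(
        config, truth, covariates, np.random.default_rng(ss[1]))
    eta = _linear_outcome_part(config, truth, covariates, model_diet)
    rng = np.random.default_rng(ss[3])
    base = rng.normal(0.0, config.base_logabund_sd, config.n_genera)
    eta = eta + base + rng.normal(0.0, config.noise_sd, eta.shape)
    eta -= eta.max(axis=1, keepdims=True)  # softmax stability
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    counts = rng.multinomial(config.sequencing_depth, p)
    counts = pd.DataFrame(
        counts, index=covariates.index, columns=list(config.genus_names))
    return pd.concat([covariates, raw_diet], axis=1), counts, truth


# ---------------------------------------------------------------------------
# Default study-like configuration


def default_config(
    scale: float = 1.0,
    n_genera: int = 152,
    seed: int = 0,
    sequencing_depth: int = 10_000,
    noise_sd: float = 1.0,
) -> SimulationConfig:
    """A five-group cohort with study-scale sizes and covariate moments.

    Group sizes (918/750/684/1969/946, scaled by ``scale``) and covariate
    means/SDs follow the cohort the analysis targets: adults aged ~73-76 at
    stool collection, group-specific BMI and energy-intake distributions,
    roughly half women, and ~17-21% recent antibiotic use.
    """
    sizes = {"White": 918, "AfricanAmerican": 750, "NativeHawaiian": 684,
             "JapaneseAmerican": 1969, "Latino": 946}
    group_sizes = {g: max(2, int(round(n * scale))) for g, n in sizes.items()}
    covariate_params = {
        "White": dict(age_mean=73.5, age_sd=6.6, bmi_mean=26.0, bmi_sd=4.9,
                      energy_mean=1925, energy_sd=712, female_prop=0.49, abx_prob=0.21),
        "AfricanAmerican": dict(age_mean=75.3, age_sd=7.2, bmi_mean=28.3, bmi_sd=5.5,
                                energy_mean=1660, energy_sd=838, female_prop=0.60, abx_prob=0.17),
        "NativeHawaiian": dict(age_mean=72.8, age_sd=6.6, bmi_mean=28.3, bmi_sd=5.5,
                               energy_mean=2067, energy_sd=997, female_prop=0.57, abx_prob=0.17),
        "JapaneseAmerican": dict(age_mean=75.1, age_sd=7.1, bmi_mean=24.8, bmi_sd=4.4,
                                 energy_mean=1789, energy_sd=653, female_prop=0.49, abx_prob=0.17),
        "Latino": dict(age_mean=75.6, age_sd=6.4, bmi_mean=27.7, bmi_sd=5.0,
                       energy_mean=2006, energy_sd=952, female_prop=0.48, abx_prob=0.21),
    }
    # Reference-group (White) intake baselines; log-scale mean = ln(typical
    # intake), SD ~0.5-0.7 as usual for self-reported intake data.
    diet_params = {
        "hei2015": dict(mean=72.6, sd=10.0, log=False),
        "fruits": dict(mean=np.log(1.94), sd=0.6),
        "vegetables": dict(mean=np.log(2.32), sd=0.5),
        "nuts_seeds_legumes": dict(mean=np.log(37.4), sd=0.7),
        "whole_grains": dict(mean=np.log(52.4), sd=0.7),
        "dairy": dict(mean=np.log(1.54), sd=0.7),
        "fish": dict(mean=np.log(26.4), sd=0.7),
        "mufa_sfa_ratio": dict(mean=np.log(1.21), sd=0.25),
        "alcohol": dict(mean=np.log(12.9), sd=1.0),
        "red_meat": dict(mean=np.log(42.8), sd=0.7),
        "refined_grains": dict(mean=np.log(105.0), sd=0.6),
        "added_sugars": dict(mean=np.log(9.55), sd=0.7),
        "sugar_sweetened_beverages": dict(mean=np.log(90.0), sd=1.0),
        "saturated_fat": dict(mean=np.log(23.1), sd=0.5),
        "sodium": dict(mean=np.log(3.15), sd=0.4),
    }
    return SimulationConfig(
        group_sizes=group_sizes,
        covariate_params=covariate_params,
        diet_params=diet_params,
        n_genera=n_genera,
        sequencing_depth=sequencing_depth,
        noise_sd=noise_sd,
        seed=seed,
    )


#: Group-mean intakes by group (same units as the default diet baselines)
#: used by :func:`default_truth` to derive alpha shifts relative to the
#: reference group.
_DEFAULT_GROUP_MEANS = {
    "hei2015": {"White": 72.6, "AfricanAmerican": 72.9, "NativeHawaiian": 70.2,
                "JapaneseAmerican": 70.4, "Latino": 68.9},
    "fruits": {"White": 1.94, "AfricanAmerican": 1.94, "NativeHawaiian": 1.99,
               "JapaneseAmerican": 1.71, "Latino": 2.30},
    "vegetables": {"White": 2.32, "AfricanAmerican": 1.84, "NativeHawaiian": 2.51,
                   "JapaneseAmerican": 2.19, "Latino": 2.04},
    "nuts_seeds_legumes": {"White": 37.4, "AfricanAmerican": 30.1, "NativeHawaiian": 30.9,
                           "JapaneseAmerican": 30.9, "Latino": 29.5},
    "whole_grains": {"White": 52.4, "AfricanAmerican": 51.3, "NativeHawaiian": 52.4,
                     "JapaneseAmerican": 48.2, "Latino": 42.0},
    "dairy": {"White": 1.54, "AfricanAmerican": 1.00, "NativeHawaiian": 1.15,
              "JapaneseAmerican": 0.88, "Latino": 1.53},
    "fish": {"White": 26.4, "AfricanAmerican": 23.2, "NativeHawaiian": 35.7,
             "JapaneseAmerican": 31.2, "Latino": 18.7},
    "mufa_sfa_ratio": {"White": 1.21, "AfricanAmerican": 1.29, "NativeHawaiian": 1.28,
                       "JapaneseAmerican": 1.36, "Latino": 1.23},
    "alcohol": {"White": 12.9, "AfricanAmerican": 6.7, "NativeHawaiian": 7.5,
                "JapaneseAmerican": 4.1, "Latino": 6.4},
    "red_meat": {"White": 42.8, "AfricanAmerican": 32.9, "NativeHawaiian": 55.0,
                 "JapaneseAmerican": 47.9, "Latino": 40.8},
    "refined_grains": {"White": 105.0, "AfricanAmerican": 90.0, "NativeHawaiian": 141.0,
                       "JapaneseAmerican": 139.0, "Latino": 151.0},
    "added_sugars": {"White": 9.55, "AfricanAmerican": 9.38, "NativeHawaiian": 9.74,
                     "JapaneseAmerican": 7.38, "Latino": 9.43},
    "sugar_sweetened_beverages": {"White": 90.0, "AfricanAmerican": 145.0,
                                  "NativeHawaiian": 117.0, "JapaneseAmerican": 80.2,
                                  "Latino": 120.0},
    "saturated_fat": {"White": 23.1, "AfricanAmerican": 19.7, "NativeHawaiian": 23.6,
                      "JapaneseAmerican": 19.2, "Latino": 23.7},
    "sodium": {"White": 3.15, "AfricanAmerican": 2.66, "NativeHawaiian": 3.47,
               "JapaneseAmerican": 3.12, "Latino": 3.34},
}


def default_truth(config: SimulationConfig) -> SimulationTruth:
    """Truth with study-like diet shifts and a null microbiome.

    Alpha encodes realistic group differences in intake: for log-scale
    factors the shift is ``ln(mean_g / mean_ref)``; for raw-scale factors
    the arithmetic difference. Gamma and beta start at zero (no genus is
    affected by diet or group); plant effects by assigning into the returned
    frames.
    """
    truth = SimulationTruth.zeros(config)
    for f in config.factor_names:
        means = _DEFAULT_GROUP_MEANS.get(f)
        if means is None:
            continue
        ref_mean = means[config.reference_group]
        for g in config.groups[1:]:
            if config.factor_is_log(f):
                truth.alpha.loc[f, g] = float(np.log(means[g] / ref_mean))
            else:
                truth.alpha.loc[f, g] = float(means[g] - ref_mean)
    return truth
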
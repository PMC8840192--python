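import numpy as np
import pytest

from clrmediate.synthetic import SimulationConfig, SimulationTruth


def make_config(
    n_per_group: int = 50,
    n_groups: int = 5,
    n_factors: int = 1,
    n_genera: int = 1,
    seed: int = 0,
    noise_sd: float = 1.0,
    diet_sd: float = 0.5,
    sequencing_depth: int = 10_000,
) -> SimulationConfig:
    """A compact cohort design with homogeneous covariate distributions."""
    groups = [f"g{i}" for i in range(n_groups)]
    cov = dict(age_mean=74.0, age_sd=7.0, bmi_mean=26.5, bmi_sd=5.0,
               energy_mean=1900.0, energy_sd=800.0, female_prop=0.5,
               abx_prob=0.2)
    diet = {f"diet{j}": dict(mean=np.log(50.0), sd=diet_sd)
            for j in range(n_factors)}
    return SimulationConfig(
        group_sizes={g: n_per_group for g in groups},
        covariate_params={g: dict(cov) for g in groups},
        diet_params=diet,
        n_genera=n_genera,
        sequencing_depth=sequencing_depth,
        noise_sd=noise_sd,
        seed=seed,
    )


def planted_truth(config, alpha=0.0, gamma=0.0, beta=0.0,
                  factor=None, genus=None, group=None) -> SimulationTruth:
    """Zero truth with one (genus, factor, group) cell planted."""
    truth = SimulationTruth.zeros(config)
    factor = factor or config.factor_names[0]
    genus = genus or config.genus_names[0]
    group = group or config.groups[1]
    truth.alpha.loc[factor, group] = alpha
    truth.gamma.loc[genus, factor] = gamma
    truth.beta.loc[genus, group] = beta
    return truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
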
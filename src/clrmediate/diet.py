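"""Covariate-adjusted group means of dietary factors and reference selection.

For each dietary factor, a general linear model of the (log-transformed,
where applicable) factor on exposure-group dummies plus covariates yields
per-group model-predicted means at the grand covariate means, with 95%
confidence limits and an overall F-test p-value for group differences.
Log-modelled factors are back-transformed for display, so the reported
estimates are adjusted geometric means in the original units.

The group with the most desirable adjusted mean — highest for the
diet-quality index and adequacy components, lowest for moderation
components — becomes the reference level for that factor's mediation
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import DESCRIPTIVE_COVARIATES, GROUP
from .factors import DietFactorSpec


@dataclass
class AdjustedMeans:
    """Per-group adjusted means for one dietary factor.

    ``table`` is indexed by group label with columns ``estimate``, ``lcl``
    and ``ucl`` (original units); ``p_value`` is the overall F-test of any
    group difference (NaN when the outcome is degenerate).
    """

    factor: str
    table: pd.DataFrame
    p_value: float

    def __post_init__(self) -> None:
        bad = (self.table["lcl"] > self.table["estimate"]) | (
            self.table["estimate"] > self.table["ucl"])
        if bad.any():
            raise ValueError("confidence limits do not bracket the estimate")


def adjusted_group_means(
    cohort: pd.DataFrame,
    factor: DietFactorSpec,
    covariates=DESCRIPTIVE_COVARIATES,
    group_col: str = GROUP,
    conf_level: float = 0.95,
) -> AdjustedMeans:
    """Model-adjusted per-group means of one dietary factor.

    Fits OLS of the (possibly log) factor on group dummies + covariates and
    evaluates the fitted mean for each group at the grand covariate means.
    """
    y = cohort[factor.name].to_numpy(dtype=float)
    if factor.log_transform:
        if (y <= 0).any():
            raise ValueError(
                f"{factor.name}: zero or negative values cannot be log-transformed; "
                "add a positive offset or exclude the affected rows")
        y = np.log(y)

    groups = pd.Categorical(cohort[group_col])
    levels = list(groups.categories)
    dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    covs = cohort[list(covariates)].astype(float)
    for c in covariates:
        if covs[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    X = pd.concat(
        [pd.Series(1.0, index=cohort.index, name="const"),
         dummies.set_index(cohort.index), covs],
        axis=1,
    )
    res = sm.OLS(y, X).fit()

    cov_means = covs.mean().to_numpy()
    rows = {}
    for g in levels:
        contrast = np.zeros(X.shape[1])
        contrast[0] = 1.0
        for j, d in enumerate(dummies.columns, start=1):
            if d == g:
                contrast[j] = 1.0
        contrast[1 + dummies.shape[1]:] = cov_means
        tt = res.t_test(contrast)
        lcl, ucl = tt.conf_int(alpha=1 - conf_level)[0]
        rows[g] = (float(tt.effect[0]), float(lcl), float(ucl))
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["estimate", "lcl", "ucl"])
    if factor.log_transform:
        table = np.exp(table)

    if np.allclose(y, y[0]):
        p_value = float("nan")  # degenerate outcome: no group test
    else:
        R = np.zeros((dummies.shape[1], X.shape[1]))
        for j in range(dummies.shape[1]):
            R[j, 1 + j] = 1.0
        p_value = float(res.f_test(R).pvalue)
    return AdjustedMeans(factor=factor.name, table=table, p_value=p_value)


def select_reference_group(means: AdjustedMeans, factor: DietFactorSpec) -> str:
    """Group with the most desirable adjusted mean intake.

    Highest estimate for index/adequacy factors, lowest for moderation
    factors; exact ties break to the lexicographically first group label.
    """
    est = means.table["estimate"]
    if est.isna().any():
        missing = est.index[est.isna()][0]
        raise ValueError(f"missing adjusted mean for group {missing!r}")
    opt = est.max() if factor.higher_is_better else est.min()
    tied = sorted(str(g) for g in est.index[est == opt])
    return tied[0]


def diet_profile_table(
    cohort: pd.DataFrame,
    factors,
    covariates=DESCRIPTIVE_COVARIATES,
    group_col: str = GROUP,
) -> pd.DataFrame:
    """Descriptive table: one row per factor, per-group "mean (lcl, ucl)",
    overall p-value and the selected reference group."""
    rows = []
    for spec in factors:
        means = adjusted_group_means(cohort, spec, covariates, group_col)
        row = {"factor": spec.name, "class": spec.factor_class}
        for g, r in means.table.iterrows():
            row[str(g)] = f"{r.estimate:.3g} ({r.lcl:.3g}, {r.ucl:.3g})"
        row["p_value"] = means.p_value
        row["reference_group"] = select_reference_group(means, spec)
        rows.append(row)
    return pd.DataFrame(rows).set_index("factor")
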
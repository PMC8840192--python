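"""Column conventions for participant metadata tables.

A cohort table is a pandas DataFrame with one row per participant and, at
minimum, the exposure-group label plus the adjustment covariates. Dietary
factor columns (see :mod:`clrmediate.factors`) sit alongside.
"""

from __future__ import annotations

import pandas as pd

GROUP = "group"
AGE = "age"
SEX = "sex"  # 0/1 indicator (1 = female)
BMI = "bmi"
ENERGY = "energy"
ANTIBIOTICS = "antibiotics"  # 0/1 indicator of recent antibiotic use

#: Covariates for the descriptive diet-intake models.
DESCRIPTIVE_COVARIATES = (AGE, SEX, ENERGY, BMI)
#: Covariates for the mediation models (adds antibiotic use).
MEDIATION_COVARIATES = (AGE, SEX, ENERGY, BMI, ANTIBIOTICS)
#: Covariates for adjusted genus-abundance means (no energy, adds antibiotics).
GENUS_MEAN_COVARIATES = (AGE, SEX, BMI, ANTIBIOTICS)


def validate_cohort(cohort: pd.DataFrame, required=(GROUP,) + MEDIATION_COVARIATES) -> None:
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if cohort.index.has_duplicates:
        dup = cohort.index[cohort.index.duplicated()][0]
        raise ValueError(f"duplicate participant id: {dup!r}")
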
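"""Dietary-factor metadata.

The analysis treats 15 dietary variables as candidate mediators: one overall
diet-quality index (HEI-2015) plus 14 component foods/nutrients. Components
split into "adequacy" items (higher intake is desirable: fruits, vegetables,
nuts/seeds/legumes, whole grains, dairy, fish, MUFA/SFA ratio) and
"moderation" items (lower intake is desirable: alcohol, red meat, refined
grains, added sugars, sugar-sweetened beverages, saturated fat, sodium).

The class of a factor determines which exposure group serves as the
reference in mediation models (the group with the most desirable adjusted
mean intake), and whether the variable is log-transformed before modelling
(all factors except the index score, which lives on its own 0-100 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

FACTOR_CLASSES = ("index", "adequacy", "moderation")


@dataclass(frozen=True)
class DietFactorSpec:
    """Metadata for one dietary mediator variable.

    Parameters
    ----------
    name:
        Column name in the cohort table.
    factor_class:
        ``"index"`` (overall diet-quality score), ``"adequacy"`` (higher is
        better) or ``"moderation"`` (lower is better).
    log_transform:
        Whether the variable is log-transformed before entering linear
        models. Intake amounts are right-skewed and are modelled on the log
        scale; the index score is not.
    units:
        Free-text units for display.
    """

    name: str
    factor_class: str
    log_transform: bool = True
    units: str = ""

    def __post_init__(self) -> None:
        if self.factor_class not in FACTOR_CLASSES:
            raise ValueError(
                f"factor_class must be one of {FACTOR_CLASSES}, "
                f"got {self.factor_class!r}"
            )

    @property
    def higher_is_better(self) -> bool:
        """Whether a larger mean intake is the desirable extreme."""
        return self.factor_class in ("index", "adequacy")


#: The 15 dietary factors of the standard analysis grid: the HEI-2015 total
#: score plus its seven adequacy and seven moderation component intakes.
DEFAULT_FACTORS: tuple[DietFactorSpec, ...] = (
    DietFactorSpec("hei2015", "index", log_transform=False, units="score (0-100)"),
    DietFactorSpec("fruits", "adequacy", units="cups/day"),
    DietFactorSpec("vegetables", "adequacy", units="cups/day"),
    DietFactorSpec("nuts_seeds_legumes", "adequacy", units="g/day"),
    DietFactorSpec("whole_grains", "adequacy", units="g/day"),
    DietFactorSpec("dairy", "adequacy", units="cups/day"),
    DietFactorSpec("fish", "adequacy", units="g/day"),
    DietFactorSpec("mufa_sfa_ratio", "adequacy", units="ratio"),
    DietFactorSpec("alcohol", "moderation", units="g/day"),
    DietFactorSpec("red_meat", "moderation", units="g/day"),
    DietFactorSpec("refined_grains", "moderation", units="g/day"),
    DietFactorSpec("added_sugars", "moderation", units="tsp/day"),
    DietFactorSpec("sugar_sweetened_beverages", "moderation", units="g/day"),
    DietFactorSpec("saturated_fat", "moderation", units="g/day"),
    DietFactorSpec("sodium", "moderation", units="g/day"),
)


def factor_by_name(name: str, factors=DEFAULT_FACTORS) -> DietFactorSpec:
    for f in factors:
        if f.name == name:
            return f
    raise KeyError(f"unknown dietary factor {name!r}")
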
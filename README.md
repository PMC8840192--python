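# clrmediate

Diet-mediation analysis of group differences in gut microbial composition.

Cohort studies routinely observe that gut microbiome composition differs
between racial/ethnic (or other demographic) groups. `clrmediate` asks *how
much of each difference travels through habitual diet*: for every microbial
genus and every dietary factor, it decomposes the group difference in the
genus's centered log-ratio (CLR) abundance into a **natural indirect effect**
(the part mediated by intake of that factor) and a **natural direct effect**
(everything else), with bootstrap inference and Bonferroni control over the
full genus × factor × comparison grid. A synthetic-cohort generator with
fully known ground truth supports validation of every step.

## The model

For subject *i* with group *X*, dietary mediator *M* (log-transformed except
for index-type scores), CLR outcome *Y*, and confounders *C* (age, sex, BMI,
total energy, recent antibiotic use), the package fits the linear working
model

```
Y = β0 + Σ_x βx · 1[X = x] + βm · M + βc' C + ε
```

and applies the imputation approach to natural effect models: each subject's
record is expanded over all hypothetical exposure levels *x₀* with the
mediator-linked level *x₁* fixed at the observed group, outcomes are imputed
from the working model, and the natural effect model

```
Ŷ = θ0 + Σ θx₀ · 1[X₀ = x₀] + Σ θx₁ · 1[X₁ = x₁] + θc' C
```

is fitted on the expanded data. The *x₀* coefficients are natural direct
effects (NDE), the *x₁* coefficients natural indirect effects (NIE), and
TE = NDE + NIE exactly. In this linear no-interaction case the estimator is
algebraically identical to the product-of-coefficients decomposition, which
the test suite verifies to ~1e-15. Standard errors come from a stratified
subject-level bootstrap (B = 100 by default); percent mediated is
100 · NIE / TE.

Each dietary factor gets its own reference group: the group with the most
desirable covariate-adjusted mean intake (highest for index/adequacy
factors, lowest for moderation factors).

## Worked example

```python
from clrmediate import (
    default_config, default_truth, generate_count_cohort,
    DietFactorSpec, GridConfig, run_grid,
)

# synthetic 5-group cohort (quarter-scale, ~1300 subjects), 8 genera
config = default_config(scale=0.25, n_genera=8, seed=7)
truth = default_truth(config)               # realistic group diet profiles
truth.gamma.loc["genus_000", "red_meat"] = 0.8   # plant one mediated effect
cohort, counts, outcomes = generate_count_cohort(config, truth)

specs = (DietFactorSpec("red_meat", "moderation"),
         DietFactorSpec("vegetables", "adequacy"))
grid = run_grid(counts, cohort, specs, GridConfig(n_boot=100, seed=1))

long = grid.to_long()
print(long.loc[long.genus == "genus_000",
               ["factor", "reference", "group", "nie", "se_nie", "p_nie",
                "significant"]].round(4).to_string(index=False))
```

Output:

```
    factor       reference            group     nie  se_nie  p_nie  significant
  red_meat AfricanAmerican JapaneseAmerican  0.2817  0.0495 0.0000         True
  red_meat AfricanAmerican           Latino  0.1232  0.0440 0.0051        False
  red_meat AfricanAmerican   NativeHawaiian  0.3343  0.0557 0.0000         True
  red_meat AfricanAmerican            White  0.1707  0.0524 0.0011        False
vegetables  NativeHawaiian  AfricanAmerican -0.0083  0.0135 0.5396        False
vegetables  NativeHawaiian JapaneseAmerican -0.0054  0.0089 0.5448        False
vegetables  NativeHawaiian           Latino -0.0084  0.0130 0.5196        False
vegetables  NativeHawaiian            White -0.0015  0.0050 0.7594        False
```

The planted red-meat-mediated effect on `genus_000` is flagged (Bonferroni
threshold 0.05 / (8 · 2 · 4) ≈ 7.8e-4) for the two largest intake contrasts;
the unplanted vegetables factor shows nothing. `grid.matrix` assembles the
significant cells as a (factor, group) × genus table of percent mediated.

The same pipeline is available from the command line:

```bash
clrmediate simulate --mode counts --scale 0.25 --seed 7 --out-dir sim/
clrmediate mediate --counts sim/counts.tsv --cohort sim/cohort.tsv \
    --n-boot 100 --seed 1 --out-prefix results/grid
```

(`mediate` fits every built-in dietary factor found in the cohort table —
all fifteen for a simulated cohort.)

See `clrmediate --help` for the full set of subcommands (`simulate`,
`filter`, `clr`, `describe`, `mediate`, `report`).

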
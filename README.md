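# mobipw

Subgroup effect-heterogeneity analysis for observational cohort studies:
**stabilized inverse-probability weighting** combined with **model-based
recursive partitioning (MOB)** of weighted binary logistic exposure–outcome
models, plus per-subgroup inference.

The package targets the epidemiological question "*for whom* is an exposure
associated with an outcome?" in settings like neighbourhood green space and
self-rated health: a binary good/bad outcome, one exposure per run (a binary
access/greenness indicator, or a continuous NDVI-like greenness value), a
set of socio-demographic confounders, and a large battery (~40) of mixed
binary / Likert-ordinal / nominal candidate *moderator* covariates.

## Method

1. **Confounding adjustment.** Propensity scores e(X) = P(E=1 | X) by
   logistic regression (binary exposure) or generalized propensity densities
   f(E | X) via a linear exposure model with a Gaussian-kernel residual
   density (continuous exposure). Stabilized weights
   `sw_i = P(E = e_i) / P(E = e_i | X_i)` (densities in the continuous case)
   create a pseudo-randomized sample; balance is checked with absolute
   standardized mean differences (or weighted exposure–covariate
   correlations) against the conventional 0.1 threshold, and positivity with
   weight means/extremes and propensity overlap.
2. **Subgroup discovery.** MOB fits `logit P(Y=1) = β₀ + β₁E` by weighted
   maximum likelihood in each node, runs score-based parameter-instability
   tests (supLM for ordered moderators, a χ² form for nominal ones,
   Bonferroni-adjusted across candidates), splits on the most unstable
   moderator at the cut maximizing the children's summed log-likelihood, and
   stops at α = 0.05, minimum node size 100, maximum depth 3.
3. **Per-subgroup inference.** For every terminal node: OR = exp(β₁) with
   robust (sandwich) 95% CIs, weighted outcome prevalence, risk differences
   P[Y=1|E=1] − P[Y=1|E=0] with 2000-replicate percentile-bootstrap CIs
   (binary exposure), ORs rescaled per 0.1-unit increment (continuous
   exposure), and a Wald-contrast classification of each split as *slope
   heterogeneity* versus a mere *prevalence difference*.

Because cohort microdata of this kind are typically access-restricted, the
package ships a first-class synthetic cohort generator
(`mobipw.synthetic`) that emulates the study design — confounded exposure
assignment, calibrated marginals, and a *planted* partition with known
subgroup-specific (β₀, β₁) — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from mobipw import (make_kora_like_config, generate_cohort,
                    BinaryPropensityWeighter, MOBLogisticTree,
                    node_effects, effects_table)
from mobipw.weighting import design_matrix

cfg = make_kora_like_config("quality", seed=5)   # n = 2534, binary exposure
gen = generate_cohort(cfg)
table, df = gen.table, gen.table.df

w = BinaryPropensityWeighter().fit(design_matrix(table, table.confounders),
                                   df["exposure"].to_numpy(float))
tree = MOBLogisticTree(exposure="exposure", moderators=table.moderators,
                       kinds={c: m.kind for c, m in table.schema.items()})
tree.fit(df, df["good_health"].to_numpy(float), sample_weight=w.weights_)
print(tree.format_tree())
```

prints (node ids in brackets; β's are weighted logistic coefficients):

```
[1] n=2534 beta0=+1.054 beta1=+0.294 OR=1.341 (robust se 0.109)  split: discrimination_disability <= 0
  L [2] n=2162 beta0=+1.253 beta1=+0.245 OR=1.278 (robust se 0.123)  split: school_education <= 0
    L [3] n=970 beta0=+0.942 beta1=+0.717 OR=2.048 (robust se 0.192)  <terminal>
    R [4] n=1192 beta0=+1.563 beta1=-0.179 OR=0.836 (robust se 0.164)  <terminal>
  R [5] n=372 beta0=+0.146 beta1=+0.442 OR=1.555 (robust se 0.246)  <terminal>
```

The tree recovers the planted structure: the root split separates the
discrimination subgroup (lower good-health prevalence, node 5), and the
education split inside the non-discriminated branch separates a subgroup
with a strong positive exposure association (node 3, planted OR 2.66) from
one with none (node 4, planted OR 0.91). `effects_table(node_effects(...))`
then attaches robust CIs, prevalences and bootstrap risk differences per
node, and `classification_table(tree)` labels the education split as
*slope heterogeneity* and the discrimination split as a *prevalence
difference*.

A command-line interface mirrors the library:

```bash
mobipw simulate --seed 1 --out cohort.csv     # synthetic cohort + truth JSON
mobipw weight cohort.csv                      # stabilized IPW + balance CSV
mobipw tree cohort.csv --out tree.json        # grown MOB tree
mobipw or2x2 641 133 1285 475                 # -> OR 1.78 [95% CI: 1.44, 2.21]
mobipw run --config run.yaml                  # full pipeline with manifest
```

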
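# foodloss

Tools for studying how food-loss percentages (FLP) differ between developed
and developing countries across commodity groups and supply-chain stages.

Global food-loss reporting (SDG 12.3) is built on country-level loss
percentages that are irregular in time and strongly structured by national
development. This package implements a two-stage analysis of such data:

1. **A development typology from temporally weighted indicators.** Each
   country's GDP per capita, GDP growth rate, and health expenditure per
   capita are averaged over its observed years with exponential weights

   $$w_t = \frac{e^{\lambda\,[t - \min(t)]}}{\sum_{s} e^{\lambda\,[s - \min(t)]}},$$

   so recent years dominate as the decay parameter λ grows (λ = 0 is the
   uniform limit). The weighted profiles are z-standardized and partitioned
   by K-means; mean silhouette width and the within-cluster-sum-of-squares
   elbow select the cluster count, and a λ grid scan (0.00–0.50) scores
   classification stability and flags *borderline* countries whose label
   flips with λ — transitional economies whose early and late histories
   point to different groups.

2. **Random-intercept mixed models of loss percentages.** Per commodity
   group *g* (or supply-chain stage *s*), FLP is modelled as

   $$\mathrm{FLP}_{c,t} = \beta_0 + \beta_1 D_c + \beta_2 (t - 2000) + u_{0c} + \varepsilon_{c,t},$$

   with $D_c = 1$ for developing countries (developed reference),
   $u_{0c} \sim N(0, \sigma_u^2)$ a persistent country intercept, and
   $\varepsilon \sim N(0, \sigma_e^2)$. Estimation is maximum likelihood via
   the profiled likelihood in the variance ratio $\sigma_u^2/\sigma_e^2$;
   inference is Wald, and variance explained is reported as
   Nakagawa–Schielzeth marginal / conditional R².

Around these sit a screening stage (raw label → group categorization,
missing-data audit, coverage-based exclusions, listwise deletion — never
imputation), descriptive group means and per-cell OLS trends, a seeded
synthetic-data generator that emulates the assumed statistical structure,
and a CLI pipeline with run manifests.

## Worked example

```python
from foodloss import simulate, typology, screening, lmm

# a 105-country panel: 13 developed / 92 developing, irregular coverage
panel, truth = simulate.generate_indicator_panel(simulate.IndicatorSimConfig(seed=11))
grid = typology.sensitivity_analysis(panel, reference_lam=0.20, restarts=30, seed=0)
res = grid.results[0.20]
print(res.sizes, round(res.silhouette, 3), f"{100*grid.stability:.1f}%")

# food-loss records under the random-intercept model, screened
records, _ = simulate.generate_flp_panel(simulate.FLPSimConfig(seed=12), truth)
records, _ = screening.categorize(records)
screened, log = screening.apply_exclusions(records)

fits, table = lmm.fit_all_strata(screened, res.labels, by="commodity_group")
g = fits["grains"]
print(round(g.beta["developing"], 3), round(g.se["developing"], 3))
```

prints

```
{'developed': 13, 'developing': 92} 0.76 100.0%
-7.953 0.786
```

The clustering recovers the generative 13/92 split exactly and stays
stable across the whole λ grid (silhouette 0.760 at the reference λ).
After screening (1949 of 3150 records survive structural missingness and
listwise deletion), the grains model estimates a developing-country FLP
difference of −7.95 ± 0.79 points against a generative value of −8.02:
developing countries lose about 8 percentage points less grain, with
country identity (σ̂ᵤ = 1.64) carrying much of the remaining variance
(R²ₘ = 0.415, R²꜀ = 0.579).

The same analysis is available from the shell:

```sh
foodloss run --seed 5 --outdir run5     # simulate → screen → classify →
foodloss report run5                    # sensitivity → fit-mlm → trends → report
```

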
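# careshift

Counterfactual deviation analysis of monthly care-utilization count panels.

When an acute disruption (such as the COVID-19 pandemic) hits a health
system, every diagnosis shows a different mix of collapse, rebound, plateau
and recovery in its visit volumes. `careshift` implements a common analytical
framework for quantifying those shifts across hundreds of diagnosis entities
at once, for epidemiologists and health-services researchers working with
registry-style monthly count panels:

1. **Counterfactual forecasting.** For each entity, a log-link count
   regression is chosen from a prespecified ladder of seasonal-trend
   structures — monthly fixed effects or harmonics with 12-, 6- and 3-month
   periods, with or without a linear trend over years — by leave-one-year-out
   blocked cross-validation on pre-disruption data (lowest mean holdout MSE).
   Residuals of the selected fit are assessed for overdispersion and the
   entity is routed to a Poisson, over-dispersed Poisson (Var = φμ) or
   negative-binomial (Var = μ + μ²/θ) simulation family; Monte-Carlo draws
   from that family over the disruption window define the counterfactual
   distribution and its 95% prediction intervals.
2. **Deviation inference.** The primary outcome per entity and timeframe is

       δ = (observed − expected) / expected

   with percentile confidence intervals and two-sided empirical p-values from
   the Monte-Carlo counterfactual (add-one rule, p = (1 + #extreme)/(S + 1)),
   for months, calendar quarters and named windows (hiatus Mar–May 2020,
   post-hiatus Jun 2020–Dec 2021), Benjamini–Hochberg adjusted at FDR 0.05.
3. **Recovery.** An entity recovers at the first run of ≥ 3 consecutive
   months with no significant negative deviation (δ < 0, adjusted p ≤ 0.05);
   recovery is *sustained* if no significant negative month follows, else
   *partial*.
4. **Patterns.** Quarterly deviation trajectories are clustered
   (Euclidean distance, complete linkage), heatmap intensities are scored as
   sign(δ)·|δ|·(−log₁₀ p_adj), and severity associations are tested with
   univariable OLS, Wilcoxon rank-sum (VT vs NVT) and Kruskal–Wallis.

Entities are included only if every study month has counts above single
digits and the selected model's out-of-sample RMSPE is below 12.5%.

Because registry data of this kind are rarely public, the package ships a
synthetic panel generator with planted ground truth (baseline structure,
shock trajectory, cluster membership, severity), so the entire framework is
testable end to end.

## Worked example

The numbered drivers under `analysis/` run the framework on a synthetic
261-entity registry:

```sh
python analysis/01_simulate.py                       # panel.csv, truth.json, severity.csv
python analysis/02_fit_counterfactuals.py            # model selection + dispersion routing
python analysis/03_deviations_and_recovery.py --n-sims 5000
python analysis/04_patterns_and_severity.py
```

which prints, among other things:

```
selected specs: {'harmonics12+trend': 121, 'harmonics12': 61, ...}
routed families: {'poisson': 130, 'overdispersed_poisson': 72, 'negbin': 59}
out-of-sample RMSPE: mean 5.4% (SD 2.6%), >= 12.5%: 6 entities
included 255 of 261 entities
mean hiatus deviation: -0.445 (SD 0.099)
mean post_hiatus deviation: -0.155 (SD 0.129)
mean April 2020 deviation: -0.661 (SD 0.094)
recovery: 112/255 entities (53 sustained, 59 partial)
```

Reading: across the synthetic panel, April 2020 volumes sat 66% below their
counterfactual expectation on average; the post-hiatus average stayed 15.5%
below; 44% of entities achieved at least partial recovery. Six entities were
excluded for poor counterfactual model performance. All artifact tables
(deviations, prediction intervals, recovery, clusters, heatmap matrix,
severity tests, run report) land under `results/run/`.

The same pipeline is scriptable via the `careshift` CLI (`simulate`, `fit`,
`deviations`, `recovery`, `cluster`, `severity-test`, `run-all`) or the
library API:

```python
from careshift import SimConfig, generate_panel, MonthlyPanel, PipelineConfig, run_pipeline

panel = MonthlyPanel.from_long(generate_panel(SimConfig(n_entities=40, seed=0))[0])
result = run_pipeline(panel, PipelineConfig(n_sims=5000, seed=1))
print(result.report["period_summaries"])
```

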
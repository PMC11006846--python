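# hemobayes

Bayesian body-state analysis for invertebrate hemolymph blood-gas
panels: posterior-predictive **reference intervals** for basal
(pre-treatment) physiology and a paired **treatment-effect decision
rule**, built for the kind of pilot study in which garden snails
(*Cornu aspersum*) are bled before and after stunning by immersion in
CO₂-enriched cold water and a sixteen-analyte panel (pH, pCO₂, pO₂,
electrolytes, bicarbonate, osmolarity, …) is measured on a
point-of-care analyzer.

It is aimed at veterinary clinical-chemistry and animal-welfare
researchers who have small, unbalanced, skewed and heavy-tailed
paired samples and want fully reproducible interval estimates and
hypothesis decisions rather than ad-hoc normal-theory ones.

## The method

For each variable, with basal observations $y_1,\dots,y_n$:

1. **Extreme-outlier screening.** Compute quartiles $Q_1, Q_3$ and
   discard values outside $(l_1, l_2)$ with
   $l_1 = Q_1 - 3\,(Q_3-Q_1)$, $l_2 = Q_3 + 3\,(Q_3-Q_1)$,
   once, per (variable, treatment) stratum.
2. **Three candidate likelihoods.** Normal$(\mu,\sigma^2)$,
   location–scale Student-t$(\mu,\sigma,\nu)$ with $\nu>1$, and the
   Azzalini skew-normal$(\xi,\omega,\alpha)$ with density
   $\tfrac{2}{\omega}\,\varphi\!\big(\tfrac{y-\xi}{\omega}\big)\,
   \Phi\!\big(\alpha\tfrac{y-\xi}{\omega}\big)$.
   Posteriors are sampled by MCMC under weakly informative,
   scale-adaptive priors; $S = 5000$ draws by default.
3. **Model selection** by PSIS-LOO (Pareto-smoothed importance-sampling
   leave-one-out expected log predictive density), with an exact refit
   fallback for observations whose Pareto shape diagnostic exceeds 0.7.
4. **Reference interval.** From the selected model, draw one
   posterior-predictive value per posterior draw and report the
   empirical 1% and 99% quantiles $(Q^{01}_{pr}, Q^{99}_{pr})$:
   future measurements outside this range deserve inspection.
5. **Treatment effect.** For animals measured under both conditions,
   form $D_j = Y^{after}_j - Y^{before}_j$, screen the differences,
   fit the same three families, select by LOO, and estimate
   $P[\mu_D > 0 \mid d]$ from the posterior draws of the *mean* of
   $D$ (for the skew-normal, $\mu_D = \xi + \omega\delta\sqrt{2/\pi}$,
   $\delta = \alpha/\sqrt{1+\alpha^2}$). Reject
   $H_0: \mu_D = 0$ when the tail probability exceeds 0.99 or falls
   below 0.01; with $S=5000$ draws the estimate has resolution
   $1/S = 0.0002$, so extremes are reported as "< 0.0002" / "> 0.9998".

A calibrated synthetic-cohort generator (75 animals, per-variable
missingness, within-animal pre/post correlation, injected gross
outliers) emulates the study design, so the whole pipeline runs and is
tested without any external data, and a quantile reconstructor turns a
printed five-number summary (plus mean and sd) back into a plausible
sample for desk-scale re-analysis.

## Worked example

```python
import hemobayes as hb
from hemobayes.simulate import reconstruct_calibration_sample

# basal pH sample (n=73) reconstructed from its published summary row
y = reconstruct_calibration_sample("pH", "Bas")
fits = hb.fit_all_families(y, hb.FitConfig(seed=0))
sel = hb.select_family(fits, y)
ri = hb.reference_interval(fits[sel.selected], y, "pH", seed=1)

# paired treatment effect from published stratum summaries (~30 pairs)
s = hb.screen_differences(
    hb.simulate_paired("pH", 30, 7.53, 0.05, 7.15, 0.21, rho=0.5, seed=11)
)
res = hb.effect_analysis(s, hb.FitConfig(seed=1))
```

Output:

```text
LOO comparison (basal pH, n=73):
  normal       elpd_loo =   113.2 (se 8.2)
  student_t    elpd_loo =   115.7 (se 8.7)
  skew_normal  elpd_loo =   121.2 (se 7.9) <- selected
reference interval: (7.39, 7.61); observed range (7.37, 7.62)
effect: model=skew_normal, 98% CI for mean difference = (-0.47, -0.32),
        P[mu_D>0] < 0.0002, reject_H0
```

Reading: the skew-normal wins the LOO comparison for basal pH (the
sample is left-skewed — a long acidic tail), and commonly observable
basal pH lies in roughly (7.39, 7.61).  After CO₂ immersion the mean
pH drop is between −0.47 and −0.32 with 98% posterior probability, and
not a single one of the 5000 posterior draws of the mean difference is
positive — the hypercapnic acidification is unambiguous.

There is also a CLI:

```sh
hemobayes simulate --out cohort.csv --seed 1
hemobayes full --input cohort.csv --out results/ --seed 1
# or equivalently: hemobayes full --synthetic --out results/ --seed 1
```

which writes summary tables (raw and screened), the outlier audit, the
per-variable LOO selection report, the reference-interval and effects
tables, PPC/QQ export data and a provenance record.

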
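# dietgxe

Quantitative genetics of diet- and age-dependent trait variation in
inbred line panels (e.g. the *Drosophila* Genetic Reference Panel),
built as a reusable, fully tested analysis pipeline.

In a panel of inbred lines measured under two diets (control vs
nutrient-restricted) and at two adult ages, within-line genetic
variance is essentially zero, so among-line variance is genetic.  This
package covers the complete chain from raw data to genetic inference:

* **Trait derivation** — locomotor activity (total counts over 6 h of
  10-s activity-monitor bins at 23 °C) and heat-knockdown time (HKDT,
  minutes to the last recorded count at 39 °C), plus the dataset
  balancing rules (drop late test ages; keep lines represented on both
  diets).
* **Mixed-model ANOVA** — REML variance components for

  y<sub>ijk</sub> = μ + L<sub>i</sub> + A<sub>j</sub> + D<sub>k</sub> +
  L<sub>i</sub>×A<sub>j</sub> + L<sub>i</sub>×D<sub>k</sub> +
  A<sub>j</sub>×D<sub>k</sub> + L<sub>i</sub>×A<sub>j</sub>×D<sub>k</sub> +
  Rep(L×A×D) + e<sub>ijk</sub>

  with line terms random and age/diet fixed, including an exact
  Type-III expected-mean-squares oracle for balanced designs and a
  boundary-corrected likelihood-ratio test for individual variance
  components.
* **Broad-sense heritability** — H² = σ²<sub>G</sub>/(σ²<sub>G</sub>+σ²<sub>e</sub>)
  with σ²<sub>G</sub> = σ²<sub>L</sub>+σ²<sub>LA</sub>+σ²<sub>LD</sub>+σ²<sub>LAD</sub>,
  delta-method standard errors from the REML asymptotic covariance
  matrix, and 95% CIs H² ± 1.96·SE.
* **G×E decomposition** — cross-diet/cross-age genetic correlations
  ρ<sub>G</sub> = cov<sub>P</sub>/(σ<sub>Li</sub>σ<sub>Lj</sub>) of line
  means, SE = (1−ρ²)/√(n−3), and Cockerham's split of the interaction
  variance into re-ranking vs scale change:
  %rank = σ<sub>i</sub>σ<sub>j</sub>(1−ρ) / [σ<sub>i</sub>σ<sub>j</sub>(1−ρ) + (σ<sub>i</sub>−σ<sub>j</sub>)²/2].
* **Survival** — the diet effect on lifespan via Cox proportional
  hazards λ(t) = λ₀(t)·e<sup>βD</sup>, Newton–Raphson on the partial
  likelihood with Breslow (or Efron) ties and multi-category
  right-censoring bookkeeping.
* **Line-mean GWAS** — single-marker mixed-model scans on line means
  and on between-diet line-mean differences (a variant-by-diet
  interaction test), with Wolbachia/inversion covariate adjustment,
  a MAF-standardized genomic relationship matrix, MAF > 0.05 filtering
  and Bonferroni thresholds.
* **Synthetic panel generator** — genotypes, phenotypes, count series
  and censored lifespans with known truth, so every stage is validated
  against the parameters that generated its data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
packaged synthetic panel (50 lines × 2 diets × 2 ages × 3 replicates,
2000 variants, 8000 survival records; `configs/synthetic_small.yaml`):

```bash
python analysis/01_simulate_panel.py
python analysis/02_derive_and_balance.py
python analysis/03_variance_components.py
python analysis/04_gxe_correlations.py
python analysis/05_survival.py
python analysis/06_gwas.py
```

With the packaged seed, `03_variance_components.py` prints (excerpt)

```
        trait         subset    H2    se  ci_low  ci_high
dry_weight_mg           full 0.437 0.035   0.368    0.506
     hkdt_min           full 0.311 0.036   0.242    0.381
lifespan_days        control 0.359 0.048   0.264    0.453
lifespan_days     restricted 0.407 0.050   0.308    0.505
```

— broad-sense heritabilities with delta-method SEs; all are well away
from zero, as expected for a panel simulated with substantial among-line
variance.  `04_gxe_correlations.py` prints the G×E summary:

```
        trait axis   cond1      cond2  rho_G    se  pct_rank
dry_weight_mg diet control restricted  0.446 0.117    99.692
     hkdt_min diet control restricted  0.632 0.088    99.746
```

Genetic correlations across diets are well below one (the line-by-diet
boundary LRT in the same script gives p < 0.004 for every trait), and
the interaction variance is almost entirely re-ranking of lines rather
than variance-scale change — the simulated panel draws line-by-diet
effects independently per diet, which re-ranks lines without changing
the among-line variance.  `05_survival.py` prints

```
Cox diet effect (restricted vs control, breslow ties):
beta=0.16572 se=0.02502 z=6.62 p=3.49e-11
```

a significantly increased death hazard on the restricted diet (the
marginal β is attenuated below the conditional log-hazard ratio of
0.2586 used in the generator because the model, by design, omits the
strong line frailty — see `docs/methods.md`).  Finally `06_gwas.py`
reports a calibrated difference scan (λ_gc = 0.951) whose single
Bonferroni-significant hit is exactly the variant carrying the planted
diet-interaction effect:

```
difference scan: 1924 variants tested, Bonferroni p<2.6e-05, 1 significant
  hit: 2L:100 effect=0.01727 p=1.2e-07
```

The same pipeline is available as a CLI (`dietgxe run-all --config
configs/synthetic_small.yaml`, plus per-stage subcommands `simulate`,
`derive`, `varcomp`, `quantgen`, `cox`, `gwas`).

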
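# Reduced-scale synthetic panel: 50 lines x 2 diets x 2 ages x 3 reps,
# 2000 variants, 8000 survival flies.  Deterministic given the seed.
seed: 1
output_dir: results/synthetic_small
traits: [dry_weight_mg, locomotor_activity, hkdt_min]
balance: true
simulation:
  n_lines: 50
  n_variants: 2000
  n_reps: 3
  flies_per_rep: 4
  ages: [7, 16]
  n_survival_flies: 8000
  cox_beta_diet: 0.25859
  baseline_hazard: [weibull, 3.0, 24.0]
  frailty_sd: 0.9
  causal:
    - {trait: dry_weight_mg, variant: auto, additive: 0.0, diet_interaction: 0.05}
gwas:
  trait: dry_weight_mg
  modes: [difference, single]
  conditions: [control, restricted]
  maf_min: 0.05
  alpha: 0.05
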
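#!/usr/bin/env python
"""Fit the mixed ANOVA models and estimate heritabilities.

For each healthspan trait: the full line x age x diet model plus
per-cell reduced models; for lifespan: a diet model on observed deaths.
Also runs the boundary likelihood-ratio test for the line-by-diet
interaction (the G-by-D signal) on each trait.  Writes variance
components, heritabilities and interaction tests to results/varcomp/.
"""

import logging
from pathlib import Path

import pandas as pd

from dietgxe.io import read_phenotypes
from dietgxe.quantgen import estimate_H2
from dietgxe.traits import balance_dataset
from dietgxe.varcomp import ModelSpec, fit_mixed_model, test_random_term

REPO = Path(__file__).resolve().parents[1]
OUT = REPO / "results" / "varcomp"
TRAITS = ["dry_weight_mg", "locomotor_activity", "hkdt_min"]


def main():
    logging.basicConfig(level="WARNING")
    OUT.mkdir(parents=True, exist_ok=True)
    pheno, _ = read_phenotypes(REPO / "results/panel/phenotypes.csv")
    healthspan = pheno[pheno["age_days"].notna()]

    vc_rows, h2_rows, lrt_rows = [], [], []
    for trait in TRAITS:
        table = balance_dataset(healthspan, trait=trait).table
        full_spec = ModelSpec(trait=trait)
        full = fit_mixed_model(table, full_spec)
        for term, s2 in full.estimates.items():
            vc_rows.append({"trait": trait, "term": term, "sigma2": s2,
                            "boundary": term in full.boundary})
        h2 = estimate_H2(full)
        h2_rows.append({"trait": trait, "subset": "full", "H2": h2.H2,
                        "se": h2.se_H2, "ci_low": h2.ci_low,
                        "ci_high": h2.ci_high})

        # boundary LRT for the line:diet interaction (G-by-D)
        reduced_spec = ModelSpec(
            trait=trait,
            random=tuple(t for t in full_spec.random if t != "line:diet"),
        )
        reduced = fit_mixed_model(table, reduced_spec, compute_cov=False)
        full_nc = fit_mixed_model(table, full_spec, compute_cov=False)
        p = test_random_term(full_nc, reduced)
        lrt_rows.append({"trait": trait, "term": "line:diet", "p": p})

        for diet in ("control", "restricted"):
            for age in sorted(table["age_days"].unique()):
                spec = ModelSpec(trait=trait, fixed=(), random=("line", "rep"),
                                 diets=(diet,), ages=(int(age),))
                vc = fit_mixed_model(table, spec)
                h2 = estimate_H2(vc)
                h2_rows.append({"trait": trait, "subset": f"{diet}:{int(age)}",
                                "H2": h2.H2, "se": h2.se_H2,
                                "ci_low": h2.ci_low, "ci_high": h2.ci_high})

    surv = pheno[pheno["lifespan_days"].notna() & (pheno["censor_code"] == "none")]
    for label, spec in {
        "diets": ModelSpec(trait="lifespan_days", fixed=("diet",),
                           random=("line", "line:diet", "rep")),
        "control": ModelSpec(trait="lifespan_days", fixed=(),
                             random=("line", "rep"), diets=("control",)),
        "restricted": ModelSpec(trait="lifespan_days", fixed=(),
                                random=("line", "rep"), diets=("restricted",)),
    }.items():
        vc = fit_mixed_model(surv, spec)
        h2 = estimate_H2(vc)
        h2_rows.append({"trait": "lifespan_days", "subset": label, "H2": h2.H2,
                        "se": h2.se_H2, "ci_low": h2.ci_low,
                        "ci_high": h2.ci_high})

    pd.DataFrame(vc_rows).to_csv(OUT / "variance_components.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    pd.DataFrame(h2_rows).to_csv(OUT / "heritability.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    pd.DataFrame(lrt_rows).to_csv(OUT / "gxd_tests.tsv", sep="\t",
                                  index=False, float_format="%.4g")
    print("heritability estimates:")
    print(pd.DataFrame(h2_rows).to_string(index=False,
                                          float_format=lambda v: f"{v:.3f}"))
    print("\nline-by-diet boundary LRTs:")
    print(pd.DataFrame(lrt_rows).to_string(index=False))


if __name__ == "__main__":
    main()
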
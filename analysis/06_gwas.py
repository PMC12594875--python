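#!/usr/bin/env python
"""Line-mean GWAS: per-diet single-condition scans and the
difference-in-line-means variant-by-diet scan.

Adjusts line means for Wolbachia and inversion karyotypes, controls
polygenic relatedness with the MAF-standardized GRM, filters on
MAF > 0.05 and applies the Bonferroni threshold.  Writes per-variant
results plus Manhattan/Q-Q tables to results/gwas/.
"""

from pathlib import Path

import pandas as pd

from dietgxe.gwas import (
    adjust_covariates,
    bonferroni_threshold,
    compute_grm,
    genomic_control_lambda,
    gwas_scan,
    make_response,
    plot_tables,
)
from dietgxe.io import read_covariates, read_genotypes

REPO = Path(__file__).resolve().parents[1]
OUT = REPO / "results" / "gwas"
TRAIT = "dry_weight_mg"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    lm = pd.read_csv(REPO / "results/derived/line_means.tsv", sep="\t")
    geno = read_genotypes(REPO / "results/panel/genotypes.tsv")
    cov = read_covariates(REPO / "results/panel/covariates.csv")
    grm = compute_grm(geno, maf_min=0.05)

    scans = {}
    for mode, conditions in (
        ("difference", ("control", "restricted")),
        ("single", "control"),
    ):
        resp = make_response(lm[lm["trait"] == TRAIT], mode=mode,
                             conditions=conditions)
        resp = adjust_covariates(resp, cov)
        scan = gwas_scan(resp, geno, grm, maf_min=0.05)
        n_tested = int(scan["tested"].sum())
        thr = bonferroni_threshold(n_tested, 0.05)
        scan["significant"] = scan["p"] < thr
        scan.to_csv(OUT / f"gwas_{TRAIT}_{mode}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        tables = plot_tables(scan)
        tables["manhattan"].to_csv(OUT / f"manhattan_{mode}.tsv", sep="\t",
                                   index=False, float_format="%.6g")
        tables["qq"].to_csv(OUT / f"qq_{mode}.tsv", sep="\t", index=False,
                            float_format="%.6g")
        scans[mode] = scan
        lam = genomic_control_lambda(scan["p"].dropna())
        hits = scan[scan["significant"]]
        print(f"{mode} scan ({resp.description}): {n_tested} variants tested, "
              f"lambda_gc={lam:.3f}, Bonferroni p<{thr:.3g}, "
              f"{len(hits)} significant")
        for _, h in hits.iterrows():
            print(f"  hit: {h['chrom']}:{h['pos']} effect={h['effect']:.4g} "
                  f"p={h['p']:.3g}")


if __name__ == "__main__":
    main()
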
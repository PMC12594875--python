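#!/usr/bin/env python
"""Cross-environment genetic correlations and the rank/scale G-by-E
decomposition, plus phenotypic (Spearman) correlations.

For each trait: the cross-diet and cross-age genetic correlation of
line means with its SE and CI, the Cockerham %rank share (how much of
the interaction comes from re-ranking of lines vs changes in among-line
variance), and the corresponding Spearman correlations with Fisher-z
intervals.  Writes results/gxe/.
"""

from pathlib import Path

import pandas as pd

from dietgxe.quantgen import gxe_summary, spearman_correlation

REPO = Path(__file__).resolve().parents[1]
OUT = REPO / "results" / "gxe"
TRAITS = ["dry_weight_mg", "locomotor_activity", "hkdt_min"]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    lm = pd.read_csv(REPO / "results/derived/line_means.tsv", sep="\t")
    ls = pd.read_csv(REPO / "results/derived/line_means_lifespan.tsv", sep="\t")

    gxe_rows, sp_rows = [], []
    for trait, table, axes in (
        [(t, lm, ("diet", "age")) for t in TRAITS] + [("lifespan_days", ls, ("diet",))]
    ):
        sub = table[table["trait"] == trait]
        for axis in axes:
            s = gxe_summary(line_means=sub, trait=trait, axis=axis)
            rho, pr = s["rho_G"], s["pct_rank"]
            gxe_rows.append({
                "trait": trait, "axis": axis,
                "cond1": s["conditions"][0], "cond2": s["conditions"][1],
                "rho_G": rho.rho, "se": rho.se, "ci_low": rho.ci_low,
                "ci_high": rho.ci_high, "pct_rank": pr.pct_rank,
                "status": pr.status, "n_lines": s["n_shared_lines"],
            })
            col = "diet" if axis == "diet" else "age_days"
            wide = (sub.groupby(["line_id", col])["mean"].mean()
                    .unstack().dropna())
            c1, c2 = s["conditions"]
            sp = spearman_correlation(wide[c1], wide[c2])
            sp_rows.append({
                "trait": trait, "axis": axis, "rho_P": sp.rho, "se": sp.se,
                "ci_low": sp.ci_low, "ci_high": sp.ci_high, "n_lines": sp.n,
            })

    gxe = pd.DataFrame(gxe_rows)
    gxe.to_csv(OUT / "genetic_correlations.tsv", sep="\t", index=False,
               float_format="%.6g")
    pd.DataFrame(sp_rows).to_csv(OUT / "phenotypic_correlations.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    print("genetic correlations and %rank:")
    print(gxe.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
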
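"""Derived quantitative-genetic statistics.

Broad-sense heritability from variance components,

    H^2 = sigma2_G / (sigma2_G + sigma2_e),

with sigma2_G the sum of all line-involving components in the fitted
model (replicate variance enters neither numerator nor denominator; an
alternative with it folded into the denominator is reported alongside,
clearly labelled).  The standard error comes from the delta method on
(sigma2_G, sigma2_e) using the REML asymptotic covariance matrix:

    d H2/d sigma2_G =  sigma2_e / (sigma2_G + sigma2_e)^2
    d H2/d sigma2_e = -sigma2_G / (sigma2_G + sigma2_e)^2

and 95% intervals are H2 +/- 1.96 SE.

Cross-environment genetic correlations are plug-in ratios
rho_G = cov_P(i,j) / (sigma_Li sigma_Lj), with cov_P the covariance of
line means between the two conditions over shared lines; the estimator
is not range-constrained, so |rho| > 1 is flagged, never clamped.
Their SE is (1 - rho^2)/sqrt(n - 3) with n the number of shared lines.

The rank/scale decomposition of G-by-E variance (Cockerham) splits the
interaction into a re-ranking part sigma_Li sigma_Lj (1 - rho_G) and a
variance-magnitude part (sigma_Li - sigma_Lj)^2 / 2; %rank is the
re-ranking share.

Phenotypic correlations are Spearman rank correlations with the same SE
and a Fisher-z confidence interval, back-transformed with tanh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import compute_line_means
from .varcomp import VarianceComponents

__all__ = [
    "HeritabilityEstimate",
    "CorrelationEstimate",
    "RankDecomposition",
    "estimate_H2",
    "genetic_correlation",
    "percent_rank",
    "spearman_correlation",
    "gxe_summary",
]

_Z95 = 1.96


@dataclass
class HeritabilityEstimate:
    H2: float
    var_H2: float
    se_H2: float
    ci_low: float
    ci_high: float
    genetic_terms: tuple[str, ...]
    sigma2_G: float
    sigma2_e: float
    H2_with_rep: float | None = None   # alternative: rep variance in denominator
    clipped: bool = False


@dataclass
class CorrelationEstimate:
    rho: float
    kind: str                  # "genetic" | "spearman"
    se: float
    ci_low: float
    ci_high: float
    n: int
    out_of_range: bool = False
    fisher_z: float | None = None
    components: dict | None = None


@dataclass
class RankDecomposition:
    pct_rank: float | None
    rank_component: float
    scale_component: float
    sigma_i: float
    sigma_j: float
    rho_G: float
    status: str = "ok"         # "ok" | "no interaction"


def estimate_H2(vc: VarianceComponents) -> HeritabilityEstimate:
    """Broad-sense heritability with delta-method SE and 95% CI."""
    gen_terms = vc.spec.genetic_terms
    missing = [t for t in gen_terms if t not in vc.estimates]
    if missing:
        raise ValueError(f"components missing from fit: {missing}")
    s2g = float(sum(vc.estimates[t] for t in gen_terms))
    s2e = float(vc.estimates["e"])
    tot = s2g + s2e
    if tot <= 0:
        raise ValueError("all variance components are zero: H2 undefined (0/0)")
    h2 = s2g / tot

    var_h2 = np.nan
    se = np.nan
    if vc.asy_cov is not None:
        names = list(gen_terms)
        C = vc.asy_cov
        var_g = float(C.loc[names, names].to_numpy().sum())
        var_e = float(C.loc["e", "e"])
        cov_ge = float(C.loc[names, "e"].to_numpy().sum())
        dg = s2e / tot**2
        de = -s2g / tot**2
        var_h2 = dg * dg * var_g + de * de * var_e + 2 * dg * de * cov_ge
        se = float(np.sqrt(max(var_h2, 0.0)))
    lo, hi = h2 - _Z95 * se, h2 + _Z95 * se
    clipped = bool(np.isfinite(lo) and (lo < 0 or hi > 1))
    h2_rep = None
    if "rep" in vc.estimates:
        h2_rep = s2g / (tot + vc.estimates["rep"])
    return HeritabilityEstimate(
        H2=h2, var_H2=float(var_h2), se_H2=se,
        ci_low=float(np.clip(lo, 0.0, 1.0)) if np.isfinite(lo) else lo,
        ci_high=float(np.clip(hi, 0.0, 1.0)) if np.isfinite(hi) else hi,
        genetic_terms=tuple(gen_terms), sigma2_G=s2g, sigma2_e=s2e,
        H2_with_rep=h2_rep, clipped=clipped,
    )


def _corr_se(rho: float, n: int) -> float:
    if n <= 3:
        raise ValueError("need more than 3 paired lines for a standard error")
    return (1.0 - rho * rho) / np.sqrt(n - 3.0)


def genetic_correlation(
    cov_p_ij: float, sigma_li: float, sigma_lj: float, n_lines: int
) -> CorrelationEstimate:
    """Cross-condition genetic correlation from line-mean covariance.

    CI endpoints are rho +/- 1.96 SE on the raw correlation scale (no
    z-transform), matching the convention for genetic correlations.
    """
    if sigma_li <= 0 or sigma_lj <= 0:
        raise ValueError("no among-line variance in condition")
    rho = float(cov_p_ij / (sigma_li * sigma_lj))
    se = _corr_se(rho, n_lines)
    return CorrelationEstimate(
        rho=rho, kind="genetic", se=float(se),
        ci_low=float(rho - _Z95 * se), ci_high=float(rho + _Z95 * se),
        n=int(n_lines), out_of_range=bool(abs(rho) > 1),
        components={"cov_p": float(cov_p_ij), "sigma_li": float(sigma_li),
                    "sigma_lj": float(sigma_lj)},
    )


def percent_rank(sigma_li: float, sigma_lj: float, rho_g: float) -> RankDecomposition:
    """Share of G-by-E variance due to re-ranking of line means.

    %rank = s_i s_j (1 - rho) / [ s_i s_j (1 - rho) + (s_i - s_j)^2 / 2 ].
    A zero denominator (rho = 1 and equal sigmas) means there is no
    interaction variance to decompose.
    """
    if sigma_li < 0 or sigma_lj < 0:
        raise ValueError("sigmas must be non-negative")
    rank_c = sigma_li * sigma_lj * (1.0 - rho_g)
    scale_c = (sigma_li - sigma_lj) ** 2 / 2.0
    denom = rank_c + scale_c
    if denom <= 0:
        return RankDecomposition(
            pct_rank=None, rank_component=rank_c, scale_component=scale_c,
            sigma_i=sigma_li, sigma_j=sigma_lj, rho_G=rho_g,
            status="no interaction",
        )
    pct = 100.0 * rank_c / denom
    if rank_c >= 0:
        pct = float(np.clip(pct, 0.0, 100.0))   # guard fp noise at the ends
    return RankDecomposition(
        pct_rank=pct, rank_component=rank_c,
        scale_component=scale_c, sigma_i=sigma_li, sigma_j=sigma_lj,
        rho_G=rho_g, status="ok",
    )


def spearman_correlation(x, y) -> CorrelationEstimate:
    """Spearman rank correlation with Fisher-z 95% CI.

    Average ranks are used for ties.  SE = (1 - rho^2)/sqrt(n - 3); the
    CI is tanh(atanh(rho) +/- 1.96 SE).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired, non-missing lines")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    se = _corr_se(rho, n)
    if abs(rho) >= 1.0:
        z = np.inf if rho > 0 else -np.inf
        lo, hi = (rho, 1.0) if rho > 0 else (-1.0, rho)
    else:
        z = np.arctanh(rho)
        lo = float(np.tanh(z - _Z95 * se))
        hi = float(np.tanh(z + _Z95 * se))
    return CorrelationEstimate(
        rho=rho, kind="spearman", se=float(se), ci_low=lo, ci_high=hi,
        n=n, fisher_z=float(z),
    )


def gxe_summary(
    line_means: pd.DataFrame | None = None,
    trait: str | None = None,
    axis: str = "diet",
    conditions: tuple | None = None,
    table: pd.DataFrame | None = None,
    sigmas: dict | None = None,
) -> dict:
    """Genetic correlation and rank/scale decomposition across one axis.

    Takes a tidy line-means table (from `compute_line_means`) or a raw
    phenotype table, pairs line means across the two conditions of the
    chosen axis (``diet`` or ``age``), and assembles the genetic
    correlation and the Cockerham decomposition end to end.  Per-
    condition among-line SDs default to the SD of line means; pass
    ``sigmas={condition: sd}`` to use SDs from variance-component fits
    instead.
    """
    if axis not in ("diet", "age"):
        raise ValueError("axis must be 'diet' or 'age'")
    col = "diet" if axis == "diet" else "age_days"
    if line_means is None:
        if table is None or trait is None:
            raise ValueError("need a line-means table or a phenotype table + trait")
        line_means = compute_line_means(table, trait)
    lm = line_means
    if trait is not None and "trait" in lm.columns:
        lm = lm[lm["trait"] == trait]
    if conditions is None:
        conditions = tuple(sorted(lm[col].unique())[:2])
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    c1, c2 = conditions

    other = [c for c in ("diet", "age_days") if c != col and c in lm.columns
             and lm[c].nunique() > 1]
    if other:
        # average over the other axis so each line contributes one value
        lm = lm.groupby(["line_id", col], as_index=False)["mean"].mean()
    wide = lm.pivot_table(index="line_id", columns=col, values="mean")
    if c1 not in wide.columns or c2 not in wide.columns:
        raise ValueError(f"conditions {conditions} not both present")
    wide = wide[[c1, c2]].dropna()
    n = len(wide)
    if n < 4:
        raise ValueError("fewer than 4 shared lines across conditions")

    v1, v2 = wide[c1].to_numpy(), wide[c2].to_numpy()
    cov = float(np.cov(v1, v2, ddof=1)[0, 1])
    if sigmas is not None:
        s1, s2_ = float(sigmas[c1]), float(sigmas[c2])
    else:
        s1, s2_ = float(np.std(v1, ddof=1)), float(np.std(v2, ddof=1))
    corr = genetic_correlation(cov, s1, s2_, n)
    rho_eff = min(corr.rho, 1.0)   # decomposition uses a correlation <= 1
    decomp = percent_rank(s1, s2_, rho_eff)
    return {
        "trait": trait,
        "axis": axis,
        "conditions": (c1, c2),
        "rho_G": corr,
        "pct_rank": decomp,
        "sigma_L": {c1: s1, c2: s2_},
        "n_shared_lines": n,
        "shared_lines": list(wide.index),
    }
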
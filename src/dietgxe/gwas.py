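"""Single-marker association on line means with polygenic control.

The response is one value per line: a line mean in one condition, or
the difference in line means between two conditions — regressing the
difference on a variant's dosage tests for a variant-by-condition
interaction.  Wolbachia infection and inversion karyotypes are removed
by least-squares residualization first.  Relatedness is controlled with
a two-step mixed-model scan: the null model

    y = mu + g + e,   g ~ N(0, sigma2_g K),  e ~ N(0, sigma2_e I)

is fitted once by REML in the eigenbasis of the genomic relationship
matrix K, and every variant is then tested by generalized least squares
with that covariance held fixed (the standard eigendecomposition-based
scan).  Per-variant residual scale is re-estimated, so with K = I the
scan reduces exactly to ordinary per-variant least squares with a
t-test on n - 2 degrees of freedom.

Variants at or below the minor-allele-frequency threshold are flagged
untested, never silently dropped; MAF is computed among the lines that
enter the current response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix, INVERSIONS

__all__ = [
    "Grm",
    "ResponsePhenotype",
    "compute_grm",
    "make_response",
    "adjust_covariates",
    "gwas_scan",
    "bonferroni_threshold",
    "plot_tables",
    "genomic_control_lambda",
]


@dataclass
class Grm:
    """Line x line genomic relationship matrix."""

    matrix: np.ndarray
    line_ids: list[str]
    n_variants_used: int
    scaling: str = "maf-standardized"

    def __post_init__(self):
        K = self.matrix
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("GRM is not positive semi-definite")


@dataclass
class ResponsePhenotype:
    values: pd.Series                 # indexed by line_id
    description: str
    adjusted: bool = False
    excluded_lines: list[str] = field(default_factory=list)


def compute_grm(genotypes: GenotypeMatrix, maf_min: float = 0.05) -> Grm:
    """MAF-standardized relationship matrix from homozygous dosages.

    Dosages are centered at 2p and scaled by sqrt(4 p (1-p)) — the
    dosage SD for a fully inbred panel — then K = Z Z' / M.  Under this
    scaling the diagonal averages about 1.
    """
    maf = genotypes.maf()
    use = maf > maf_min
    if use.sum() < 2:
        raise ValueError("fewer than 2 variants pass the MAF threshold")
    X = genotypes.dosages[:, use]
    p = np.nanmean(X, axis=0) / 2.0
    Z = (np.nan_to_num(X, nan=0.0) - 2.0 * p[None, :]) / np.sqrt(
        4.0 * p * (1.0 - p)
    )[None, :]
    M = int(use.sum())
    K = Z @ Z.T / M
    return Grm(matrix=K, line_ids=list(genotypes.line_ids), n_variants_used=M)


def make_response(
    line_means: pd.DataFrame,
    mode: str = "single",
    conditions=None,
    trait: str | None = None,
    condition_col: str = "diet",
) -> ResponsePhenotype:
    """Per-line response: a condition's line mean, or the difference
    between two conditions (condition1 - condition2).

    Lines missing either condition in difference mode are excluded and
    reported.
    """
    lm = line_means
    if trait is not None and "trait" in lm.columns:
        lm = lm[lm["trait"] == trait]
    if lm.empty:
        raise ValueError("no line means for the requested trait")
    other = [c for c in ("diet", "age_days") if c != condition_col
             and c in lm.columns and lm[c].nunique() > 1]
    if other:
        lm = lm.groupby(["line_id", condition_col], as_index=False)["mean"].mean()
    wide = lm.pivot_table(index="line_id", columns=condition_col, values="mean")

    if mode == "single":
        cond = conditions if not isinstance(conditions, (tuple, list)) else conditions[0]
        if cond is None:
            raise ValueError("single mode requires a condition")
        vals = wide[cond].dropna()
        desc = f"line means | {condition_col}={cond}"
        excluded = sorted(set(wide.index) - set(vals.index))
    elif mode == "difference":
        if conditions is None or len(conditions) != 2:
            raise ValueError("difference mode requires two conditions")
        c1, c2 = conditions
        both = wide[[c1, c2]].dropna()
        if both.empty:
            raise ValueError("no lines observed in both conditions")
        vals = both[c1] - both[c2]
        desc = f"line-mean difference | {condition_col}: {c1} - {c2}"
        excluded = sorted(set(wide.index) - set(both.index))
    else:
        raise ValueError("mode must be 'single' or 'difference'")
    if vals.empty:
        raise ValueError("no overlapping lines for the response")
    vals.name = "response"
    return ResponsePhenotype(values=vals, description=desc, excluded_lines=excluded)


def _covariate_design(cov: pd.DataFrame, line_ids) -> tuple[np.ndarray, list[str]]:
    cov = cov.set_index("line_id").loc[list(line_ids)]
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    if "wolbachia" in cov.columns:
        cols.append(cov["wolbachia"].astype(float).to_numpy())
        names.append("wolbachia")
    for inv in INVERSIONS:
        if inv in cov.columns:
            codes = cov[inv].astype(str)
            ref = codes.value_counts().idxmax()   # most common code = reference
            for code in sorted(set(codes) - {ref}):
                cols.append((codes == code).to_numpy(float))
                names.append(f"{inv}[{code}]")
    return np.column_stack(cols), names


def adjust_covariates(
    response: ResponsePhenotype, covariates: pd.DataFrame
) -> ResponsePhenotype:
    """Residualize the response on Wolbachia + inversion karyotypes.

    Inversions are one-hot encoded with the most common karyotype as
    reference; aliased (rank-deficient) columns are dropped with a
    warning.  The returned response is the least-squares residual.
    """
    lines = list(response.values.index)
    missing = set(lines) - set(covariates["line_id"])
    if missing:
        raise ValueError(f"covariates missing for lines: {sorted(missing)[:5]} ...")
    X, names = _covariate_design(covariates, lines)
    # drop aliased columns
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        import warnings

        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased covariate columns: {dropped}", stacklevel=2)
        X = X[:, keep]
    y = response.values.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return ResponsePhenotype(
        values=pd.Series(resid, index=response.values.index, name="response"),
        description=response.description + " | covariate-adjusted",
        adjusted=True,
        excluded_lines=response.excluded_lines,
    )


def _null_h2_reml(yt: np.ndarray, ones_t: np.ndarray, lam: np.ndarray) -> float:
    """1-d REML for h2 = sigma2_g/(sigma2_g+sigma2_e) in the GRM eigenbasis."""
    n = len(yt)

    def minus2ll(h2):
        d = h2 * lam + (1.0 - h2)
        if np.any(d <= 0):
            return np.inf
        wi = 1.0 / d
        xwx = float((ones_t * ones_t * wi).sum())
        beta = float((ones_t * yt * wi).sum()) / xwx
        r = yt - beta * ones_t
        quad = float((r * r * wi).sum())
        s2 = quad / (n - 1)
        return (n - 1) * np.log(s2) + np.log(d).sum() + np.log(xwx)

    res = optimize.minimize_scalar(
        minus2ll, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    # compare against the boundary explicitly
    if minus2ll(0.0) <= res.fun:
        h2 = 0.0
    return h2


def gwas_scan(
    response: ResponsePhenotype,
    genotypes: GenotypeMatrix,
    grm: Grm | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model single-marker scan over all variants.

    Returns one row per variant: effect, SE, t statistic, p, tested
    flag and filter reason.  p-values are two-sided on n-2 degrees of
    freedom.
    """
    lines = list(response.values.index)
    pos = [genotypes.line_ids.index(l) for l in lines if l in genotypes.line_ids]
    if len(pos) != len(lines):
        raise ValueError("response contains lines absent from the genotypes")
    y = response.values.to_numpy(float)
    n = len(y)
    X = genotypes.dosages[pos, :]

    if grm is not None:
        if grm.line_ids != genotypes.line_ids:
            raise ValueError("GRM and genotype line ordering differ")
        K = grm.matrix[np.ix_(pos, pos)]
        lam, U = np.linalg.eigh(K)
        lam = np.maximum(lam, 0.0)
    else:
        lam = np.ones(n)
        U = np.eye(n)

    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    h2 = _null_h2_reml(yt, ones_t, lam)
    pure_noise = h2 == 0.0
    d = h2 * lam + (1.0 - h2)
    wi = 1.0 / d

    # MAF among lines entering this response
    p_alt = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    tested = maf > maf_min

    Xt = U.T @ np.nan_to_num(X, nan=0.0)   # missing dosages imputed at 0 pre-centering
    # fill missing with per-variant mean dosage instead of 0
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        Xf = np.where(np.isnan(X), col_mean[None, :], X)
        Xt = U.T @ Xf

    # per-variant GLS of y on [1, x] with weights wi
    a = float((ones_t**2 * wi).sum())                 # 1'W1
    b = (ones_t[:, None] * Xt * wi[:, None]).sum(0)   # 1'Wx per variant
    cxx = (Xt * Xt * wi[:, None]).sum(0)              # x'Wx
    cy1 = float((ones_t * yt * wi).sum())             # 1'Wy
    cxy = (Xt * yt[:, None] * wi[:, None]).sum(0)     # x'Wy
    det = a * cxx - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a * cxy - b * cy1) / det
        mu = (cy1 - b * beta) / a
        rss = float((yt * yt * wi).sum()) - mu * cy1 - beta * cxy
        dof = n - 2
        s2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(s2 * a / det)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    out = genotypes.variant_meta[["chrom", "pos", "ref", "alt"]].copy()
    out["maf"] = maf
    out["effect"] = np.where(tested, beta, np.nan)
    out["se"] = np.where(tested, se, np.nan)
    out["statistic"] = np.where(tested, tstat, np.nan)
    out["p"] = np.where(tested, pvals, np.nan)
    out["tested"] = tested
    out["filter_reason"] = np.where(tested, "", f"maf<={maf_min}")
    out.attrs["null_h2"] = h2
    out.attrs["pure_noise_model"] = pure_noise
    out.attrs["response"] = response.description
    return out


def bonferroni_threshold(n_tested: int, alpha: float = 0.05) -> float:
    """Family-wise significance cutoff alpha / number of tested variants."""
    if n_tested < 1:
        raise ValueError("need at least one tested variant")
    return alpha / n_tested


def genomic_control_lambda(pvals) -> float:
    """Median chi-square inflation factor of a p-value set."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def plot_tables(results: pd.DataFrame) -> dict:
    """Data behind Manhattan and Q-Q plots.

    The Manhattan table is sorted by genome coordinate with -log10(p);
    the Q-Q table pairs observed with expected uniform order-statistic
    quantiles, with a 95% pointwise band from Beta(k, n+1-k).
    """
    tested = results[results["tested"]]
    if tested.empty:
        raise ValueError("no tested variants")
    man = tested.sort_values(["chrom", "pos"]).reset_index(drop=True)
    man = man[["chrom", "pos", "ref", "alt", "maf", "effect", "p"]].copy()
    man["neglog10p"] = -np.log10(man["p"])

    p_sorted = np.sort(tested["p"].to_numpy())
    m = len(p_sorted)
    k = np.arange(1, m + 1)
    expected = k / (m + 1.0)
    lo = stats.beta.ppf(0.025, k, m + 1 - k)
    hi = stats.beta.ppf(0.975, k, m + 1 - k)
    qq = pd.DataFrame({
        "expected_neglog10p": -np.log10(expected),
        "observed_neglog10p": -np.log10(p_sorted),
        "band_low_neglog10p": -np.log10(hi),
        "band_high_neglog10p": -np.log10(lo),
    })
    return {"manhattan": man, "qq": qq}
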
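"""Mixed-model analysis of variance for inbred line panels.

The full model for a trait measured on individual flies is

    y = mu + A + D + A:D        (fixed: age class, diet, their interaction)
        + L + L:A + L:D + L:A:D + Rep(L:A:D)   (random)
        + e,

with L the inbred line.  Because lines are (nearly) completely inbred,
the among-line variance components are genetic variance; their estimates
feed broad-sense heritability and cross-environment genetic correlations
downstream.

Two estimators are provided: REML (`fit_mixed_model`, the primary path,
valid for unbalanced data) and a closed-form Type-III expected-mean-square
method-of-moments solution for perfectly balanced designs
(`anova_type3_balanced`), which serves as an independent oracle — on
balanced data with an interior solution the two coincide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RemlResult, fit_reml

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "fit_mixed_model",
    "anova_type3_balanced",
    "test_random_term",
    "FULL_RANDOM_TERMS",
]

FULL_RANDOM_TERMS = ("line", "line:age", "line:diet", "line:age:diet", "rep")
_FIXED_ALLOWED = ("age", "diet", "age:diet")


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed and random terms to fit, and on which data subset."""

    trait: str
    fixed: tuple[str, ...] = ("age", "diet", "age:diet")
    random: tuple[str, ...] = FULL_RANDOM_TERMS
    diets: tuple[str, ...] | None = None
    ages: tuple[int, ...] | None = None

    def __post_init__(self):
        for t in self.fixed:
            if t not in _FIXED_ALLOWED:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random:
            if t not in FULL_RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        if "age:diet" in self.fixed and not {"age", "diet"} <= set(self.fixed):
            raise ValueError("age:diet requires age and diet main effects")

    @property
    def genetic_terms(self) -> tuple[str, ...]:
        """Line-involving terms (everything except rep), per the
        broad-sense heritability numerator convention."""
        return tuple(t for t in self.random if t != "rep")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.trait == other.trait
            and self.fixed == other.fixed
            and set(self.random) < set(other.random)
            and self.diets == other.diets
            and self.ages == other.ages
        )


@dataclass
class VarianceComponents:
    """Variance-component estimates with asymptotic covariance."""

    spec: ModelSpec
    estimates: dict[str, float]          # term -> sigma^2, residual under "e"
    asy_cov: pd.DataFrame | None         # rows/cols: random terms + "e"
    fixed_effects: pd.Series
    fixed_se: pd.Series
    loglik: float
    n_obs: int
    converged: bool
    boundary: set[str] = field(default_factory=set)
    method: str = "reml"

    @property
    def terms(self) -> list[str]:
        return [t for t in self.estimates if t != "e"] + ["e"]

    def genetic_variance(self) -> float:
        return float(sum(self.estimates[t] for t in self.spec.genetic_terms))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"term": t, "sigma2": self.estimates[t],
             "boundary": t in self.boundary}
            for t in self.terms
        ]
        return pd.DataFrame(rows)


def _subset(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = table
    if spec.diets is not None:
        df = df[df["diet"].isin(spec.diets)]
    if spec.ages is not None:
        df = df[df["age_days"].isin(spec.ages)]
    df = df.dropna(subset=[spec.trait])
    if df.empty:
        raise ValueError(f"no data for trait {spec.trait!r} in requested subset")
    return df.copy()


def _fixed_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    parts = {}
    for term in ("age", "diet"):
        if term in spec.fixed:
            col = "age_days" if term == "age" else "diet"
            levels = np.sort(df[col].unique())
            if len(levels) > 1:
                dummies = [(df[col] == lv).to_numpy(float) for lv in levels[1:]]
                parts[term] = (levels[1:], dummies)
                for lv, d in zip(levels[1:], dummies):
                    cols.append(d)
                    names.append(f"{term}[{lv}]")
    if "age:diet" in spec.fixed and "age" in parts and "diet" in parts:
        for (la, da), (ld, dd) in itertools.product(
            zip(*(parts["age"])), zip(*(parts["diet"]))
        ):
            cols.append(da * dd)
            names.append(f"age[{la}]:diet[{ld}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (aliased term)")
    return X, names


def _random_codes(df: pd.DataFrame, term: str) -> pd.Series:
    cols = {"line": ["line_id"],
            "line:age": ["line_id", "age_days"],
            "line:diet": ["line_id", "diet"],
            "line:age:diet": ["line_id", "age_days", "diet"],
            "rep": ["line_id", "age_days", "diet", "replicate"]}[term]
    key = df[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + "\x1f" + df[c].astype(str)
    return pd.factorize(key)[0]


def fit_mixed_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    compute_cov: bool = True,
) -> VarianceComponents:
    """REML fit of the mixed ANOVA model for one trait.

    Rows with identical fixed- and random-effect design are collapsed to
    weighted means before optimization (an exact sufficiency reduction),
    so fits on fully replicated designs are fast.  Components estimated
    at the zero boundary are truncated to 0 and flagged.
    """
    df = _subset(table, spec)
    y = df[spec.trait].to_numpy(float)
    X, names = _fixed_design(df, spec)
    for term in spec.random:
        codes = _random_codes(df, term)
        if codes.max() < 1:
            raise ValueError(f"random term {term!r} has fewer than 2 levels")

    # collapse duplicate design rows
    design = pd.DataFrame({f"x{j}": X[:, j] for j in range(X.shape[1])})
    for term in spec.random:
        design[term] = _random_codes(df, term)
    design["_y"] = y
    keys = [c for c in design.columns if c != "_y"]
    grp = design.groupby(keys, sort=False)["_y"]
    agg = grp.agg(["mean", "count", "var"]).reset_index()
    w = agg["count"].to_numpy(float)
    ssw = float(np.nansum(agg["var"].to_numpy() * (w - 1)))
    dfw = float((w - 1).sum())
    Xc = agg[[f"x{j}" for j in range(X.shape[1])]].to_numpy(float)
    Z_codes = {t: agg[t].to_numpy() for t in spec.random}

    # warm start from the balanced moment oracle when applicable
    starts = None
    try:
        mom = anova_type3_balanced(table, spec)
        s0 = np.array(
            [max(mom.estimates[t], 0.0) for t in spec.random]
            + [max(mom.estimates["e"], 1e-8 * np.var(y))]
        )
        starts = [s0, np.full(len(spec.random) + 1, np.var(y) / (len(spec.random) + 1))]
    except ValueError:
        pass

    fit = fit_reml(
        agg["mean"].to_numpy(float),
        Xc,
        Z_codes,
        weights=w,
        ssw=ssw,
        dfw=dfw,
        beta_names=names,
        n_obs=len(df),
        compute_cov=compute_cov,
        starts=starts,
    )
    if not fit.converged:
        raise RuntimeError(
            f"REML did not converge for {spec.trait!r} after {fit.n_iter} iterations"
        )
    asy = None
    if fit.asy_cov is not None:
        asy = pd.DataFrame(fit.asy_cov, index=fit.terms, columns=fit.terms)
    return VarianceComponents(
        spec=spec,
        estimates=fit.variance,
        asy_cov=asy,
        fixed_effects=pd.Series(fit.beta, index=fit.beta_names),
        fixed_se=pd.Series(fit.beta_se, index=fit.beta_names),
        loglik=fit.loglik,
        n_obs=fit.n_obs,
        converged=fit.converged,
        boundary=fit.boundary,
        method="reml",
    )


# ---------------------------------------------------------------------------
# Balanced Type-III / expected-mean-squares oracle


def _term_factors(term: str) -> tuple[str, ...]:
    return {"line": ("line_id",),
            "line:age": ("line_id", "age_days"),
            "line:diet": ("line_id", "diet"),
            "line:age:diet": ("line_id", "age_days", "diet")}[term]


def anova_type3_balanced(table: pd.DataFrame, spec: ModelSpec) -> VarianceComponents:
    """Method-of-moments variance components from Type-III expected mean
    squares on a perfectly balanced design.

    Valid only when every cell of the (line x age x diet [x rep]) layout
    has the same number of observations; otherwise raises.  Negative
    moment estimates are reported as-is (this function is an oracle, not
    the primary estimator).  Under balance and an interior solution the
    estimates coincide with REML.
    """
    df = _subset(table, spec)
    y = df[spec.trait].to_numpy(float)
    n = len(df)

    crossed = ["line_id"]
    for f, col in (("age", "age_days"), ("diet", "diet")):
        involved = any(f in t.split(":") for t in spec.fixed + spec.random)
        if involved and df[col].nunique() > 1:
            crossed.append(col)
    levels = {c: np.sort(df[c].unique()) for c in crossed}
    a = {c: len(levels[c]) for c in crossed}
    with_rep = "rep" in spec.random

    cell_cols = crossed + (["replicate"] if with_rep else [])
    counts = df.groupby(cell_cols, sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("design is not balanced; use fit_mixed_model")
    m = int(counts.iloc[0])
    n_cells_finest = len(counts)
    if with_rep:
        reps_per_cell = df.groupby(crossed, sort=False)["replicate"].nunique()
        if reps_per_cell.nunique() != 1:
            raise ValueError("design is not balanced; use fit_mixed_model")
        r = int(reps_per_cell.iloc[0])
        if n_cells_finest != r * int(np.prod([a[c] for c in crossed])):
            raise ValueError("design is not balanced; use fit_mixed_model")

    # marginal means for every subset of crossed factors
    grand = y.mean()
    margins: dict[tuple[str, ...], pd.Series] = {}
    for size in range(1, len(crossed) + 1):
        for sub in itertools.combinations(crossed, size):
            margins[sub] = df.groupby(list(sub), sort=False)[spec.trait].mean()

    def ss_term(factors: tuple[str, ...]) -> tuple[float, int]:
        sub_levels = [levels[c] for c in factors]
        n_per = n / int(np.prod([a[c] for c in factors]))
        ss = 0.0
        for combo in itertools.product(*sub_levels):
            d = 0.0
            for size in range(len(factors) + 1):
                for s in itertools.combinations(range(len(factors)), size):
                    sign = (-1) ** (len(factors) - size)
                    if size == 0:
                        d += sign * grand
                    else:
                        key = tuple(factors[i] for i in s)
                        idx = tuple(combo[i] for i in s)
                        val = margins[key].loc[idx if len(idx) > 1 else idx[0]]
                        d += sign * val
            ss += d * d
        ss *= n_per
        dof = int(np.prod([a[c] - 1 for c in factors]))
        return ss, dof

    random_cross = [t for t in spec.random if t != "rep"]
    ms: dict[str, float] = {}
    dof: dict[str, int] = {}
    for t in random_cross:
        fac = _term_factors(t)
        missing = [c for c in fac if c not in crossed]
        if missing:
            raise ValueError(f"term {t!r} involves a factor with one level")
        ss, d = ss_term(fac)
        ms[t] = ss / d
        dof[t] = d

    cell_means = df.groupby(crossed, sort=False)[spec.trait].transform("mean")
    if with_rep:
        rep_means = df.groupby(cell_cols, sort=False)[spec.trait].transform("mean")
        ss_rep = float(((rep_means - cell_means) ** 2).sum())
        d_rep = n_cells_finest - int(np.prod([a[c] for c in crossed]))
        ms["rep"] = ss_rep / d_rep
        dof["rep"] = d_rep
        ss_e = float(((y - rep_means) ** 2).sum())
        d_e = n - n_cells_finest
    else:
        ss_e = float(((y - cell_means) ** 2).sum())
        d_e = n - len(df.groupby(crossed, sort=False))
    if d_e <= 0:
        raise ValueError("no residual degrees of freedom")
    ms["e"] = ss_e / d_e
    dof["e"] = d_e

    # expected mean squares (unrestricted mixed model):
    # E[MS_U] = sigma2_e + sum over random W with U subset of W of
    #           (N / #levels(W)) * sigma2_W
    terms = list(spec.random) + ["e"]
    nlev = {}
    for t in random_cross:
        nlev[t] = int(np.prod([a[c] for c in _term_factors(t)]))
    if with_rep:
        nlev["rep"] = n_cells_finest
    C = np.zeros((len(terms), len(terms)))
    for i, u in enumerate(terms):
        C[i, terms.index("e")] = 1.0
        if u == "e":
            continue
        u_fac = set(_term_factors(u)) if u != "rep" else set(crossed) | {"replicate"}
        for w_t in spec.random:
            w_fac = set(_term_factors(w_t)) if w_t != "rep" else set(crossed) | {"replicate"}
            if u_fac <= w_fac:
                C[i, terms.index(w_t)] = n / nlev[w_t]
    rhs = np.array([ms[t] for t in terms])
    sol = np.linalg.solve(C, rhs)
    est = {t: float(s) for t, s in zip(terms, sol)}

    return VarianceComponents(
        spec=spec,
        estimates=est,
        asy_cov=None,
        fixed_effects=pd.Series({"intercept": grand}),
        fixed_se=pd.Series({"intercept": np.nan}),
        loglik=np.nan,
        n_obs=n,
        converged=True,
        boundary=set(),
        method="ems",
    )


def test_random_term(full: VarianceComponents, reduced: VarianceComponents) -> float:
    """Boundary-corrected REML likelihood-ratio test for one random term.

    The statistic 2*(l_full - l_reduced) is referred to the mixture
    0.5*chi2_0 + 0.5*chi2_1, the correct null reference when a single
    variance component is tested on its zero boundary; the test is
    conservative.
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("reduced model is not nested in the full model")
    if len(set(full.spec.random) - set(reduced.spec.random)) != 1:
        raise ValueError("exactly one random term must be dropped")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted to different data")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat <= 1e-10:
        return 1.0
    return float(0.5 * stats.chi2.sf(stat, df=1))
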
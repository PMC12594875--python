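"""Synthetic inbred line panel with known truth.

Generates every input the analysis pipeline consumes — homozygous line
genotypes, fly-level phenotypes from the mixed ANOVA model, lifespans
from a proportional-hazards law with multi-category right-censoring, and
activity-monitor count series — so each downstream stage can be tested
against the parameters that generated its data.

Conventions
-----------
* Inbred genotypes are coded {0, 2}: lines are homozygous, so dosage/2
  is the line's allele count on one haplotype.
* All random effects are Gaussian, the distributional assumption of the
  ANOVA framework; it is the only supported law.
* One global seed expands into independent per-stream child seeds
  (genotypes, effects, noise, censoring, counts) via
  `numpy.random.SeedSequence`, so stages can be regenerated
  independently and outputs are byte-identical under a fixed seed.
* A planted variant with additive effect ``a`` shifts the trait by ``a``
  between the two homozygous classes; a diet-interaction effect ``d``
  shifts the (control - restricted) difference by ``d`` between the two
  classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationTruth",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_lifespans",
    "simulate_activity_series",
    "CENSOR_CATEGORIES",
    "DEFAULT_CENSOR_PROBS",
    "INVERSIONS",
]

CENSOR_CATEGORIES = ("escaped", "stuck", "trapped", "sampled")

# Censoring category shares observed in a large diet panel
# (303 escaped, 1706 stuck, 336 trapped, 6338 sampled of 43,750 flies).
DEFAULT_CENSOR_PROBS = {
    "escaped": 303 / 43750,
    "stuck": 1706 / 43750,
    "trapped": 336 / 43750,
    "sampled": 6338 / 43750,
}

INVERSIONS = ("In2Lt", "In2RNS", "In3RP", "In3RK", "In3RMo")
_KARYOTYPES = ("ST", "INV")

_STREAMS = ("genotypes", "effects", "noise", "censoring", "counts", "covariates")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class SimulationTruth:
    """Population parameters behind a simulated panel."""

    n_lines: int = 98
    n_variants: int = 5000
    maf_law: tuple = ("uniform", 0.05, 0.5)
    var_components: dict = field(
        default_factory=lambda: {
            "line": 1.0, "line:age": 0.3, "line:diet": 0.3,
            "line:age:diet": 0.15, "rep": 0.1, "e": 4.0,
        }
    )
    grand_mean: float = 0.0
    diet_effect: float = 0.0          # restricted minus control, fixed
    age_effect: float = 0.0           # per later age class, fixed
    causal_variants: tuple = ()       # (variant index, additive, diet interaction)
    cox_beta_diet: float = 0.25859    # log hazard ratio, restricted vs control
    baseline_hazard: tuple = ("weibull", 3.0, 24.0)   # family, shape, scale
    frailty_sd: float = 0.9           # among-line SD of log-hazard
    censor_probs: dict = field(default_factory=lambda: dict(DEFAULT_CENSOR_PROBS))
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.var_components.values()):
            raise ValueError("variance components must be non-negative")
        if not 0 <= sum(self.censor_probs.values()) < 1:
            raise ValueError("censoring probabilities must sum to < 1")
        for name in self.censor_probs:
            if name not in CENSOR_CATEGORIES:
                raise ValueError(f"unknown censor category {name!r}")


@dataclass
class GenotypeMatrix:
    """Line x variant dosages (entries in {0, 2}, NaN = missing)."""

    dosages: np.ndarray
    variant_meta: pd.DataFrame        # chrom, pos, ref, alt, maf
    line_ids: list[str]

    def __post_init__(self):
        if len(self.line_ids) != len(set(self.line_ids)):
            raise ValueError("line_ids must be unique")
        if self.dosages.shape != (len(self.line_ids), len(self.variant_meta)):
            raise ValueError("dosage matrix shape does not match metadata")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Empirical minor allele frequency per variant from dosages."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


def _draw_maf(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = law[1], law[2]
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("uniform MAF support must lie in (0, 0.5]")
        return rng.uniform(lo, hi, size)
    if kind == "point":
        p = law[1]
        if not 0 < p <= 0.5:
            raise ValueError("point MAF must lie in (0, 0.5]")
        return np.full(size, float(p))
    raise ValueError(f"unknown MAF law {kind!r}")


def simulate_genotypes(
    n_lines: int,
    n_variants: int,
    maf_law: tuple = ("uniform", 0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Exchangeable biallelic homozygous genotypes for an inbred panel.

    Each line carries dosage 2 of the alternate allele with probability
    equal to the variant's allele frequency.  Monomorphic draws are
    resampled so every variant has empirical MAF > 0.
    """
    if n_lines < 2 or n_variants < 1:
        raise ValueError("need at least 2 lines and 1 variant")
    rng = _child_rngs(seed)["genotypes"]
    p = _draw_maf(rng, maf_law, n_variants)
    dos = np.where(rng.random((n_lines, n_variants)) < p[None, :], 2.0, 0.0)
    for _ in range(1000):
        mono = (dos.sum(axis=0) == 0) | (dos.sum(axis=0) == 2 * n_lines)
        if not mono.any():
            break
        k = int(mono.sum())
        dos[:, mono] = np.where(
            rng.random((n_lines, k)) < p[None, mono], 2.0, 0.0
        )
    else:
        raise RuntimeError("could not generate polymorphic variants")
    maf = np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2)
    meta = pd.DataFrame({
        "chrom": np.where(np.arange(n_variants) % 2 == 0, "2L", "3R"),
        "pos": np.arange(1, n_variants + 1) * 100,
        "ref": "A",
        "alt": "T",
        "maf": maf,
    })
    lines = [f"line_{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(dosages=dos, variant_meta=meta, line_ids=lines)


def simulate_covariates(line_ids: list[str], seed: int = 0) -> pd.DataFrame:
    """Wolbachia infection status and five inversion karyotypes per line."""
    rng = _child_rngs(seed)["covariates"]
    out = pd.DataFrame({"line_id": list(line_ids)})
    out["wolbachia"] = rng.random(len(out)) < 0.5
    for inv in INVERSIONS:
        out[inv] = np.where(rng.random(len(out)) < 0.15, "INV", "ST")
    return out


def simulate_phenotypes(
    truth: SimulationTruth,
    genotypes: GenotypeMatrix | None = None,
    diets: tuple[str, str] = ("control", "restricted"),
    ages: tuple[int, ...] = (7, 16),
    n_reps: int = 3,
    flies_per_rep: int = 4,
    trait: str = "trait",
) -> pd.DataFrame:
    """Fly-level phenotypes from the mixed ANOVA model.

    Random line, line:age, line:diet, line:age:diet, replicate and
    residual effects are drawn once per grouping level with the truth
    variances; fixed diet/age means and planted variant effects are
    added on top.  Returns a long table with columns line_id, diet,
    age_days, replicate and the trait.
    """
    if n_reps < 1 or flies_per_rep < 1:
        raise ValueError("design counts must be >= 1")
    vc = {k: float(truth.var_components.get(k, 0.0))
          for k in ("line", "line:age", "line:diet", "line:age:diet", "rep", "e")}
    rngs = _child_rngs(truth.seed)
    rng_eff, rng_noise = rngs["effects"], rngs["noise"]

    if genotypes is not None:
        line_ids = list(genotypes.line_ids)
    else:
        line_ids = [f"line_{i + 1:03d}" for i in range(truth.n_lines)]
    nL, nA, nD = len(line_ids), len(ages), len(diets)

    eff_L = rng_eff.normal(0.0, np.sqrt(vc["line"]), nL)
    eff_LA = rng_eff.normal(0.0, np.sqrt(vc["line:age"]), (nL, nA))
    eff_LD = rng_eff.normal(0.0, np.sqrt(vc["line:diet"]), (nL, nD))
    eff_LAD = rng_eff.normal(0.0, np.sqrt(vc["line:age:diet"]), (nL, nA, nD))
    eff_rep = rng_eff.normal(0.0, np.sqrt(vc["rep"]), (nL, nA, nD, n_reps))

    planted = np.zeros(nL)
    planted_gxd = np.zeros(nL)   # added to control, subtracted from restricted, halved
    for (v, add, inter) in truth.causal_variants:
        if genotypes is None:
            raise ValueError("causal variants require a genotype matrix")
        if not 0 <= v < genotypes.n_variants:
            raise ValueError(f"causal variant index {v} out of range")
        x = np.nan_to_num(genotypes.dosages[:, v]) / 2.0   # 0 or 1
        planted += add * x
        planted_gxd += inter * x

    rows = []
    for i in range(nL):
        for j, age in enumerate(ages):
            for k, diet in enumerate(diets):
                # diet contrast: +1/2 control, -1/2 restricted
                c_diet = 0.5 if k == 0 else -0.5
                cell = (
                    truth.grand_mean
                    + truth.age_effect * j
                    + truth.diet_effect * (k == 1)
                    + eff_L[i] + eff_LA[i, j] + eff_LD[i, k] + eff_LAD[i, j, k]
                    + planted[i] + planted_gxd[i] * c_diet
                )
                for rep in range(n_reps):
                    mu = cell + eff_rep[i, j, k, rep]
                    e = rng_noise.normal(0.0, np.sqrt(vc["e"]), flies_per_rep)
                    for f in range(flies_per_rep):
                        rows.append((line_ids[i], diet, age, rep + 1, mu + e[f]))
    df = pd.DataFrame(rows, columns=["line_id", "diet", "age_days", "replicate", trait])
    df[trait] = df[trait].astype(float)
    return df


def _sample_event_times(rng, family, params, log_hr):
    """Inverse-transform sampling under hazard lambda0(t) * exp(log_hr)."""
    n = len(log_hr)
    E = rng.exponential(1.0, n) / np.exp(log_hr)   # cumulative baseline hazard at T
    if family == "exponential":
        (rate,) = params
        return E / rate
    if family == "weibull":
        shape, scale = params
        return scale * E ** (1.0 / shape)
    if family == "gompertz":
        a, b = params
        return np.log1p(b * E / a) / b
    raise ValueError(f"unknown baseline hazard family {family!r}")


def simulate_lifespans(
    truth: SimulationTruth,
    n_flies: int,
    seed: int | None = None,
    diets: tuple[str, str] = ("control", "restricted"),
    n_reps: int = 3,
) -> pd.DataFrame:
    """Lifespans under a proportional-hazards law with censoring.

    Flies split evenly between diets; the restricted diet multiplies the
    hazard by exp(cox_beta_diet).  Per-line Gaussian log-hazard frailty
    (sd ``frailty_sd``) creates among-line lifespan variation.
    Censoring is a competing process with hazard proportional to the
    death hazard (ratio p/(1-p) for total censoring probability p), so
    the expected censored fraction equals ``sum(censor_probs)`` and
    censoring is independent of death time given diet; each censored
    fly draws its category independently with the relative category
    probabilities.
    """
    family, *params = truth.baseline_hazard
    if family not in ("exponential", "weibull", "gompertz"):
        raise ValueError(f"unknown baseline hazard family {family!r}")
    rngs = _child_rngs(truth.seed if seed is None else seed)
    rng, rng_c = rngs["noise"], rngs["censoring"]

    line_ids = [f"line_{i + 1:03d}" for i in range(truth.n_lines)]
    frail = rngs["effects"].normal(0.0, truth.frailty_sd, truth.n_lines)
    line_idx = rng.integers(0, truth.n_lines, n_flies)
    diet = np.where(np.arange(n_flies) % 2 == 0, diets[0], diets[1])
    d_ind = (diet == diets[1]).astype(float)
    log_hr = truth.cox_beta_diet * d_ind + frail[line_idx]
    t_death = _sample_event_times(rng, family, params, log_hr)

    # competing censoring process with hazard c * lambda(t), c = p/(1-p):
    # under proportional hazards P(C < T) = c/(1+c) = p exactly, and
    # censoring is independent of the death time given diet (unbiased
    # partial-likelihood estimation downstream)
    cats = list(truth.censor_probs)
    probs = np.array([truth.censor_probs[c] for c in cats])
    p_cens = float(probs.sum())
    if p_cens > 0:
        c_ratio = p_cens / (1.0 - p_cens)
        t_censor = _sample_event_times(
            rng_c, family, params, log_hr + np.log(c_ratio)
        )
        censored = t_censor < t_death
        draw = rng_c.choice(len(cats), n_flies, p=probs / p_cens)
        category = np.where(censored, np.array(cats)[draw], "none")
    else:
        censored = np.zeros(n_flies, dtype=bool)
        category = np.full(n_flies, "none")
    t_obs = np.where(censored, t_censor, t_death) if p_cens > 0 else t_death
    t_obs = np.maximum(t_obs, 1e-6)

    return pd.DataFrame({
        "line_id": np.array(line_ids)[line_idx],
        "diet": diet,
        "replicate": rng.integers(1, n_reps + 1, n_flies),
        "lifespan_days": t_obs,
        "event": (~censored).astype(int),
        "censor_code": category,
    })


def simulate_activity_series(
    rate: float,
    n_bins_23c: int = 2160,
    n_bins_39c: int = 720,
    knockdown_bin: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Activity-monitor count series for one fly.

    Counts are Poisson with the given per-bin rate.  At 39 C the fly is
    active through ``knockdown_bin`` (1-based; forced to at least one
    count there so the knockdown time is exactly that bin) and all later
    bins are zero.
    """
    if rate < 0:
        raise ValueError("activity rate must be non-negative")
    if knockdown_bin is None:
        knockdown_bin = n_bins_39c
    if not 0 <= knockdown_bin <= n_bins_39c:
        raise ValueError("knockdown_bin must lie within the 39C window")
    rng = _child_rngs(seed)["counts"]
    series_23 = rng.poisson(rate, n_bins_23c)
    series_39 = np.zeros(n_bins_39c, dtype=int)
    if knockdown_bin > 0:
        series_39[:knockdown_bin] = rng.poisson(rate, knockdown_bin)
        if rate > 0:
            series_39[knockdown_bin - 1] = max(series_39[knockdown_bin - 1], 1)
    return series_23, series_39
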
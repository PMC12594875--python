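"""End-to-end pipeline driver.

Runs the full analysis — simulate (or load) panel data, derive and
balance traits, fit variance components, compute heritabilities,
cross-environment genetic correlations and the rank/scale G-by-E
decomposition, fit the diet Cox model, and scan for single-marker and
variant-by-diet associations — writing one tidy table per stage plus a
run manifest.  Outputs are deterministic given the config seed: two
runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GwasBlock, PipelineConfig, SimulationBlock
from .cox import censoring_report, fit_cox
from .gwas import (
    adjust_covariates,
    bonferroni_threshold,
    compute_grm,
    genomic_control_lambda,
    gwas_scan,
    make_response,
    plot_tables,
)
from .io import (
    read_covariates,
    read_genotypes,
    read_phenotypes,
    write_genotypes_tsv,
    write_phenotypes,
)
from .quantgen import estimate_H2, gxe_summary, spearman_correlation
from .simulate import (
    SimulationTruth,
    simulate_covariates,
    simulate_genotypes,
    simulate_lifespans,
    simulate_phenotypes,
)
from .traits import balance_dataset, compute_line_means
from .varcomp import ModelSpec, fit_mixed_model

log = logging.getLogger("dietgxe")

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def simulate_panel(cfg: PipelineConfig) -> dict:
    """Generate the synthetic panel inputs declared in the config."""
    sim: SimulationBlock = cfg.simulation
    seed = cfg.seed
    log.info("stage=simulate n_lines=%d n_variants=%d", sim.n_lines, sim.n_variants)
    geno = simulate_genotypes(sim.n_lines, sim.n_variants, sim.maf_law, seed=seed)
    cov = simulate_covariates(geno.line_ids, seed=seed)

    causal_by_trait: dict[str, list] = {}
    maf = geno.maf()
    for c in sim.causal:
        v = c["variant"]
        if v in (None, "auto"):
            # pick a common variant so the planted signal is well powered
            v = int(np.argmin(np.abs(maf - 0.4)))
        causal_by_trait.setdefault(c["trait"], []).append(
            (int(v), float(c.get("additive", 0.0)),
             float(c.get("diet_interaction", 0.0)))
        )

    pheno = None
    for t_ix, trait in enumerate(cfg.traits):
        model = sim.trait_models[trait]
        truth = SimulationTruth(
            n_lines=sim.n_lines,
            n_variants=sim.n_variants,
            var_components=model["var_components"],
            causal_variants=tuple(causal_by_trait.get(trait, ())),
            seed=seed * 1000 + t_ix,
        )
        df = simulate_phenotypes(
            truth, geno, ages=sim.ages, n_reps=sim.n_reps,
            flies_per_rep=sim.flies_per_rep, trait=trait,
        )
        # overlay the fixed cell means for this trait
        cm = model["cell_means"]
        shift = df.apply(lambda r: cm[(r["diet"], r["age_days"])], axis=1)
        df[trait] = df[trait] + shift
        if pheno is None:
            pheno = df
        else:
            pheno[trait] = df[trait]

    surv = simulate_lifespans(
        SimulationTruth(
            n_lines=sim.n_lines,
            cox_beta_diet=sim.cox_beta_diet,
            baseline_hazard=sim.baseline_hazard,
            frailty_sd=sim.frailty_sd,
            seed=seed,
        ),
        n_flies=sim.n_survival_flies,
    )
    surv["age_days"] = np.nan
    for t in cfg.traits:
        surv[t] = np.nan
    pheno["lifespan_days"] = np.nan
    pheno["censor_code"] = "sampled"   # healthspan flies leave the survival pool
    pheno["event"] = 0
    full = pd.concat([pheno, surv], ignore_index=True)[
        ["line_id", "diet", "age_days", "replicate"]
        + list(cfg.traits) + ["lifespan_days", "event", "censor_code"]
    ]
    return {"phenotypes": full, "genotypes": geno, "covariates": cov,
            "survival": surv, "causal": causal_by_trait}


def load_inputs(cfg: PipelineConfig) -> dict:
    paths = cfg.inputs
    pheno, report = read_phenotypes(paths["phenotypes"])
    log.info("stage=load rows=%d rejected=%d", len(pheno), report.n_bad)
    out = {"phenotypes": pheno, "read_report": report}
    if "genotypes" in paths:
        out["genotypes"] = read_genotypes(paths["genotypes"])
    if "covariates" in paths:
        out["covariates"] = read_covariates(paths["covariates"])
    surv = pheno[pheno["lifespan_days"].notna()]
    out["survival"] = surv
    return out


def _healthspan_specs(trait: str, ages, diets=("control", "restricted")):
    """Model specs fitted per trait: the full model plus one reduced
    model per age x diet cell (lines + replicate only)."""
    specs = {"full": ModelSpec(trait=trait)}
    for diet in diets:
        for age in ages:
            specs[f"{diet}:{age}"] = ModelSpec(
                trait=trait, fixed=(), random=("line", "rep"),
                diets=(diet,), ages=(int(age),),
            )
    return specs


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all configured stages; returns the in-memory results."""
    outdir = Path(outdir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    logging.basicConfig(level=cfg.log_level)
    results: dict = {"config_hash": cfg_hash}
    counts: dict[str, int] = {}

    data = simulate_panel(cfg) if cfg.simulation is not None else load_inputs(cfg)
    pheno = data["phenotypes"]
    counts["phenotype_rows"] = len(pheno)
    write_phenotypes(pheno, outdir / "phenotypes.csv")
    if "genotypes" in data and cfg.simulation is not None:
        write_genotypes_tsv(data["genotypes"], outdir / "genotypes.tsv")
        data["covariates"].to_csv(outdir / "covariates.csv", index=False)

    # --- balancing and line means -------------------------------------
    healthspan = pheno[pheno["age_days"].notna()]
    ages = sorted(healthspan["age_days"].dropna().unique())
    balanced = {}
    line_mean_frames = []
    balance_rows = []
    for trait in cfg.traits:
        if cfg.balance:
            rep = balance_dataset(healthspan, trait=trait)
            balanced[trait] = rep.table
            balance_rows.append({
                "trait": trait, "rows_in": rep.n_rows_in,
                "rows_age_removed": rep.n_rows_age_removed,
                "lines_removed": len(rep.lines_removed),
                "rows_out": rep.n_rows_out,
            })
        else:
            balanced[trait] = healthspan
        line_mean_frames.append(compute_line_means(balanced[trait], trait))
    line_means = pd.concat(line_mean_frames, ignore_index=True)
    counts["line_mean_rows"] = len(line_means)
    _write(line_means, outdir / "line_means.tsv", cfg_hash)
    if balance_rows:
        _write(pd.DataFrame(balance_rows), outdir / "balance_report.tsv", cfg_hash)
    results["line_means"] = line_means

    # --- variance components and heritability -------------------------
    vc_rows, h2_rows = [], []
    vcs = {}
    for trait in cfg.traits:
        table = balanced[trait]
        retained_ages = sorted(table["age_days"].dropna().unique())
        for label, spec in _healthspan_specs(trait, retained_ages).items():
            try:
                vc = fit_mixed_model(table, spec)
            except (ValueError, RuntimeError) as exc:
                log.warning("varcomp %s/%s failed: %s", trait, label, exc)
                continue
            vcs[(trait, label)] = vc
            for term, s2 in vc.estimates.items():
                vc_rows.append({
                    "trait": trait, "subset": label, "term": term, "sigma2": s2,
                    "boundary": term in vc.boundary,
                })
            h2 = estimate_H2(vc)
            h2_rows.append({
                "trait": trait, "subset": label, "H2": h2.H2, "se": h2.se_H2,
                "ci_low": h2.ci_low, "ci_high": h2.ci_high,
                "H2_with_rep_denominator": h2.H2_with_rep,
            })
    results["varcomp"] = vcs
    _write(pd.DataFrame(vc_rows), outdir / "variance_components.tsv", cfg_hash)
    _write(pd.DataFrame(h2_rows), outdir / "heritability.tsv", cfg_hash)
    counts["varcomp_fits"] = len(vcs)

    # --- G-by-E: genetic correlations and rank decomposition ----------
    gxe_rows, sp_rows = [], []
    for trait in cfg.traits:
        lm = line_means[line_means["trait"] == trait]
        for axis in ("diet", "age"):
            try:
                s = gxe_summary(line_means=lm, trait=trait, axis=axis)
            except ValueError as exc:
                log.warning("gxe %s/%s skipped: %s", trait, axis, exc)
                continue
            rho, pr = s["rho_G"], s["pct_rank"]
            gxe_rows.append({
                "trait": trait, "axis": axis,
                "cond1": s["conditions"][0], "cond2": s["conditions"][1],
                "rho_G": rho.rho, "se": rho.se,
                "ci_low": rho.ci_low, "ci_high": rho.ci_high,
                "rho_out_of_range": rho.out_of_range,
                "pct_rank": pr.pct_rank, "status": pr.status,
                "n_lines": s["n_shared_lines"],
            })
            # phenotypic (Spearman) correlation over the same pairing
            col = "diet" if axis == "diet" else "age_days"
            wide = lm.groupby(["line_id", col])["mean"].mean().unstack()
            wide = wide.dropna()
            if len(wide) >= 4:
                c1, c2 = s["conditions"]
                sp = spearman_correlation(wide[c1], wide[c2])
                sp_rows.append({
                    "trait": trait, "axis": axis, "cond1": c1, "cond2": c2,
                    "rho_P": sp.rho, "se": sp.se, "ci_low": sp.ci_low,
                    "ci_high": sp.ci_high, "n_lines": sp.n,
                })
    _write(pd.DataFrame(gxe_rows), outdir / "genetic_correlations.tsv", cfg_hash)
    _write(pd.DataFrame(sp_rows), outdir / "phenotypic_correlations.tsv", cfg_hash)
    results["gxe"] = gxe_rows

    # --- lifespan as a quantitative trait -----------------------------
    surv_obs = data["survival"]
    surv_obs = surv_obs[(surv_obs["event"] == 1)] if "event" in surv_obs else surv_obs
    if len(surv_obs) and surv_obs["line_id"].nunique() >= 4:
        ls_rows = []
        for label, spec in {
            "diets": ModelSpec(trait="lifespan_days", fixed=("diet",),
                               random=("line", "line:diet", "rep")),
            "control": ModelSpec(trait="lifespan_days", fixed=(),
                                 random=("line", "rep"), diets=("control",)),
            "restricted": ModelSpec(trait="lifespan_days", fixed=(),
                                    random=("line", "rep"), diets=("restricted",)),
        }.items():
            try:
                vc = fit_mixed_model(surv_obs, spec)
            except (ValueError, RuntimeError) as exc:
                log.warning("lifespan varcomp %s failed: %s", label, exc)
                continue
            h2 = estimate_H2(vc)
            ls_rows.append({
                "trait": "lifespan_days", "subset": label, "H2": h2.H2,
                "se": h2.se_H2, "ci_low": h2.ci_low, "ci_high": h2.ci_high,
                "H2_with_rep_denominator": h2.H2_with_rep,
            })
            vcs[("lifespan_days", label)] = vc
        if ls_rows:
            _write(pd.DataFrame(ls_rows), outdir / "heritability_lifespan.tsv",
                   cfg_hash)
            results["lifespan_h2"] = ls_rows
        ls_means = compute_line_means(surv_obs.assign(age_days=np.nan),
                                      "lifespan_days",
                                      grouping=("line_id", "diet"))
        try:
            s = gxe_summary(line_means=ls_means, trait="lifespan_days",
                            axis="diet")
            results["lifespan_gxe"] = s
            gxe_rows.append({
                "trait": "lifespan_days", "axis": "diet",
                "cond1": s["conditions"][0], "cond2": s["conditions"][1],
                "rho_G": s["rho_G"].rho, "se": s["rho_G"].se,
                "ci_low": s["rho_G"].ci_low, "ci_high": s["rho_G"].ci_high,
                "rho_out_of_range": s["rho_G"].out_of_range,
                "pct_rank": s["pct_rank"].pct_rank,
                "status": s["pct_rank"].status,
                "n_lines": s["n_shared_lines"],
            })
            _write(pd.DataFrame(gxe_rows), outdir / "genetic_correlations.tsv",
                   cfg_hash)
        except ValueError as exc:
            log.warning("lifespan gxe skipped: %s", exc)

    # --- survival ------------------------------------------------------
    surv = data["survival"]
    if len(surv):
        fit = fit_cox(surv)
        _write(fit.table(), outdir / "cox_diet.tsv", cfg_hash)
        report = censoring_report(surv)
        (outdir / "censoring.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        results["cox"] = fit
        results["censoring"] = report
        counts["survival_rows"] = len(surv)

    # --- GWAS -----------------------------------------------------------
    if cfg.gwas is not None and "genotypes" in data:
        gw: GwasBlock = cfg.gwas
        geno = data["genotypes"]
        grm = compute_grm(geno, maf_min=gw.maf_min)
        lm = line_means[line_means["trait"] == gw.trait]
        for mode in gw.modes:
            resp = make_response(
                lm, mode=mode,
                conditions=gw.conditions if mode == "difference" else gw.conditions[0],
                condition_col=gw.condition_col,
            )
            if "covariates" in data:
                resp = adjust_covariates(resp, data["covariates"])
            scan = gwas_scan(resp, geno, grm, maf_min=gw.maf_min)
            n_tested = int(scan["tested"].sum())
            thr = bonferroni_threshold(n_tested, gw.alpha)
            scan["significant"] = scan["p"] < thr
            _write(scan, outdir / f"gwas_{gw.trait}_{mode}.tsv", cfg_hash)
            tables = plot_tables(scan)
            _write(tables["qq"], outdir / f"gwas_{gw.trait}_{mode}_qq.tsv", cfg_hash)
            results[f"gwas_{mode}"] = {
                "scan": scan,
                "bonferroni": thr,
                "lambda_gc": genomic_control_lambda(scan["p"].dropna()),
                "null_h2": scan.attrs["null_h2"],
            }
            counts[f"gwas_{mode}_tested"] = n_tested

    manifest = {
        "package": "dietgxe",
        "version": __version__,
        "versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "seed": cfg.seed,
        "config_hash": cfg_hash,
        "record_counts": counts,
        "planted_variants": {
            t: [list(c) for c in cs]
            for t, cs in data.get("causal", {}).items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    results["manifest"] = manifest
    return results
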
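"""Readers and writers for the pipeline's file formats.

Phenotypes travel as a CSV with a fixed schema; genotypes as VCF v4.2
(GT field, homozygous calls) or a plain line x variant dosage TSV;
covariates as CSV.  Validation is row-level and counted — bad rows are
rejected and reported, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "PHENOTYPE_COLUMNS",
    "ReadReport",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_covariates",
]

PHENOTYPE_COLUMNS = [
    "line_id", "diet", "age_days", "replicate", "dry_weight_mg",
    "locomotor_activity", "hkdt_min", "lifespan_days", "censor_code",
]

_NUMERIC = ["age_days", "dry_weight_mg", "locomotor_activity", "hkdt_min",
            "lifespan_days"]


@dataclass
class ReadReport:
    n_rows: int
    n_bad: int
    bad_rows: list[tuple[int, str]] = field(default_factory=list)


def read_phenotypes(path) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate the fly-level phenotype CSV.

    Returns the typed table of valid rows and a report listing rejected
    rows with their (1-based, header-exclusive) row numbers and reasons.
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype CSV is missing required columns: {missing}")
    for c in _NUMERIC:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    bad: list[tuple[int, str]] = []
    ok = pd.Series(True, index=df.index)

    def reject(mask, reason):
        nonlocal ok
        for i in df.index[mask & ok]:
            bad.append((int(i) + 1, reason))
        ok &= ~mask

    reject(df["line_id"].isna(), "missing line_id")
    reject(~df["diet"].isin(["control", "restricted"]), "unknown diet")
    reject(df["dry_weight_mg"].notna() & (df["dry_weight_mg"] <= 0),
           "non-positive dry weight")
    reject(df["hkdt_min"].notna() & ~df["hkdt_min"].between(0, 120, inclusive="right"),
           "hkdt outside (0, 120] minutes")
    reject(df["lifespan_days"].notna() & (df["lifespan_days"] <= 0),
           "non-positive lifespan")
    out = df[ok].reset_index(drop=True)
    return out, ReadReport(n_rows=len(df), n_bad=len(bad), bad_rows=bad)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for c in PHENOTYPE_COLUMNS:          # schema columns always present
        if c not in out.columns:
            out[c] = np.nan
    extra = [c for c in table.columns if c not in PHENOTYPE_COLUMNS]
    out[PHENOTYPE_COLUMNS + extra].to_csv(path, index=False,
                                          float_format="%.10g")


# ---------------------------------------------------------------------------
# Genotypes


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read line genotypes from VCF v4.2 or a dosage TSV.

    Homozygous calls map to dosages {0, 2}.  Heterozygous calls violate
    the inbred-panel contract: they are set missing and counted in a
    warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    lines = list(vcf.samples)
    dosages = []
    meta = []
    n_het = 0
    for v in vcf:
        gt = np.asarray(v.gt_types, dtype=float)   # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        dose = np.where(gt == 0, 0.0, np.where(gt == 2, 2.0, np.nan))
        n_het += int((gt == 1).sum())
        dosages.append(dose)
        alt = v.ALT[0] if v.ALT else "."
        meta.append((v.CHROM, v.POS, v.REF, alt))
    if n_het:
        warnings.warn(
            f"{n_het} heterozygous calls set to missing (inbred panel contract)",
            stacklevel=2,
        )
    dos = np.array(dosages).T if dosages else np.empty((len(lines), 0))
    mdf = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    p = np.nanmean(dos, axis=0) / 2.0
    mdf["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(dosages=dos, variant_meta=mdf, line_ids=lines)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "line_id":
        raise ValueError("dosage TSV must have 'line_id' as its first column")
    lines = df["line_id"].astype(str).tolist()
    dos = df.drop(columns="line_id").to_numpy(float)
    n_het = int(np.isin(dos, [1.0]).sum())
    if n_het:
        warnings.warn(
            f"{n_het} dosage-1 calls set to missing (inbred panel contract)",
            stacklevel=2,
        )
        dos = np.where(dos == 1.0, np.nan, dos)
    ids = list(df.columns[1:])
    chrom, pos, ref, alt = [], [], [], []
    for vid in ids:
        parts = str(vid).split("_")
        if len(parts) >= 4:
            chrom.append(parts[0]); pos.append(int(parts[1]))
            ref.append(parts[2]); alt.append(parts[3])
        else:
            chrom.append("unknown"); pos.append(len(pos) + 1)
            ref.append("N"); alt.append("N")
    p = np.nanmean(dos, axis=0) / 2.0
    meta = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "maf": np.minimum(p, 1 - p)})
    return GenotypeMatrix(dosages=dos, variant_meta=meta, line_ids=lines)


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    ids = [
        f"{r.chrom}_{r.pos}_{r.ref}_{r.alt}"
        for r in geno.variant_meta.itertuples()
    ]
    df = pd.DataFrame(geno.dosages, columns=ids)
    df.insert(0, "line_id", geno.line_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF v4.2 with homozygous GT calls."""
    chroms = list(dict.fromkeys(geno.variant_meta["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dietgxe\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.line_ids) + "\n")
        code = {0.0: "0/0", 2.0: "1/1"}
        for j, r in enumerate(geno.variant_meta.itertuples()):
            calls = [
                code.get(geno.dosages[i, j], "./.")
                if np.isfinite(geno.dosages[i, j]) else "./."
                for i in range(geno.n_lines)
            ]
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "line_id" not in df.columns:
        raise ValueError("covariate CSV must contain line_id")
    if df["line_id"].duplicated().any():
        raise ValueError("covariate CSV has duplicated line_id rows")
    return df
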
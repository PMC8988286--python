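"""Interchange formats: PLINK FAM/bed/bim, VCF, TSV tables, GRM files.

Conventions: in VCF output REF is the other allele and ALT the effect
allele, so dosages count ALT copies; in the PLINK triplet A1 is the effect
allele (bed codes 00=hom A1 -> dosage 2, 10=het, 11=hom A2, 01=missing).
The GRM is stored as a gzipped row-major lower triangle (n(n+1)/2 values,
one per line) next to a plain id list, optionally also as a square TSV.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import RelatednessMatrix
from .simulate import MISSING_PARENT, GenotypeMatrix, validate_pedigree

__all__ = [
    "write_fam", "read_fam",
    "write_vcf", "read_vcf",
    "write_plink", "read_plink",
    "write_sumstats", "read_sumstats",
    "write_table", "read_table",
    "write_grm", "read_grm",
]

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P"]


# -- pedigree (PLINK FAM dialect) -------------------------------------------

def write_fam(pedigree: pd.DataFrame, path, phenotype=None) -> None:
    """Six-column FAM: FID IID father mother sex phenotype (0 = missing parent)."""
    validate_pedigree(pedigree)
    pheno = pd.Series(-9, index=range(len(pedigree))) if phenotype is None else pd.Series(np.asarray(phenotype))
    out = pd.DataFrame(
        {
            "fid": pedigree["family_id"],
            "iid": pedigree["individual_id"],
            "father": pedigree["father_id"],
            "mother": pedigree["mother_id"],
            "sex": pedigree["sex"],
            "pheno": pheno.to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fam(path) -> pd.DataFrame:
    """Read a FAM file; generation (not stored in FAM) is inferred as pedigree depth."""
    fam = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str)
    generation = _infer_generations(fam)
    ped = pd.DataFrame(
        {
            "individual_id": fam["iid"],
            "family_id": fam["fid"],
            "father_id": fam["father"],
            "mother_id": fam["mother"],
            "sex": fam["sex"].astype(int),
            "generation": generation,
        }
    )
    validate_pedigree(ped)
    return ped


def _infer_generations(fam: pd.DataFrame) -> np.ndarray:
    gen = {}
    out = np.zeros(len(fam), dtype=int)
    for i, row in enumerate(fam.itertuples(index=False)):
        if row.father == MISSING_PARENT:
            g = 0
        else:
            g = max(gen.get(row.father, 0), gen.get(row.mother, 0)) + 1
        gen[row.iid] = g
        out[i] = g
    return out


# -- VCF ---------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, panel: pd.DataFrame, path) -> None:
    """Plain-text VCF with GT calls; REF = other allele, ALT = effect allele."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(str(i) for i in genotypes.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in enumerate(panel.itertuples(index=False)):
            calls = [
                "./." if genotypes.missing[i, j] else _GT[int(genotypes.dosage[i, j])]
                for i in range(genotypes.n_individuals)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.other_allele}\t{row.effect_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read genotypes + a minimal variant panel from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    dosage_rows, missing_rows, meta = [], [], []
    for v in vcf:
        gts = np.array([g[:2] for g in v.genotypes])
        miss = (gts < 0).any(axis=1)
        dose = np.where(miss, 0, gts.clip(min=0).sum(axis=1))
        dosage_rows.append(dose)
        missing_rows.append(miss)
        meta.append((v.ID, v.CHROM, v.POS, v.ALT[0], v.REF))
    vcf.close()
    panel = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele"])
    dosage = np.array(dosage_rows, dtype=np.int8).T
    missing = np.array(missing_rows, dtype=bool).T
    return GenotypeMatrix(dosage, missing, ids, panel["variant_id"].to_numpy()), panel


# -- PLINK bed/bim/fam -------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit code per genotype, indexed by dosage of A1 (effect allele); 01 = missing
_CODE_OF_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_OF_CODE = {0b00: 2, 0b10: 1, 0b11: 0}


def write_plink(genotypes: GenotypeMatrix, panel: pd.DataFrame, pedigree: pd.DataFrame, prefix) -> None:
    """Write <prefix>.bed/.bim/.fam with A1 = effect allele."""
    prefix = Path(prefix)
    write_fam(pedigree, prefix.with_suffix(".fam"))
    bim = pd.DataFrame(
        {
            "chrom": panel["chrom"],
            "id": panel["variant_id"],
            "cm": 0,
            "pos": panel["pos"],
            "a1": panel["effect_allele"],
            "a2": panel["other_allele"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    n = genotypes.n_individuals
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(genotypes.n_variants):
            byte_row = bytearray((n + 3) // 4)
            for i in range(n):
                code = 0b01 if genotypes.missing[i, j] else _CODE_OF_DOSAGE[int(genotypes.dosage[i, j])]
                byte_row[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(byte_row))


def read_plink(prefix) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK triplet written by :func:`write_plink`."""
    prefix = Path(prefix)
    pedigree = read_fam(prefix.with_suffix(".fam"))
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str})
    n = len(pedigree)
    m = len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK bed file")
    stride = (n + 3) // 4
    body = raw[3:].reshape(m, stride)
    dosage = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    for j in range(m):
        for i in range(n):
            code = (body[j, i // 4] >> (2 * (i % 4))) & 0b11
            if code == 0b01:
                missing[i, j] = True
            else:
                dosage[i, j] = _DOSAGE_OF_CODE[code]
    panel = pd.DataFrame(
        {
            "variant_id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "effect_allele": bim["a1"],
            "other_allele": bim["a2"],
        }
    )
    geno = GenotypeMatrix(dosage, missing, pedigree["individual_id"].to_numpy(), panel["variant_id"].to_numpy())
    return geno, panel, pedigree


# -- summary statistics ------------------------------------------------------

def write_sumstats(panel: pd.DataFrame, path) -> None:
    """Tab-separated summary statistics (SNP CHR BP A1 A2 FREQ BETA SE P)."""
    out = pd.DataFrame(
        {
            "SNP": panel["variant_id"],
            "CHR": panel["chrom"],
            "BP": panel["pos"],
            "A1": panel["effect_allele"],
            "A2": panel["other_allele"],
            "FREQ": panel["freq"],
            "BETA": panel["beta_published"],
            "SE": panel["se_published"],
            "P": panel["p_published"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return df.rename(
        columns={
            "SNP": "variant_id", "CHR": "chrom", "BP": "pos", "A1": "effect_allele",
            "A2": "other_allele", "FREQ": "freq", "BETA": "beta_published",
            "SE": "se_published", "P": "p_published",
        }
    )


# -- generic TSV tables ------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -- GRM ---------------------------------------------------------------------

def write_grm(grm: RelatednessMatrix, prefix, square_tsv: bool = False) -> None:
    """Gzipped lower triangle (row-major, n(n+1)/2 lines) + id list."""
    prefix = Path(prefix)
    n = len(grm.ids)
    with open(str(prefix) + ".grm.gz", "wb") as raw:
        # mtime=0 keeps output byte-identical across reruns
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            lines = (f"{grm.values[i, j]:.10g}\n" for i in range(n) for j in range(i + 1))
            gz.write("".join(lines).encode())
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\n")
    if square_tsv:
        pd.DataFrame(grm.values, index=grm.ids, columns=grm.ids).to_csv(str(prefix) + ".grm.tsv", sep="\t")


def read_grm(prefix, kind: str = "empirical") -> RelatednessMatrix:
    prefix = Path(prefix)
    with open(str(prefix) + ".grm.id") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    n = len(ids)
    with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
        vals = np.array([float(line) for line in fh])
    if len(vals) != n * (n + 1) // 2:
        raise ValueError("GRM triangle length does not match id list")
    k = np.zeros((n, n))
    pos = 0
    for i in range(n):
        k[i, : i + 1] = vals[pos : pos + i + 1]
        pos += i + 1
    k = k + np.tril(k, -1).T
    return RelatednessMatrix(k, np.array(ids, dtype=object), kind)
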
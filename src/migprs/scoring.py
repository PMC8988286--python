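"""Clump-and-threshold polygenic risk scoring.

Harmonizes GWAS summary statistics to a genotype panel, applies variant QC
(MAF, missingness, founder Hardy-Weinberg exact test), greedily LD-clumps by
p-value, filters on a p-value threshold, computes the weighted allele score
raw_i = sum_v dosage_iv * beta_v (missing dosages mean-imputed to 2*freq),
and scales scores to a population reference so that 0 is the reference mean
and 1 the reference standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import GenotypeMatrix

__all__ = [
    "hwe_exact_p",
    "qc_filter",
    "harmonize",
    "ld_clump",
    "p_threshold",
    "compute_prs",
    "scale_to_reference",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WEIGHT_COLUMNS = ["variant_id", "chrom", "pos", "aligned_beta", "p", "kept", "drop_reason"]


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg exact test p-value by full enumeration.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (two-sided, Wigginton-style).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    # P(het = h | allele counts) ∝ n! / (hom_a! h! hom_b!) * 2^h  (conditional
    # distribution of heterozygotes given allele counts under random union)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = hets * np.log(2.0) + gammaln(n + 1) - gammaln(hom_minor + 1) - gammaln(hets + 1) - gammaln(hom_major + 1)
    logp -= np.max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = int(min(n_het, n_minor))
    p_obs = probs[np.flatnonzero(hets == obs)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    genotypes: GenotypeMatrix,
    panel: pd.DataFrame,
    maf_min: float = 0.01,
    missing_max: float = 0.05,
    hwe_p_min: float = 1e-6,
    founders: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant QC: sample MAF, call-rate and founder HWE filters.

    ``founders`` is a boolean mask over individuals used for the HWE test
    (defaults to everyone); computing HWE among pedigree founders only
    avoids relatedness-induced departures. Returns a DataFrame indexed like
    the panel with columns maf, missing_rate, hwe_p, kept.
    """
    for name, v in (("maf_min", maf_min), ("missing_max", missing_max), ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if founders is None:
        founders = np.ones(genotypes.n_individuals, dtype=bool)
    freq = genotypes.allele_frequency()
    maf = np.fmin(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    missing_rate = genotypes.missing.mean(axis=0)

    fd = genotypes.dosage[founders]
    fm = genotypes.missing[founders]
    hwe_p = np.ones(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        d = fd[~fm[:, j], j]
        hwe_p[j] = hwe_exact_p(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
    kept = (maf >= maf_min) & (missing_rate <= missing_max) & (hwe_p >= hwe_p_min)
    return pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "maf": maf,
            "missing_rate": missing_rate,
            "hwe_p": hwe_p,
            "kept": kept,
        }
    )


def _check_unique(ids: pd.Series, source: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant_id {dup.iloc[0]!r} in {source}")


def harmonize(stats: pd.DataFrame, genotype_panel: pd.DataFrame, qc: pd.DataFrame | None = None) -> pd.DataFrame:
    """Align published effects to the genotype panel's effect/other alleles.

    Matching alleles keep the published beta; swapped effect/other alleles
    flip its sign; strand-flipped non-palindromic pairs are resolved by
    complementing; palindromic (A/T, C/G) variants are dropped as
    ``ambiguous``; irreconcilable alleles as ``mismatch``. Variants failing
    an upstream QC table (if given) are dropped as ``qc_fail``.
    """
    _check_unique(stats["variant_id"], "summary stats")
    _check_unique(genotype_panel["variant_id"], "genotype panel")
    stats_by_id = stats.set_index("variant_id")
    qc_kept = None
    if qc is not None:
        qc_kept = qc.set_index("variant_id")["kept"]
    rows = []
    for row in genotype_panel.itertuples(index=False):
        beta = np.nan
        p = np.nan
        kept = False
        reason = "none"
        if qc_kept is not None and not bool(qc_kept.get(row.variant_id, False)):
            reason = "qc_fail"
        elif row.variant_id not in stats_by_id.index:
            reason = "mismatch"
        else:
            s = stats_by_id.loc[row.variant_id]
            ea, oa = str(s["effect_allele"]), str(s["other_allele"])
            gea, goa = str(row.effect_allele), str(row.other_allele)
            if COMPLEMENT.get(ea) == oa:
                reason = "ambiguous"  # palindromic: strand unresolvable
            else:
                flipped = (COMPLEMENT.get(ea), COMPLEMENT.get(oa))
                if (ea, oa) == (gea, goa) or flipped == (gea, goa):
                    beta, p, kept = float(s["beta_published"]), float(s["p_published"]), True
                elif (oa, ea) == (gea, goa) or (flipped[1], flipped[0]) == (gea, goa):
                    beta, p, kept = -float(s["beta_published"]), float(s["p_published"]), True
                else:
                    reason = "mismatch"
        rows.append((row.variant_id, row.chrom, row.pos, beta, p, kept, reason))
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def _pair_r2(genotypes: GenotypeMatrix, j: int, k: int) -> float:
    """Squared Pearson correlation of dosages over individuals non-missing at both."""
    ok = ~(genotypes.missing[:, j] | genotypes.missing[:, k])
    if ok.sum() < 2:
        return 0.0
    a = genotypes.dosage[ok, j].astype(float)
    b = genotypes.dosage[ok, k].astype(float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return float(r * r)


def ld_clump(weights: pd.DataFrame, genotypes: GenotypeMatrix, r2_max: float = 0.1, window_kb: float = 500.0) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping.

    Iterate kept variants in ascending p (ties by chrom, pos, variant_id);
    each selected index variant removes (reason ``clumped``) every
    not-yet-selected variant on the same chromosome within ``window_kb``
    whose sample r2 with it exceeds ``r2_max``.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    out = weights.copy().reset_index(drop=True)
    col_of = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    cand = out[out["kept"]].copy()
    if cand["p"].isna().any():
        raise ValueError("all kept variants need a p-value before clumping")
    order = cand.sort_values(["p", "chrom", "pos", "variant_id"], kind="mergesort").index
    window = window_kb * 1000.0
    removed: set = set()
    selected: set = set()
    for i in order:
        if i in removed:
            continue
        selected.add(i)
        ci, pi = out.at[i, "chrom"], out.at[i, "pos"]
        near = cand.index[
            (cand["chrom"] == ci)
            & (np.abs(cand["pos"] - pi) <= window)
            & ~cand.index.isin(selected)
            & ~cand.index.isin(removed)
        ]
        for k in near:
            if _pair_r2(genotypes, col_of[out.at[i, "variant_id"]], col_of[out.at[k, "variant_id"]]) > r2_max:
                removed.add(k)
    removed_idx = sorted(removed)
    out.loc[removed_idx, "kept"] = False
    out.loc[removed_idx, "drop_reason"] = "clumped"
    return out


def p_threshold(weights: pd.DataFrame, p_max: float) -> pd.DataFrame:
    """Keep variants with p <= p_max (boundary inclusive); others get ``p_fail``."""
    if not 0.0 < p_max <= 1.0:
        raise ValueError("p_max must lie in (0, 1]")
    out = weights.copy()
    fail = out["kept"] & (out["p"] > p_max)
    out.loc[fail, "kept"] = False
    out.loc[fail, "drop_reason"] = "p_fail"
    return out


def compute_prs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> pd.DataFrame:
    """Raw weighted allele score per individual over the kept variants.

    Missing dosages are imputed to twice the variant's sample effect-allele
    frequency, so individuals remain comparable across missingness patterns.
    """
    kept = weights[weights["kept"]]
    if kept.empty:
        raise ValueError("no variants in score")
    sub = genotypes.subset_variants(kept["variant_id"].to_list())
    d = sub.dosage.astype(float)
    freq = sub.allele_frequency()
    freq = np.where(np.isnan(freq), 0.0, freq)
    d = np.where(sub.missing, 2.0 * freq[None, :], d)
    raw = d @ kept["aligned_beta"].to_numpy()
    return pd.DataFrame({"iid": genotypes.ids, "raw_score": raw})


def scale_to_reference(scores: pd.DataFrame, reference_scores) -> pd.DataFrame:
    """Center/scale raw scores to a reference cohort's mean and sd (n-1).

    Zero on the returned scale is the reference mean; one is the reference
    standard deviation.
    """
    ref = np.asarray(reference_scores, dtype=float)
    if len(np.unique(ref)) < 2:
        raise ValueError("zero reference variance")
    mu = ref.mean()
    sd = ref.std(ddof=1)
    out = scores.copy()
    out["scaled_score"] = (out["raw_score"] - mu) / sd
    return out
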
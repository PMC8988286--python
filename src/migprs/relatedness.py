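"""Genetic relatedness: LD pruning, empirical GRM, and the pedigree oracle.

The empirical genetic relatedness matrix (GRM) is the frequency-standardized
average over variants, K = (1/M) sum_v z_v z_v', with
z_iv = (d_iv - 2 p_v) / sqrt(2 p_v (1 - p_v)) and p_v the sample
effect-allele frequency; missing dosages contribute zero after
standardization. The pedigree-expected additive relationship matrix computed
by the classic tabular recursion serves as its large-M oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING_PARENT, GenotypeMatrix, validate_pedigree

__all__ = [
    "RelatednessMatrix",
    "ld_prune",
    "compute_grm",
    "pedigree_relationship",
    "pedigree_relationship_blocks",
]


@dataclass
class RelatednessMatrix:
    """Symmetric relatedness matrix with its provenance flag."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # "empirical" | "pedigree_expected"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("ids length does not match matrix size")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("relatedness matrix must be symmetric")


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise r2 among columns of a dosage block (missing already imputed)."""
    x = d - d.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: correlate with nothing
    c = (x.T @ x) / len(x)
    r = c / np.outer(sd, sd)
    return r * r


def ld_prune(
    genotypes: GenotypeMatrix,
    panel: pd.DataFrame,
    window_variants: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Sliding-window greedy LD pruning; returns the kept variant ids.

    Within each window of ``window_variants`` consecutive variants (position
    order per chromosome) the highest-r2 pair above ``r2_max`` loses its
    later-positioned member, repeatedly, until no such pair survives;
    windows advance by ``step``.
    """
    if window_variants < 2:
        raise ValueError("window_variants must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    d = genotypes.dosage.astype(float)
    if genotypes.missing.any():
        freq = genotypes.allele_frequency()
        d = np.where(genotypes.missing, 2.0 * np.where(np.isnan(freq), 0.0, freq)[None, :], d)
    removed = np.zeros(genotypes.n_variants, dtype=bool)
    for _, grp in panel.groupby("chrom", sort=False):
        cols = grp.sort_values("pos").index.to_numpy()
        start = 0
        while start < len(cols):
            win = cols[start : start + window_variants]
            while True:
                alive = win[~removed[win]]
                if len(alive) < 2:
                    break
                r2 = _window_r2(d[:, alive])
                np.fill_diagonal(r2, 0.0)
                jj, kk = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[jj, kk] <= r2_max:
                    break
                # drop the later-positioned member of the worst pair
                removed[alive[max(jj, kk)]] = True
            if start + window_variants >= len(cols):
                break
            start += step
    return genotypes.variant_ids[~removed]


def compute_grm(genotypes: GenotypeMatrix, kept: np.ndarray | None = None) -> RelatednessMatrix:
    """Frequency-standardized empirical GRM over the kept variants."""
    sub = genotypes if kept is None else genotypes.subset_variants(list(kept))
    freq = sub.allele_frequency()
    poly = ~np.isnan(freq) & (freq > 0) & (freq < 1)
    if poly.sum() < 1:
        raise ValueError("no polymorphic variants available for the GRM")
    d = sub.dosage[:, poly].astype(float)
    miss = sub.missing[:, poly]
    p = freq[poly]
    z = (d - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    z[miss] = 0.0
    m = poly.sum()
    k = (z @ z.T) / m
    k = (k + k.T) / 2.0
    return RelatednessMatrix(k, sub.ids, "empirical")


def pedigree_relationship(pedigree: pd.DataFrame) -> RelatednessMatrix:
    """Additive (numerator) relationship matrix by the tabular recursion.

    A_ii = 1 + 0.5 A_fm for parents f, m (founders: 1); for j later than i,
    A_ij = 0.5 (A_i,f(j) + A_i,m(j)).
    """
    validate_pedigree(pedigree)
    ids = pedigree["individual_id"].to_numpy()
    row_of = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    fathers = pedigree["father_id"].to_numpy()
    mothers = pedigree["mother_id"].to_numpy()
    for j in range(n):
        if fathers[j] == MISSING_PARENT:
            a[j, j] = 1.0
        else:
            f, m = row_of[fathers[j]], row_of[mothers[j]]
            a[j, j] = 1.0 + 0.5 * a[f, m]
            for i in range(j):
                a[i, j] = a[j, i] = 0.5 * (a[i, f] + a[i, m])
    return RelatednessMatrix(a, ids, "pedigree_expected")


def pedigree_relationship_blocks(pedigree: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-family (row-indices, relationship-block) pairs.

    Families are unrelated, so the full matrix is block-diagonal; this form
    scales to cohorts where the dense matrix would not.
    """
    validate_pedigree(pedigree)
    blocks = []
    for _, grp in pedigree.groupby("family_id", sort=False):
        sub = grp.reset_index()
        a = pedigree_relationship(sub.drop(columns="index")).values
        blocks.append((sub["index"].to_numpy(), a))
    return blocks
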
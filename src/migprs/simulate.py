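"""Synthetic family-cohort generator.

Builds everything the downstream analysis consumes without touching real
data: multi-generation pedigrees, LD-blocked genotypes dropped through the
pedigree, GWAS-style summary statistics (true effects plus estimation
noise), and a liability-threshold symptom battery whose diagnostic ladder
rises with polygenic burden by construction.

The genotype model draws founder haplotypes from a per-block exchangeable
latent-Gaussian (probit) model: within an LD block every variant shares a
common latent factor with loading sqrt(rho), so marginal effect-allele
frequencies are exact while within-block r2 is positive and tunable.
Children inherit whole blocks from each parent (gene dropping), with an
independent choice of parental haplotype per block, so Mendelian
consistency holds exactly and LD survives transmission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnosis import AURA_COLUMNS, BATTERY_COLUMNS, HEADACHE_SYMPTOMS, MIGRAINE_LABELS

__all__ = [
    "FamilyShape",
    "GenotypeMatrix",
    "LiabilityModel",
    "generate_pedigrees",
    "make_variant_panel",
    "simulate_genotypes",
    "founder_population",
    "gene_drop",
    "simulate_summary_stats",
    "simulate_phenotypes",
    "ascertain_families",
    "validate_pedigree",
]

MISSING_PARENT = "0"

PEDIGREE_COLUMNS = ["individual_id", "family_id", "father_id", "mother_id", "sex", "generation"]

PANEL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele", "freq",
    "beta_true", "beta_published", "se_published", "p_published", "ld_block",
]


@dataclass(frozen=True)
class FamilyShape:
    """Shape of one simulated family: generation depth and mean sibship size.

    Sibship sizes are Poisson(mean_sibs) truncated to be at least one child,
    every child in a non-terminal generation marries an unrelated founder.
    """

    n_generations: int = 3
    mean_sibs: float = 2.5

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mean_sibs <= 0:
            raise ValueError("mean_sibs must be > 0")


@dataclass
class GenotypeMatrix:
    """Individuals x variants effect-allele dosages with a missingness mask.

    ``dosage`` holds values in {0, 1, 2}; entries where ``missing`` is True
    carry no information (the stored dosage there is 0 by convention).
    """

    dosage: np.ndarray           # (n, m) int8
    missing: np.ndarray          # (n, m) bool
    ids: np.ndarray              # (n,) individual ids
    variant_ids: np.ndarray      # (m,) variant ids

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.ids = np.asarray(self.ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.dosage.shape != self.missing.shape:
            raise ValueError("dosage and missing mask shapes differ")
        if self.dosage.shape != (len(self.ids), len(self.variant_ids)):
            raise ValueError("dosage shape does not match ids x variant_ids")
        observed = self.dosage[~self.missing]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Sample effect-allele frequency per variant over non-missing calls."""
        obs = (~self.missing).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs > 0, self.dosage.astype(float).sum(axis=0) / (2 * np.maximum(obs, 1)), np.nan)

    def subset_individuals(self, keep_ids: Sequence) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.ids)}
        rows = np.array([index[i] for i in keep_ids], dtype=int)
        return GenotypeMatrix(self.dosage[rows], self.missing[rows], np.asarray(keep_ids, dtype=object), self.variant_ids)

    def subset_variants(self, keep_variant_ids: Sequence) -> "GenotypeMatrix":
        index = {vid: j for j, vid in enumerate(self.variant_ids)}
        cols = np.array([index[v] for v in keep_variant_ids], dtype=int)
        return GenotypeMatrix(self.dosage[:, cols], self.missing[:, cols], self.ids, np.asarray(keep_variant_ids, dtype=object))


def validate_pedigree(pedigree: pd.DataFrame) -> None:
    """Raise ValueError if the pedigree violates its structural invariants.

    Checks: required columns; parents precede children in record order (which
    also rules out ancestry cycles); fathers are male, mothers female; and
    parents are both present or both missing.
    """
    missing_cols = [c for c in PEDIGREE_COLUMNS if c not in pedigree.columns]
    if missing_cols:
        raise ValueError(f"pedigree missing columns: {missing_cols}")
    if pedigree["individual_id"].duplicated().any():
        dup = pedigree.loc[pedigree["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicate individual_id {dup!r}")
    if not pedigree["sex"].isin([1, 2]).all():
        raise ValueError("sex must be 1 (male) or 2 (female)")
    seen: dict = {}
    sex = dict(zip(pedigree["individual_id"], pedigree["sex"]))
    for order, row in enumerate(pedigree.itertuples(index=False)):
        father, mother = row.father_id, row.mother_id
        if (father == MISSING_PARENT) != (mother == MISSING_PARENT):
            raise ValueError(f"{row.individual_id}: both parents must be present or both missing")
        if father != MISSING_PARENT:
            for pid in (father, mother):
                if pid not in seen:
                    raise ValueError(f"{row.individual_id}: parent {pid!r} does not precede child")
            if sex[father] != 1:
                raise ValueError(f"father {father!r} must have sex 1")
            if sex[mother] != 2:
                raise ValueError(f"mother {mother!r} must have sex 2")
        seen[row.individual_id] = order


def _truncated_poisson(mean: float, rng: np.random.Generator) -> int:
    """Poisson(mean) conditioned on >= 1 by redrawing."""
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def generate_pedigrees(n_families: int, family_shape: FamilyShape | Mapping | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate ``n_families`` independent pedigrees.

    Each family starts from one founder couple; every child in a
    non-terminal generation marries a new unrelated founder, so the family
    grows for ``n_generations`` generations. Record order puts parents
    before children. Deterministic given ``seed``.
    """
    if not isinstance(n_families, (int, np.integer)) or n_families < 1:
        raise ValueError("n_families must be a positive integer")
    if family_shape is None:
        family_shape = FamilyShape()
    elif isinstance(family_shape, Mapping):
        family_shape = FamilyShape(**family_shape)
    rng = np.random.default_rng(seed)
    records = []
    for fam in range(n_families):
        fid = f"F{fam:05d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}_I{counter:03d}"

        father, mother = new_id(), new_id()
        records.append((father, fid, MISSING_PARENT, MISSING_PARENT, 1, 0))
        records.append((mother, fid, MISSING_PARENT, MISSING_PARENT, 2, 0))
        couples = [(father, mother)]
        for gen in range(1, family_shape.n_generations):
            next_couples = []
            for f_id, m_id in couples:
                for _ in range(_truncated_poisson(family_shape.mean_sibs, rng)):
                    child = new_id()
                    child_sex = int(rng.integers(1, 3))
                    records.append((child, fid, f_id, m_id, child_sex, gen))
                    if gen < family_shape.n_generations - 1:
                        spouse = new_id()
                        spouse_sex = 1 if child_sex == 2 else 2
                        records.append((spouse, fid, MISSING_PARENT, MISSING_PARENT, spouse_sex, gen))
                        pair = (child, spouse) if child_sex == 1 else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    pedigree = pd.DataFrame(records, columns=PEDIGREE_COLUMNS)
    validate_pedigree(pedigree)
    return pedigree


# ---------------------------------------------------------------------------
# Variant panel and summary statistics
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def make_variant_panel(
    n_variants: int = 1000,
    n_blocks: int = 50,
    seed: int = 0,
    n_chrom: int = 2,
    freq_range: tuple[float, float] = (0.05, 0.5),
    causal_fraction: float = 0.3,
    effect_sd: float = 0.05,
) -> pd.DataFrame:
    """Construct a common-variant panel with contiguous LD-block labels.

    Variants inside a block sit a few kb apart; consecutive blocks are
    separated by ~1 Mb so block structure and physical clumping windows
    coincide. A random ``causal_fraction`` of variants get nonzero
    ``beta_true`` drawn from Normal(0, effect_sd); the published columns are
    left unset until :func:`simulate_summary_stats` fills them.
    """
    if n_variants < 1 or n_blocks < 1 or n_blocks > n_variants:
        raise ValueError("need 1 <= n_blocks <= n_variants")
    rng = np.random.default_rng(seed)
    block = np.sort(rng.integers(0, n_blocks, size=n_variants)) if n_blocks > 1 else np.zeros(n_variants, dtype=int)
    # every block must be non-empty: fall back to an even split
    if len(np.unique(block)) < n_blocks:
        block = np.repeat(np.arange(n_blocks), int(np.ceil(n_variants / n_blocks)))[:n_variants]
    chrom_of_block = block % n_chrom
    order = np.lexsort((block, chrom_of_block))
    block = block[order]
    chrom = chrom_of_block[order]

    pos = np.zeros(n_variants, dtype=int)
    for c in range(n_chrom):
        on_c = np.flatnonzero(chrom == c)
        cur = 10_000
        prev_block = None
        for j in on_c:
            if prev_block is not None and block[j] != prev_block:
                cur += 1_000_000
            cur += int(rng.integers(1_000, 5_000))
            pos[j] = cur
            prev_block = block[j]

    effect = rng.integers(0, 4, size=n_variants)
    shift = rng.integers(1, 4, size=n_variants)
    other = (effect + shift) % 4
    beta_true = np.zeros(n_variants)
    causal = rng.random(n_variants) < causal_fraction
    beta_true[causal] = rng.normal(0.0, effect_sd, size=int(causal.sum()))
    panel = pd.DataFrame(
        {
            "variant_id": [f"rs{c + 1}_{p}" for c, p in zip(chrom, pos)],
            "chrom": [str(c + 1) for c in chrom],
            "pos": pos,
            "effect_allele": _BASES[effect],
            "other_allele": _BASES[other],
            "freq": rng.uniform(freq_range[0], freq_range[1], size=n_variants),
            "beta_true": beta_true,
            "beta_published": np.nan,
            "se_published": np.nan,
            "p_published": np.nan,
            "ld_block": block,
        }
    )
    return panel


def simulate_summary_stats(panel: pd.DataFrame, gwas_n: int, seed: int = 0) -> pd.DataFrame:
    """Emulate published GWAS summary statistics for the panel.

    Under a standardized-trait approximation the sampling standard error of
    a per-allele effect at frequency ``f`` in a GWAS of ``gwas_n`` samples is
    1 / sqrt(2 f (1 - f) gwas_n); the published effect is the true effect
    plus Normal(0, se) noise, and the p-value is the two-sided normal tail
    of beta/se.
    """
    if not isinstance(gwas_n, (int, np.integer)) or gwas_n <= 0:
        raise ValueError("gwas_n must be a positive integer")
    if "beta_true" not in panel.columns or panel["beta_true"].isna().any():
        raise ValueError("panel must carry beta_true for every variant")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    f = out["freq"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * gwas_n)
    beta = out["beta_true"].to_numpy() + rng.normal(0.0, 1.0, size=len(out)) * se
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out["beta_published"] = beta
    out["se_published"] = se
    out["p_published"] = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return out


# ---------------------------------------------------------------------------
# Genotypes: founder haplotypes + gene dropping
# ---------------------------------------------------------------------------

def _draw_founder_haplotypes(panel: pd.DataFrame, n_haplotypes: int, rng: np.random.Generator, ld_rho: float) -> np.ndarray:
    """Draw haplotypes (n_haplotypes x m) from the block-probit model.

    allele_v = 1 iff sqrt(rho) * u_block + sqrt(1-rho) * eps_v < Phi^-1(f_v),
    giving exact Bernoulli(f_v) marginals and exchangeable within-block LD.
    """
    freq = panel["freq"].to_numpy()
    if np.any(freq <= 0) or np.any(freq >= 1):
        raise ValueError("panel frequencies must lie strictly in (0, 1)")
    if not 0 <= ld_rho < 1:
        raise ValueError("ld_rho must lie in [0, 1)")
    block = panel["ld_block"].to_numpy()
    blocks, block_idx = np.unique(block, return_inverse=True)
    thr = stats.norm.ppf(freq)
    u = rng.normal(size=(n_haplotypes, len(blocks)))
    eps = rng.normal(size=(n_haplotypes, len(freq)))
    z = np.sqrt(ld_rho) * u[:, block_idx] + np.sqrt(1.0 - ld_rho) * eps
    return (z < thr).astype(np.int8)


def gene_drop(pedigree: pd.DataFrame, panel: pd.DataFrame, founder_haplotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Drop founder haplotypes through the pedigree; return (n, 2, m) haplotypes.

    ``founder_haplotypes`` has shape (2 * n_founders, m) in pedigree founder
    order. Each gamete copies one of the parent's two haplotypes per LD
    block, the choice independent across blocks (inter-block recombination
    probability 1/2; within-block transmission intact).
    """
    block = panel["ld_block"].to_numpy()
    blocks, block_idx = np.unique(block, return_inverse=True)
    n_blocks = len(blocks)
    n = len(pedigree)
    m = len(panel)
    haps = np.zeros((n, 2, m), dtype=np.int8)
    row_of = {iid: i for i, iid in enumerate(pedigree["individual_id"])}
    founder_rows = np.flatnonzero((pedigree["father_id"] == MISSING_PARENT).to_numpy())
    if founder_haplotypes.shape != (2 * len(founder_rows), m):
        raise ValueError("founder_haplotypes shape does not match pedigree founders x panel")
    for k, i in enumerate(founder_rows):
        haps[i, 0] = founder_haplotypes[2 * k]
        haps[i, 1] = founder_haplotypes[2 * k + 1]
    for row in pedigree.itertuples(index=False):
        if row.father_id == MISSING_PARENT:
            continue
        i = row_of[row.individual_id]
        for slot, parent in enumerate((row.father_id, row.mother_id)):
            p = row_of[parent]
            choice = rng.integers(0, 2, size=n_blocks)[block_idx]
            haps[i, slot] = np.where(choice == 0, haps[p, 0], haps[p, 1])
    return haps


def simulate_genotypes(
    pedigree: pd.DataFrame,
    panel: pd.DataFrame,
    seed: int = 0,
    ld_rho: float = 0.5,
    missing_rate: float = 0.0,
    founder_haplotypes: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Simulate effect-allele dosages for every pedigree member.

    Founder haplotypes come from the block-probit model (or are supplied
    explicitly), children by gene dropping. Mendelian consistency holds by
    construction. ``missing_rate`` masks calls completely at random.
    """
    validate_pedigree(pedigree)
    rng = np.random.default_rng(seed)
    n_founders = int((pedigree["father_id"] == MISSING_PARENT).sum())
    if founder_haplotypes is None:
        founder_haplotypes = _draw_founder_haplotypes(panel, 2 * n_founders, rng, ld_rho)
    haps = gene_drop(pedigree, panel, founder_haplotypes, rng)
    dosage = haps.sum(axis=1, dtype=np.int8)
    missing = np.zeros(dosage.shape, dtype=bool)
    if missing_rate > 0:
        missing = rng.random(dosage.shape) < missing_rate
        dosage = np.where(missing, 0, dosage).astype(np.int8)
    return GenotypeMatrix(dosage, missing, pedigree["individual_id"].to_numpy(), panel["variant_id"].to_numpy())


def founder_population(n: int, panel: pd.DataFrame, seed: int = 0, ld_rho: float = 0.5) -> GenotypeMatrix:
    """Simulate ``n`` unrelated individuals (a population reference sample)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    haps = _draw_founder_haplotypes(panel, 2 * n, rng, ld_rho)
    dosage = (haps[0::2] + haps[1::2]).astype(np.int8)
    ids = np.array([f"POP_I{i:06d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosage, np.zeros(dosage.shape, dtype=bool), ids, panel["variant_id"].to_numpy())


# ---------------------------------------------------------------------------
# Liability-threshold symptom model
# ---------------------------------------------------------------------------

def _default_thresholds(prevalences: Mapping[str, float], noise_sd: float) -> dict[str, float]:
    scale = np.sqrt(1.0 + noise_sd**2)
    return {s: float(stats.norm.ppf(1.0 - q) * scale) for s, q in prevalences.items()}


# Target population prevalences behind the default thresholds. Chosen so the
# implied category ladder is well populated and ordered
# (any headache > migraine headache > visual aura > motor aura).
DEFAULT_SYMPTOM_PREVALENCE = {
    "attacks_ge5": 0.35,
    "duration_4_72h": 0.30,
    "unilateral": 0.25,
    "pulsating": 0.25,
    "moderate_or_severe": 0.40,
    "activity_aggravates": 0.30,
    "nausea": 0.30,
    "vomiting": 0.15,
    "photophobia": 0.32,
    "phonophobia": 0.28,
    "osmophobia": 0.10,
}
DEFAULT_AURA_PREVALENCE = {
    "aura_visual": 0.10,
    "aura_sensory": 0.05,
    "aura_speech": 0.035,
    "aura_motor": 0.02,
}
_DEFAULT_NOISE_SD = 0.6


@dataclass
class LiabilityModel:
    """Single-liability threshold model for the symptom battery.

    liability_i = standardized(true-beta score)_i * sqrt(prs_weight) + e_i
    with e_i ~ Normal(0, env_sd); symptom s is present iff
    liability_i + Normal(0, symptom_noise_sd) > symptom_thresholds[s].
    Aura indicators use the (higher) aura_thresholds, so aura prevalence
    sits above migraine-level liability.
    """

    prs_weight: float = 0.35
    env_sd: float | None = None
    symptom_noise_sd: float = _DEFAULT_NOISE_SD
    symptom_thresholds: dict[str, float] = field(
        default_factory=lambda: _default_thresholds(DEFAULT_SYMPTOM_PREVALENCE, _DEFAULT_NOISE_SD)
    )
    aura_thresholds: dict[str, float] = field(
        default_factory=lambda: _default_thresholds(DEFAULT_AURA_PREVALENCE, _DEFAULT_NOISE_SD)
    )
    family_env_sd: float = 0.0  # shared-environment knob, off by default

    def __post_init__(self) -> None:
        if not 0.0 <= self.prs_weight <= 1.0:
            raise ValueError("prs_weight must lie in [0, 1]")
        if self.env_sd is None:
            self.env_sd = float(np.sqrt(max(1.0 - self.prs_weight, 0.0)))
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    panel: pd.DataFrame,
    model: LiabilityModel | None = None,
    seed: int = 0,
    family_ids: Sequence | None = None,
    return_liability: bool = False,
) -> pd.DataFrame:
    """Generate the boolean symptom battery from genotypes under ``model``.

    Returns a DataFrame indexed by individual id with one boolean column per
    battery field (complete rows: unanswered/missing is false by
    construction). With ``return_liability`` the realized latent liability is
    returned alongside, for validation of the generative structure.
    """
    if model is None:
        model = LiabilityModel()
    if len(panel) != genotypes.n_variants:
        raise ValueError("panel and genotype matrix disagree on variant count")
    rng = np.random.default_rng(seed)
    beta = panel["beta_true"].to_numpy()
    raw = (genotypes.dosage * ~genotypes.missing) @ beta
    sd = raw.std()
    score = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    n = genotypes.n_individuals
    liability = score * np.sqrt(model.prs_weight) + rng.normal(0.0, model.env_sd, size=n)
    if model.family_env_sd > 0:
        if family_ids is None:
            raise ValueError("family_ids required when family_env_sd > 0")
        fams, fam_idx = np.unique(np.asarray(family_ids), return_inverse=True)
        liability = liability + rng.normal(0.0, model.family_env_sd, size=len(fams))[fam_idx]
    cols = {}
    for s in HEADACHE_SYMPTOMS + ["osmophobia"]:
        thr = model.symptom_thresholds[s]
        cols[s] = liability + rng.normal(0.0, model.symptom_noise_sd, size=n) > thr
    for s in AURA_COLUMNS:
        thr = model.aura_thresholds[s]
        cols[s] = liability + rng.normal(0.0, model.symptom_noise_sd, size=n) > thr
    battery = pd.DataFrame(cols, index=pd.Index(genotypes.ids, name="individual_id"))
    battery = battery[BATTERY_COLUMNS]
    if return_liability:
        return battery, pd.Series(liability, index=battery.index, name="liability")
    return battery


def ascertain_families(
    pedigree: pd.DataFrame,
    battery: pd.DataFrame,
    diagnoses: pd.Series,
    min_affected: int = 4,
) -> pd.DataFrame:
    """Keep whole families with at least ``min_affected`` migraine-affected members.

    Affected means an exclusive-ladder label in {mwoa, mwa, hm}. All members
    of a retained family are kept regardless of their own status, mirroring
    family-based recruitment of relatives.
    """
    if min_affected < 1:
        raise ValueError("min_affected must be >= 1")
    if len(battery) != len(pedigree):
        raise ValueError("battery and pedigree disagree on cohort size")
    labels = pd.Series(np.asarray(diagnoses), index=pedigree["individual_id"].to_numpy())
    affected = labels.isin(MIGRAINE_LABELS).to_numpy()
    counts = pd.Series(affected).groupby(pedigree["family_id"].to_numpy()).sum()
    keep_fams = set(counts.index[counts >= min_affected])
    return pedigree[pedigree["family_id"].isin(keep_fams)].reset_index(drop=True)
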
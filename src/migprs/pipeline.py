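"""End-to-end, configuration-driven analysis on a synthetic family cohort.

Runs the whole chain: simulate panel + summary statistics + pedigrees +
genotypes + symptom battery; diagnose with the ICHD-3 rule engine;
ascertain families on affected count; QC/harmonize/clump/threshold/score;
scale scores to a simulated population reference; LD-prune and build the
empirical GRM; and fit the mixed-model analysis surfaces: a
criteria-by-category percentage table, exclusive-ladder category means
contrasted to the no-headache group, per-criterion and per-symptom
univariate means with Holm adjustment, the symptom-count trend, aura
analyses among migraine-headache cases, and multivariable criterion and
aura models. Every emitted table carries the configuration hash and seed;
identical configurations reproduce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .diagnosis import CRITERIA_COLUMNS, HEADACHE_SYMPTOMS, AURA_COLUMNS, LADDER, diagnose
from .lmm import SpectralGRM, group_means, holm_bonferroni, multivariable_fit
from .relatedness import compute_grm, ld_prune
from .scoring import compute_prs, harmonize, ld_clump, p_threshold, qc_filter, scale_to_reference
from .simulate import (
    FamilyShape,
    LiabilityModel,
    ascertain_families,
    founder_population,
    generate_pedigrees,
    make_variant_panel,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_summary_stats,
)

__all__ = ["RunConfig", "run_full_pipeline", "summarize_criteria_by_category"]

UNIVARIATE_VARIABLES = CRITERIA_COLUMNS + HEADACHE_SYMPTOMS + ["osmophobia"]


@dataclass
class RunConfig:
    """All knobs of the synthetic-cohort analysis in one place."""

    seed: int = 0
    # cohort
    n_families: int = 600
    n_generations: int = 3
    mean_sibs: float = 2.5
    min_affected: int = 4
    # variant panel / GWAS
    n_variants: int = 2000
    n_blocks: int = 100
    n_chrom: int = 2
    gwas_n: int = 375_000
    ld_rho: float = 0.5
    missing_rate: float = 0.0
    # liability model
    prs_weight: float = 0.35
    symptom_noise_sd: float = 0.6
    family_env_sd: float = 0.0
    # scoring
    maf_min: float = 0.01
    missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    clump_r2: float = 0.1
    clump_window_kb: float = 500.0
    p_max: float = 0.05
    reference_n: int = 2000
    # GRM
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    # model
    reference_group: str = "no_headache"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def summarize_criteria_by_category(variables: pd.DataFrame, flags: pd.DataFrame, sex: pd.Series | None = None) -> pd.DataFrame:
    """Percentage of flagged individuals with each criterion/symptom true.

    ``variables`` holds boolean criterion/symptom columns, ``flags`` boolean
    (non-exclusive) diagnostic-category columns; ``sex`` (1=male, 2=female)
    enables the women/men split. Empty categories yield NaN (undefined), not
    zero. Returns a long table: category, variable, pct, pct_women, pct_men, n.
    """
    rows = []
    sex_arr = None if sex is None else np.asarray(sex)
    for cat in flags.columns:
        in_cat = flags[cat].to_numpy(dtype=bool)
        n_cat = int(in_cat.sum())
        for var in variables.columns:
            v = variables[var].to_numpy(dtype=bool)

            def pct(mask):
                return float(100.0 * v[mask].mean()) if mask.sum() else np.nan

            rows.append(
                {
                    "category": cat,
                    "variable": var,
                    "pct": pct(in_cat),
                    "pct_women": pct(in_cat & (sex_arr == 2)) if sex_arr is not None else np.nan,
                    "pct_men": pct(in_cat & (sex_arr == 1)) if sex_arr is not None else np.nan,
                    "n": n_cat,
                }
            )
    return pd.DataFrame(rows)


def _group_means_table(y, labels, spec, reference, order=None) -> pd.DataFrame:
    results = group_means(y, labels, spec, reference=reference, order=order)
    df = pd.DataFrame(
        [
            {
                "label": r.label, "n": r.n, "mean": r.mean, "se": r.se,
                "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                "diff_vs_ref": r.diff_vs_ref, "p": r.p_vs_ref,
            }
            for r in results
        ]
    )
    non_ref = df["label"] != reference
    p_holm = np.full(len(df), np.nan)
    if non_ref.any():
        p_holm[non_ref.to_numpy()] = holm_bonferroni(df.loc[non_ref, "p"].to_numpy())
    df["p_holm"] = p_holm
    return df


def _univariate_table(y, variables: pd.DataFrame, spec) -> pd.DataFrame:
    """Mean PRS among individuals with each indicator true, one LMM per row."""
    rows = []
    for var in variables.columns:
        v = variables[var].to_numpy(dtype=bool)
        if v.all() or not v.any():
            rows.append({"variable": var, "n_true": int(v.sum()), "mean_true": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "diff": np.nan, "p": np.nan})
            continue
        labels = pd.Series(np.where(v, "present", "absent"))
        res = group_means(y, labels, spec, reference="absent", order=["absent", "present"])
        present = res[1]
        rows.append(
            {
                "variable": var, "n_true": present.n, "mean_true": present.mean,
                "ci_low": present.ci95[0], "ci_high": present.ci95[1],
                "diff": present.diff_vs_ref, "p": present.p_vs_ref,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    p_holm = np.full(len(df), np.nan)
    if ok.any():
        p_holm[ok.to_numpy()] = holm_bonferroni(df.loc[ok, "p"].to_numpy())
    df["p_holm"] = p_holm
    return df


def _contrast_table(results) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"label": r.label, "beta": r.estimate, "se": r.se,
             "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p}
            for r in results
        ]
    )
    df["p_holm"] = holm_bonferroni(df["p"].to_numpy())
    return df


def run_full_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole synthetic analysis; return (and optionally write) the bundle."""
    seed = config.seed
    chash = config.config_hash()

    with _stage("simulate"):
        panel = make_variant_panel(config.n_variants, config.n_blocks, seed=seed, n_chrom=config.n_chrom)
        stats = simulate_summary_stats(panel, config.gwas_n, seed=seed + 1)
        pedigree = generate_pedigrees(
            config.n_families, FamilyShape(config.n_generations, config.mean_sibs), seed=seed + 2
        )
        genotypes = simulate_genotypes(pedigree, stats, seed=seed + 3, ld_rho=config.ld_rho,
                                       missing_rate=config.missing_rate)
        model = LiabilityModel(prs_weight=config.prs_weight, symptom_noise_sd=config.symptom_noise_sd,
                               family_env_sd=config.family_env_sd)
        battery = simulate_phenotypes(genotypes, stats, model, seed=seed + 4,
                                      family_ids=pedigree["family_id"].to_numpy())

    with _stage("diagnose"):
        dx = diagnose(battery)

    with _stage("ascertain"):
        kept_ped = ascertain_families(pedigree, battery, dx["label"], min_affected=config.min_affected)
        if kept_ped.empty:
            raise ValueError("no family satisfied the ascertainment rule")
        keep_ids = kept_ped["individual_id"].to_list()
        geno = genotypes.subset_individuals(keep_ids)
        battery_a = battery.loc[keep_ids]
        dx_a = dx.loc[keep_ids]

    with _stage("score"):
        founders = (kept_ped["father_id"] == "0").to_numpy()
        qc = qc_filter(geno, stats, config.maf_min, config.missing_max, config.hwe_p_min, founders=founders)
        weights = harmonize(stats, panel, qc=qc)
        weights = ld_clump(weights, geno, r2_max=config.clump_r2, window_kb=config.clump_window_kb)
        weights = p_threshold(weights, config.p_max)
        raw = compute_prs(geno, weights)
        reference = founder_population(config.reference_n, panel, seed=seed + 5, ld_rho=config.ld_rho)
        ref_raw = compute_prs(reference, weights)
        scores = scale_to_reference(raw, ref_raw["raw_score"])
        y = scores["scaled_score"].to_numpy()

    with _stage("grm"):
        pruned = ld_prune(geno, panel.reset_index(drop=True), config.prune_window, config.prune_step, config.prune_r2)
        # exclude the score's own variants (proximal contamination): with the
        # response being a weighted sum of dosages, a GRM whose span contains
        # all score variants makes the residual variance collapse to zero
        score_variants = set(weights.loc[weights["kept"], "variant_id"])
        grm_variants = np.array([v for v in pruned if v not in score_variants], dtype=object)
        if len(grm_variants) < 2:
            grm_variants = pruned
        grm = compute_grm(geno, grm_variants)
        spec = SpectralGRM.from_dense(grm.values)

    with _stage("fit"):
        crit_cols = dx_a[CRITERIA_COLUMNS]
        flag_cols = dx_a[["headache", "probable_migraine", "mwoa", "mwa", "hm"]]
        variables = pd.concat([crit_cols, battery_a[HEADACHE_SYMPTOMS + ["osmophobia"]]], axis=1)
        table2 = summarize_criteria_by_category(variables, flag_cols, sex=kept_ped["sex"])

        labels = dx_a["label"]
        present = [c for c in LADDER if (labels == c).any()]
        reference = config.reference_group if config.reference_group in present else present[0]
        category_means = _group_means_table(y, labels, spec, reference, order=present)

        univariate = _univariate_table(y, variables, spec)

        counts = dx_a["symptom_count"]
        count_labels = pd.Series([f"{c:02d}" for c in counts], index=counts.index)
        count_order = sorted(count_labels.unique())
        symptom_trend = _group_means_table(y, count_labels, spec, reference=count_order[0], order=count_order)

        mig = dx_a["mwoa"].to_numpy(dtype=bool)  # ICHD-3 migraine headache fulfilled
        rows_m = np.flatnonzero(mig)
        spec_m = SpectralGRM.from_dense(grm.values[np.ix_(rows_m, rows_m)])
        aura_univariate = _univariate_table(y[rows_m], battery_a.iloc[rows_m][AURA_COLUMNS], spec_m)

        multivariable_criteria = _contrast_table(
            multivariable_fit(y, dx_a[["A", "B", "C", "D1", "D2"]], spec)
        )
        multivariable_aura = _contrast_table(
            multivariable_fit(y[rows_m], battery_a.iloc[rows_m][AURA_COLUMNS], spec_m)
        )

    bundle = {
        "criteria_by_category": table2,
        "category_means": category_means,
        "univariate_means": univariate,
        "symptom_count_trend": symptom_trend,
        "aura_univariate": aura_univariate,
        "multivariable_criteria": multivariable_criteria,
        "multivariable_aura": multivariable_aura,
    }
    for tab in bundle.values():
        tab["config_hash"] = chash
        tab["seed"] = seed
    bundle["meta"] = {
        "config_hash": chash,
        "seed": seed,
        "n_simulated": len(pedigree),
        "n_ascertained": len(kept_ped),
        "n_families_ascertained": int(kept_ped["family_id"].nunique()),
        "n_variants_in_score": int(weights["kept"].sum()),
        "n_variants_grm": int(len(grm_variants)),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with _stage("write"):
            for name, tab in bundle.items():
                if name == "meta":
                    continue
                tab.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
            with open(out_dir / "meta.json", "w") as fh:
                json.dump(bundle["meta"], fh, indent=2, sort_keys=True)
            # intermediates, so any table can be regenerated in isolation
            mio.write_fam(kept_ped, out_dir / "cohort.fam")
            mio.write_table(scores.set_index("iid"), out_dir / "scores.tsv")
            mio.write_table(dx_a, out_dir / "diagnoses.tsv")
            mio.write_table(weights.set_index("variant_id"), out_dir / "harmonization.tsv")
            mio.write_grm(grm, out_dir / "cohort")
    return bundle
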
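"""C+T scoring: QC, harmonization, clumping, thresholding, scoring, scaling."""

import math

import numpy as np
import pandas as pd
import pytest

import migprs as M
from migprs.simulate import GenotypeMatrix

from conftest import random_genotypes


def hwe_exact_oracle(hom_ref, het, hom_alt):
    """Exact-rational HWE enumeration with integer combinatorics."""
    n = hom_ref + het + hom_alt
    n_alt = 2 * hom_alt + het
    n_minor = min(n_alt, 2 * n - n_alt)
    obs = min(het, n_minor)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        a = (n_minor - h) // 2
        b = n - h - a
        weights[h] = (math.factorial(n) * 2**h) // (
            math.factorial(a) * math.factorial(h) * math.factorial(b)
        )
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= weights[obs]) / total


def make_weights(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "aligned_beta", "p", "kept", "drop_reason"])


class TestHWE:
    @pytest.mark.parametrize(
        "counts", [(25, 50, 25), (10, 5, 1), (0, 10, 0), (50, 0, 50), (3, 7, 11), (100, 20, 1)]
    )
    def test_matches_exact_rational_oracle(self, counts):
        assert M.hwe_exact_p(*counts) == pytest.approx(hwe_exact_oracle(*counts), rel=1e-9)

    def test_hwe_proportions_give_p_one(self):
        # 25/50/25 puts the heterozygote count at the conditional mode
        assert M.hwe_exact_p(25, 50, 25) == pytest.approx(1.0)


class TestQC:
    def test_monomorphic_dropped(self):
        dosage = np.zeros((50, 1), dtype=np.int8)
        geno = GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool),
                              [f"i{i}" for i in range(50)], ["v0"])
        qc = M.qc_filter(geno, None, maf_min=0.01)
        assert not qc["kept"].iloc[0]

    def test_zero_missingness_passes_zero_threshold(self):
        rng = np.random.default_rng(0)
        geno, _ = random_genotypes(rng, 60, 3)
        qc = M.qc_filter(geno, None, maf_min=0.0, missing_max=0.0, hwe_p_min=0.0)
        assert qc["kept"].all()

    def test_hwe_kept_at_modal_configuration(self):
        dosage = np.repeat([0, 1, 2], [25, 50, 25]).astype(np.int8)[:, None]
        geno = GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool),
                              [f"i{i}" for i in range(100)], ["v0"])
        qc = M.qc_filter(geno, None, maf_min=0.0, missing_max=1.0, hwe_p_min=1e-6)
        assert qc["hwe_p"].iloc[0] == pytest.approx(1.0)
        assert qc["kept"].iloc[0]

    def test_threshold_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        geno, _ = random_genotypes(rng, 10, 2)
        with pytest.raises(ValueError):
            M.qc_filter(geno, None, maf_min=-0.1)


def _stats_row(vid, ea, oa, beta=0.2, p=1e-4):
    return {"variant_id": vid, "effect_allele": ea, "other_allele": oa,
            "beta_published": beta, "p_published": p}


def _panel_row(vid, ea, oa, chrom="1", pos=1000):
    return {"variant_id": vid, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa}


class TestHarmonize:
    @pytest.mark.parametrize(
        "stats_alleles, geno_alleles, expected_beta, expected_reason",
        [
            (("A", "G"), ("A", "G"), 0.2, "none"),       # identity
            (("A", "G"), ("G", "A"), -0.2, "none"),      # effect/other swap
            (("A", "G"), ("T", "C"), 0.2, "none"),       # strand flip
            (("A", "G"), ("C", "T"), -0.2, "none"),      # strand flip + swap
            (("A", "T"), ("A", "T"), None, "ambiguous"), # palindromic
            (("C", "G"), ("C", "G"), None, "ambiguous"),
            (("A", "G"), ("A", "C"), None, "mismatch"),
        ],
    )
    def test_allele_alignment(self, stats_alleles, geno_alleles, expected_beta, expected_reason):
        stats = pd.DataFrame([_stats_row("v0", *stats_alleles)])
        panel = pd.DataFrame([_panel_row("v0", *geno_alleles)])
        w = M.harmonize(stats, panel).iloc[0]
        if expected_beta is None:
            assert not w["kept"] and w["drop_reason"] == expected_reason
        else:
            assert w["kept"] and w["aligned_beta"] == pytest.approx(expected_beta)

    def test_duplicate_id_rejected(self):
        stats = pd.DataFrame([_stats_row("v0", "A", "G"), _stats_row("v0", "A", "G")])
        panel = pd.DataFrame([_panel_row("v0", "A", "G")])
        with pytest.raises(ValueError, match="v0"):
            M.harmonize(stats, panel)

    def test_swap_sign_rule_equals_manual_recoding(self):
        """Scoring swapped-allele stats equals recoding dosages d -> 2-d."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n, m = 20, 5
            geno, panel = random_genotypes(rng, n, m)
            panel = panel.assign(effect_allele="A", other_allele="G")
            betas = rng.normal(size=m)
            swap = rng.random(m) < 0.5
            stats = pd.DataFrame(
                [
                    _stats_row(f"v{j}", "G" if swap[j] else "A", "A" if swap[j] else "G",
                               beta=betas[j])
                    for j in range(m)
                ]
            )
            w = M.harmonize(stats, panel)
            score = M.compute_prs(geno, w)["raw_score"].to_numpy()
            # oracle: recode swapped variants' dosages (d -> 2-d) and score
            # with the published betas; differs only by a per-cohort constant
            d = geno.dosage.astype(float).copy()
            d[:, swap] = 2 - d[:, swap]
            expected = d @ betas
            offset = score - expected
            assert np.allclose(offset, offset[0])
            assert np.allclose(score - score.mean(), expected - expected.mean(), atol=1e-10)


class TestClump:
    def test_independent_variants_untouched(self):
        rng = np.random.default_rng(1)
        geno, panel = random_genotypes(rng, 200, 4)
        w = make_weights(
            [(f"v{j}", "1", (j + 1) * 1000, 0.1, 10 ** -(j + 2), True, "none") for j in range(4)]
        )
        out = M.ld_clump(w, geno, r2_max=0.99, window_kb=500)
        assert out["kept"].all()

    def test_perfect_ld_keeps_smaller_p(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        dosage = np.column_stack([col, col])
        geno = GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool),
                              [f"i{i}" for i in range(50)], ["a", "b"])
        w = make_weights([("a", "1", 1000, 0.1, 1e-4, True, "none"),
                          ("b", "1", 2000, 0.1, 1e-8, True, "none")])
        out = M.ld_clump(w, geno, r2_max=0.1, window_kb=500).set_index("variant_id")
        assert out.loc["b", "kept"] and not out.loc["a", "kept"]
        assert out.loc["a", "drop_reason"] == "clumped"

    def test_duplicating_kept_index_variant_leaves_score_unchanged(self):
        rng = np.random.default_rng(3)
        geno, panel = random_genotypes(rng, 100, 3)
        w = make_weights(
            [(f"v{j}", "1", (j + 1) * 1000, 0.2, 10 ** -(j + 3), True, "none") for j in range(3)]
        )
        base = M.p_threshold(M.ld_clump(w, geno, 0.2, 500), 1.0)
        s_base = M.compute_prs(geno, base)["raw_score"].to_numpy()
        # duplicate v0 (the best p) as v0dup in perfect LD, worse p
        dosage = np.column_stack([geno.dosage, geno.dosage[:, 0]])
        geno2 = GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool), geno.ids,
                               ["v0", "v1", "v2", "v0dup"])
        w2 = pd.concat([w, make_weights([("v0dup", "1", 1010, 0.2, 1e-2, True, "none")])],
                       ignore_index=True)
        dup = M.p_threshold(M.ld_clump(w2, geno2, 0.2, 500), 1.0)
        assert not dup.set_index("variant_id").loc["v0dup", "kept"]
        s_dup = M.compute_prs(geno2, dup)["raw_score"].to_numpy()
        assert np.allclose(s_base, s_dup)

    def test_invalid_r2_rejected(self):
        rng = np.random.default_rng(0)
        geno, _ = random_genotypes(rng, 10, 2)
        w = make_weights([("v0", "1", 1000, 0.1, 0.01, True, "none")])
        with pytest.raises(ValueError):
            M.ld_clump(w, geno, r2_max=0.0, window_kb=500)


class TestPThreshold:
    def test_pmax_one_is_identity(self):
        w = make_weights([("v0", "1", 1, 0.1, 0.4, True, "none"),
                          ("v1", "1", 2, 0.1, 0.9, True, "none")])
        assert M.p_threshold(w, 1.0)["kept"].all()

    def test_boundary_inclusive(self):
        w = make_weights([("v0", "1", 1, 0.1, 0.01, True, "none"),
                          ("v1", "1", 2, 0.1, 0.05, True, "none"),
                          ("v2", "1", 3, 0.1, 0.06, True, "none")])
        out = M.p_threshold(w, 0.05).set_index("variant_id")
        assert out.loc["v0", "kept"] and out.loc["v1", "kept"]
        assert not out.loc["v2", "kept"] and out.loc["v2", "drop_reason"] == "p_fail"

    def test_empty_in_empty_out(self):
        w = make_weights([("v0", "1", 1, 0.1, 0.5, False, "qc_fail")])
        assert not M.p_threshold(w, 0.05)["kept"].any()


class TestComputePRS:
    def test_zero_weights_zero_scores(self):
        rng = np.random.default_rng(0)
        geno, _ = random_genotypes(rng, 20, 3)
        w = make_weights([(f"v{j}", "1", j, 0.0, 0.01, True, "none") for j in range(3)])
        assert np.allclose(M.compute_prs(geno, w)["raw_score"], 0.0)

    def test_single_variant_identity(self):
        dosage = np.array([[0], [1], [2]], dtype=np.int8)
        geno = GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool), ["a", "b", "c"], ["v0"])
        w = make_weights([("v0", "1", 1, 1.0, 0.01, True, "none")])
        assert np.allclose(M.compute_prs(geno, w)["raw_score"], [0, 1, 2])

    def test_hand_computed_dot_product(self):
        dosage = np.array([[1, 2, 0]], dtype=np.int8)
        geno = GenotypeMatrix(dosage, np.zeros_like(dosage, dtype=bool), ["a"], ["v0", "v1", "v2"])
        w = make_weights([("v0", "1", 1, 0.1, 0.01, True, "none"),
                          ("v1", "1", 2, -0.2, 0.01, True, "none"),
                          ("v2", "1", 3, 0.3, 0.01, True, "none")])
        assert M.compute_prs(geno, w)["raw_score"].iloc[0] == pytest.approx(-0.3)

    def test_missing_dosage_mean_imputed(self):
        dosage = np.array([[2], [2], [0]], dtype=np.int8)
        missing = np.array([[False], [False], [True]])
        geno = GenotypeMatrix(np.where(missing, 0, dosage).astype(np.int8), missing,
                              ["a", "b", "c"], ["v0"])
        w = make_weights([("v0", "1", 1, 1.0, 0.01, True, "none")])
        scores = M.compute_prs(geno, w)["raw_score"]
        assert scores.iloc[2] == pytest.approx(2 * 1.0)  # 2 * freq(=1.0 among observed)

    def test_empty_score_rejected(self):
        rng = np.random.default_rng(0)
        geno, _ = random_genotypes(rng, 5, 1)
        w = make_weights([("v0", "1", 1, 0.1, 0.5, False, "p_fail")])
        with pytest.raises(ValueError, match="no variants"):
            M.compute_prs(geno, w)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        geno, _ = random_genotypes(rng, 30, 6)
        w = make_weights([(f"v{j}", "1", j, rng.normal(), 0.01, True, "none") for j in range(6)])
        s = M.compute_prs(geno, w).set_index("iid")["raw_score"]
        perm = rng.permutation(30)
        geno_p = GenotypeMatrix(geno.dosage[perm], geno.missing[perm], geno.ids[perm], geno.variant_ids)
        s_p = M.compute_prs(geno_p, w).set_index("iid")["raw_score"]
        pd.testing.assert_series_equal(s.sort_index(), s_p.sort_index())


class TestScaleToReference:
    def test_self_reference_standardizes(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"iid": range(500), "raw_score": rng.normal(2.0, 3.0, 500)})
        out = M.scale_to_reference(scores, scores["raw_score"])
        assert abs(out["scaled_score"].mean()) < 1e-10
        assert abs(out["scaled_score"].std(ddof=1) - 1) < 1e-10

    def test_two_point_reference_hand_values(self):
        scores = pd.DataFrame({"iid": ["a", "b"], "raw_score": [1.0, 2.0]})
        out = M.scale_to_reference(scores, [0.0, 2.0])
        assert out["scaled_score"].iloc[0] == pytest.approx(0.0)
        assert out["scaled_score"].iloc[1] == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=50)
        ref = rng.normal(size=100)
        a = M.scale_to_reference(pd.DataFrame({"iid": range(50), "raw_score": raw}), ref)
        b = M.scale_to_reference(pd.DataFrame({"iid": range(50), "raw_score": raw + 3.0}), ref)
        shift = 3.0 / np.std(ref, ddof=1)
        assert np.allclose(b["scaled_score"] - a["scaled_score"], shift)

    def test_constant_reference_rejected(self):
        scores = pd.DataFrame({"iid": ["a"], "raw_score": [1.0]})
        with pytest.raises(ValueError, match="reference variance"):
            M.scale_to_reference(scores, [1.0, 1.0, 1.0])


def test_true_weight_score_correlates_with_liability_at_sqrt_weight():
    """With noiseless (true-beta) weights, corr(PRS, liability) ~ sqrt(prs_weight)."""
    panel = M.make_variant_panel(400, 40, seed=44)
    pop = M.founder_population(10_000, panel, seed=45)
    w = 0.3
    _, liability = M.simulate_phenotypes(
        pop, panel, M.LiabilityModel(prs_weight=w), seed=46, return_liability=True
    )
    weights = pd.DataFrame(
        {"variant_id": panel["variant_id"], "chrom": panel["chrom"], "pos": panel["pos"],
         "aligned_beta": panel["beta_true"], "p": 1e-8, "kept": True, "drop_reason": "none"}
    )
    scores = M.scale_to_reference(M.compute_prs(pop, weights), M.compute_prs(pop, weights)["raw_score"])
    r = np.corrcoef(scores["scaled_score"], liability)[0, 1]
    assert abs(r - np.sqrt(w)) <= 0.05
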
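"""Lineage-aware screening: classification, variance tests, arm design, titer curves."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from clonotrace.screening import (
    CloneRecord,
    classify_lineages,
    design_arms,
    fdr_adjust,
    max_titer_curve,
    pairwise_difference_test,
    screen_phenotypes,
)
from clonotrace.simulate import simulate_phenotypes


def _clone(i, bc, titer=1.0):
    return CloneRecord(f"c{i}", bc, {"titer": titer})


def _sibling_cohort(barcodes):
    """Cohort from a barcode-per-clone list with simple phenotypes."""
    return [_clone(i, bc) for i, bc in enumerate(barcodes)]


class TestClassifyLineages:
    def test_basic_partition(self):
        groups = classify_lineages(_sibling_cohort(["X", "X", "X", "Y", "Z"]))
        assert set(groups.siblings) == {"X"}
        assert {c.barcode for c in groups.relatives} == {"Y", "Z"}

    def test_all_unique_no_siblings(self):
        groups = classify_lineages(_sibling_cohort(list("ABCDE")))
        assert not groups.siblings and len(groups.relatives) == 5

    def test_intermediate_multiplicity_in_neither_group(self):
        groups = classify_lineages(_sibling_cohort(["X", "X", "Y"]))
        assert not groups.siblings
        assert {c.barcode for c in groups.relatives} == {"Y"}

    def test_simulated_cohort_group_sizes_match_generator(self, rng):
        # 34 sibling clones in multiplicity->=3 lineages + 33 unique barcodes
        barcodes = (
            ["S1"] * 4 + ["S2"] * 3 + ["S3"] * 5 + ["S4"] * 3 + ["S5"] * 4
            + ["S6"] * 3 + ["S7"] * 4 + ["S8"] * 4 + ["S9"] * 4
            + [f"U{i}" for i in range(33)]
        )
        assert sum(c.startswith("S") for c in barcodes) == 34
        records = simulate_phenotypes(barcodes, seed=0)
        groups = classify_lineages(records)
        assert groups.n_sibling_clones == 34
        assert len(groups.relatives) == 33


class TestPairwiseDifferenceTest:
    def test_identical_siblings_spread_relatives(self, rng):
        cohort = [_clone(i, "S", titer=5.0) for i in range(6)]
        cohort += [_clone(10 + i, f"U{i}", titer=float(v)) for i, v in enumerate(rng.normal(5, 3, 12))]
        groups = classify_lineages(cohort)
        res = pairwise_difference_test(groups, "titer")
        assert res.sibling_mean_diff == 0.0
        assert res.relative_mean_diff > 0
        assert res.pvalue < 0.01

    def test_null_behavior_without_lineage_structure(self):
        # with zero between-lineage variance all values are iid, so sibling
        # and relative |differences| share one distribution; shared clones
        # make pairs dependent, which inflates the rank-sum type-I rate
        # above alpha, so only approximate calibration is checked here
        rejections = 0
        ratios = []
        n_rep = 200
        for seed in range(n_rep):
            barcodes = ["S1"] * 5 + ["S2"] * 5 + [f"U{i}" for i in range(10)]
            records = simulate_phenotypes(
                barcodes, phenotypes={"titer": (100.0, 0.0, 10.0)}, seed=seed
            )
            res = pairwise_difference_test(classify_lineages(records), "titer")
            rejections += res.pvalue < 0.05
            ratios.append(res.sibling_mean_diff / res.relative_mean_diff)
        assert rejections / n_rep < 0.35
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_power_with_lineage_structure(self):
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            barcodes = [f"S{i // 4}" for i in range(36)] + [f"U{i}" for i in range(33)]
            records = simulate_phenotypes(
                barcodes, phenotypes={"titer": (2000.0, 400.0, 80.0)}, seed=seed
            )
            res = pairwise_difference_test(classify_lineages(records), "titer")
            hits += res.pvalue < 0.05
        assert hits / n_rep >= 0.9

    def test_degenerate_sets_error(self):
        groups = classify_lineages(_sibling_cohort(["X", "X", "X", "Y"]))
        with pytest.raises(ValueError, match="titer"):
            pairwise_difference_test(groups, "titer")


class TestFdrAdjust:
    def test_hand_evaluated_bh(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels_and_preserves_order(self, rng):
        p = rng.uniform(size=30)
        out = fdr_adjust(p)
        assert np.allclose(out, multipletests(p, method="fdr_bh")[1])
        assert np.all(out >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-15)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_screen_phenotypes_adds_qvalues(self):
        barcodes = [f"S{i // 4}" for i in range(24)] + [f"U{i}" for i in range(20)]
        records = simulate_phenotypes(
            barcodes,
            phenotypes={
                "titer": (2000.0, 400.0, 80.0),
                "vcd": (10.0, 2.0, 0.5),
                "glutamate": (1.0, 0.0, 0.3),
            },
            seed=1,
        )
        df = screen_phenotypes(classify_lineages(records), ["titer", "vcd", "glutamate"])
        assert list(df["phenotype"]) == ["titer", "vcd", "glutamate"]
        assert (df["qvalue"] >= df["pvalue"] - 1e-15).all()


class TestDesignArms:
    def _cohort(self):
        barcodes = [f"S{i % 15}" for i in range(60)] + [f"U{i}" for i in range(48)]
        return simulate_phenotypes(barcodes, seed=3)

    def test_arm_structure(self):
        arms = design_arms(self._cohort(), arm_size=48, n_lineages_depletion=15, seed=0)
        assert len(arms.enrichment) == 48 and arms.enrichment_barcodes == 48
        assert len(arms.depletion) == 48 and arms.depletion_barcodes == 15

    def test_reproducible_under_seed(self):
        cohort = self._cohort()
        a = design_arms(cohort, seed=42)
        b = design_arms(cohort, seed=42)
        assert [c.clone_id for c in a.enrichment] == [c.clone_id for c in b.enrichment]
        assert [c.clone_id for c in a.depletion] == [c.clone_id for c in b.depletion]

    def test_trivial_arm_size_one(self):
        arms = design_arms(self._cohort(), arm_size=1, n_lineages_depletion=1, seed=0)
        assert len(arms.enrichment) == 1 and len(arms.depletion) == 1

    def test_infeasible_cohort_errors(self):
        cohort = simulate_phenotypes([f"U{i}" for i in range(10)], seed=0)
        with pytest.raises(ValueError, match="enrichment"):
            design_arms(cohort, arm_size=48)


class TestMaxTiterCurve:
    def test_full_depth_is_global_max(self, rng):
        titers = rng.normal(2000, 300, size=60)
        df = max_titer_curve(titers, depths=[len(titers)], replicates=3, seed=0)
        assert df["max_titer_mean"].iloc[0] == pytest.approx(titers.max())
        assert df["max_titer_sd"].iloc[0] == 0.0

    def test_constant_titers(self):
        df = max_titer_curve([7.0] * 20, depths=[1, 5, 20], replicates=3, seed=0)
        assert np.allclose(df["max_titer_mean"], 7.0)

    def test_mean_max_monotone_in_depth(self, rng):
        titers = rng.normal(100, 20, size=96)
        df = max_titer_curve(titers, depths=[2, 8, 24, 48, 96], replicates=200, seed=1)
        means = df["max_titer_mean"].to_numpy()
        assert np.all(np.diff(means) >= -1e-9)

    def test_enrichment_arm_outscreens_depletion_arm(self):
        # between-lineage variance >> within: at every screening depth the
        # diverse arm's expected maximum titer is at least the depleted arm's,
        # so the top producer is found with fewer screened clones
        barcodes = [f"S{i % 15}" for i in range(80)] + [f"U{i}" for i in range(55)]
        cohort = simulate_phenotypes(
            barcodes, phenotypes={"titer": (2000.0, 400.0, 40.0)}, seed=5
        )
        arms = design_arms(cohort, arm_size=48, n_lineages_depletion=15, seed=5)
        t_enr = [c.phenotypes["titer"] for c in arms.enrichment]
        t_dep = [c.phenotypes["titer"] for c in arms.depletion]
        depths = [4, 8, 16, 32, 48]
        df_e = max_titer_curve(t_enr, depths, replicates=500, seed=7)
        df_d = max_titer_curve(t_dep, depths, replicates=500, seed=8)
        assert (df_e["max_titer_mean"].to_numpy() >= df_d["max_titer_mean"].to_numpy() - 1e-9).all()
        # the diverse arm reaches the depleted arm's plateau at shallow depth
        assert df_e["max_titer_mean"].iloc[1] >= max(t_dep)

    def test_depth_too_large_errors(self):
        with pytest.raises(ValueError):
            max_titer_curve([1.0, 2.0], depths=[5])
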
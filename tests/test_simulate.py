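"""Synthetic-data generator: library, founding, passaging, dilution, reads."""

import math

import numpy as np
import pytest

from clonotrace.calling import call_genuine
from clonotrace.design import BarcodeSpec
from clonotrace.diversity import diversity_trajectory
from clonotrace.reads import FLANKS, CountTable, count_barcodes, count_merged
from clonotrace.simulate import (
    SimConfig,
    SimPool,
    random_barcodes,
    simulate_library,
    simulate_limited_dilution,
    simulate_merged_reads,
    simulate_passaging,
    simulate_phenotypes,
    simulate_pool_founding,
    simulate_read_pairs,
)


class TestSimulateLibrary:
    def test_zero_skew_equal_abundances(self):
        lib = simulate_library(BarcodeSpec(), 100, skew=0.0, seed=0)
        assert len(set(lib.entries.values())) == 1
        assert len(lib) == 100

    def test_capacity_bound(self):
        spec = BarcodeSpec(random_length=3, meta_length=0)
        lib = simulate_library(spec, 64, seed=0)
        assert len(lib) == 64
        with pytest.raises(ValueError):
            simulate_library(spec, 65, seed=0)

    def test_dispersion_recovery(self):
        lib = simulate_library(BarcodeSpec(), 10_000, skew=0.4, seed=1)
        counts = np.array(list(lib.entries.values()), dtype=float)
        cv = counts.std() / counts.mean()
        assert cv == pytest.approx(0.4, rel=0.05)

    def test_reproducible(self):
        a = simulate_library(BarcodeSpec(), 500, skew=0.3, seed=9)
        b = simulate_library(BarcodeSpec(), 500, skew=0.3, seed=9)
        assert a.entries == b.entries


class TestPoolFounding:
    def test_zero_rmce_rate_empty_pool(self):
        lib = simulate_library(BarcodeSpec(), 100, seed=0)
        pool = simulate_pool_founding(lib, SimConfig(rmce_rate=0.0), seed=0)
        assert not pool.abundances

    def test_founder_count_distribution(self):
        lib = simulate_library(BarcodeSpec(), 200_000, seed=0)
        cfg = SimConfig(n_transfected=1_000_000, rmce_rate=2e-3, selection_survival=0.3)
        totals = [
            simulate_pool_founding(lib, cfg, seed=s).total for s in range(5)
        ]
        expected = cfg.n_transfected * cfg.rmce_rate * cfg.selection_survival
        assert np.mean(totals) == pytest.approx(expected, rel=0.05)

    def test_single_barcode_library_all_collide(self):
        lib = simulate_library(BarcodeSpec(), 1, seed=0)
        pool = simulate_pool_founding(lib, SimConfig(n_transfected=10_000, rmce_rate=0.1), seed=1)
        assert pool.collision_fraction > 0.995


class TestPassaging:
    def _pool(self, rng, n=200, sd=0.0):
        barcodes = random_barcodes(n, 15, rng)
        rates = rng.normal(0.69, sd, size=n).clip(min=0)
        return SimPool(
            abundances={b: 1000.0 for b in barcodes},
            growth_rates=dict(zip(barcodes, rates)),
        )

    def test_neutral_control_flat_relative_abundances(self, rng):
        pool = self._pool(rng, sd=0.0)
        cfg = SimConfig(growth_rate_sd=0.0, passage_bottleneck=10**18)
        ts = simulate_passaging(pool, days=28, cfg=cfg, timepoints=[0, 14, 28], seed=0)
        first = ts.tables[0]
        last = ts.tables[-1]
        f0 = np.array([first.counts[b] for b in sorted(first.counts)]) / first.total
        f1 = np.array([last.counts.get(b, 0) for b in sorted(first.counts)]) / last.total
        assert np.allclose(f0, f1, atol=1e-6)

    def test_growth_variance_skews_pool(self, rng):
        pool = self._pool(rng, sd=0.08)
        cfg = SimConfig(passage_bottleneck=100_000)
        ts = simulate_passaging(pool, days=80, cfg=cfg, timepoints=[0, 40, 80], seed=1)
        tops = []
        for table in ts.tables:
            tops.append(max(table.counts.values()) / table.total)
        assert tops[0] < tops[1] < tops[2]

    def test_eighty_day_diversity_loss(self, rng):
        # aggressive skewing run: the pool loses most of its variants in 80 days
        pool = self._pool(rng, n=1000, sd=0.08)
        cfg = SimConfig(passage_bottleneck=50_000)
        ts = simulate_passaging(pool, days=80, cfg=cfg, timepoints=[0, 80], seed=2)
        retained = len(ts.tables[-1].counts) / len(ts.tables[0].counts)
        assert retained <= 0.5

    def test_trajectory_metrics_from_simulated_series(self, rng):
        pool = self._pool(rng, n=100, sd=0.05)
        cfg = SimConfig(passage_bottleneck=100_000)
        ts = simulate_passaging(pool, days=40, cfg=cfg, timepoints=[0, 20, 40], seed=3)
        traj = diversity_trajectory(ts)
        assert all(0 <= p.retention <= 1.0 + 1e-9 for p in traj)
        assert traj[0].retention == 1.0


class TestLimitedDilution:
    def test_empty_well_fraction(self):
        pool = SimPool(abundances={"A" * 15: 1.0}, growth_rates={})
        wells = simulate_limited_dilution(pool, lam=0.6, a=0.5, n_wells=50_000, seed=0)
        frac_empty = np.mean([w.k == 0 for w in wells])
        assert frac_empty == pytest.approx(math.exp(-0.6), abs=0.01)

    def test_growth_fraction_matches_analytic_identity(self):
        # under the single-survivor model W/N = sum_k P(k) G_k = analytic value
        from clonotrace.clonality import growth_probability, poisson_pmf

        pool = SimPool(abundances={"A" * 15: 1.0, "C" * 15: 2.0}, growth_rates={})
        lam, a = 0.6, 0.372
        wells = simulate_limited_dilution(pool, lam, a, 100_000, seed=1)
        observed = np.mean([w.grew for w in wells])
        expected = sum(poisson_pmf(k, lam) * growth_probability(k, a) for k in range(1, 30))
        assert observed == pytest.approx(expected, abs=0.005)

    def test_both_grow_variant_matches_occupancy_identity(self):
        pool = SimPool(abundances={"A" * 15: 1.0}, growth_rates={})
        lam, a = 0.6, 0.372
        wells = simulate_limited_dilution(pool, lam, a, 100_000, seed=2, both_grow=True)
        observed = np.mean([w.grew for w in wells])
        assert observed == pytest.approx(1 - math.exp(-lam * a), abs=0.005)

    def test_grown_wells_have_single_founder(self):
        pool = SimPool(abundances={"A" * 15: 1.0, "C" * 15: 1.0}, growth_rates={})
        wells = simulate_limited_dilution(pool, 1.5, 0.4, 5000, seed=3)
        assert all(len(w.founders) == 1 for w in wells if w.grew)


class TestReads:
    def test_error_free_round_trip(self, rng):
        barcodes = random_barcodes(10, 15, rng)
        truth = {b: int(c) for b, c in zip(barcodes, rng.integers(10, 100, 10))}
        n = sum(truth.values())
        seqs = simulate_merged_reads(
            {b: c for b, c in truth.items()}, n, FLANKS["M1"], error_rate=0.0, seed=4
        )
        table, rej = count_merged(seqs.items(), FLANKS["M1"])
        assert rej.total == 0
        # multinomial sampling: totals match, support is the truth set
        assert set(table.counts) <= set(truth)
        assert table.total == n

    def test_fixed_seed_byte_identical(self):
        fr = {"ACGTACGTACGTACG": 3, "TTTTACGTACGTACG": 1}
        a = simulate_merged_reads(fr, 10_000, FLANKS["M2"], 1e-3, seed=7)
        b = simulate_merged_reads(fr, 10_000, FLANKS["M2"], 1e-3, seed=7)
        assert a == b
        pairs_a = list(simulate_read_pairs(CountTable(counts=fr), FLANKS["M2"], SimConfig(), n_reads=50, seed=7))
        pairs_b = list(simulate_read_pairs(CountTable(counts=fr), FLANKS["M2"], SimConfig(), n_reads=50, seed=7))
        assert [(p.forward_seq, p.reverse_seq) for p in pairs_a] == [
            (p.forward_seq, p.reverse_seq) for p in pairs_b
        ]

    def test_pair_pipeline_monoclonal_call(self, rng):
        barcode = random_barcodes(1, 15, rng)[0]
        cfg = SimConfig(error_rate=1e-3)
        pairs = simulate_read_pairs(
            CountTable(counts={barcode: 1}), FLANKS["M3"], cfg, n_reads=20_000, seed=5
        )
        table, _ = count_barcodes(pairs, FLANKS["M3"])
        res = call_genuine(table)
        assert res.genuine == {barcode}

    def test_minor_clone_survives_knee_filter(self, rng):
        barcodes = random_barcodes(2, 15, rng)
        seqs = simulate_merged_reads(
            {barcodes[0]: 1000, barcodes[1]: 1}, 1_000_000, FLANKS["M1"], 1e-3, seed=6
        )
        table, _ = count_merged(seqs.items(), FLANKS["M1"])
        res = call_genuine(table)
        assert barcodes[1] in res.genuine


class TestPhenotypes:
    def test_zero_within_sd_siblings_identical(self):
        records = simulate_phenotypes(
            ["X", "X", "X", "Y"], phenotypes={"titer": (100.0, 10.0, 0.0)}, seed=0
        )
        sib = [r.phenotypes["titer"] for r in records if r.barcode == "X"]
        assert len(set(sib)) == 1

    def test_lineage_structure_variances(self):
        records = simulate_phenotypes(
            [f"L{i // 20}" for i in range(400)],
            phenotypes={"titer": (0.0, 5.0, 1.0)},
            seed=1,
        )
        import pandas as pd

        df = pd.DataFrame(
            {"bc": [r.barcode for r in records], "v": [r.phenotypes["titer"] for r in records]}
        )
        within = df.groupby("bc")["v"].std(ddof=1).mean()
        between = df.groupby("bc")["v"].mean().std(ddof=1)
        assert within == pytest.approx(1.0, rel=0.25)
        assert between == pytest.approx(5.0, rel=0.4)
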
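import json

import numpy as np
import pytest

from erosure.diversity import fst_windows
from erosure.io_formats import Impact, SampleSheet, parse_impact, read_genotypes
from erosure.simulate import (
    ROHPlan,
    SimConfig,
    plant_roh,
    simulate_cohorts,
    write_fixture,
)


class TestSimulateCohorts:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_sites=2000, seed=11)
        gm1, t1 = simulate_cohorts(cfg)
        gm2, t2 = simulate_cohorts(SimConfig(n_sites=2000, seed=11))
        np.testing.assert_array_equal(gm1.genotypes, gm2.genotypes)
        np.testing.assert_array_equal(gm1.pos, gm2.pos)
        np.testing.assert_array_equal(gm1.impact, gm2.impact)
        np.testing.assert_array_equal(t1.ancestral_freq, t2.ancestral_freq)
        gm3, _ = simulate_cohorts(SimConfig(n_sites=2000, seed=12))
        assert not np.array_equal(gm1.genotypes, gm3.genotypes)

    def test_invalid_proportions_error(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(impact_mix={"SYNONYMOUS": 0.5, "OTHER": 0.2})

    def test_invalid_divergence_error(self):
        with pytest.raises(ValueError, match="divergence"):
            SimConfig(divergence_f=1.0)

    def test_no_divergence_fst_near_zero(self):
        cfg = SimConfig(n_pops=2, n_diploids=15, n_sites=20_000, divergence_f=0.0, seed=3)
        gm, _ = simulate_cohorts(cfg)
        est = fst_windows(gm, "North", "South", 50_000, 50_000).genome_wide()
        assert abs(est) <= 0.01

    def test_expected_heterozygosity_matches_model(self):
        """Observed het-call fraction tracks 2p(1-p) within 3 Monte-Carlo SE."""
        cfg = SimConfig(n_pops=1, n_diploids=20, n_sites=20_000, divergence_f=0.0, seed=4)
        gm, truth = simulate_cohorts(cfg)
        p = truth.pop_freq_t1["North"]
        expected = 2 * p * (1 - p)
        n_calls = gm.n_samples * gm.n_sites
        obs = (gm.genotypes == 1).mean()
        se = np.sqrt(np.sum(expected * (1 - expected)) * gm.n_samples) / n_calls
        assert abs(obs - expected.mean()) <= 3 * se

    def test_programmed_het_change_applied(self):
        cfg = SimConfig(
            n_pops=1, n_diploids=10, n_sites=30_000, divergence_f=0.0,
            two_time_points=True, years_between=40, annual_het_change_pct=-0.5, seed=5,
        )
        gm, truth = simulate_cohorts(cfg)
        p1, p2 = truth.pop_freq_t1["North"], truth.pop_freq_t2["North"]
        h1, h2 = (2 * p1 * (1 - p1)).mean(), (2 * p2 * (1 - p2)).mean()
        assert h2 / h1 == pytest.approx(0.8, rel=1e-6)

    def test_drift_moves_frequencies(self):
        cfg = SimConfig(
            n_pops=1, n_diploids=5, n_sites=5000, divergence_f=0.0,
            two_time_points=True, years_between=70, drift_ne=100, seed=6,
        )
        gm, truth = simulate_cohorts(cfg)
        d = truth.pop_freq_t2["North"] - truth.pop_freq_t1["North"]
        assert d.std() > 0
        # drift variance ~ p(1-p) g / (2Ne) with g = 10 generations
        p = truth.pop_freq_t1["North"]
        expected_sd = np.sqrt((p * (1 - p) * 10 / 200).mean())
        assert d.std() == pytest.approx(expected_sd, rel=0.1)


class TestPlantRoh:
    def test_zero_target_unchanged(self):
        gm, truth = simulate_cohorts(SimConfig(n_sites=1000, seed=7))
        gm2, tracts = plant_roh(gm, ROHPlan(target_fraction=0.0), seed=1)
        np.testing.assert_array_equal(gm.genotypes, gm2.genotypes)
        assert tracts.empty

    def test_fraction_bookkeeping(self):
        gm, truth = simulate_cohorts(
            SimConfig(n_pops=1, n_diploids=3, n_sites=5000, n_chroms=2,
                      chrom_length_bp=50_000_000, seed=8)
        )
        plan = ROHPlan(target_fraction=0.02, tract_min_mb=0.5, tract_mean_mb=2.0)
        gm2, tracts = plant_roh(gm, plan, seed=2, chrom_lengths=truth.chrom_lengths)
        genome = sum(truth.chrom_lengths.values())
        for sid in gm.sample_ids:
            t = tracts[tracts.sample_id == sid]
            frac = (t.end - t.start + 1).sum() / genome
            assert frac == pytest.approx(0.02, rel=0.10)

    def test_tracts_are_homozygous(self):
        gm, truth = simulate_cohorts(
            SimConfig(n_pops=1, n_diploids=2, n_sites=20_000, n_chroms=2,
                      chrom_length_bp=10_000_000, seed=9)
        )
        gm2, tracts = plant_roh(
            gm, ROHPlan(target_fraction=0.2), seed=3, chrom_lengths=truth.chrom_lengths
        )
        for row in tracts.itertuples():
            i = gm.sample_ids.index(row.sample_id)
            inside = (gm2.chrom == row.chrom) & (gm2.pos >= row.start) & (gm2.pos <= row.end)
            assert not (gm2.genotypes[i, inside] == 1).any()

    def test_infeasible_fraction_errors(self):
        with pytest.raises(ValueError):
            ROHPlan(target_fraction=0.95)


class TestWriteFixture:
    def test_round_trip_and_truth_schema(self, tmp_path):
        cfg = SimConfig(n_pops=2, n_diploids=3, n_sites=800, n_chroms=2,
                        chrom_length_bp=2_000_000, divergence_f=0.05, seed=10)
        gm, truth = simulate_cohorts(cfg)
        paths = write_fixture(gm, truth, tmp_path)
        gm2 = read_genotypes(paths["vcf"], SampleSheet.read_tsv(paths["samples"]))
        np.testing.assert_array_equal(gm2.genotypes, gm.genotypes)
        np.testing.assert_array_equal(gm2.impact, gm.impact)
        # ANN strings parse back to the assigned categories
        assert all(
            parse_impact(f"T|{term}|x|g") == Impact[name]
            for term, name in [
                ("stop_gained", "HIGH"),
                ("missense_variant", "MODERATE"),
                ("synonymous_variant", "SYNONYMOUS"),
            ]
        )
        payload = json.loads(paths["truth"].read_text())
        for key in ("seed", "chrom_lengths", "ancestral_freq", "pop_freq_t1", "impacts"):
            assert key in payload
        assert len(payload["impacts"]) == gm.n_sites
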
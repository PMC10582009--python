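import numpy as np
import pytest

from erosure.io_formats import Impact
from erosure.load import (
    load_counts,
    normalized_total_load,
    realised_load,
    rxy,
)
from erosure.simulate import SimConfig, simulate_cohorts
from conftest import make_gm

H, M, S = int(Impact.HIGH), int(Impact.MODERATE), int(Impact.SYNONYMOUS)


def _annotated_gm(genotypes, impact, **kw):
    return make_gm(genotypes, impact=np.asarray(impact, dtype=np.int8), **kw)


class TestLoadCounts:
    def test_hand_counted_high_sites(self):
        # 4 HIGH sites; sample 0 carries derived alleles at two of them
        g = np.array([[1, 0, 2, 0, 1], [0, 1, 1, 1, 0]])
        gm = _annotated_gm(g, [H, H, H, H, S])
        counts = load_counts(gm)
        assert counts.loc["s0", "HIGH"] == 2
        assert counts.loc["s1", "HIGH"] == 3

    def test_fixed_derived_site_excluded(self):
        g = np.array([[2, 1], [2, 0]])  # site 0 hom-derived in everyone
        counts = load_counts(_annotated_gm(g, [H, H]))
        assert counts["HIGH"].tolist() == [1, 0]

    def test_sample_without_derived_alleles(self):
        g = np.array([[0, 0, 0], [1, 2, 1]])
        counts = load_counts(_annotated_gm(g, [H, M, S]))
        assert counts.loc["s0"].tolist() == [0, 0, 0]

    def test_orientation_respected(self):
        # at a ref-derived site, hom-REF carries two derived alleles
        g = np.array([[0], [2]])
        gm = _annotated_gm(g, [H], ancestral_is_ref=[False])
        counts = load_counts(gm)
        assert counts["HIGH"].tolist() == [1, 0]

    def test_allele_count_mode(self):
        g = np.array([[2, 1], [0, 0]])
        counts = load_counts(_annotated_gm(g, [H, H]), mode="alleles")
        assert counts.loc["s0", "HIGH"] == 3

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.choice([0, 1, 2], size=(5, 40)).astype(np.int8)
        imp = rng.choice([H, M, S], size=40)
        gm = _annotated_gm(g, imp)
        perm = rng.permutation(5)
        shuffled = gm.take_samples(perm)
        a = load_counts(gm).sort_index()
        b = load_counts(shuffled).sort_index()
        assert (a == b).all().all()

    def test_unannotated_only_errors(self):
        with pytest.raises(ValueError, match="annotated"):
            load_counts(make_gm([[0, 1]]))


class TestNormalizedTotal:
    def test_direct_ratios(self):
        import pandas as pd

        counts = pd.DataFrame(
            {"HIGH": [10, 0, 7], "MODERATE": [0, 0, 41], "SYNONYMOUS": [1000, 5, 350]},
            index=["a", "b", "c"],
        )
        norm = normalized_total_load(counts)
        assert norm.loc["a", "HIGH_per_syn"] == pytest.approx(0.01)
        assert norm.loc["b", "HIGH_per_syn"] == 0.0
        assert norm.loc["c", "HIGH_per_syn"] == pytest.approx(0.02)
        assert norm.loc["c", "MODERATE_per_syn"] == pytest.approx(41 / 350)

    def test_zero_synonymous_flagged_missing(self):
        import pandas as pd

        counts = pd.DataFrame({"HIGH": [3], "MODERATE": [1], "SYNONYMOUS": [0]})
        assert normalized_total_load(counts).isna().all().all()


class TestRealisedLoad:
    def test_direct_substitution(self):
        # 10 segregating HIGH sites; sample 0 homozygous-derived at 3
        g = np.vstack([
            np.array([2, 2, 2, 1, 1, 0, 0, 0, 1, 0]),
            np.array([0, 1, 0, 1, 0, 1, 1, 1, 0, 1]),
        ])
        r = realised_load(_annotated_gm(g, [H] * 10), Impact.HIGH)
        assert r.loc["s0"] == pytest.approx(3 / 20)

    def test_all_heterozygous_is_zero(self):
        g = np.array([[1, 1], [0, 1]])
        assert realised_load(_annotated_gm(g, [H, H]), Impact.HIGH).loc["s0"] == 0.0

    def test_maximum_is_half(self):
        g = np.array([[2, 2], [0, 1]])  # s0 hom-derived at every segregating site
        r = realised_load(_annotated_gm(g, [H, H]), Impact.HIGH)
        assert r.loc["s0"] == 0.5

    def test_no_segregating_sites_errors(self):
        g = np.array([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="HIGH"):
            realised_load(_annotated_gm(g, [H, H]), Impact.HIGH)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_exceeds_half(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.choice([0, 1, 2], size=(6, 50)).astype(np.int8)
        r = realised_load(_annotated_gm(g, [H] * 50), Impact.HIGH)
        assert (r <= 0.5 + 1e-12).all()


def _two_pop_fixture(seed=0, n_sites=400, shift=None):
    cfg = SimConfig(
        n_pops=2,
        n_diploids=8,
        n_sites=n_sites,
        n_chroms=4,
        divergence_f=0.05,
        category_freq_multiplier=shift,
        seed=seed,
    )
    gm, _ = simulate_cohorts(cfg)
    return gm


class TestRxy:
    def test_equal_frequencies_give_unity(self):
        # identical genotypes in both populations at every site
        rng = np.random.default_rng(1)
        g = rng.choice([0, 1, 2], size=(4, 60)).astype(np.int8)
        gm = _annotated_gm(
            np.vstack([g, g]),
            rng.choice([H, S], size=60),
            populations=["X"] * 4 + ["Y"] * 4,
            chrom=np.repeat([f"chr{i}" for i in range(4)], 15),
            pos=np.tile(np.arange(1, 16) * 100, 4),
        )
        res = rxy(gm, "X", "Y", Impact.HIGH)
        assert res.ratio == pytest.approx(1.0, abs=1e-12)
        assert res.ci_low <= res.ratio <= res.ci_high

    def test_reciprocity(self):
        gm = _two_pop_fixture(seed=5)
        a = rxy(gm, "North", "South", Impact.HIGH, blocks=8)
        b = rxy(gm, "South", "North", Impact.HIGH, blocks=8)
        assert a.ratio * b.ratio == pytest.approx(1.0, abs=1e-9)

    def test_four_site_fixture_brute_force(self):
        # category/neutral sites interleaved so every block holds both;
        # expected ratio recomputed by independent spreadsheet-style sums
        def freqs_to_genotypes(freqs):
            # 2 diploids: frequency f realised as allele dosages over 4 alleles
            return np.array(
                [[round(4 * f) // 2 for f in freqs],
                 [round(4 * f) - round(4 * f) // 2 for f in freqs]]
            )

        # interleaved [cat, neu] per chromosome; category doubled in X
        gx = freqs_to_genotypes([0.50, 0.25, 0.50, 0.25, 0.50, 0.50, 0.50, 0.50])
        gy = freqs_to_genotypes([0.25, 0.25, 0.25, 0.25, 0.25, 0.50, 0.25, 0.50])
        gm = _annotated_gm(
            np.vstack([gx, gy]),
            [H, S, H, S, H, S, H, S],
            populations=["X", "X", "Y", "Y"],
            chrom=np.repeat(["c1", "c2", "c3", "c4"], 2),
            pos=np.tile([100, 200], 4),
        )
        # recompute the target ratio by direct summation from realised counts
        def f(pop, cols):
            rows = gm.sample_index(population=pop)
            sub = gm.genotypes[np.ix_(rows, cols)]
            return sub.sum(axis=0) / (2.0 * len(rows))

        cat_cols, neu_cols = np.arange(0, 8, 2), np.arange(1, 8, 2)
        fx_c, fy_c = f("X", cat_cols), f("Y", cat_cols)
        fx_n, fy_n = f("X", neu_cols), f("Y", neu_cols)
        expected = (
            np.sum(fx_c * (1 - fy_c)) / np.sum(fy_c * (1 - fx_c))
        ) / (np.sum(fx_n * (1 - fy_n)) / np.sum(fy_n * (1 - fx_n)))
        res = rxy(gm, "X", "Y", Impact.HIGH)
        assert res.ratio == pytest.approx(expected, abs=1e-12)
        assert res.ratio > 1  # category frequencies elevated in X

    def test_too_few_blocks_errors(self):
        g = np.array([[1, 1], [1, 1]])
        gm = _annotated_gm(g, [H, S], populations=["X", "Y"])
        with pytest.raises(ValueError, match="blocks"):
            rxy(gm, "X", "Y", Impact.HIGH)

    def test_jackknife_interval_covers_unity_without_shift(self):
        """With no category-specific frequency shift the 95% interval
        contains 1 in at least 90% of seeded replicates."""
        hits = 0
        n = 100
        for seed in range(n):
            cfg = SimConfig(
                n_pops=2, n_diploids=10, n_sites=3000, n_chroms=4,
                divergence_f=0.05, seed=10_000 + seed,
            )
            gm, _ = simulate_cohorts(cfg)
            res = rxy(gm, "North", "South", Impact.HIGH, blocks=20)
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits >= 90

    def test_detects_planted_excess(self):
        gm = _two_pop_fixture(
            seed=9, n_sites=4000, shift={"HIGH": (1.6, 1.0)}
        )
        res = rxy(gm, "North", "South", Impact.HIGH, blocks=20)
        assert res.ratio > 1.1
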
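import numpy as np
import pytest

from epioverlap import (
    GenomeAssembly,
    multiway_colocalization_test,
    permutation_overlap_test,
    randomize_sites,
    shuffle_sites,
)
from conftest import make_set, random_interval_set


@pytest.fixture(scope="module")
def perm_assembly():
    return GenomeAssembly([(f"chr{i + 1}", 5_000_000) for i in range(4)])


class TestRandomizeSites:
    def test_zero_sites(self, perm_assembly):
        rng = np.random.default_rng(0)
        assert len(randomize_sites(0, 1_000, perm_assembly, rng)) == 0

    def test_forced_placement_on_exact_fit_chromosome(self):
        assembly = GenomeAssembly([("chr1", 1_000)])
        rng = np.random.default_rng(0)
        s = randomize_sites(20, 1_000, assembly, rng)
        assert all(
            (m.interval.start, m.interval.end) == (0, 1_000) for m in s
        )

    def test_chromosome_choice_proportional_to_length(self):
        assembly = GenomeAssembly([("chr1", 3_000_000), ("chr2", 1_000_000)])
        rng = np.random.default_rng(1)
        s = randomize_sites(10_000, 1_000, assembly, rng)
        frac = sum(m.interval.chrom == "chr1" for m in s) / 10_000
        # expected ~0.75 (weights length - size + 1); 4 sigma tolerance
        assert abs(frac - 0.75) < 4 * np.sqrt(0.75 * 0.25 / 10_000)

    def test_short_chromosomes_cannot_host(self):
        assembly = GenomeAssembly([("chr1", 500)])
        with pytest.raises(ValueError):
            randomize_sites(5, 1_000, assembly, np.random.default_rng(0))

    def test_sites_have_exact_width_and_fit(self, perm_assembly):
        rng = np.random.default_rng(2)
        s = randomize_sites(500, 10_000, perm_assembly, rng)
        for m in s:
            assert m.interval.length == 10_000
            assert m.interval.end <= perm_assembly.length_of(m.interval.chrom)


class TestPermutationOverlapTest:
    def test_saturated_fixed_set_gives_p_one(self):
        assembly = GenomeAssembly([("chr1", 100_000)])
        fixed = make_set([("chr1", 0, 100_000)])
        test = make_set(
            [("chr1", i * 2_000, i * 2_000 + 1_000) for i in range(10)],
            mark="ncRNA",
        )
        res = permutation_overlap_test(
            fixed, test, assembly, site_size_bp=1_000, n_perm=99, seed=5
        )
        assert res.observed == 10
        assert (res.null_counts == 10).all()
        assert res.p_empirical == 1.0

    def test_empty_fixed_set_gives_p_one(self, perm_assembly):
        fixed = make_set([])
        test = make_set([("chr1", 0, 1_000)], mark="ncRNA")
        res = permutation_overlap_test(
            fixed, test, perm_assembly, n_perm=99, seed=5
        )
        assert res.observed == 0
        assert (res.null_counts == 0).all()
        assert res.p_empirical == 1.0

    def test_identical_seed_bitwise_identical(self, perm_assembly):
        rng = np.random.default_rng(7)
        fixed = random_interval_set(rng, 100, n_chrom=4, chrom_len=5_000_000)
        test = random_interval_set(rng, 100, n_chrom=4, chrom_len=5_000_000,
                                   mark="ncRNA")
        r1 = permutation_overlap_test(fixed, test, perm_assembly,
                                      n_perm=199, seed=123)
        r2 = permutation_overlap_test(fixed, test, perm_assembly,
                                      n_perm=199, seed=123)
        assert (r1.null_counts == r2.null_counts).all()
        assert r1.p_empirical == r2.p_empirical
        r3 = permutation_overlap_test(fixed, test, perm_assembly,
                                      n_perm=199, seed=124)
        assert not (r1.null_counts == r3.null_counts).all()

    def test_add_one_rule_bounds_p_away_from_zero(self, perm_assembly):
        # planted total overlap: observed is maximal, p hits the floor
        fixed = make_set(
            [("chr1", i * 10_000, i * 10_000 + 1_000) for i in range(50)]
        )
        test = make_set(
            [("chr1", i * 10_000, i * 10_000 + 1_000) for i in range(50)],
            mark="ncRNA",
        )
        res = permutation_overlap_test(
            fixed, test, perm_assembly, site_size_bp=1_000, n_perm=199, seed=1
        )
        assert res.p_empirical == pytest.approx(1 / 200)
        assert res.p_empirical >= 1 / (1 + res.n_perm)

    def test_n_perm_zero_rejected(self, perm_assembly):
        fixed = make_set([("chr1", 0, 1_000)])
        test = make_set([("chr1", 0, 1_000)], mark="ncRNA")
        with pytest.raises(ValueError):
            permutation_overlap_test(fixed, test, perm_assembly, n_perm=0)

    def test_null_p_values_stochastically_not_subuniform(self, perm_assembly):
        # add-one estimator is conservative: over null replicates the
        # empirical CDF of p at alpha must not exceed alpha by more than
        # binomial noise (one-sided check at desk scale)
        n_rep, n_perm = 60, 99
        p_values = []
        for r in range(n_rep):
            rng = np.random.default_rng(40_000 + r)
            fixed = randomize_sites(200, 1_000, perm_assembly, rng)
            test = randomize_sites(200, 1_000, perm_assembly, rng,
                                   mark="ncRNA")
            res = permutation_overlap_test(
                fixed, test, perm_assembly, site_size_bp=1_000,
                n_perm=n_perm, seed=50_000 + r,
            )
            p_values.append(res.p_empirical)
        p_values = np.array(p_values)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            frac = np.mean(p_values <= alpha)
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
            assert frac <= bound

    def test_width_preserving_shuffle_mode(self, perm_assembly):
        rng = np.random.default_rng(3)
        fixed = random_interval_set(rng, 80, n_chrom=4, chrom_len=5_000_000)
        test = random_interval_set(rng, 80, n_chrom=4, chrom_len=5_000_000,
                                   mark="ncRNA")
        res = permutation_overlap_test(
            fixed, test, perm_assembly, n_perm=49, seed=9,
            width_preserving=True,
        )
        assert len(res.null_counts) == 49
        shuffled = shuffle_sites(test, perm_assembly,
                                 np.random.default_rng(0))
        assert sorted(m.interval.length for m in shuffled) == sorted(
            m.interval.length for m in test
        )


class TestMultiwayTest:
    def test_planted_tri_loci_with_zero_background_hit_p_floor(self):
        assembly = GenomeAssembly([("chr1", 10_000_000)])
        centers = [100_000 + i * 200_000 for i in range(30)]
        catalog = [
            make_set([("chr1", c, c + 1_000, 1e-08) for c in centers],
                     generation="F3", mark="DMR"),
            make_set([("chr1", c + 200, c + 700, 1e-06) for c in centers],
                     generation="F3", mark="ncRNA"),
            make_set([("chr1", c + 100, c + 1_100, 1e-08) for c in centers],
                     generation="F3", mark="DHR"),
        ]
        res = multiway_colocalization_test(
            catalog, "vinclozolin", assembly, n_perm=99, seed=2
        )
        assert res.observed == 30
        assert res.p_empirical == pytest.approx(1 / 100)

    def test_missing_required_set_is_an_error(self, perm_assembly):
        catalog = [
            make_set([("chr1", 0, 1_000, 1e-08)], generation="F3", mark="DMR"),
            make_set([("chr1", 0, 500, 1e-06)], generation="F3", mark="ncRNA"),
        ]
        with pytest.raises(Exception):
            multiway_colocalization_test(catalog, "vinclozolin", perm_assembly)

    def test_no_planted_structure_is_rarely_significant(self, perm_assembly):
        # crude calibration at desk scale: random catalogs should reject
        # at roughly the nominal rate, certainly not always
        rejections = 0
        n_rep = 20
        for r in range(n_rep):
            rng = np.random.default_rng(60_000 + r)
            catalog = [
                make_set(
                    [
                        (m.interval.chrom, m.interval.start, m.interval.end,
                         1e-08)
                        for m in randomize_sites(100, 1_000, perm_assembly,
                                                 rng)
                    ],
                    generation="F3", mark=mark,
                )
                for mark in ("DMR", "ncRNA", "DHR")
            ]
            res = multiway_colocalization_test(
                catalog, "vinclozolin", perm_assembly, n_perm=49,
                seed=70_000 + r,
            )
            rejections += res.p_empirical <= 0.05
        assert rejections <= 5
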
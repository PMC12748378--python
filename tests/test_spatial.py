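"""High-expression masks, proximity statistics, permutation nulls, screen."""

import itertools
import math

import numpy as np
import pytest

from ampscape import (
    ConfigurationError,
    InputError,
    SpatialConfig,
    empirical_pvalue,
    generate_spatial_section,
    genome_screen,
    high_region_mask,
    mwu_test,
    nn_distance,
    permutation_null,
    spearman_coloc,
)
from ampscape.spatial import RegionMask, SKIP_UNINFORMATIVE, anchor_distance_field
from tests.conftest import make_section


class TestHighRegionMask:
    def test_percentile_threshold_top_quarter(self):
        sec = make_section(
            np.array([[1.0], [2.0], [3.0], [4.0]]),
            [(0, 0), (1, 0), (2, 0), (3, 0)],
            ["g"],
        )
        mask = high_region_mask(sec, "g")
        assert mask.threshold == pytest.approx(3.25)
        assert list(mask.members) == [3]

    def test_top_half(self):
        sec = make_section(
            np.array([[1.0], [2.0], [3.0], [4.0]]),
            [(0, 0), (1, 0), (2, 0), (3, 0)],
            ["g"],
        )
        mask = high_region_mask(sec, "g", top_fraction=0.5)
        assert list(mask.members) == [2, 3]

    def test_constant_gene_skipped(self):
        sec = make_section(np.ones((5, 1)), [(i, 0) for i in range(5)], ["g"])
        mask = high_region_mask(sec, "g")
        assert mask.skipped and mask.skip_reason == SKIP_UNINFORMATIVE

    def test_single_spot_section_rejected(self):
        sec = make_section(np.array([[1.0]]), [(0, 0)], ["g"])
        assert high_region_mask(sec, "g").skipped

    def test_absent_gene_raises(self, worked_section):
        with pytest.raises(InputError):
            high_region_mask(worked_section, "nope")


class TestNNDistance:
    def _mask(self, members, sid="test"):
        return RegionMask("g", sid, np.asarray(members), 1.0)

    def test_identical_masks_zero(self):
        coords = np.array([(0.0, 0.0), (5.0, 5.0)])
        d, d_obs = nn_distance(self._mask([0, 1]), self._mask([0, 1]), coords)
        assert d_obs == 0.0 and np.all(d == 0)

    def test_three_four_five_triangle(self):
        coords = np.array([(0.0, 0.0), (3.0, 4.0)])
        _, d_obs = nn_distance(self._mask([0]), self._mask([1]), coords)
        assert d_obs == pytest.approx(5.0)

    def test_brute_force_pairwise(self):
        coords = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (5.0, 5.0)])
        d, d_obs = nn_distance(self._mask([0, 1]), self._mask([2, 3]), coords)
        np.testing.assert_allclose(sorted(d), [1.0, math.sqrt(2)])
        assert d_obs == pytest.approx((1 + math.sqrt(2)) / 2)

    def test_cross_section_masks_rejected(self):
        coords = np.zeros((2, 2))
        with pytest.raises(InputError):
            nn_distance(self._mask([0]), self._mask([1], sid="other"), coords)


class TestPermutationNull:
    def test_worked_example_exhaustive(self, worked_section):
        res = permutation_null(
            worked_section, "ANCHOR", "TEST", exhaustive=True
        )
        assert res.d_obs == pytest.approx(1.0)
        assert res.empirical_p == pytest.approx(19 / 25)

    def test_empirical_p_bounds_and_plus_one_convention(self):
        null = np.array([2.0, 3.0, 4.0, 5.0])
        assert empirical_pvalue(1.0, null) == pytest.approx(1 / 5)
        assert empirical_pvalue(10.0, null) == pytest.approx(1.0)
        assert empirical_pvalue(3.0, null) == pytest.approx(3 / 5)

    def test_monte_carlo_matches_exhaustive(self, worked_section):
        res = permutation_null(
            worked_section, "ANCHOR", "TEST", B=10000, seed=0
        )
        assert res.empirical_p == pytest.approx(19 / 25, abs=0.02)

    def test_deterministic_given_seed(self, worked_section):
        r1 = permutation_null(worked_section, "ANCHOR", "TEST", B=50, seed=9)
        r2 = permutation_null(worked_section, "ANCHOR", "TEST", B=50, seed=9)
        np.testing.assert_array_equal(r1.null_d, r2.null_d)
        assert r1.empirical_p == r2.empirical_p

    def test_skipped_gene_propagates(self, worked_section):
        sec = worked_section.copy()
        sec.X[:, 1] = 1.0
        res = permutation_null(sec, "ANCHOR", "TEST", B=10)
        assert res.skipped and res.skip_reason == SKIP_UNINFORMATIVE

    def test_invalid_b_raises(self, worked_section):
        with pytest.raises(ConfigurationError):
            permutation_null(worked_section, "ANCHOR", "TEST", B=0)

    def test_coordinate_null_mode_runs(self, worked_section):
        res = permutation_null(
            worked_section, "ANCHOR", "TEST", B=200, seed=1,
            null_mode="coordinates",
        )
        assert 0 < res.empirical_p <= 1


class TestInvariances:
    def _random_section(self, seed, n=40, genes=6):
        rng = np.random.default_rng(seed)
        return make_section(
            rng.gamma(2.0, 2.0, (n, genes)),
            rng.uniform(0, 10, (n, 2)),
            [f"g{j}" for j in range(genes)],
        )

    def test_rigid_motion_invariance(self):
        sec = self._random_section(1)
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)],
             [math.sin(theta), math.cos(theta)]]
        )
        moved = sec.copy()
        moved.obsm["spatial"] = sec.obsm["spatial"] @ rot.T + np.array([3.0, -2.0])
        r0 = permutation_null(sec, "g0", "g1", B=100, seed=5)
        r1 = permutation_null(moved, "g0", "g1", B=100, seed=5)
        assert r0.d_obs == pytest.approx(r1.d_obs)
        assert r0.empirical_p == r1.empirical_p
        assert spearman_coloc(sec, "g0", "g1") == spearman_coloc(moved, "g0", "g1")

    def test_scale_equivariance(self):
        sec = self._random_section(2)
        scaled = sec.copy()
        scaled.obsm["spatial"] = sec.obsm["spatial"] * 3.0
        r0 = permutation_null(sec, "g0", "g1", B=100, seed=5)
        r1 = permutation_null(scaled, "g0", "g1", B=100, seed=5)
        assert r1.d_obs == pytest.approx(3.0 * r0.d_obs)
        np.testing.assert_allclose(r1.null_d, 3.0 * r0.null_d)
        assert r0.empirical_p == r1.empirical_p

    def test_monte_carlo_within_002_of_exhaustive_small_sections(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 7))
            sec = make_section(
                rng.gamma(2.0, 2.0, (n, 2)),
                rng.uniform(0, 5, (n, 2)),
                ["a", "t"],
            )
            ex = permutation_null(sec, "a", "t", exhaustive=True)
            if ex.skipped:
                continue
            mc = permutation_null(sec, "a", "t", B=10000, seed=seed)
            assert mc.empirical_p == pytest.approx(ex.empirical_p, abs=0.02)


class TestMWU:
    def test_separated_samples_exact(self):
        assert mwu_test([1, 2, 3], [4, 5, 6]) == pytest.approx(1 / 20)
        assert mwu_test([4, 5, 6], [1, 2, 3]) == pytest.approx(1.0)

    def test_equal_multisets_not_significant(self):
        assert mwu_test([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_empty_sample_raises(self):
        with pytest.raises(InputError):
            mwu_test([], [1.0])

    def test_exact_matches_independent_enumeration(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(3)
        for _ in range(20):
            na, nb = rng.integers(2, 9, 2)
            a = rng.integers(0, 5, na).astype(float)
            b = rng.integers(0, 5, nb).astype(float)
            # independent oracle: enumerate rank-sum null from scratch
            pooled = np.concatenate([a, b])
            ranks = rankdata(pooled)
            w_obs = ranks[:na].sum()
            sums = [
                sum(ranks[list(c)])
                for c in itertools.combinations(range(na + nb), na)
            ]
            expected = np.mean([s <= w_obs + 1e-9 for s in sums])
            assert mwu_test(a, b) == pytest.approx(expected)

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=8)
        b = rng.normal(1.0, size=8)
        exact = mwu_test(a, b)
        approx = mwu_test(np.r_[a, a[:1] + 1e-7], b)  # size 9 -> asymptotic
        assert approx == pytest.approx(exact, abs=0.05)


class TestSpearman:
    def test_perfect_monotone(self, worked_section):
        sec = make_section(
            np.column_stack([np.arange(5.0), np.arange(5.0) ** 2]),
            [(i, 0) for i in range(5)],
            ["a", "b"],
        )
        assert spearman_coloc(sec, "a", "b") == pytest.approx(1.0)

    def test_perfect_antitone(self):
        sec = make_section(
            np.column_stack([np.arange(5.0), -np.arange(5.0)]),
            [(i, 0) for i in range(5)],
            ["a", "b"],
        )
        assert spearman_coloc(sec, "a", "b") == pytest.approx(-1.0)

    def test_hand_ranked_tied_oracle(self):
        sec = make_section(
            np.column_stack([[1.0, 2.0, 2.0, 3.0], [1.0, 3.0, 2.0, 4.0]]),
            [(i, 0) for i in range(4)],
            ["a", "b"],
        )
        # average ranks: a -> (1, 2.5, 2.5, 4); b -> (1, 3, 2, 4);
        # Pearson of those rank vectors = 4.5 / sqrt(4.5 * 5)
        assert spearman_coloc(sec, "a", "b") == pytest.approx(
            4.5 / math.sqrt(22.5)
        )

    def test_zero_variance_undefined_not_zero(self):
        sec = make_section(
            np.column_stack([np.ones(4), np.arange(4.0)]),
            [(i, 0) for i in range(4)],
            ["a", "b"],
        )
        assert math.isnan(spearman_coloc(sec, "a", "b"))


class TestGenomeScreen:
    def test_anchor_excluded_and_planted_partner_found(self):
        sec = generate_spatial_section(
            SpatialConfig(
                rows=15, cols=15, niche_radius=5.0, anchor_strength=3.0,
                partner_genes=[("PARTNER", 4.0)], n_background_genes=10,
                seed=1,
            )
        )
        res = genome_screen([sec], "CCNE1", B=500, alpha=0.05, seed=1)
        assert "CCNE1" not in res.per_gene
        assert res.consistent and res.consistent[0] == "PARTNER"

    def test_gene_skipped_anywhere_is_not_consistent(self):
        cfg = dict(
            rows=12, cols=12, niche_radius=4.0, anchor_strength=3.0,
            partner_genes=[("PARTNER", 4.0)], n_background_genes=5,
        )
        s1 = generate_spatial_section(SpatialConfig(**cfg, section_id="A", seed=2))
        s2 = generate_spatial_section(SpatialConfig(**cfg, section_id="B", seed=3))
        s2.X[:, list(s2.var_names).index("PARTNER")] = 1.0  # uninformative in B
        res = genome_screen([s1, s2], "CCNE1", B=300, seed=2)
        assert "PARTNER" not in res.consistent

    def test_distance_field_matches_nn_distance(self):
        sec = generate_spatial_section(
            SpatialConfig(rows=8, cols=8, niche_radius=3.0, seed=4)
        )
        mask = high_region_mask(sec, "CCNE1")
        d = anchor_distance_field(sec, mask)
        assert np.all(d[mask.members] == 0)
        assert d.shape == (sec.n_obs,)
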
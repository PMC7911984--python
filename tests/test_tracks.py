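"""SNP density, distance weighting, the conservation score and MinMax."""

import numpy as np
import pytest

from consite.phylo import DistanceVector
from consite.scan import IdentityMatrix
from consite.tracks import (
    conservation_score,
    group_mean_identity,
    minmax_scale,
    normalize_identity,
    percentile_of,
    snp_density,
)


def brute_force_sigma(positions, length, window):
    out = np.zeros(length)
    pos = set(int(p) for p in positions)
    for n in range(length):
        lo = max(0, n - window // 2)
        hi = min(length, n - window // 2 + window)
        out[n] = sum(1 for p in pos if lo <= p < hi) / (hi - lo)
    return out


class TestSnpDensity:
    def test_no_variants_all_zero(self):
        assert not snp_density(np.array([], dtype=np.int64), 100).any()

    def test_every_position_variant_gives_one(self):
        sigma = snp_density(np.arange(100), 100)
        np.testing.assert_allclose(sigma, 1.0)

    def test_single_variant_spreads_over_window_positions(self):
        sigma = snp_density(np.array([100]), 300, window=20)
        hit = np.flatnonzero(sigma > 0)
        assert hit.tolist() == list(range(91, 111))  # windows covering pos 100
        np.testing.assert_allclose(sigma[hit], 0.05)

    def test_truncated_window_uses_actual_span(self):
        sigma = snp_density(np.array([0]), 100, window=20)
        assert sigma[0] == pytest.approx(1 / 10)  # window [0,10): span 10

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        positions = np.flatnonzero(rng.random(400) < 0.05)
        got = snp_density(positions, 400, window=20)
        np.testing.assert_allclose(got, brute_force_sigma(positions, 400, 20))

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            snp_density(np.array([5, 3]), 100)


class TestNormalizeIdentity:
    def test_unit_distances_leave_matrix_unchanged(self):
        mat = IdentityMatrix("chr1", ["a", "b"], np.full((2, 4), 0.9))
        dv = DistanceVector(["a", "b"], np.ones(2))
        np.testing.assert_array_equal(normalize_identity(mat, dv), mat.values)

    def test_distant_species_weighted_up(self):
        mat = IdentityMatrix("chr1", ["near", "far"], np.full((2, 3), 0.9))
        dv = DistanceVector(["near", "far"], np.array([0.1, 0.5]))
        weighted = normalize_identity(mat, dv)
        np.testing.assert_allclose(weighted[0], 0.09)
        np.testing.assert_allclose(weighted[1], 0.45)

    def test_hand_elementwise_products(self):
        values = np.array([[0.2, 0.4, 0.6], [0.1, 0.5, 1.0]])
        d = np.array([2.0, 3.0])
        mat = IdentityMatrix("chr1", ["a", "b"], values)
        dv = DistanceVector(["a", "b"], d)
        np.testing.assert_allclose(normalize_identity(mat, dv), values * d[:, None])

    def test_species_order_mismatch_raises(self):
        mat = IdentityMatrix("chr1", ["a", "b"], np.zeros((2, 3)))
        dv = DistanceVector(["b", "a"], np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="order"):
            normalize_identity(mat, dv)


class TestConservationScore:
    def test_neutral_factors_reduce_to_mean_identity(self):
        norm = np.array([[0.4, 0.8], [0.2, 0.0]])
        cs = conservation_score(norm, np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(cs, norm.mean(axis=0))

    def test_saturated_snp_density_zeroes_score(self):
        norm = np.full((3, 4), 0.9)
        cs = conservation_score(norm, np.ones(4), np.zeros(4))
        np.testing.assert_allclose(cs, 0.0)

    def test_worked_value(self):
        # mean identity 0.5, sigma 0.05, p 1 -> 0.5 * (0.95/1.05) * 2
        cs = conservation_score(
            np.array([[0.5]]), np.array([0.05]), np.array([1.0])
        )
        assert cs[0] == pytest.approx(0.5 * (0.95 / 1.05) * 2, rel=1e-12)
        assert cs[0] == pytest.approx(0.9048, abs=5e-5)

    def test_scalar_reimplementation_oracle(self):
        rng = np.random.default_rng(8)
        m, n = 5, 1000
        identity = rng.random((m, n))
        d = rng.random(m) * 2
        sigma = rng.random(n)
        p = rng.normal(size=n)
        mat = IdentityMatrix("chr1", [f"s{i}" for i in range(m)], identity)
        dv = DistanceVector(mat.species, d)
        vectorised = conservation_score(normalize_identity(mat, dv), sigma, p)
        for pos in range(0, n, 37):
            acc = sum(identity[i, pos] * d[i] for i in range(m)) / m
            expected = acc * (1 - sigma[pos]) / (1 + sigma[pos]) * 2 ** p[pos]
            assert vectorised[pos] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_monotone_in_sigma_and_p(self):
        norm = np.full((2, 50), 0.8)
        sigmas = np.linspace(0, 1, 50)
        cs = conservation_score(norm, sigmas, np.zeros(50))
        assert np.all(np.diff(cs) < 0)  # strictly decreasing in sigma
        ps = np.linspace(-3, 3, 50)
        cs = conservation_score(norm, np.zeros(50), ps)
        assert np.all(np.diff(cs) > 0)  # strictly increasing in p

    def test_snp_factor_grid_properties(self):
        sigma = np.linspace(0, 1, 101)
        f = (1 - sigma) / (1 + sigma)
        assert f[0] == 1.0 and f[-1] == 0.0
        assert np.all(np.diff(f) < 0)

    def test_no_alignment_no_signal(self):
        cs = conservation_score(np.zeros((3, 10)), np.zeros(10), np.ones(10))
        np.testing.assert_array_equal(cs, 0.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            conservation_score(np.ones((1, 2)), np.array([0.5, 1.2]), np.zeros(2))


class TestMinMax:
    def test_closed_form(self):
        np.testing.assert_allclose(
            minmax_scale(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_scale(np.array([3.0, 3.0, 3.0]))
        np.testing.assert_array_equal(out, 0.0)

    def test_nonconstant_spans_unit_interval(self):
        rng = np.random.default_rng(4)
        out = minmax_scale(rng.normal(size=500))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_distance_rescaling_invariance_after_minmax(self):
        # global rescaling of the distance vector must not change cs_scaled
        rng = np.random.default_rng(12)
        mat = IdentityMatrix("chr1", ["a", "b", "c"], rng.random((3, 200)))
        sigma = rng.random(200) * 0.5
        p = rng.normal(size=200)
        d = rng.random(3)
        out = {}
        for scale in (1.0, 7.3):
            dv = DistanceVector(mat.species, d * scale)
            raw = conservation_score(normalize_identity(mat, dv), sigma, p)
            out[scale] = minmax_scale(raw)
        np.testing.assert_allclose(out[1.0], out[7.3], atol=1e-12)


class TestGroupMeanIdentity:
    def test_constant_single_species(self):
        mat = IdentityMatrix("chr1", ["a"], np.full((1, 100), 0.8))
        _, _, values = group_mean_identity(mat, ["a"], window=100)
        np.testing.assert_allclose(values, 80.0)

    def test_two_species_average(self):
        mat = IdentityMatrix(
            "chr1", ["a", "b"], np.vstack([np.ones(50), np.full(50, 0.6)])
        )
        _, _, values = group_mean_identity(mat, ["a", "b"], window=50)
        np.testing.assert_allclose(values, 80.0)

    def test_tail_window_averages_actual_span(self):
        row = np.concatenate([np.ones(100), np.zeros(30)])
        mat = IdentityMatrix("chr1", ["a"], row[None, :])
        starts, ends, values = group_mean_identity(mat, ["a"], window=100)
        assert ends[-1] - starts[-1] == 30
        np.testing.assert_allclose(values, [100.0, 0.0])

    def test_unknown_species_raises(self):
        mat = IdentityMatrix("chr1", ["a"], np.zeros((1, 10)))
        with pytest.raises(ValueError, match="zz"):
            group_mean_identity(mat, ["zz"])


class TestPercentile:
    def test_track_maximum_is_100th(self):
        track = np.linspace(0.1, 1.0, 10)
        assert percentile_of(1.0, track) == 100.0

    def test_below_all_positives_is_zero(self):
        track = np.array([0.0, 0.2, 0.4])
        assert percentile_of(0.1, track) == 0.0

    def test_counting_oracle(self):
        track = np.round(np.arange(0.1, 1.05, 0.1), 10)
        assert percentile_of(0.55, track) == pytest.approx(50.0)

    def test_zeros_excluded_from_reference_set(self):
        track = np.array([0.0] * 90 + [0.5] * 10)
        assert percentile_of(0.5, track) == 100.0

    def test_all_zero_track_raises(self):
        with pytest.raises(ValueError):
            percentile_of(0.5, np.zeros(10))
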
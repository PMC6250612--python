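"""Second-order statistics against brute force, closed forms and simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import follistat as fs
from follistat.datatypes import PointPattern


def brute_force_k(pp, r_grid):
    """Independent oracle: K (no correction) by enumeration of ordered pairs."""
    n = pp.n
    area = pp.window.area_um2
    out = np.zeros(len(r_grid))
    for a, r in enumerate(r_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(pp.points[i] - pp.points[j])) <= r:
                    count += 1
        out[a] = area / (n * (n - 1)) * count
    return out


class TestDensity:
    def test_density_is_count_over_area(self):
        w = fs.rectangle_window(200, 500, 1.0)  # 0.1 mm^2
        pts = np.random.default_rng(0).uniform([0, 0], [200, 500], size=(100, 2))
        assert fs.density(PointPattern(pts, w, "B")) == pytest.approx(1000.0)

    def test_empty_pattern_has_zero_density(self, square_window):
        assert fs.density(PointPattern(np.zeros((0, 2)), square_window, "B")) == 0.0

    def test_zero_area_window_is_invalid(self):
        w = fs.RegionMask(np.zeros((4, 4), dtype=bool), 1.0, "GC")
        with pytest.raises(ValueError):
            fs.density(PointPattern(np.zeros((0, 2)), w, "B"))

    def test_csr_replicate_mean_density_matches_intensity(self):
        w = fs.rectangle_window(500, 500, 2.0)
        dens = [
            fs.density(fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=2000, seed=s), w)[0])
            for s in range(100)
        ]
        mean, se = np.mean(dens), np.std(dens, ddof=1) / np.sqrt(len(dens))
        assert abs(mean - 2000.0) < 3 * se

    def test_zone_partition_additivity_is_exact(self, follicle_windows):
        gc, lz, dz = follicle_windows
        pp, _ = fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=800, seed=12), gc)
        parts = []
        for w in (gc, lz, dz):
            sub = PointPattern(pp.points[w.contains(pp.points)], w, "B")
            parts.append(fs.density(sub) * w.area_mm2)
        assert parts[0] == pytest.approx(parts[1] + parts[2], abs=1e-9)


class TestRipleyK:
    @pytest.mark.parametrize("seed,n", [(0, 10), (1, 25), (2, 50)])
    def test_matches_brute_force_enumeration_exactly(self, seed, n):
        w = fs.rectangle_window(200, 200, 2.0)
        rng = np.random.default_rng(seed)
        pp = PointPattern(rng.uniform(0, 200, size=(n, 2)), w, "B")
        r = np.array([5.0, 20.0, 50.0, 90.0])
        k = fs.ripley_k(pp, r, correction="none").k
        np.testing.assert_allclose(k, brute_force_k(pp, r), rtol=1e-12)

    def test_three_point_toy_pattern_by_hand(self):
        # points at (0,0), (3,0), (0,4): pair distances 3, 4, 5 (each twice)
        w = fs.rectangle_window(10, 10, 1.0)
        pp = PointPattern(np.array([[0.5, 0.5], [3.5, 0.5], [0.5, 4.5]]), w, "B")
        r = np.array([2.9, 3.5, 4.5, 5.5])
        k = fs.ripley_k(pp, r, correction="none").k
        area = 100.0
        np.testing.assert_allclose(k, area / 6 * np.array([0, 2, 4, 6]), rtol=1e-12)

    def test_csr_mean_matches_pi_r_squared(self):
        w = fs.rectangle_window(500, 500, 2.0)
        r = np.array([10.0, 25.0, 50.0])
        ks = []
        for s in range(100):
            pp, _ = fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=2000, seed=s), w)
            ks.append(fs.ripley_k(pp, r, correction="translation").k)
        ks = np.array(ks)
        mean = ks.mean(axis=0)
        se = ks.std(axis=0, ddof=1) / np.sqrt(len(ks))
        assert np.all(np.abs(mean - np.pi * r**2) < 3 * se)

    def test_coincident_points_give_constant_k(self, square_window):
        pp = PointPattern(np.full((4, 2), 250.0), square_window, "B")
        k = fs.ripley_k(pp, np.array([1.0, 10.0, 50.0]), correction="none").k
        assert k[0] == k[1] == k[2] > 0

    def test_fewer_than_two_points_is_an_error(self, square_window):
        with pytest.raises(ValueError, match="fewer than 2"):
            fs.ripley_k(PointPattern(np.array([[10.0, 10.0]]), square_window, "B"))

    @given(seed=st.integers(0, 1000))
    def test_k_is_nondecreasing(self, seed):
        w = fs.rectangle_window(300, 300, 2.0)
        rng = np.random.default_rng(seed)
        pp = PointPattern(rng.uniform(0, 300, size=(30, 2)), w, "B")
        for corr in ("none", "translation"):
            k = fs.ripley_k(pp, correction=corr).k
            assert np.all(np.diff(k) >= -1e-9)

    def test_translation_weights_only_increase_k(self, square_window):
        pp, _ = fs.simulate_points(
            fs.ProcessSpec(kind="csr", intensity=1000, seed=5), square_window
        )
        r = fs.default_r_grid()
        k_none = fs.ripley_k(pp, r, correction="none").k
        k_trans = fs.ripley_k(pp, r, correction="translation").k
        assert np.all(k_trans >= k_none - 1e-9)


class TestPairCorrelation:
    def test_csr_mean_g_is_close_to_one(self):
        w = fs.rectangle_window(500, 500, 2.0)
        r = fs.default_r_grid()
        gs = [
            fs.pair_correlation(
                fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=2000, seed=s), w)[0], r
            ).g
            for s in range(20)
        ]
        band = (r >= 5) & (r <= 50)
        assert np.all(np.abs(np.mean(gs, axis=0)[band] - 1.0) < 0.1)

    def test_hardcore_exclusion_suppresses_short_range_g(self, square_window):
        pp, _ = fs.simulate_points(
            fs.ProcessSpec(kind="hardcore", intensity=300, hardcore_radius=20, seed=3),
            square_window,
        )
        c = fs.pair_correlation(pp)
        assert np.all(c.g[c.r <= 15] < 0.5)

    def test_thomas_g_matches_closed_form(self):
        # g(r) = 1 + exp(-r^2 / 4 sigma^2) / (4 pi sigma^2 kappa)
        w = fs.rectangle_window(500, 500, 2.0)
        sig, kap_mm = 5.0, 40.0
        kap = kap_mm / 1e6
        r = fs.default_r_grid(30.0)
        gs = []
        for s in range(30):
            pp, _ = fs.simulate_points(
                fs.ProcessSpec(kind="thomas", thomas_parent_intensity=kap_mm,
                               thomas_mean_offspring=5.0, thomas_sigma=sig, seed=1000 + s), w)
            if pp.n >= 2:
                gs.append(fs.pair_correlation(pp, r, bandwidth_rule="fixed", bandwidth=2.0).g)
        gs = np.array(gs)
        mean = gs.mean(axis=0)
        se = gs.std(axis=0, ddof=1) / np.sqrt(len(gs))
        theory = 1 + np.exp(-(r**2) / (4 * sig**2)) / (4 * np.pi * sig**2 * kap)
        check = (r >= 5) & (r <= 20)
        # 3 MC s.e. plus 5% slack for kernel-smoothing bias
        assert np.all(np.abs(mean - theory)[check] < (3 * se + 0.05 * theory)[check])

    def test_g_is_nonnegative_and_small_r_is_flagged(self, square_window):
        pp, _ = fs.simulate_points(
            fs.ProcessSpec(kind="csr", intensity=300, seed=9), square_window
        )
        c = fs.pair_correlation(pp)
        assert np.all(c.g >= 0)
        h = c.meta["bandwidth"]
        np.testing.assert_array_equal(c.unreliable, c.r < h)

    def test_r_grid_with_zero_is_rejected(self, square_window):
        pp, _ = fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=300, seed=9),
                                   square_window)
        with pytest.raises(ValueError, match="exclude"):
            fs.pair_correlation(pp, np.array([0.0, 1.0, 2.0]))

    def test_stoyan_bandwidth_formula(self, square_window):
        pp = PointPattern(np.random.default_rng(3).uniform(0, 500, (500, 2)),
                          square_window, "B")
        lam = 500 / square_window.area_um2
        assert fs.stoyan_bandwidth(pp) == pytest.approx(0.15 / np.sqrt(lam))


class TestEnvelopes:
    def test_identical_curves_pool_to_themselves(self):
        r = fs.default_r_grid(10.0)
        g = np.linspace(0.5, 1.5, len(r))
        curves = [fs.SpatialCurve(r=r, g=g.copy()) for _ in range(9)]
        pooled = fs.pooled_envelope(curves)
        np.testing.assert_allclose(pooled.lo, g)
        np.testing.assert_allclose(pooled.med, g)
        np.testing.assert_allclose(pooled.hi, g)
        assert pooled.source == "pooled_follicles"

    def test_constant_curves_pool_to_min_median_max(self):
        r = fs.default_r_grid(10.0)
        curves = [fs.SpatialCurve(r=r, g=np.full(len(r), v)) for v in (0.5, 1.0, 1.5)]
        pooled = fs.pooled_envelope(curves)
        assert np.all(pooled.lo == 0.5) and np.all(pooled.med == 1.0) and np.all(pooled.hi == 1.5)

    def test_mismatched_grids_are_rejected(self):
        a = fs.SpatialCurve(r=np.array([1.0, 2.0]), g=np.array([1.0, 1.0]))
        b = fs.SpatialCurve(r=np.array([1.0, 3.0]), g=np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="identical r grid"):
            fs.pooled_envelope([a, b])

    def test_nine_csr_replicates_pool_near_one(self):
        w = fs.rectangle_window(500, 500, 2.0)
        r = fs.default_r_grid()
        curves = [
            fs.pair_correlation(
                fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=2000, seed=50 + s), w)[0],
                r,
            )
            for s in range(9)
        ]
        pooled = fs.pooled_envelope(curves)
        band = (r >= 10) & (r <= 50)
        assert np.all(np.abs(pooled.med[band] - 1.0) < 0.15)

    def test_rank_arithmetic_of_envelope_level(self, square_window):
        pp, _ = fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=200, seed=1),
                                   square_window)
        env = fs.csr_envelope(pp, n_sim=19, rank=1, seed=2)
        assert env.meta["pointwise_level"] == pytest.approx(2 / 20)

    def test_csr_pattern_rarely_exits_its_own_envelope(self, square_window):
        pp, _ = fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=1000, seed=4),
                                   square_window)
        r = fs.default_r_grid()
        c = fs.pair_correlation(pp, r)
        env = fs.csr_envelope(pp, n_sim=99, rank=3, r_grid=r, seed=5)
        exits = ((c.g > env.hi) | (c.g < env.lo)).mean()
        assert exits < 0.2


class TestClassification:
    def test_flat_unit_curve_is_csr(self, square_window):
        r = fs.default_r_grid()
        curve = fs.SpatialCurve(r=r, g=np.ones(len(r)))
        env = fs.SpatialCurve(r=r, lo=np.full(len(r), 0.8), hi=np.full(len(r), 1.2),
                              source="csr_sim")
        call, radii = fs.classify_pattern(curve, env)
        assert call == "csr" and len(radii) == 0

    def test_thomas_pattern_is_called_clustered_at_the_cluster_scale(self, square_window):
        pp, _ = fs.simulate_points(
            fs.ProcessSpec(kind="thomas", thomas_parent_intensity=40,
                           thomas_mean_offspring=5, thomas_sigma=5, seed=7),
            square_window,
        )
        r = fs.default_r_grid()
        c = fs.pair_correlation(pp, r)
        env = fs.csr_envelope(pp, 99, 3, r, seed=8)
        call, radii = fs.classify_pattern(c, env, r_band=(2, 20))
        assert call == "clustered"
        assert radii.min() <= 10 and radii.max() >= 5  # excursion overlaps 5-10 um

    def test_hardcore_pattern_is_called_regular(self, square_window):
        pp, _ = fs.simulate_points(
            fs.ProcessSpec(kind="hardcore", intensity=400, hardcore_radius=20, seed=9),
            square_window,
        )
        r = fs.default_r_grid()
        c = fs.pair_correlation(pp, r)
        env = fs.csr_envelope(pp, 99, 3, r, seed=10)
        call, _ = fs.classify_pattern(c, env, r_band=(2, 20))
        assert call == "regular"

    def test_non_csr_envelope_is_rejected(self):
        r = fs.default_r_grid(5.0)
        curve = fs.SpatialCurve(r=r, g=np.ones(len(r)))
        env = fs.SpatialCurve(r=r, lo=np.zeros(len(r)), hi=np.ones(len(r)),
                              source="pooled_follicles")
        with pytest.raises(ValueError):
            fs.classify_pattern(curve, env)


class TestDensityComparison:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p, ma, mb = fs.compare_densities([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert t == 0.0 and p == 1.0 and ma == mb == 5.0

    def test_matches_hand_computed_welch(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p, ma, mb = fs.compare_densities(a, b)
        # closed-form Welch: se = sqrt(s_a^2/3 + s_b^2/3), df by Welch-Satterthwaite
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t_hand = (a.mean() - b.mean()) / se
        df = se**4 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_small_groups_are_rejected(self):
        with pytest.raises(ValueError):
            fs.compare_densities([1.0], [2.0, 3.0])


class TestEdgeCorrection:
    def test_uncorrected_g_is_biased_low_at_long_range(self):
        # documents why the translation correction exists
        w = fs.rectangle_window(500, 500, 2.0)
        r = np.array([50.0])
        g_none, g_trans = [], []
        for s in range(20):
            pp, _ = fs.simulate_points(fs.ProcessSpec(kind="csr", intensity=2000, seed=s), w)
            g_none.append(fs.pair_correlation(pp, r, correction="none").g[0])
            g_trans.append(fs.pair_correlation(pp, r, correction="translation").g[0])
        assert np.mean(g_none) < 0.93
        assert abs(np.mean(g_trans) - 1.0) < 0.1
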
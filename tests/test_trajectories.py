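"""Trajectory design: counting formulas, placement rules, density, timing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eccentric_mrsi as em
from eccentric_mrsi.trajectories import (
    analytic_radial_mass,
    design_eccentric_2d,
    eccentric_center_density,
    format_ta,
    plan_sample_weights,
)


class TestCounts:
    @pytest.mark.parametrize(
        "n,R_frac,expected",
        [(64, 0.5, 202), (64, 1.0, 101), (64, 0.25, 403)],
    )
    def test_full_sampling_count(self, n, R_frac, expected):
        kmax = 7.3  # arbitrary: the count only depends on R/kmax
        assert em.full_sampling_count(n, kmax, R_frac * kmax) == expected

    @pytest.mark.parametrize("n,expected", [(64, 101), (2, 4), (32, 51)])
    def test_rosette_count(self, n, expected):
        assert em.rosette_count(n) == expected

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            em.full_sampling_count(64, 1.0, 0.0)
        with pytest.raises(ValueError):
            em.full_sampling_count(64, -1.0, 0.5)
        with pytest.raises(ValueError):
            em.rosette_count(1)

    @given(n=st.integers(4, 256).filter(lambda n: n % 2 == 0),
           rfrac=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_count_matches_ceiling_formula(self, n, rfrac):
        kmax = n / (2 * 0.22)
        got = em.full_sampling_count(n, kmax, rfrac * kmax)
        assert got == math.ceil(math.pi * n * kmax / (2 * rfrac * kmax))


class TestEccentricDesign:
    def test_full_sampling_circle_count_and_containment(self, grid64):
        plan = design_eccentric_2d(grid64, grid64.kmax / 2, af=1.0, seed=0)
        assert plan.n_circles == 202
        for c in plan.circles:
            assert c.r_c + c.R <= grid64.kmax + 1e-9

    def test_af_equal_to_full_count_gives_single_circle(self, grid16):
        full = em.full_sampling_count(16, grid16.kmax, grid16.kmax / 2)
        circles = em.design_eccentric_plane(grid16, grid16.kmax / 2, af=full,
                                            seed=0)
        assert len(circles) == 1

    def test_determinism(self, grid64):
        a = design_eccentric_2d(grid64, grid64.kmax / 4, af=2.0, seed=42)
        b = design_eccentric_2d(grid64, grid64.kmax / 4, af=2.0, seed=42)
        assert a.circles == b.circles

    def test_seed_changes_centres(self, grid64):
        a = design_eccentric_2d(grid64, grid64.kmax / 4, af=2.0, seed=1)
        b = design_eccentric_2d(grid64, grid64.kmax / 4, af=2.0, seed=2)
        assert a.n_circles == b.n_circles
        assert a.circles != b.circles

    @pytest.mark.parametrize("seed", range(12))
    def test_consecutive_overlap_rule(self, grid64, seed):
        # Nyquist rule on consecutive same-partition centres, many plans
        plan = design_eccentric_2d(grid64, grid64.kmax / 4, af=1.0, seed=seed)
        centres = np.array([c.center for c in plan.circles])
        gaps = np.hypot(*np.diff(centres, axis=0).T)
        assert np.all(gaps >= grid64.dk - 1e-12)

    def test_count_monotonicity(self, grid64):
        counts_af = [design_eccentric_2d(grid64, grid64.kmax / 2, af=af,
                                         seed=0).n_circles
                     for af in (1, 2, 3, 4, 6)]
        assert all(a >= b for a, b in zip(counts_af, counts_af[1:]))
        counts_n = [design_eccentric_2d(em.GridSpec(n, 0.22),
                                        em.GridSpec(n, 0.22).kmax / 2,
                                        seed=0).n_circles
                    for n in (16, 32, 64)]
        assert counts_n == sorted(counts_n)

    def test_rosette_subset_passes_through_origin(self, grid64):
        plan = design_eccentric_2d(grid64, grid64.kmax / 2, af=1.0, seed=3,
                                   rosette_fraction=0.04)
        n_ros = math.ceil(0.04 * plan.n_circles)
        for c in plan.circles[:n_ros]:
            assert c.r_c == pytest.approx(c.R)

    def test_monte_carlo_density_follows_inverse_radius(self, grid64):
        # sampling density of the random-circle model ~ 1/||k|| outside the
        # central region, checked per annulus against the analytic oracle
        R = grid64.kmax / 4
        pts = eccentric_center_density(grid64, R, n_centers=20000, seed=0)
        radii = np.hypot(pts[:, 0], pts[:, 1])
        r_max = grid64.kmax - R
        # annuli between the rosette-sampled core and the outer band where
        # the centre distribution is truncated by the k-space boundary
        edges = np.linspace(1.5 * R, r_max - R, 9)
        mass_mc, _ = np.histogram(radii, bins=edges)
        mass_mc = mass_mc / mass_mc.sum()
        mass_an = analytic_radial_mass(R, r_max, edges)
        mass_an = mass_an / mass_an.sum()
        assert np.all(np.abs(mass_mc - mass_an) / mass_an < 0.10)
        # and the analytic masses themselves follow the 1/||k|| area law:
        # annulus mass ~ width * mean radius * (1/r) = const * width
        widths = np.diff(edges)
        flat = mass_an / widths
        assert flat.max() / flat.min() < 1.10


class TestStack:
    def test_single_partition_matches_plane(self, grid64):
        stack = em.design_stack(grid64, grid64.kmax / 4, af=1.0, seed=5)
        plane = em.design_eccentric_plane(
            grid64, grid64.kmax / 4, af=1.0, kz_index=0,
            rng=np.random.default_rng(
                np.random.SeedSequence(5, spawn_key=(2**20,))),
        )
        assert stack.circles == plane

    def test_same_counts_different_centres_across_seeds(self):
        grid = em.GridSpec(64, 0.22, n_z=7, fov_z=0.105)
        a = em.design_stack(grid, grid.kmax / 8, af=1.0, seed=1)
        b = em.design_stack(grid, grid.kmax / 8, af=1.0, seed=2)
        for kz in range(-3, 4):
            ca = [c for c in a.circles if c.kz_index == kz]
            cb = [c for c in b.circles if c.kz_index == kz]
            assert len(ca) == len(cb)
        assert a.circles != b.circles

    def test_ellipsoid_vs_cylinder_ratio_converges_to_three_halves(self):
        grid = em.GridSpec(64, 0.22, n_z=257, fov_z=0.257)
        R = grid.kmax / 4
        ell = em.design_stack(grid, R, af=1.0, seed=0, coverage="ellipsoid")
        cyl = em.design_stack(grid, R, af=1.0, seed=0, coverage="cylinder")
        ratio = cyl.n_circles / ell.n_circles
        assert abs(ratio - 1.5) < 0.02 * 1.5

    def test_radius_clamped_with_warning_on_edge_partitions(self):
        grid = em.GridSpec(64, 0.22, n_z=31, fov_z=0.105)
        plan = em.design_stack(grid, grid.kmax / 2, af=1.0, seed=0)
        assert any("clamped" in w for w in plan.warnings)


class TestComparators:
    @pytest.mark.parametrize("af,expected", [(1, 101), (2, 51), (3, 34)])
    def test_rosette_counts(self, grid64, af, expected):
        assert em.design_comparators(grid64, "rosette", af=af).n_circles == expected

    @pytest.mark.parametrize("af,expected", [(1, 31), (2, 16), (3, 11)])
    def test_concentric_counts(self, grid64, af, expected):
        assert em.design_comparators(grid64, "concentric", af=af).n_circles == expected

    def test_concentric_radii_below_kmax(self, grid64):
        plan = em.design_comparators(grid64, "concentric", af=1)
        for c in plan.circles:
            assert c.r_c == 0.0
            assert c.R < grid64.kmax

    @pytest.mark.parametrize("af,expected", [(1, 202), (2, 101), (3, 67)])
    def test_uniform_counts_match_eccentric_rule(self, grid64, af, expected):
        plan = em.design_comparators(grid64, "uniform", af=af, seed=0)
        assert plan.n_circles == expected

    def test_unknown_family_rejected(self, grid64):
        with pytest.raises(ValueError):
            em.design_comparators(grid64, "spiral")


class TestSamplePoints:
    def test_chord_bound_and_shape(self, plan16):
        pts = em.sample_points(plan16)
        m = plan16.samples_per_rev
        assert pts.shape == (plan16.n_circles, m, 2)
        R = plan16.circles[0].R
        chords = np.hypot(*np.diff(pts, axis=1, append=pts[:, :1]).T)
        assert chords.max() <= 2 * math.pi * R / m + 1e-9

    def test_default_samples_per_rev_is_circumference_nyquist(self, grid64):
        plan = design_eccentric_2d(grid64, grid64.kmax / 4, seed=0)
        assert plan.samples_per_rev == math.ceil(
            2 * math.pi * (grid64.kmax / 4) * grid64.fov_xy)  # 51 for n=64

    def test_containment_of_all_samples(self, grid64):
        for seed in range(3):
            plan = design_eccentric_2d(grid64, grid64.kmax / 2, af=2, seed=seed)
            pts = em.sample_points(plan).reshape(-1, 2)
            assert np.hypot(*pts.T).max() <= grid64.kmax + grid64.dk / 2 + 1e-9


class TestGradientDemand:
    def test_worked_values(self):
        gd = em.gradient_demand(8 / 0.22, 2280.0)
        assert gd.amplitude == pytest.approx(12.235, rel=1e-3)
        assert gd.slew == pytest.approx(175.3, rel=1e-3)

    def test_matches_numerical_waveform_differentiation(self, grid64):
        # oracle: differentiate the sampled k-space waveform twice
        R, sbw = grid64.kmax / 4, 2280.0
        gamma_bar = 42.577e6
        m = 4096
        t = np.arange(m) / (m * sbw)
        k = R * np.stack([np.cos(2 * np.pi * sbw * t),
                          np.sin(2 * np.pi * sbw * t)])
        g = np.gradient(k, t, axis=1) / gamma_bar  # T/m
        s = np.gradient(g, t, axis=1)
        amp_num = np.hypot(*g).max() * 1e3
        slew_num = np.hypot(*s).max()
        gd = em.gradient_demand(R, sbw)
        assert gd.amplitude == pytest.approx(amp_num, rel=1e-3)
        assert gd.slew == pytest.approx(slew_num, rel=1e-2)

    def test_linearity_in_radius_and_bandwidth(self):
        gd = em.gradient_demand(10.0, 1000.0)
        half = em.gradient_demand(5.0, 1000.0)
        assert half.amplitude == pytest.approx(gd.amplitude / 2)
        assert half.slew == pytest.approx(gd.slew / 2)
        double_bw = em.gradient_demand(10.0, 2000.0)
        assert double_bw.amplitude == pytest.approx(2 * gd.amplitude)
        assert double_bw.slew == pytest.approx(4 * gd.slew)


class TestMaxSbw:
    def test_worked_value(self):
        sbw = em.max_sbw(8 / 0.22, {"g_max": 80.0, "s_max": 200.0})
        assert sbw == pytest.approx(2436.0, rel=2e-3)

    def test_round_trip_satisfies_limits(self):
        limits = {"g_max": 40.0, "s_max": 180.0}
        R = 20.0
        sbw = em.max_sbw(R, limits)
        gd = em.gradient_demand(R, sbw)
        assert gd.amplitude <= limits["g_max"] * (1 + 1e-9)
        assert gd.slew <= limits["s_max"] * (1 + 1e-9)

    def test_infinite_limits_unbounded(self):
        assert em.max_sbw(10.0, {}) == math.inf


class TestTiming:
    def test_protocol_acquisition_times(self):
        t = em.sequence_timing(4072, 0.275, n_time=500, sbw=2280.0)
        assert t.ta == pytest.approx(1119.8)
        assert format_ta(t.ta) == "18 min 40 s"
        assert t.fid_duration == pytest.approx(0.2193, abs=1e-4)
        t4 = em.sequence_timing(1018, 0.275)
        assert t4.ta == pytest.approx(279.95)
        assert format_ta(t4.ta) == "4 min 40 s"

    def test_plan_timing_uses_circle_count(self, plan16):
        t = em.timing(plan16, 0.5)
        assert t.n_excitations == plan16.n_circles
        assert t.ta == pytest.approx(plan16.n_circles * 0.5)


class TestVoronoi:
    def test_cartesian_interior_weights_equal_dk_squared(self, grid16):
        dk = grid16.dk
        kk = (np.arange(16) - 8) * dk
        KX, KY = np.meshgrid(kk, kk, indexing="ij")
        pts = np.column_stack([KX.ravel(), KY.ravel()])
        w = em.voronoi_density(pts, clip_radius=grid16.kmax + dk / 2)
        interior = np.hypot(pts[:, 0], pts[:, 1]) < grid16.kmax - 2 * dk
        assert np.allclose(w[interior], dk**2, rtol=1e-9)

    def test_weights_partition_the_disc(self, plan16):
        w = plan_sample_weights(plan16)
        clip = plan16.grid.kmax + plan16.grid.dk / 2
        n_arc = 4096
        poly_area = 0.5 * n_arc * clip**2 * math.sin(2 * math.pi / n_arc)
        assert np.sum(w) == pytest.approx(poly_area, rel=1e-6)
        assert np.all(w > 0)

    def test_concentric_ring_weights_grow_with_radius(self, grid64):
        plan = em.design_comparators(grid64, "concentric", af=1)
        pts = em.sample_points(plan)
        w = plan_sample_weights(plan).reshape(pts.shape[:2])
        ring_mean = w.mean(axis=1)
        radii = np.array([c.R for c in plan.circles])
        order = np.argsort(radii)
        # oracle: annulus area between ring mid-lines ~ 2 pi r dk / m
        m = plan.samples_per_rev
        expected = 2 * math.pi * radii * grid64.dk / m
        inner = order[1:-1]  # boundary rings are clipped differently
        ratio = ring_mean[inner] / expected[inner]
        assert np.all(np.abs(ratio - 1) < 0.25)
        assert np.all(np.diff(ring_mean[order]) > -1e-12)

    def test_coincident_points_share_area(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-1, 1, size=(30, 2))
        dup = np.vstack([base, base[:3]])
        w = em.voronoi_density(dup, clip_radius=2.0)
        for i in range(3):
            assert w[i] == pytest.approx(w[30 + i])
            assert w[i] > 0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 8), np.zeros(8)])
        with pytest.raises(ValueError):
            em.voronoi_density(pts, clip_radius=2.0)


class TestSubsample:
    def test_keeps_requested_count_and_central_circles(self, grid64):
        plan = design_eccentric_2d(grid64, grid64.kmax / 4, af=1.0, seed=7)
        sub, keep = em.subsample_plan(plan, 4.0, seed=3)
        assert sub.n_circles == round(plan.n_circles / 4)
        assert len(keep) == sub.n_circles
        central = [c for c in plan.circles if abs(c.r_c - c.R) < 1e-12]
        assert all(c in sub.circles for c in central)
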
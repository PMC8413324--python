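"""Generator correctness: point processes, cell geometry, rendering."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.distance import pdist

from cortex3d.synthetic import (SceneParams, generate_scene, render_stack,
                                simulate_columnar_pattern,
                                simulate_csr_pattern, solve_spheroid_axes,
                                spheroid_sphericity, synthesize_cells)


def make_params(**kw):
    defaults = dict(window_box=(100.0, 100.0, 100.0), hardcore_distance=0.0,
                    seed=0)
    defaults.update(kw)
    return SceneParams(**defaults)


class TestColumnarPattern:
    def test_zero_column_intensity_gives_empty_pattern(self):
        pat = simulate_columnar_pattern(make_params(column_intensity=0.0))
        assert pat.n == 0

    def test_mean_count_matches_compound_poisson(self):
        # E[N] = column_intensity * Ly * Lz * points_per_column_mean = 200
        p = make_params(column_intensity=1e-3, points_per_column_mean=20.0,
                        column_radius_sd=5.0)
        counts = [simulate_columnar_pattern(p, seed=s).n for s in range(200)]
        counts = np.asarray(counts, dtype=float)
        mc_sd = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 200.0) < 3 * mc_sd + 1e-9

    def test_hardcore_thinning_enforces_min_distance(self):
        p = make_params(column_intensity=2e-3, points_per_column_mean=10.0,
                        hardcore_distance=10.0, seed=3)
        pat = simulate_columnar_pattern(p)
        assert pat.n > 2
        assert pdist(pat.points).min() >= 10.0

    def test_all_points_inside_window_and_reproducible(self):
        p = make_params(column_intensity=1e-3, points_per_column_mean=10.0,
                        seed=7)
        a = simulate_columnar_pattern(p)
        b = simulate_columnar_pattern(p)
        assert np.array_equal(a.points, b.points)
        assert a.window.contains(a.points).all()

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SceneParams(window_box=(0.0, 100.0, 100.0))

    def test_wide_columns_degenerate_to_csr(self):
        """σ_r → ∞ erases the columnar signal (envelope contains K̂)."""
        from cortex3d.pointpattern import global_envelope_test

        p = make_params(window_box=(120.0, 120.0, 120.0),
                        column_intensity=4e-4, points_per_column_mean=12.0,
                        column_radius_sd=400.0)
        inside = 0
        n_rep = 10
        for s in range(n_rep):
            pat = simulate_columnar_pattern(p, seed=100 + s)
            env = global_envelope_test(
                pat, "x", r_grid=np.linspace(0, 25, 16), t_grid=[60.0],
                nsim=99, seed=900 + s)
            inside += not env.reject
        assert inside >= int(0.9 * n_rep) - 1


class TestCSRPattern:
    def test_zero_points(self):
        assert simulate_csr_pattern((1, 1, 1), n=0, seed=0).n == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            simulate_csr_pattern((1, 1, 1), n=-1, seed=0)
        with pytest.raises(ValueError):
            simulate_csr_pattern((1, 1, 1), intensity=-2.0, seed=0)

    def test_uniform_coordinate_means(self):
        pat = simulate_csr_pattern((1.0, 1.0, 1.0), n=10_000, seed=5)
        se = (1.0 / math.sqrt(12.0)) / math.sqrt(10_000)
        assert np.all(np.abs(pat.points.mean(axis=0) - 0.5) < 3 * se)

    def test_poisson_count_variance(self):
        # intensity * |W| = 50; over 1000 seeds the count variance ≈ 50
        counts = [simulate_csr_pattern((10.0, 10.0, 10.0), intensity=0.05,
                                       seed=s).n for s in range(1000)]
        var = np.var(counts, ddof=1)
        # Var(S²) ≈ (μ₄ − σ⁴)/n for Poisson(50): sd ≈ 2.25
        assert abs(var - 50.0) < 3 * 2.25

    def test_intensity_estimate_unbiased(self):
        ints = [simulate_csr_pattern((20.0, 20.0, 20.0), intensity=0.01,
                                     seed=s).intensity for s in range(500)]
        ints = np.asarray(ints)
        mc_sd = ints.std(ddof=1) / np.sqrt(len(ints))
        assert abs(ints.mean() - 0.01) < 3 * mc_sd


class TestCellGeometry:
    def test_sphere_request_yields_exact_radius(self):
        axes = solve_spheroid_axes(4188.790205, 1.0)
        assert np.allclose(axes, 10.0, atol=1e-6)

    def test_prolate_solution_matches_quadrature_oracle(self):
        # surface of revolution: A = 2π ∫ y(x) sqrt(1 + y'(x)²) dx
        axes = solve_spheroid_axes(167.5516, 0.7327)
        a, b = axes[0], axes[1]

        def integrand(x):
            y = b * math.sqrt(max(0.0, 1 - (x / a) ** 2))
            if y == 0:
                return 0.0
            dy = -b * x / (a * a * math.sqrt(1 - (x / a) ** 2))
            return y * math.sqrt(1 + dy * dy)

        area, _ = quad(integrand, -a * (1 - 1e-12), a * (1 - 1e-12),
                       limit=200)
        area *= 2 * math.pi
        vol = 4 / 3 * math.pi * a * b * b
        psi = math.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area
        assert axes == pytest.approx((10.0, 2.0, 2.0), rel=2e-3)
        assert psi == pytest.approx(0.7327, rel=1e-3)

    def test_unsatisfiable_sphericity_rejected(self):
        with pytest.raises(ValueError, match="sphericity"):
            solve_spheroid_axes(100.0, 1.2)

    def test_zero_concentration_aligns_all_cells_with_x(self):
        p = make_params(column_intensity=1e-3, points_per_column_mean=5.0,
                        orientation_concentration=0.0)
        pat = simulate_columnar_pattern(p, seed=1)
        cells = synthesize_cells(pat, p, seed=2)
        for c in cells:
            if c.class_label == "pyramidal":
                assert np.allclose(c.orientation, (1.0, 0.0, 0.0))

    def test_sphericity_monotone_in_aspect(self):
        xs = np.linspace(0.05, 1.0, 30)
        psis = [spheroid_sphericity(x) for x in xs]
        assert np.all(np.diff(psis) > 0)
        assert psis[-1] == pytest.approx(1.0)


class TestRendering:
    def test_noise_free_stack_is_two_valued(self):
        p = make_params(window_box=(30.0, 30.0, 30.0), psf_sigma=0.0,
                        noise_sd=0.0, column_intensity=1e-3,
                        points_per_column_mean=4.0, seed=11)
        scene = generate_scene(p)
        vals = np.unique(scene.stack.data)
        assert set(vals.tolist()) <= {int(p.cell_level),
                                      int(p.background_level)}

    def test_single_sphere_volume_within_two_percent(self):
        from cortex3d.synthetic import GroundTruthCell

        p = make_params(window_box=(40.0, 40.0, 40.0),
                        voxel_spacing=(0.272, 0.272, 0.9))
        cell = GroundTruthCell(1, (20.0, 20.0, 20.0), (10.0, 10.0, 10.0),
                               (1.0, 0.0, 0.0), "pyramidal")
        scene = render_stack([cell], p)
        vol = (scene.truth_labels.data > 0).sum() * \
            scene.truth_labels.voxel_volume
        assert vol == pytest.approx(4188.790205, rel=0.02)

    def test_scene_labelled_volume_matches_analytic_within_three_percent(
            self, small_scene):
        # restrict to cells whose ellipsoid lies fully inside the window
        # (border cells are clipped by construction)
        lo = np.zeros(3)
        hi = np.asarray(small_scene.params.window_box)
        counts = np.bincount(small_scene.truth_labels.data.ravel())
        vox = small_scene.truth_labels.voxel_volume
        analytic = labelled = 0.0
        for c in small_scene.cells:
            a = c.semi_axes[0]
            if np.all(c.centroid - a >= lo) and np.all(c.centroid + a <= hi):
                analytic += c.volume
                if c.id < len(counts):
                    labelled += counts[c.id] * vox
        assert analytic > 0
        assert labelled == pytest.approx(analytic, rel=0.03)

    def test_fixed_seed_reproducible(self):
        p = make_params(window_box=(25.0, 25.0, 25.0), column_intensity=1e-3,
                        points_per_column_mean=4.0, seed=9)
        s1 = generate_scene(p)
        s2 = generate_scene(p)
        assert np.array_equal(s1.stack.data, s2.stack.data)
        assert np.array_equal(s1.truth_labels.data, s2.truth_labels.data)
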
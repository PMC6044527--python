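"""Signed distance, curvature, joint guidance and the deformable-boundary
evolution, including the per-b-value segmentation orchestration."""

import itertools

import numpy as np
import pytest

from renalseg import lcdg, levelset, metrics, mgrf4, phantom, preprocess
from renalseg import shape_prior as sp
from renalseg.io_volumes import RegionMap, Volume


def _ball_mask(dims, r, center=None):
    c = center or tuple((n - 1) / 2 for n in dims)
    x, y, z = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    return ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r * r


class TestSignedDistance:
    def test_single_voxel_object(self):
        m = np.zeros((7, 7, 7), dtype=np.uint8)
        m[3, 3, 3] = 1
        phi = levelset.signed_distance(RegionMap(m))
        assert phi.phi[3, 3, 3] == 0.0
        assert (phi.phi <= 0).all()

    def test_sphere_center_distance_close_to_radius(self):
        # odd dims put the center on-lattice; half-integer radius keeps the
        # boundary voxel shell within half a voxel of the continuous sphere
        r = 10.5
        mask = _ball_mask((33, 33, 33), r, center=(16, 16, 16))
        phi = levelset.signed_distance(RegionMap(mask.astype(np.uint8)))
        assert abs(phi.phi[16, 16, 16] - r) <= 1.0

    def test_sign_convention_inside_positive_outside_negative(self):
        mask = _ball_mask((16, 16, 16), 5.0)
        m = RegionMap(mask.astype(np.uint8))
        phi = levelset.signed_distance(m)
        from renalseg.levelset import _boundary_voxels

        boundary = _boundary_voxels(m.labels)
        interior = mask & ~boundary
        assert (phi.phi[interior] > 0).all()
        assert (phi.phi[~mask] < 0).all()
        assert (phi.phi[boundary] == 0).all()

    def test_matches_brute_force_on_8cube(self):
        rng = np.random.default_rng(0)
        m = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
        if m.min() == m.max():
            m[0, 0, 0] = 1 - m[0, 0, 0]
        phi = levelset.signed_distance(RegionMap(m))
        from renalseg.levelset import _boundary_voxels

        bnd = np.argwhere(_boundary_voxels(m))
        for p in itertools.product(range(8), repeat=3):
            d = np.sqrt(((bnd - np.asarray(p)) ** 2).sum(axis=1)).min()
            expected = d if m[p] else -d
            assert phi.phi[p] == pytest.approx(expected, abs=1e-9)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            levelset.signed_distance(RegionMap(np.ones((4, 4, 4), dtype=np.uint8)))


class TestCurvature:
    def test_planar_interface_flat(self):
        phi = np.broadcast_to(
            np.arange(32, dtype=float)[:, None, None] - 15.5, (32, 32, 32)
        ).copy()
        k = levelset.mean_curvature(levelset.LevelSetField(phi, (1, 1, 1)))
        band = np.abs(phi) < 2
        assert np.abs(k[band]).max() < 1e-6

    @pytest.mark.parametrize("r", [10.0, 12.0])
    def test_sphere_curvature_two_over_r(self, r):
        mask = _ball_mask((40, 40, 40), r)
        phi = levelset.signed_distance(RegionMap(mask.astype(np.uint8)))
        k = levelset.mean_curvature(phi)
        band = np.abs(phi.phi) < 1.0
        assert k[band].mean() == pytest.approx(2.0 / r, rel=0.15)

    def test_sign_flips_with_phi_negation(self):
        mask = _ball_mask((24, 24, 24), 7.0)
        phi = levelset.signed_distance(RegionMap(mask.astype(np.uint8)))
        k = levelset.mean_curvature(phi)
        k_neg = levelset.mean_curvature(
            levelset.LevelSetField(-phi.phi, phi.spacing)
        )
        band = np.abs(phi.phi) < 1.0
        np.testing.assert_allclose(k_neg[band], -k[band], atol=1e-9)


class TestGuidance:
    def _uniform_inputs(self, dims, pq1, pq0, prv1, prsp1, g_level=100):
        v = Volume(np.full(dims, g_level, dtype=int))
        pr = np.zeros((2, 256))
        pr[1, g_level] = pq1
        pr[0, g_level] = pq0
        sub = lcdg.ClassSubmodels(pr=pr, class_weights=np.array([0.5, 0.5]),
                                  threshold=128)
        prior = sp.ShapePrior(np.full(dims, prsp1))
        # potentials chosen so Pr_V:p(1) is uniform: zero potentials -> 0.5
        fams = mgrf4.default_families()
        V = mgrf4.GibbsPotentials.zeros(fams)
        m = RegionMap(np.zeros(dims, dtype=np.uint8))
        return v, m, prior, sub, V, fams

    def test_plugin_values_match_hand_computation(self, monkeypatch):
        """Omega_kd = 0.8*0.9*0.75, Omega_bg = 0.2*0.1*0.25 -> Pr ~ 0.9908."""
        dims = (5, 5, 5)
        v = Volume(np.full(dims, 100, dtype=int))
        pr = np.zeros((2, 256))
        pr[1, 100], pr[0, 100] = 0.8, 0.2
        sub = lcdg.ClassSubmodels(pr=pr, class_weights=np.array([0.5, 0.5]),
                                  threshold=128)
        prior = sp.ShapePrior(np.full(dims, 0.75))
        monkeypatch.setattr(
            levelset.mgrf4, "spatial_probability_volume",
            lambda m, V, fams=None: np.full(dims, 0.9),
        )
        fams = mgrf4.default_families()
        V = mgrf4.GibbsPotentials.zeros(fams)
        m = RegionMap(np.zeros(dims, dtype=np.uint8))
        g = levelset.guidance(v, m, prior, sub, V, fams)
        np.testing.assert_allclose(g.pr1, 0.54 / 0.545)
        np.testing.assert_allclose(g.pr1, 0.9908, atol=1e-4)
        np.testing.assert_allclose(g.theta, -0.9908, atol=1e-4)

    def test_all_factors_half_gives_background_branch(self):
        dims = (4, 4, 4)
        v, m, prior, sub, V, fams = self._uniform_inputs(
            dims, pq1=0.5, pq0=0.5, prv1=0.5, prsp1=0.5
        )
        g = levelset.guidance(v, m, prior, sub, V, fams)
        np.testing.assert_allclose(g.pr1, 0.5)
        np.testing.assert_allclose(g.theta, 0.5)  # Eq-10 otherwise branch

    def test_zero_mass_fallback(self):
        dims = (4, 4, 4)
        v, m, prior, sub, V, fams = self._uniform_inputs(
            dims, pq1=0.0, pq0=0.0, prv1=0.5, prsp1=0.5
        )
        g = levelset.guidance(v, m, prior, sub, V, fams)
        np.testing.assert_allclose(g.pr1, 0.5)
        np.testing.assert_allclose(g.theta, 0.5)

    def test_probabilities_normalized_for_random_inputs(self):
        rng = np.random.default_rng(5)
        dims = (6, 6, 6)
        v = Volume(rng.integers(0, 256, dims))
        pr = rng.random((2, 256))
        pr /= pr.sum(axis=1, keepdims=True)
        sub = lcdg.ClassSubmodels(pr=pr, class_weights=np.array([0.5, 0.5]),
                                  threshold=128)
        prior = sp.ShapePrior(rng.random(dims))
        m = RegionMap((rng.random(dims) < 0.5).astype(np.uint8))
        fams = mgrf4.default_families()
        V = mgrf4.estimate_potentials(mgrf4.config_frequencies(m, fams))
        g = levelset.guidance(v, m, prior, sub, V, fams)
        np.testing.assert_allclose(g.pr1 + g.pr0, 1.0)
        assert np.all(np.abs(g.theta) <= 1.0)
        # Eq 10 case split: theta negative exactly where kidney has majority
        np.testing.assert_array_equal(g.theta < 0, g.pr1 > 0.5)


class TestBayesInitialMap:
    def test_uniform_prior_reduces_to_likelihood_ratio(self):
        rng = np.random.default_rng(1)
        dims = (6, 6, 6)
        v = Volume(rng.integers(0, 256, dims))
        pr = rng.random((2, 256))
        pr /= pr.sum(axis=1, keepdims=True)
        sub = lcdg.ClassSubmodels(pr=pr, class_weights=np.array([0.5, 0.5]),
                                  threshold=128)
        m = levelset.bayes_initial_map(v, sp.ShapePrior.uniform(dims), sub)
        expected = pr[1][v.data] > pr[0][v.data]
        np.testing.assert_array_equal(m.labels.astype(bool), expected)

    def test_hard_prior_forces_map(self):
        dims = (8, 8, 8)
        ball = _ball_mask(dims, 3.0)
        prior = sp.ShapePrior(ball.astype(float))
        rng = np.random.default_rng(2)
        v = Volume(rng.integers(0, 256, dims))
        pr = np.full((2, 256), 1.0 / 256)
        sub = lcdg.ClassSubmodels(pr=pr, class_weights=np.array([0.5, 0.5]),
                                  threshold=128)
        m = levelset.bayes_initial_map(v, prior, sub)
        np.testing.assert_array_equal(m.labels.astype(bool), ball)

    def test_noise_free_phantom_initial_map(self):
        """Separated classes + adapted prior give a near-perfect Bayes map."""
        spec = phantom.PhantomSpec(seed=31, n_subjects=3, noise_sigma=0.0,
                                   bias_amplitude=0.0)
        series, truth = phantom.generate_subject(spec, 0)
        v = series.volumes[0]
        h = lcdg.build_histogram(v)
        sub = lcdg.split_classes(lcdg.fit_lcdg(h))
        prior = sp.ShapePrior(truth.labels * 0.9 + 0.05)
        m = levelset.bayes_initial_map(v, prior, sub)
        assert metrics.dsc(m, truth) >= 0.95


class TestEvolve:
    def test_uniform_kidney_pull_expands_sphere(self):
        mask = _ball_mask((32, 32, 32), 6.0)
        phi = levelset.signed_distance(RegionMap(mask.astype(np.uint8)))
        guide = levelset.GuidanceField(
            pr1=np.ones(mask.shape), theta=np.full(mask.shape, -0.8)
        )
        vol0 = mask.sum()
        volumes = [vol0]
        f = phi
        for _ in range(4):
            f = levelset.evolve(f, guide, n_max=10, reinit_every=0,
                                convergence_tol=0.0, patience=10**9)
            volumes.append(int(f.mask.sum()))
        assert all(v2 >= v1 for v1, v2 in zip(volumes, volumes[1:]))
        assert volumes[-1] > vol0

    def test_divergence_raises_with_trace(self):
        mask = _ball_mask((16, 16, 16), 2.0)
        phi = levelset.signed_distance(RegionMap(mask.astype(np.uint8)))
        guide = levelset.GuidanceField(
            pr1=np.zeros(mask.shape), theta=np.full(mask.shape, 0.9)
        )
        with pytest.raises(levelset.EvolutionError) as err:
            levelset.evolve(phi, guide, n_max=500, reinit_every=0,
                            convergence_tol=0.0, patience=10**9)
        assert isinstance(err.value.trace, list)

    def test_noise_free_guidance_reaches_truth(self):
        """Exact probabilities from a clean phantom drive DSC >= 0.98."""
        spec = phantom.PhantomSpec(seed=33, n_subjects=3, noise_sigma=0.0,
                                   bias_amplitude=0.0)
        series, truth = phantom.generate_subject(spec, 0)
        v = series.volumes[0]
        prior = sp.ShapePrior(truth.labels.astype(float) * 0.98 + 0.01)
        res = levelset.segment_bvalue(v, prior)
        assert metrics.dsc(res.mask, truth) >= 0.98
        # mask changes settle after burn-in
        trace = res.diagnostics["mask_change_trace"]
        if len(trace) > 10:
            assert np.mean(trace[-5:]) <= np.mean(trace[:5]) + 1e-9


class TestSegmentation:
    @pytest.fixture(scope="class")
    def fold(self, small_cohort, small_db):
        spec = phantom.PhantomSpec(seed=11, n_subjects=8)
        series, truth = phantom.generate_subject(spec, 7)
        _, db = small_db
        return series, truth, db

    def test_series_segmentation_accuracy_all_b(self, fold):
        series, truth, db = fold
        results = levelset.segment_series(series, db)
        assert len(results) == len(series.b_values)
        for r in results:
            assert metrics.dsc(r.mask, truth) >= 0.90

    def test_per_b_appearance_models_differ_but_prior_shared(self, fold):
        """Kidney dominant means shift down with b under one shared prior."""
        series, truth, db = fold
        cfg = levelset.SegmentationConfig()
        vols = [preprocess.preprocess_volume(v) for v in series.volumes]
        field = sp.align_test(vols[0], db)
        prior = sp.adapt_shape_prior(vols[0], db, field=field)
        thresholds = []
        for v in series.volumes:
            sub = levelset._fit_appearance(v, prior, cfg)
            thresholds.append(sub.threshold)
        assert len(set(thresholds)) > 1  # per-b appearance models differ

    def test_deterministic_masks(self, fold):
        series, truth, db = fold
        r1 = levelset.segment_series(series, db)
        r2 = levelset.segment_series(series, db)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.mask.labels, b.mask.labels)

    def test_single_b0_series_reduces_to_segment_bvalue(self, fold):
        series, truth, db = fold
        from renalseg.io_volumes import DWISeries

        single = DWISeries(b_values=(0.0,), volumes=[series.volumes[0]],
                           subject_id=series.subject_id)
        res = levelset.segment_series(single, db)
        assert len(res) == 1
        assert metrics.dsc(res[0].mask, truth) >= 0.90

    def test_series_without_b0_rejected(self, fold):
        series, _, db = fold
        from renalseg.io_volumes import DWISeries

        no_b0 = DWISeries(b_values=series.b_values[1:],
                          volumes=series.volumes[1:],
                          subject_id=series.subject_id)
        with pytest.raises(ValueError, match="b0"):
            levelset.segment_series(no_b0, db)

    def test_invalid_mgrf_order_rejected(self, fold):
        series, _, db = fold
        v = series.volumes[0]
        prior = sp.ShapePrior.uniform(v.dims)
        with pytest.raises(RuntimeError, match="mgrf_order"):
            levelset.segment_bvalue(
                v, prior, levelset.SegmentationConfig(mgrf_order=3)
            )
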
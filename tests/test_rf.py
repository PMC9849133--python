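import numpy as np
import pytest

import vpngrad as v
from vpngrad.io import DENDRITE_ENDPOINT


def _arbor(name, pts):
    pts = np.asarray(pts, float)
    return v.ArborPointCloud(name, pts, np.array([DENDRITE_ENDPOINT] * len(pts), object))


@pytest.fixture(scope="module")
def flat_surface():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-5, 5, 200), rng.uniform(-5, 5, 200), np.zeros(200)])
    return v.fit_surface(pts)


@pytest.fixture(scope="module")
def eye_frame():
    # surface origin -> eye centre (65, 0); 5 units dorsal -> (65, 45)
    return v.EyeFrame([[0, 0], [0, 5]], [[65, 0], [65, 45]])


class TestSurfaceFit:
    def test_plane_has_zero_quadratic_terms_and_residual(self, flat_surface):
        a, b, c, d, e, f = flat_surface.coefficients
        assert flat_surface.residual == pytest.approx(0.0, abs=1e-9)
        for coef in (d, e, f):
            assert coef == pytest.approx(0.0, abs=1e-9)

    def test_paraboloid_recovery(self):
        g = np.linspace(-1, 1, 15)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), (xx**2 + yy**2).ravel()])
        surf = v.fit_surface(pts)
        assert surf.residual == pytest.approx(0.0, abs=1e-6)
        a, b, c, d, e, f = surf.coefficients
        # frame axes may be flipped/swapped; the symmetric quadratic survives
        assert abs(d) == pytest.approx(1.0, abs=1e-6)
        assert abs(f) == pytest.approx(1.0, abs=1e-6)
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            v.fit_surface(np.zeros((5, 3)))

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            v.fit_surface(pts)


class TestArborToRF:
    def test_unit_peak_before_weighting(self, flat_surface, eye_frame):
        arbor = _arbor("a", [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        rf = v.arbor_to_rf(arbor, flat_surface, eye_frame)
        assert rf.height == 1.0
        az, el = rf.centre
        assert rf.value(az, el) == pytest.approx(1.0)

    def test_equal_area_circle_width(self, flat_surface, eye_frame):
        # square polygon of area pi in surface units -> sigma = 1 unit * scale
        s = np.sqrt(np.pi)
        arbor = _arbor("a", [[0, 0, 0], [s, 0, 0], [0, s, 0], [s, s, 0]])
        rf = v.arbor_to_rf(arbor, flat_surface, eye_frame)
        assert rf.sigma_deg == pytest.approx(1.0 * eye_frame.scale, rel=1e-6)

    def test_cutoff_width_mode_halves_sigma(self, flat_surface, eye_frame):
        arbor = _arbor("a", [[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]])
        rf_s = v.arbor_to_rf(arbor, flat_surface, eye_frame, width_mode="sigma")
        rf_c = v.arbor_to_rf(arbor, flat_surface, eye_frame, width_mode="cutoff")
        assert rf_c.sigma_deg == pytest.approx(rf_s.sigma_deg / 2)

    def test_anchors_map_to_assigned_eye_coordinates(self, eye_frame):
        np.testing.assert_allclose(eye_frame.to_eye([[0, 0]]), [[65, 0]], atol=1e-12)
        np.testing.assert_allclose(eye_frame.to_eye([[0, 5]]), [[65, 45]], atol=1e-12)

    def test_too_few_endpoints_rejected(self, flat_surface, eye_frame):
        with pytest.raises(ValueError, match=">= 3"):
            v.arbor_to_rf(_arbor("a", [[0, 0, 0], [1, 1, 0]]), flat_surface, eye_frame)

    def test_identical_anchor_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            v.EyeFrame([[0, 0], [0, 0]], [[65, 0], [65, 45]])


class TestDnResponse:
    def test_contribution_is_connections_times_covered_fraction(self):
        rf = v.GaussianRF((50, 0), sigma_deg=10.0)
        # concentric stimulus with radius sigma*sqrt(0.4) covers exactly 40%
        stim = v.LoomingStimulus(
            mode="constant_angular_velocity",
            max_diameter_deg=2 * 10.0 * np.sqrt(0.4),
            centre=(50, 0),
        )
        assert v.overlap_fraction(rf, stim) == pytest.approx(0.4)
        resp = v.dn_response(v.DnRF([(rf, 7.0)]), stim)
        assert resp == pytest.approx(7.0 * 0.4)

    def test_non_overlapping_cells_contribute_nothing(self):
        rfs = [v.GaussianRF((0, 0), 5.0), v.GaussianRF((100, 0), 5.0)]
        stim = v.LoomingStimulus(mode="constant_angular_velocity", max_diameter_deg=30, centre=(0, 0))
        resp = v.dn_response(v.DnRF([(rfs[0], 3.0), (rfs[1], 1000.0)]), stim)
        assert resp == pytest.approx(3.0 * v.overlap_fraction(rfs[0], stim))

    def test_full_coverage_sums_weights(self):
        rfs = [v.GaussianRF((60 + dx, 0), 2.0) for dx in (-3, 0, 3)]
        stim = v.LoomingStimulus(mode="constant_angular_velocity", max_diameter_deg=60, centre=(60, 0))
        resp = v.dn_response(v.DnRF([(r, w) for r, w in zip(rfs, [1.0, 2.0, 3.5])]), stim)
        assert resp == pytest.approx(6.5)

    def test_negative_weight_rejected(self):
        rf = v.GaussianRF((0, 0), 5.0)
        stim = v.LoomingStimulus(mode="constant_angular_velocity", max_diameter_deg=30)
        with pytest.raises(ValueError, match="negative"):
            v.dn_response(v.DnRF([(rf, -1.0)]), stim)

    def test_linear_in_weight_vector(self):
        rng = np.random.default_rng(0)
        rfs = [v.GaussianRF((rng.uniform(30, 70), rng.uniform(-20, 20)), 8.0) for _ in range(6)]
        w1, w2 = rng.uniform(0, 10, 6), rng.uniform(0, 10, 6)
        stim = v.LoomingStimulus(mode="constant_angular_velocity", max_diameter_deg=30, centre=(50, 0))

        def resp(w):
            return v.dn_response(v.DnRF(list(zip(rfs, w))), stim)

        assert resp(2.0 * w1) == pytest.approx(2.0 * resp(w1))
        assert resp(w1 + w2) == pytest.approx(resp(w1) + resp(w2))


class TestHemifieldProfile:
    template = v.LoomingStimulus(mode="constant_angular_velocity", max_diameter_deg=30, centre=(0, 0))

    def test_normalized_to_unit_maximum(self, tiling_rf_population):
        dn = v.DnRF([(rf, 5.0) for rf in tiling_rf_population])
        curve = v.hemifield_profile(dn, np.linspace(30, 100, 8), self.template)
        assert curve.max() == 1.0

    def test_uniform_weights_give_flat_tuning(self, tiling_rf_population):
        dn = v.DnRF([(rf, 5.0) for rf in tiling_rf_population])
        curve = v.hemifield_profile(dn, np.linspace(30, 100, 15), self.template)
        assert (curve.max() - curve.min()) / curve.max() < 0.05

    def test_monotone_gradient_gives_monotone_tuning(self, tiling_rf_population):
        dn = v.DnRF([(rf, 20.0 + rf.centre[0]) for rf in tiling_rf_population])
        curve = v.hemifield_profile(dn, np.linspace(40, 90, 11), self.template)
        assert np.all(np.diff(curve) > 0)

    def test_empty_grid_rejected(self, tiling_rf_population):
        dn = v.DnRF([(rf, 1.0) for rf in tiling_rf_population])
        with pytest.raises(ValueError, match="empty"):
            v.hemifield_profile(dn, [], self.template)


class TestEndToEnd:
    def test_antiparallel_gradients_give_opposed_tuning(self, pair_connectome):
        """Planted opposite synaptic gradients must produce anticorrelated
        hemifield tuning with preferred azimuths at opposite ends."""
        cfg, arbors, matrix, _, _ = pair_connectome
        pts = np.vstack([a.dendrite_endpoints for a in arbors.values()])
        surf = v.fit_surface(pts)
        # anchors: lobula-sheet centre -> eye centre; dorsal-edge midpoint ->
        # dorsal point on the central meridian
        half = cfg.lobula_extent / 2
        anchors = surf.project(np.array([[half, half, 0.0], [half, cfg.lobula_extent, 0.0]]))
        frame = v.EyeFrame(anchors, [[65, 0], [65, 45]])
        rfs = {cid: v.arbor_to_rf(a, surf, frame) for cid, a in arbors.items()}
        az = np.linspace(30, 100, 15)
        tmpl = v.LoomingStimulus(mode="constant_angular_velocity", max_diameter_deg=30, centre=(0, 0))
        pa = v.hemifield_profile(v.build_dn_rf(rfs, matrix["DN_A"]), az, tmpl)
        pp = v.hemifield_profile(v.build_dn_rf(rfs, matrix["DN_P"]), az, tmpl)
        assert np.corrcoef(pa, pp)[0, 1] <= -0.8
        lo, hi = az[5], az[9]
        assert (az[pa.argmax()] < lo) != (az[pp.argmax()] < lo)
        assert min(az[pa.argmax()], az[pp.argmax()]) < lo
        assert max(az[pa.argmax()], az[pp.argmax()]) > hi
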
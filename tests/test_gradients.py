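import numpy as np
import pandas as pd
import pytest

import vpngrad as v
from vpngrad.io import DENDRITE_ENDPOINT


def _arbor(name, pts):
    pts = np.asarray(pts, float)
    return v.ArborPointCloud(name, pts, np.array([DENDRITE_ENDPOINT] * len(pts), object))


def _line_angle(direction):
    return np.degrees(np.arctan2(direction[1], direction[0])) % 180.0


class TestProjection:
    def test_square_corner_endpoints_average_to_centre(self, lobula_plane):
        arbor = _arbor("a", [[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]])
        pmap = v.project_dendrites([arbor], lobula_plane)
        np.testing.assert_allclose(pmap.centroids.loc["a"], [1, 1])

    def test_points_on_plane_project_identically(self):
        plane = v.CutPlane(anchor=[0, 0, 0], normal=[0, 0, 1], axes=[[1, 0, 0], [0, 1, 0]])
        pts = np.array([[0.3, -0.7, 0.0], [2.5, 1.5, 0.0], [1.1, 0.2, 0.0]])
        pmap = v.project_dendrites([_arbor("a", pts)], plane)
        np.testing.assert_allclose(pmap.centroids.loc["a"], pts[:, :2].mean(axis=0))

    def test_unit_square_hull_area_by_shoelace(self, lobula_plane):
        arbor = _arbor("a", [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        pmap = v.project_dendrites([arbor], lobula_plane)
        assert pmap.hull_area == pytest.approx(1.0)

    def test_cell_behind_plane_excluded_with_warning(self, lobula_plane):
        good = _arbor("good", [[0, 0, 0.5], [1, 1, 0.5], [1, 0, 0.5]])
        bad = _arbor("bad", [[0, 0, -5.0]])
        with pytest.warns(UserWarning, match="bad"):
            pmap = v.project_dendrites([good, bad], lobula_plane)
        assert list(pmap.centroids.index) == ["good"]


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        assert v.weighted_median([1.0, 2.0, 9.0], [1, 1, 1]) == 2.0

    def test_majority_weight_pins_centroid(self, lobula_plane):
        arbors = [_arbor(f"c{i}", [[i, i, 0]]) for i in range(4)]
        pmap = v.project_dendrites(arbors, lobula_plane)
        w = pd.Series([1, 1, 10, 1], index=[f"c{i}" for i in range(4)])
        np.testing.assert_allclose(v.weighted_input_centroid(pmap, w), [2, 2])

    def test_matches_expansion_oracle(self):
        values = np.array([0.0, 5.0, 7.0])
        weights = np.array([1, 2, 3])
        expanded = np.sort(np.repeat(values, weights))
        lower_median = expanded[(len(expanded) - 1) // 2]  # lower-median tie rule
        assert v.weighted_median(values, weights) == lower_median

    def test_all_zero_weights_rejected(self, lobula_plane):
        pmap = v.project_dendrites([_arbor("a", [[0, 0, 0]]), _arbor("b", [[1, 1, 0]])], lobula_plane)
        with pytest.raises(ValueError, match="weights"):
            v.weighted_input_centroid(pmap, pd.Series({"a": 0, "b": 0}))


class TestSeparation:
    def test_planted_antiparallel_gradient_recovers_x_axis(self, noiseless_pair_connectome):
        cfg, arbors, matrix, _, _ = noiseless_pair_connectome
        plane = v.CutPlane(anchor=[0, 0, -5], normal=[0, 0, 1], axes=[[1, 0, 0], [0, 1, 0]])
        pmap = v.project_dendrites(arbors, plane, weights=matrix)
        corr, _ = v.partner_correlation_matrix(matrix, top_n=2)
        geom = v.anticorrelated_separation(corr, pmap, matrix)
        angle = _line_angle(geom.projection_direction)
        assert min(angle, 180 - angle) < 5.0

    def test_single_pair_uses_exact_bisector(self, lobula_plane):
        # two partners anchored on two single-cell point masses
        arbors = [_arbor("a", [[0, 0, 0]]), _arbor("b", [[4, 2, 0]])]
        pmap = v.project_dendrites(arbors, lobula_plane)
        weights = pd.DataFrame({"p": {"a": 10, "b": 1}, "q": {"a": 1, "b": 10}})
        corr = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["p", "q"], columns=["p", "q"])
        geom = v.anticorrelated_separation(corr, pmap, weights)
        # centroids are the majority cells (0,0) and (4,2); bisector is
        # perpendicular to that segment through its midpoint
        seg = np.array([4.0, 2.0])
        assert abs(np.dot(geom.separation_direction, seg / np.linalg.norm(seg))) < 1e-12
        np.testing.assert_allclose(geom.separation_point, [2, 1])

    def test_rotation_equivariance(self, lobula_plane):
        arbors = [_arbor("a", [[0, 0, 0]]), _arbor("b", [[4, 0, 0]])]
        weights = pd.DataFrame({"p": {"a": 10, "b": 1}, "q": {"a": 1, "b": 10}})
        corr = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["p", "q"], columns=["p", "q"])
        g0 = v.anticorrelated_separation(corr, v.project_dendrites(arbors, lobula_plane), weights)
        th = np.deg2rad(30)
        rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        arbors_r = [_arbor(a.neuron_id, a.points @ rot.T) for a in arbors]
        g1 = v.anticorrelated_separation(corr, v.project_dendrites(arbors_r, lobula_plane), weights)
        assert _line_angle(g1.projection_direction) == pytest.approx(
            (_line_angle(g0.projection_direction) + 30) % 180, abs=1e-8
        )

    def test_no_anticorrelated_pairs_is_error(self, lobula_plane):
        pmap = v.project_dendrites([_arbor("a", [[0, 0, 0]]), _arbor("b", [[1, 0, 0]])], lobula_plane)
        weights = pd.DataFrame({"p": {"a": 1, "b": 2}, "q": {"a": 1, "b": 2}})
        corr = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["p", "q"], columns=["p", "q"])
        with pytest.raises(ValueError, match="no anticorrelated"):
            v.anticorrelated_separation(corr, pmap, weights)


class TestDistanceMatrix:
    @pytest.fixture()
    def geometry(self):
        return v.SeparationGeometry(
            threshold=-0.5,
            selected_pairs=[("p", "q")],
            separation_point=np.zeros(2),
            separation_direction=np.array([0.0, 1.0]),
            projection_direction=np.array([1.0, 0.0]),
            partner_centroids={"p": np.array([0.0, 3.0]), "q": np.array([10.0, -2.0]), "r": None},
        )

    def test_self_distance_zero_and_antisymmetry(self, geometry):
        d = v.centroid_distance_matrix(geometry)
        assert d.loc["p", "p"] == 0
        np.testing.assert_allclose(d.to_numpy()[:2, :2], -d.to_numpy()[:2, :2].T)

    def test_planted_offset_along_projection_line(self, geometry):
        d = v.centroid_distance_matrix(geometry)
        assert d.loc["q", "p"] == pytest.approx(10.0)

    def test_missing_centroid_gives_missing_entry(self, geometry):
        d = v.centroid_distance_matrix(geometry)
        assert np.isnan(d.loc["r", "p"])


class TestGradientFit:
    def test_exact_linear_counts(self):
        x = np.linspace(0, 10, 20)
        fit = v.gradient_fit(x, 3.0 * x + 2.0)
        assert fit.slope == pytest.approx(3.0)
        assert fit.spearman_rho == pytest.approx(1.0)

    def test_noiseless_antiparallel_rho_is_minus_one(self, noiseless_pair_connectome):
        _, _, matrix, _, _ = noiseless_pair_connectome
        assert v.pair_spearman(matrix["DN_A"], matrix["DN_P"]) == pytest.approx(-1.0)

    def test_zero_variance_coordinate_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            v.gradient_fit([1.0, 1.0, 1.0], [1, 2, 3])


def test_rigid_transform_leaves_distance_matrix_unchanged(pair_connectome):
    """Rotating and translating all 3D inputs (and the cut-plane with them)
    must not change projected geometry or signed distances."""
    _, arbors, matrix, _, _ = pair_connectome
    plane = v.CutPlane(anchor=[0, 0, -5], normal=[0, 0, 1], axes=[[1, 0, 0], [0, 1, 0]])
    corr, _ = v.partner_correlation_matrix(matrix, top_n=2)

    def run(arbs, pl):
        pmap = v.project_dendrites(arbs, pl, weights=matrix)
        geom = v.anticorrelated_separation(corr, pmap, matrix)
        return v.centroid_distance_matrix(geom)

    d0 = run(arbors, plane)
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = np.array([5.0, -3.0, 11.0])
    arbors_t = {
        k: v.ArborPointCloud(k, a.points @ q.T + shift, a.labels) for k, a in arbors.items()
    }
    plane_t = v.CutPlane(anchor=q @ plane.anchor + shift, normal=q @ plane.normal, axes=plane.axes @ q.T)
    d1 = run(arbors_t, plane_t)
    np.testing.assert_allclose(d0.to_numpy(float), d1.to_numpy(float), atol=1e-8)
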
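import numpy as np
import pytest

from brainclass.connectivity import (
    CorticalMesh,
    Streamline,
    StreamlineSet,
    aggregate_to_parcels,
    build_connectivity_matrix,
    compute_vertex_metrics,
    filter_streamlines,
    geodesic_neighborhood,
    smooth_vertex_map,
    streamline_mean_fa,
    turning_angles,
)
from brainclass.exceptions import InvalidInputError

from _oracles import all_pairs_geodesic_bruteforce


def polyline(*pts, fa=None):
    pts = np.asarray(pts, dtype=float)
    return Streamline(pts, np.full(len(pts), fa) if np.isscalar(fa) else fa)


def grid_mesh(nx=6, ny=6, spacing=1.0):
    """Flat regular grid triangulated into right triangles."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append([a, a + 1, a + nx])
            faces.append([a + 1, a + nx + 1, a + nx])
    return CorticalMesh(verts, np.array(faces))


class TestMeshInvariants:
    def test_vertex_areas_sum_to_total(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        assert mesh.vertex_areas.sum() == pytest.approx(mesh.total_area, rel=1e-6)
        assert (mesh.vertex_areas > 0).all()

    def test_degenerate_triangle_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], float)
        with pytest.raises(InvalidInputError, match="degenerate"):
            CorticalMesh(verts, np.array([[0, 1, 2], [0, 1, 3]]))

    def test_bad_face_index_rejected(self):
        verts = np.eye(3)
        with pytest.raises(InvalidInputError):
            CorticalMesh(verts, np.array([[0, 1, 5]]))


class TestFilterStreamlines:
    def test_straight_retained(self):
        s = polyline([0, 0, 0], [1, 0, 0], [2, 0, 0], fa=0.5)
        assert len(filter_streamlines(StreamlineSet((s,)))) == 1

    def test_right_angle_discarded(self):
        s = polyline([0, 0, 0], [1, 0, 0], [1, 1, 0], fa=0.5)
        assert len(filter_streamlines(StreamlineSet((s,)))) == 0

    @pytest.mark.parametrize("second_angle,kept", [(59.0, True), (61.0, False)])
    def test_threshold_boundary(self, second_angle, kept):
        """Angles {10 deg, ~59/61 deg} computed from explicit coordinates."""

        def bend(prev_dir, angle_deg):
            a = np.radians(angle_deg)
            c, s = np.cos(a), np.sin(a)
            return np.array(
                [c * prev_dir[0] - s * prev_dir[1], s * prev_dir[0] + c * prev_dir[1], 0]
            )

        p0 = np.zeros(3)
        d0 = np.array([1.0, 0, 0])
        p1 = p0 + d0
        d1 = bend(d0, 10.0)
        p2 = p1 + d1
        d2 = bend(d1, second_angle)
        p3 = p2 + d2
        s = Streamline(np.array([p0, p1, p2, p3]), np.full(4, 0.5))
        np.testing.assert_allclose(
            turning_angles(s.points), [10.0, second_angle], atol=1e-9
        )
        assert (len(filter_streamlines(StreamlineSet((s,)))) == 1) is kept

    def test_empty_input(self):
        assert len(filter_streamlines(StreamlineSet(()))) == 0

    def test_literal_rule_inverts(self):
        straight = polyline([0, 0, 0], [1, 0, 0], [2, 0, 0], fa=0.5)
        bent = polyline([0, 0, 0], [1, 0, 0], [1, 1, 0], fa=0.5)
        sset = StreamlineSet((straight, bent))
        literal = filter_streamlines(sset, literal_angle_rule=True)
        assert len(literal) == 1 and literal[0] is bent

    def test_order_preserved(self):
        lines = [polyline([0, 0, 0], [i + 1, 0, 0], fa=0.5) for i in range(5)]
        out = filter_streamlines(StreamlineSet(tuple(lines)))
        assert [id(s) for s in out] == [id(s) for s in lines]


class TestStreamlineMeanFA:
    def test_constant(self):
        s = polyline(*[[i, 0, 0] for i in range(10)], fa=0.5)
        assert streamline_mean_fa(s) == pytest.approx(0.5)

    def test_arithmetic(self):
        s = Streamline(
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float),
            np.array([0.2, 0.4, 0.6]),
        )
        assert streamline_mean_fa(s) == pytest.approx(0.4)

    def test_all_zero(self):
        s = polyline([0, 0, 0], [1, 0, 0], fa=0.0)
        assert streamline_mean_fa(s) == 0.0

    def test_missing_fa_errors(self):
        s = Streamline(np.array([[0, 0, 0], [1, 0, 0]], float))
        with pytest.raises(InvalidInputError):
            streamline_mean_fa(s)


class TestConnectivityMatrix:
    def test_single_streamline(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        s = Streamline(np.array([mesh.vertices[0], mesh.vertices[50]]), np.full(2, 0.5))
        cmat = build_connectivity_matrix(mesh, StreamlineSet((s,)), snap_radius=0.5)
        assert cmat.matrix[0, 50] == 1 and cmat.matrix[50, 0] == 1
        assert cmat.n_connections == 1

    def test_two_parallel_streamlines_add(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        s = Streamline(np.array([mesh.vertices[0], mesh.vertices[50]]), np.full(2, 0.5))
        cmat = build_connectivity_matrix(mesh, StreamlineSet((s, s)), snap_radius=0.5)
        assert cmat.matrix[0, 50] == 2
        assert cmat.n_connections == 2

    def test_out_of_range_endpoint_dropped(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        far = mesh.vertices[0] * 10
        s = Streamline(np.array([far, mesh.vertices[50]]), np.full(2, 0.5))
        cmat = build_connectivity_matrix(mesh, StreamlineSet((s,)), snap_radius=0.5)
        assert cmat.n_connections == 0 and cmat.n_unmapped == 1
        assert cmat.matrix.nnz == 0

    def test_symmetry_nonnegativity(self, sphere_fixture):
        mesh, streams, _ = sphere_fixture
        cmat = build_connectivity_matrix(mesh, streams, snap_radius=0.5)
        m = cmat.matrix
        assert (m != m.T).nnz == 0
        assert (m.data >= 0).all()
        assert m.diagonal().sum() == 0

    def test_total_equals_upper_triangle(self, sphere_fixture):
        import scipy.sparse as sp

        mesh, streams, _ = sphere_fixture
        cmat = build_connectivity_matrix(mesh, streams, snap_radius=0.5)
        assert cmat.n_connections == sp.triu(cmat.matrix, k=1).data.sum()


class TestGeodesicNeighborhood:
    def test_tiny_radius_gives_seed(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        nb = geodesic_neighborhood(mesh, 17, radius=1e-6)
        assert list(nb) == [17]

    def test_huge_radius_gives_all(self):
        mesh = grid_mesh(4, 4)
        nb = geodesic_neighborhood(mesh, 0, radius=1e6)
        assert len(nb) == mesh.n_vertices

    def test_grid_radius_matches_bruteforce(self):
        mesh = grid_mesh(6, 6, spacing=1.0)
        d = all_pairs_geodesic_bruteforce(mesh)
        for seed_v in [0, 7, 21, 35]:
            nb = geodesic_neighborhood(mesh, seed_v, radius=2.05)
            expected = np.where(d[seed_v] <= 2.05)[0]
            np.testing.assert_array_equal(nb, expected)

    def test_agrees_with_bruteforce_on_sphere(self):
        from brainclass.simulate import generate_toy_brain

        mesh, _, _ = generate_toy_brain(162, 0, seed=0, radius=5.0)
        assert mesh.n_vertices <= 200
        d = all_pairs_geodesic_bruteforce(mesh)
        for v in [0, 40, 100]:
            nb = geodesic_neighborhood(mesh, v, radius=3.0)
            np.testing.assert_array_equal(nb, np.where(d[v] <= 3.0)[0])

    def test_invalid_vertex(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        with pytest.raises(InvalidInputError):
            geodesic_neighborhood(mesh, mesh.n_vertices, radius=5)


class TestVertexMetrics:
    def _metrics(self, mesh, streams, radius=3.0, **kw):
        cmat = build_connectivity_matrix(mesh, streams, snap_radius=0.5)
        fa = [streamline_mean_fa(streams[i]) for i in cmat.kept_indices]
        return cmat, compute_vertex_metrics(mesh, cmat, fa, radius=radius, **kw)

    def test_no_streamlines_zero_cd(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        with pytest.warns(UserWarning, match="no connections"):
            _, vm = self._metrics(mesh, StreamlineSet(()))
        assert np.all(vm.cd == 0)

    def test_single_streamline_direct_evaluation(self, sphere_fixture):
        """CD at an endpoint equals 1 / (neighborhood area * total count)."""
        mesh, _, _ = sphere_fixture
        a, b = 0, 300  # far apart on the sphere
        s = Streamline(np.array([mesh.vertices[a], mesh.vertices[b]]), np.full(2, 0.7))
        _, vm = self._metrics(mesh, StreamlineSet((s,)), radius=3.0)
        nb = geodesic_neighborhood(mesh, a, radius=3.0)
        area = mesh.vertex_areas[nb].sum()
        assert vm.cd[a] == pytest.approx(1.0 / area, rel=1e-12)
        assert vm.mean_fa[a] == pytest.approx(0.7)

    def test_duplication_scale_invariance(self, sphere_fixture):
        mesh, streams, _ = sphere_fixture
        _, vm1 = self._metrics(mesh, streams)
        doubled = StreamlineSet(tuple(streams) + tuple(streams))
        _, vm2 = self._metrics(mesh, doubled)
        np.testing.assert_allclose(vm1.cd, vm2.cd, rtol=1e-12)

    def test_both_endpoints_inside_not_counted(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        nb = geodesic_neighborhood(mesh, 0, radius=3.0)
        inside = nb[-1]  # another vertex of the same neighborhood
        s = Streamline(
            np.array([mesh.vertices[0], mesh.vertices[inside]]), np.full(2, 0.5)
        )
        _, vm = self._metrics(mesh, StreamlineSet((s,)), radius=3.0)
        assert vm.cd[0] == 0.0  # does not link the neighborhood to the rest

    def test_entries_denominator_option(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        s = Streamline(np.array([mesh.vertices[0], mesh.vertices[300]]), np.full(2, 0.5))
        sset = StreamlineSet((s, s))  # 2 streamlines, 1 distinct pair
        cmat = build_connectivity_matrix(mesh, sset, snap_radius=0.5)
        fa = [0.5, 0.5]
        by_stream = compute_vertex_metrics(mesh, cmat, fa, 3.0, "streamlines")
        by_entry = compute_vertex_metrics(mesh, cmat, fa, 3.0, "entries")
        assert by_entry.cd[0] == pytest.approx(2 * by_stream.cd[0])


class TestSmoothing:
    def test_constant_preserved(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        out = smooth_vertex_map(mesh, np.full(mesh.n_vertices, 3.7), fwhm=5.0)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_spike_peaks_at_source_and_decays(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        spike = np.zeros(mesh.n_vertices)
        spike[10] = 1.0
        out = smooth_vertex_map(mesh, spike, fwhm=4.0)
        assert out.argmax() == 10
        assert (out >= 0).all()
        d = mesh.geodesic_distances(indices=[10], limit=np.inf)[0]
        near = out[(d > 0) & (d < 1.5)].mean()
        far = out[(d > 3) & (d < 4.5)].mean()
        assert near > far

    def test_tiny_fwhm_identity(self, sphere_fixture, rng):
        mesh, _, _ = sphere_fixture
        values = rng.normal(size=mesh.n_vertices)
        out = smooth_vertex_map(mesh, values, fwhm=0.05)
        np.testing.assert_allclose(out, values, rtol=1e-12)

    def test_convex_combination(self, sphere_fixture, rng):
        mesh, _, _ = sphere_fixture
        values = rng.normal(size=mesh.n_vertices)
        out = smooth_vertex_map(mesh, values, fwhm=6.0)
        assert out.min() >= values.min() - 1e-12
        assert out.max() <= values.max() + 1e-12

    def test_length_mismatch(self, sphere_fixture):
        mesh, _, _ = sphere_fixture
        with pytest.raises(InvalidInputError):
            smooth_vertex_map(mesh, np.zeros(3), fwhm=5.0)


class TestParcelAggregation:
    def test_constant_map(self, sphere_fixture):
        mesh, _, parcels = sphere_fixture
        out = aggregate_to_parcels(mesh, np.full(mesh.n_vertices, 2.0), parcels)
        np.testing.assert_allclose(out.to_numpy(), 2.0)

    def test_two_parcel_split(self):
        mesh = grid_mesh(4, 4)
        labels = (mesh.vertices[:, 0] >= 1.5).astype(int)
        values = np.where(labels == 1, 2.0, 0.0)
        out = aggregate_to_parcels(mesh, values, labels)
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(2.0)

    def test_mixed_parcel_matches_handweighted(self, sphere_fixture, rng):
        mesh, _, parcels = sphere_fixture
        values = rng.normal(size=mesh.n_vertices)
        out = aggregate_to_parcels(mesh, values, parcels)
        w = mesh.vertex_areas
        pick = parcels == 3
        expected = np.sum(w[pick] * values[pick]) / np.sum(w[pick])
        assert out[3] == pytest.approx(expected, rel=1e-12)

    def test_unlabeled_vertex_errors(self, sphere_fixture):
        mesh, _, parcels = sphere_fixture
        bad = parcels.copy()
        bad[5] = -1
        with pytest.raises(InvalidInputError, match="5"):
            aggregate_to_parcels(mesh, np.zeros(mesh.n_vertices), bad)
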
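"""Mesh container, adjacency and geometric primitive tests."""

import numpy as np
import pytest

import tetromap as tm
from tetromap.mesh import FACE_NODES, MeshError, PARALLEL, barycentric


def random_tet(rng):
    """A non-degenerate random tetrahedron mesh."""
    while True:
        nodes = rng.uniform(-1, 1, size=(4, 3))
        v = np.dot(nodes[1] - nodes[0],
                   np.cross(nodes[2] - nodes[0], nodes[3] - nodes[0])) / 6
        if abs(v) > 1e-3:
            return tm.TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]),
                              region_tag=np.array([1]),
                              medium_id=np.array([0]))


class TestTetMesh:
    def test_orientation_fixed_and_volumes_positive(self, rng):
        for _ in range(50):
            mesh = random_tet(rng)
            assert mesh.volumes()[0] > 0

    def test_degenerate_rejected(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]])
        with pytest.raises(MeshError):
            tm.TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]),
                       region_tag=np.array([1]), medium_id=np.array([0]))

    def test_region_medium_must_be_function(self, two_tets):
        with pytest.raises(MeshError):
            tm.TetMesh(nodes=two_tets.nodes, elements=two_tets.elements,
                       region_tag=np.array([1, 1]),
                       medium_id=np.array([0, 1]))

    def test_index_out_of_range(self):
        with pytest.raises(MeshError):
            tm.TetMesh(nodes=np.eye(3), elements=np.array([[0, 1, 2, 5]]),
                       region_tag=np.array([1]), medium_id=np.array([0]))


class TestOpticalMedium:
    def test_mu_t(self):
        assert tm.ILLUMINATION_488.mu_t == pytest.approx(23.52)
        assert tm.EMISSION_669.mu_t == pytest.approx(21.9)

    def test_bath_is_non_scattering(self):
        assert not tm.SALINE_BATH.scattering

    @pytest.mark.parametrize("kw", [dict(mu_a=-1, mu_s=1, g=0),
                                    dict(mu_a=1, mu_s=1, g=1.5),
                                    dict(mu_a=0, mu_s=0, g=0)])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            tm.OpticalMedium(**kw)


class TestFaceAdjacency:
    def test_single_tet_all_exterior(self, single_tet):
        adj = tm.build_face_adjacency(single_tet)
        assert np.all(adj.neighbor == tm.EXTERIOR)
        assert np.all(adj.boundary_face)

    def test_two_tets_share_one_face(self, two_tets):
        adj = tm.build_face_adjacency(two_tets)
        assert (adj.neighbor == tm.EXTERIOR).sum() == 6
        # each element lists the other on its shared face
        f0 = int(np.nonzero(adj.neighbor[0] == 1)[0][0])
        f1 = int(np.nonzero(adj.neighbor[1] == 0)[0][0])
        assert adj.neighbor[0, f0] == 1 and adj.neighbor[1, f1] == 0
        assert not adj.boundary_face[0, f0]  # same medium

    def test_symmetry_and_manifold_on_slab(self, cube2_mesh):
        """Every interior face is shared by exactly 2 elements; checked
        against an independent face-hashing oracle (sorted node triples)."""
        adj = tm.build_face_adjacency(cube2_mesh)
        # independent oracle: count multiplicity of each sorted triple
        from collections import Counter

        faces = Counter()
        for row in cube2_mesh.elements:
            for f in range(4):
                faces[tuple(sorted(row[FACE_NODES[f]]))] += 1
        assert set(faces.values()) <= {1, 2}
        n_interior_oracle = sum(1 for v in faces.values() if v == 2)
        assert (adj.neighbor != tm.EXTERIOR).sum() == 2 * n_interior_oracle
        # symmetry
        m = cube2_mesh.n_elements
        for e in range(m):
            for f in range(4):
                nb = adj.neighbor[e, f]
                if nb != tm.EXTERIOR:
                    assert e in adj.neighbor[nb]

    def test_nonmanifold_rejected(self):
        # three tets sharing one face
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1.0, 1, 1], [-1.0, -1, 1]])
        with pytest.raises(MeshError, match="non-manifold"):
            tm.build_face_adjacency(tm.TetMesh(
                nodes=nodes,
                elements=np.array([[0, 1, 2, 3], [4, 1, 2, 3], [5, 1, 2, 3]]),
                region_tag=np.array([1, 1, 1]), medium_id=np.array([0, 0, 0])))

    def test_media_boundary_flagged(self, two_tets):
        mesh = tm.TetMesh(nodes=two_tets.nodes, elements=two_tets.elements,
                          region_tag=np.array([1, 2]),
                          medium_id=np.array([0, 1]))
        adj = tm.build_face_adjacency(mesh)
        f0 = int(np.nonzero(adj.neighbor[0] == 1)[0][0])
        f1 = int(np.nonzero(adj.neighbor[1] == 0)[0][0])
        assert adj.boundary_face[0, f0] and adj.boundary_face[1, f1]


class TestInwardNormal:
    def test_axis_aligned_face(self, single_tet):
        # face opposite node 3 lies in the z=0 plane; inward normal +z
        n = tm.inward_normal(single_tet, 0, 3)
        assert np.allclose(n, [0, 0, 1])

    def test_oblique_face(self, single_tet):
        # face opposite node 0 is the plane x+y+z=1; inward is -(1,1,1)/sqrt3
        n = tm.inward_normal(single_tet, 0, 0)
        assert np.allclose(n, -np.ones(3) / np.sqrt(3))

    def test_points_toward_centroid_randomized(self, rng):
        for _ in range(200):
            mesh = random_tet(rng)
            centroid = mesh.nodes.mean(axis=0)
            for f in range(4):
                n = tm.inward_normal(mesh, 0, f)
                a = mesh.nodes[mesh.elements[0, FACE_NODES[f][0]]]
                assert np.dot(n, centroid - a) > 0
                assert np.linalg.norm(n) == pytest.approx(1.0)


class TestFacePlaneDistance:
    def test_axis_aligned(self, single_tet):
        a = tm.face_plane_distance((0.1, 0.1, 0.1), (0, 0, -1),
                                   single_tet, 0, 3)
        assert a == pytest.approx(0.1)

    def test_parallel_sentinel(self, single_tet):
        a = tm.face_plane_distance((0.1, 0.1, 0.1), (1, 0, 0),
                                   single_tet, 0, 3)
        assert a == PARALLEL

    def test_matches_ray_triangle_oracle(self, rng):
        """Minimum positive face distance equals the Moller-Trumbore
        ray/triangle intersection distance for the exiting face."""

        def moller_trumbore(orig, d, v0, v1, v2):
            e1, e2 = v1 - v0, v2 - v0
            p = np.cross(d, e2)
            det = np.dot(e1, p)
            if abs(det) < 1e-12:
                return None
            tvec = orig - v0
            u = np.dot(tvec, p) / det
            q = np.cross(tvec, e1)
            v = np.dot(d, q) / det
            w = np.dot(e2, q) / det  # distance along the ray
            if u < -1e-9 or v < -1e-9 or u + v > 1 + 1e-9:
                return None
            return w

        hits = 0
        for _ in range(400):
            mesh = random_tet(rng)
            # random interior point + random direction
            lam = rng.dirichlet(np.ones(4))
            p = lam @ mesh.nodes
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            dists = [tm.face_plane_distance(p, d, mesh, 0, f)
                     for f in range(4)]
            a_min = min(a for a in dists if a > 1e-12)
            oracle = []
            for f in range(4):
                tri = mesh.nodes[mesh.elements[0, FACE_NODES[f]]]
                w = moller_trumbore(p, d, *tri)
                if w is not None and w > 1e-12:
                    oracle.append(w)
            if oracle:
                hits += 1
                assert a_min == pytest.approx(min(oracle), rel=1e-8)
        assert hits > 350  # almost every interior ray exits through a face


class TestLocateElement:
    def test_centroid_maps_to_element(self, cube2_mesh):
        for e in (0, 7, 23, 47):
            c = cube2_mesh.nodes[cube2_mesh.elements[e]].mean(axis=0)
            assert tm.locate_element(cube2_mesh, c) == e

    def test_shared_face_tie_breaks_low(self, two_tets):
        # centroid of the shared face
        p = two_tets.nodes[[1, 2, 3]].mean(axis=0)
        assert tm.locate_element(two_tets, p) == 0

    def test_outside_raises(self, cube2_mesh):
        with pytest.raises(LookupError):
            tm.locate_element(cube2_mesh, (10.0, 10.0, 10.0))

    def test_random_points_against_scan_oracle(self, cube2_mesh, rng):
        for _ in range(150):
            p = rng.uniform(0.01, 1.99, size=3)
            e = tm.locate_element(cube2_mesh, p)
            assert barycentric(cube2_mesh, e, p).min() >= -1e-9
            # exhaustive-scan oracle: lowest containing element
            oracle = next(i for i in range(cube2_mesh.n_elements)
                          if barycentric(cube2_mesh, i, p).min() >= -1e-9)
            assert e == oracle
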
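"""Tetrahedral mesh container, connectivity tables and geometric primitives.

The transport engine walks photon packets from tetrahedron to tetrahedron,
so the mesh layer precomputes everything that walk needs: a face-to-face
adjacency table (one row per element, four columns, one per face), inward
face normals and plane offsets, and per-element medium assignments.

Conventions (fixed so adjacency tables are reproducible):

* node and element indices are 0-based everywhere; file readers convert
  1-based dialects on input,
* local face ``j`` of a tetrahedron is the triangle opposite local node
  ``j`` (``FACE_NODES``),
* coordinates are in mm, optical coefficients in 1/mm,
* elements are oriented so their signed volume is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: sentinel in the adjacency table for "no neighbour: domain exterior"
EXTERIOR = -1

#: local nodes of face j (the face opposite local node j)
FACE_NODES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int64)

#: region tags used by the parametric builders
REGION_TISSUE = 1
REGION_BATH = 2

_DEGENERATE_VOL = 1e-12  # mm^3


class MeshError(ValueError):
    """Raised for structurally invalid meshes (non-manifold faces, ...)."""


@dataclass
class OpticalMedium:
    """Optical properties of one medium at one wavelength.

    Parameters
    ----------
    mu_a, mu_s : float
        Absorption / scattering coefficients, 1/mm.
    g : float
        Henyey-Greenstein scattering anisotropy, in [-1, 1].
    n : float
        Refractive index.
    scattering : bool
        False for saline bath media, which are traversed in straight lines
        without absorption or scattering.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float = 1.4
    scattering: bool = True

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n <= 0:
            raise ValueError("refractive index must be positive")
        if self.scattering and self.mu_t <= 0:
            raise ValueError("scattering media need mu_t = mu_a + mu_s > 0")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, 1/mm."""
        return self.mu_a + self.mu_s


# Cardiac tissue parameters for di-4-ANEPPS optical mapping: illumination
# (488 nm) and fluorescent emission (669 nm) wavelengths.
ILLUMINATION_488 = OpticalMedium(mu_a=0.52, mu_s=23.0, g=0.94, n=1.40)
EMISSION_669 = OpticalMedium(mu_a=0.10, mu_s=21.8, g=0.96, n=1.40)
#: non-scattering saline (perfusate); photons fly straight through it
SALINE_BATH = OpticalMedium(mu_a=0.0, mu_s=0.0, g=0.0, n=1.33, scattering=False)


def media_arrays(media: list[OpticalMedium]):
    """Flatten a media table into parallel numpy arrays for the kernels."""
    mu_a = np.array([m.mu_a for m in media], dtype=np.float64)
    mu_s = np.array([m.mu_s for m in media], dtype=np.float64)
    mu_t = mu_a + mu_s
    g = np.array([m.g for m in media], dtype=np.float64)
    n = np.array([m.n for m in media], dtype=np.float64)
    scat = np.array([m.scattering for m in media], dtype=np.bool_)
    return mu_a, mu_s, mu_t, g, n, scat


@dataclass
class TetMesh:
    """Unstructured tetrahedral mesh with per-element region/medium tags.

    Attributes
    ----------
    nodes : (N, 3) float64
        Node coordinates, mm.
    elements : (M, 4) int32
        Node indices per tetrahedron, positively oriented.
    region_tag : (M,) int32
        Integer region label per element (e.g. tissue / bath).
    medium_id : (M,) int32
        Index into the media table per element.  Each region maps to
        exactly one medium.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region_tag: np.ndarray
    medium_id: np.ndarray
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _centroids: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int32)
        self.region_tag = np.ascontiguousarray(self.region_tag, dtype=np.int32)
        self.medium_id = np.ascontiguousarray(self.medium_id, dtype=np.int32)
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= len(self.nodes):
            raise MeshError("element node index out of range")
        vols = self.volumes()
        neg = vols <= 0
        if neg.any():
            # fix orientation by swapping two nodes, then re-check degeneracy
            e = self.elements
            e[neg, 0], e[neg, 1] = e[neg, 1].copy(), e[neg, 0].copy()
            vols = self.volumes()
        if (vols < _DEGENERATE_VOL).any():
            bad = int(np.argmin(vols))
            raise MeshError(f"degenerate tetrahedron {bad} (|V| < {_DEGENERATE_VOL} mm^3)")
        # region -> medium must be a function
        for r in np.unique(self.region_tag):
            mids = np.unique(self.medium_id[self.region_tag == r])
            if len(mids) != 1:
                raise MeshError(f"region {r} maps to several media {mids}")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def volumes(self) -> np.ndarray:
        """Signed volumes per element, mm^3 (positive after orientation)."""
        p = self.nodes[self.elements]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.nodes[self.elements].mean(axis=1)
        return self._centroids

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.centroids())
        return self._tree


@dataclass
class FaceAdjacency:
    """Face-to-face connectivity and cached face geometry.

    ``neighbor[e, f]`` is the element sharing face ``f`` of element ``e``,
    or :data:`EXTERIOR`.  ``boundary_face[e, f]`` flags faces where the two
    incident elements carry different media (or one side is exterior).
    ``normals``/``offsets`` cache the inward unit normal and plane offset
    ``d = n . p0`` of every face for the transport kernels.
    """

    neighbor: np.ndarray       # (M, 4) int32
    boundary_face: np.ndarray  # (M, 4) bool
    normals: np.ndarray        # (M, 4, 3) float64, inward unit normals
    offsets: np.ndarray        # (M, 4) float64, n . p0


def build_face_adjacency(mesh: TetMesh) -> FaceAdjacency:
    """Build the symmetric face adjacency table plus face-plane cache.

    Faces are matched by their sorted node triples.  A triple shared by
    more than two elements is non-manifold and raises :class:`MeshError`.
    """
    m = mesh.n_elements
    elems = mesh.elements.astype(np.int64)
    # all 4 faces of every element: (4m, 3) sorted node triples
    faces = elems[:, FACE_NODES].reshape(-1, 3)
    faces_sorted = np.sort(faces, axis=1)
    owner_elem = np.repeat(np.arange(m, dtype=np.int64), 4)
    owner_face = np.tile(np.arange(4, dtype=np.int64), m)

    order = np.lexsort(faces_sorted.T[::-1])
    fs = faces_sorted[order]
    same = np.all(fs[1:] == fs[:-1], axis=1)
    # detect runs of >= 3 identical triples
    if same.size >= 2 and np.any(same[1:] & same[:-1]):
        i = int(np.argmax(same[1:] & same[:-1]))
        raise MeshError(f"non-manifold face with nodes {tuple(fs[i + 1])}")

    neighbor = np.full((m, 4), EXTERIOR, dtype=np.int32)
    idx = np.nonzero(same)[0]
    ea, fa = owner_elem[order[idx]], owner_face[order[idx]]
    eb, fb = owner_elem[order[idx + 1]], owner_face[order[idx + 1]]
    neighbor[ea, fa] = eb
    neighbor[eb, fb] = ea

    med = mesh.medium_id
    nbr_med = np.where(neighbor >= 0, med[np.clip(neighbor, 0, None)], -999)
    boundary = nbr_med != med[:, None]

    normals, offsets = _face_planes(mesh)
    return FaceAdjacency(neighbor=neighbor, boundary_face=boundary,
                         normals=normals, offsets=offsets)


def _face_planes(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Inward unit normals and offsets for all faces of all elements."""
    p = mesh.nodes[mesh.elements]          # (M, 4, 3)
    normals = np.empty((mesh.n_elements, 4, 3))
    offsets = np.empty((mesh.n_elements, 4))
    for f in range(4):
        i, j, k = FACE_NODES[f]
        a, b, c = p[:, i], p[:, j], p[:, k]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        if (norm < 1e-15).any():
            raise MeshError("degenerate face (zero area)")
        n /= norm
        # orient toward the opposite node (inward)
        opp = p[:, f]
        flip = np.einsum("ij,ij->i", n, opp - a) < 0
        n[flip] *= -1.0
        normals[:, f] = n
        offsets[:, f] = np.einsum("ij,ij->i", n, a)
    return normals, offsets


def inward_normal(mesh: TetMesh, element: int, face: int) -> np.ndarray:
    """Unit normal of face `face` of `element`, pointing toward its centroid."""
    i, j, k = FACE_NODES[face]
    e = mesh.elements[element]
    a, b, c = mesh.nodes[e[i]], mesh.nodes[e[j]], mesh.nodes[e[k]]
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < 1e-15:
        raise MeshError(f"degenerate face {face} of element {element}")
    n = n / norm
    centroid = mesh.nodes[e].mean(axis=0)
    if np.dot(n, centroid - a) < 0:
        n = -n
    return n


#: sentinel returned when a trajectory is parallel to a face plane
PARALLEL = np.inf


def face_plane_distance(position, direction, mesh: TetMesh, element: int,
                        face: int) -> float:
    """Signed distance along `direction` from `position` to a face plane.

    Returns ``a = n . (p0 - x) / n . d``; :data:`PARALLEL` (+inf) when the
    trajectory is parallel to the plane (|n . d| < 1e-12).
    """
    n = inward_normal(mesh, element, face)
    p0 = mesh.nodes[mesh.elements[element, FACE_NODES[face][0]]]
    nd = float(np.dot(n, direction))
    if abs(nd) < 1e-12:
        return PARALLEL
    return float(np.dot(n, p0 - np.asarray(position, dtype=float))) / nd


def barycentric(mesh: TetMesh, element: int, point) -> np.ndarray:
    """Barycentric coordinates of `point` in `element` (sum to 1)."""
    p = mesh.nodes[mesh.elements[element]]
    T = (p[1:] - p[0]).T
    lam = np.linalg.solve(T, np.asarray(point, dtype=float) - p[0])
    return np.concatenate(([1.0 - lam.sum()], lam))


def locate_element(mesh: TetMesh, point, tol: float = 1e-9) -> int:
    """Element containing `point` (barycentric coordinates all >= -tol).

    Ties on shared faces are broken toward the lowest element index.
    Raises ``LookupError`` for points outside the mesh hull.
    """
    point = np.asarray(point, dtype=float)
    tree = mesh._kdtree()
    k = min(64, mesh.n_elements)
    _, cand = tree.query(point, k=k)
    cand = np.atleast_1d(cand)
    hits = [int(e) for e in cand if barycentric(mesh, int(e), point).min() >= -tol]
    if hits:
        return min(hits)
    # fall back to an exhaustive scan (rare: point near hull, skewed elements)
    for e in range(mesh.n_elements):
        if barycentric(mesh, e, point).min() >= -tol:
            return e
    raise LookupError(f"point {point} is outside the mesh")
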
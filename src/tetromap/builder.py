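"""Parametric slab phantoms: cuboid myocardium, optional vessel cavity, bath.

The phantoms emulate perfused ventricular wedge preparations: a scattering
myocardial slab (default 4 x 4 x 2 mm), optionally pierced by a saline-filled
cylindrical vessel cavity running in the apex-base (y) direction just below
the epicardial surface, surrounded on all sides by a thin non-scattering
bath layer.  The epicardial (illuminated / imaged) surface is the z = Lz
tissue face.

Construction is a structured cube lattice, each cube split into six
tetrahedra (Kuhn / Freudenthal subdivision, face-compatible across
neighbouring cubes).  Elements are tagged bath when their centroid falls
inside the cylindrical cavity or outside the tissue box; the stair-stepped
cavity wall this produces is adequate for photon transport, which has no
curvature-sensitive term, and its volume error vanishes with the lattice
spacing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .mesh import REGION_BATH, REGION_TISSUE, MeshError, TetMesh

# The six tetrahedra of the Kuhn subdivision of the unit cube: every
# permutation (p0,p1,p2) of the axes gives the tet {0, e_p0, e_p0+e_p1, 1}.
_CUBE_TETS: list[tuple[int, int, int, int]] = []
for perm in itertools.permutations(range(3)):
    corners = [(0, 0, 0)]
    c = [0, 0, 0]
    for ax in perm:
        c = c.copy()
        c[ax] = 1
        corners.append(tuple(c))
    _CUBE_TETS.append(tuple((cx << 0) | (cy << 1) | (cz << 2) for cx, cy, cz in corners))


@dataclass
class VesselSpec:
    """Cylindrical vessel cavity along the y axis.

    ``depth`` is measured from the epicardial surface down to the *upper
    cavity edge*; the cylinder axis therefore sits at
    ``z = Lz - depth - diameter/2``, laterally centred at ``x = Lx/2``.
    """

    diameter: float  # mm
    depth: float     # mm, epicardium to cavity edge


@dataclass
class SlabSpec:
    """Cuboid phantom specification.

    Parameters
    ----------
    dims : (Lx, Ly, Lz) mm
        Tissue box dimensions; the epicardium is the z = Lz face.
    spacing : float
        Target lattice edge length h, mm (default 0.1 mm; finer spacing
        converges toward the smooth-cavity limit).
    vessel : VesselSpec, optional
    bath_width : float
        Width of the non-scattering saline shell added on all six faces
        (default 0.1 mm, matching a perfused preparation).
    """

    dims: tuple[float, float, float]
    spacing: float = 0.1
    vessel: VesselSpec | None = None
    bath_width: float = 0.1

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.bath_width < 0:
            raise ValueError("bath_width must be non-negative")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        v = self.vessel
        if v is not None:
            if v.diameter <= 0 or v.depth < 0:
                raise ValueError("vessel diameter/depth invalid")
            if v.depth + v.diameter >= self.dims[2]:
                raise ValueError("vessel does not fit inside the slab")
            if self.spacing > v.diameter / 2:
                raise ValueError(
                    "spacing exceeds the vessel radius; cavity unresolvable")

    @property
    def vessel_center(self) -> tuple[float, float] | None:
        """(x, z) of the cavity axis, or None."""
        if self.vessel is None:
            return None
        lx, _, lz = self.dims
        return lx / 2.0, lz - self.vessel.depth - self.vessel.diameter / 2.0


def build_slab_mesh(spec: SlabSpec) -> TetMesh:
    """Build the tetrahedral phantom described by `spec`.

    Returns a mesh whose elements carry ``region_tag``/``medium_id`` 1 for
    myocardium and 2/0... — concretely REGION_TISSUE -> medium 0 and
    REGION_BATH -> medium 1 (cavity plus surrounding shell).
    """
    lx, ly, lz = spec.dims
    h = spec.spacing
    b = spec.bath_width
    lo = np.array([-b, -b, -b])
    hi = np.array([lx + b, ly + b, lz + b])
    ncell = np.maximum(1, np.rint((hi - lo) / h).astype(int))
    # keep the tissue box resolved exactly: spacing must tile dims and bath
    for L, n in zip(hi - lo, ncell):
        if abs(L / n - h) > 1e-9:
            raise ValueError("spacing must evenly divide dims + 2*bath_width")

    nx, ny, nz = ncell + 1
    xs = lo[0] + h * np.arange(nx)
    ys = lo[1] + h * np.arange(ny)
    zs = lo[2] + h * np.arange(nz)
    # node index (i, j, k) -> i + nx*(j + ny*k)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([
        X.transpose(2, 1, 0).ravel(),
        Y.transpose(2, 1, 0).ravel(),
        Z.transpose(2, 1, 0).ravel(),
    ])

    ci, cj, ck = np.meshgrid(np.arange(ncell[0]), np.arange(ncell[1]),
                             np.arange(ncell[2]), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()

    def nid(i, j, k):
        return i + nx * (j + ny * k)

    corner = np.empty((ci.size, 8), dtype=np.int64)
    for bit in range(8):
        dx, dy, dz = bit & 1, (bit >> 1) & 1, (bit >> 2) & 1
        corner[:, bit] = nid(ci + dx, cj + dy, ck + dz)

    elements = np.empty((ci.size * 6, 4), dtype=np.int64)
    for t, tet in enumerate(_CUBE_TETS):
        elements[t::6] = corner[:, list(tet)]

    # tag by centroid
    cent = nodes[elements].mean(axis=1)
    inside_tissue = (
        (cent[:, 0] > 0) & (cent[:, 0] < lx)
        & (cent[:, 1] > 0) & (cent[:, 1] < ly)
        & (cent[:, 2] > 0) & (cent[:, 2] < lz)
    )
    region = np.where(inside_tissue, REGION_TISSUE, REGION_BATH)
    vc = spec.vessel_center
    if vc is not None:
        xc, zc = vc
        r = spec.vessel.diameter / 2.0
        in_cavity = (cent[:, 0] - xc) ** 2 + (cent[:, 2] - zc) ** 2 < r * r
        region[in_cavity] = REGION_BATH

    medium = np.where(region == REGION_TISSUE, 0, 1)
    return TetMesh(nodes=nodes, elements=elements,
                   region_tag=region, medium_id=medium)


def epicardial_surface(mesh: TetMesh, z_epi: float | None = None,
                       tol: float = 1e-9):
    """Triangles of the flat epicardial tissue surface.

    Returns ``(elems, faces, tri_pts)``: for every tissue element with a
    face whose three nodes lie in the plane z = z_epi, the element index,
    local face index and the (n, 3, 3) triangle vertex coordinates.  When
    ``z_epi`` is omitted it defaults to the maximum z over tissue nodes.
    """
    from .mesh import FACE_NODES

    tissue = np.nonzero(mesh.region_tag == REGION_TISSUE)[0]
    if tissue.size == 0:
        raise MeshError("mesh has no tissue elements")
    if z_epi is None:
        z_epi = mesh.nodes[np.unique(mesh.elements[tissue])][:, 2].max()
    elems, faces = [], []
    nodes_z = mesh.nodes[:, 2]
    for f in range(4):
        tri = mesh.elements[tissue][:, FACE_NODES[f]]
        on_plane = np.all(np.abs(nodes_z[tri] - z_epi) < tol, axis=1)
        elems.append(tissue[on_plane])
        faces.append(np.full(on_plane.sum(), f, dtype=np.int64))
    elems = np.concatenate(elems)
    faces = np.concatenate(faces)
    if elems.size == 0:
        raise MeshError("no epicardial surface triangles found")
    tri_nodes = mesh.elements[elems][np.arange(elems.size)[:, None],
                                     FACE_NODES[faces]]
    tri_pts = mesh.nodes[tri_nodes]
    return elems, faces, tri_pts


def cavity_elements(mesh: TetMesh, spec: SlabSpec) -> np.ndarray:
    """Indices of bath elements inside the vessel cavity (not the shell)."""
    if spec.vessel is None:
        return np.array([], dtype=np.int64)
    lx, ly, lz = spec.dims
    cent = mesh.centroids()
    xc, zc = spec.vessel_center
    r = spec.vessel.diameter / 2.0
    mask = (
        (mesh.region_tag == REGION_BATH)
        & ((cent[:, 0] - xc) ** 2 + (cent[:, 2] - zc) ** 2 < r * r)
        & (cent[:, 1] > 0) & (cent[:, 1] < ly)
    )
    return np.nonzero(mask)[0]
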
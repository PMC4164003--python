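"""Shared fixtures: small meshes and (session-scoped) Monte Carlo runs.

The heavy fixtures run the full illumination -> emission pipeline for the
three cuboid phantoms at reduced packet budgets and are shared by the
scattering-volume, signal and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import tetromap as tm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def single_tet():
    """Unit right tetrahedron: origin plus the three unit axis points."""
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    return tm.TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]),
                      region_tag=np.array([1]), medium_id=np.array([0]))


@pytest.fixture()
def two_tets():
    """Two tetrahedra sharing the x+y+z=1 face."""
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1.0, 1, 1]])
    return tm.TetMesh(nodes=nodes,
                      elements=np.array([[0, 1, 2, 3], [4, 1, 2, 3]]),
                      region_tag=np.array([1, 1]),
                      medium_id=np.array([0, 0]))


@pytest.fixture(scope="session")
def cube2_mesh():
    """2x2x2 mm slab at h=1 (48 tets), no bath: tiny structured mesh."""
    return tm.build_slab_mesh(tm.SlabSpec(dims=(2, 2, 2), spacing=1.0,
                                          bath_width=0.0))


@dataclass
class ModelRun:
    """One phantom's reduced-budget illumination + emission results."""

    spec: tm.SlabSpec
    mesh: tm.TetMesh
    adjacency: tm.FaceAdjacency
    field: tm.PhotonDensityField
    svs: list          # ScatteringVolume per pixel edge 0.16/0.32/0.64


def _run_model(dims, vessel, seed, illum_packets, emis_packets):
    spec = tm.SlabSpec(dims=dims, spacing=0.1, vessel=vessel, bath_width=0.1)
    mesh = tm.build_slab_mesh(spec)
    adjacency = tm.build_face_adjacency(mesh)
    field = tm.run_illumination(
        mesh, adjacency, [tm.ILLUMINATION_488, tm.SALINE_BATH],
        tm.IlluminationConfig(total_packets=illum_packets),
        tm.TransportConfig(seed=seed))
    pixels = tm.central_pixels(mesh)
    svs, _ = tm.run_emission(
        mesh, adjacency, field, [tm.EMISSION_669, tm.SALINE_BATH], pixels,
        total_packets=emis_packets, transport=tm.TransportConfig(seed=seed + 1))
    return ModelRun(spec=spec, mesh=mesh, adjacency=adjacency, field=field,
                    svs=svs)


# Reduced budgets (vs the desk-scale 2e6/5e6 of the acceptance script) keep
# the default test run inside its time budget; the checks that consume these
# fixtures use the same tolerances regardless.
_ILLUM_N = 600_000
_EMIS_N = 2_000_000


@pytest.fixture(scope="session")
def novessel_run():
    return _run_model((4, 4, 2), None, 101, _ILLUM_N, _EMIS_N)


@pytest.fixture(scope="session")
def small_vessel_run():
    return _run_model((4, 4, 2), tm.VesselSpec(diameter=0.35, depth=0.10),
                      202, _ILLUM_N, _EMIS_N)


@pytest.fixture(scope="session")
def large_vessel_run():
    return _run_model((4, 4, 2), tm.VesselSpec(diameter=0.80, depth=0.20),
                      303, _ILLUM_N, _EMIS_N)
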
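"""Synthetic transmembrane-voltage fields.

Stand-ins for full monodomain/bidomain electrophysiology, carrying the two
spatial structures the optical synthesis needs:

* a traveling plane wave with a logistic upstroke (paced propagation,
  circumferential or transmural), and
* a parametric shock-end polarization snapshot: exponential epicardial
  depolarization / endocardial hyperpolarization boundary layers plus an
  optional dipolar virtual-electrode pattern around a vessel cavity
  (depolarized on the epicardial side, hyperpolarized on the distal side).

These emulate the qualitative spatial patterns of bidomain shock
simulations; no ionic model or PDE is solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import REGION_TISSUE, TetMesh

#: default resting potential and action-potential amplitude, mV
REST_MV = -85.0
AMPLITUDE_MV = 125.0
#: logistic time constant giving a ~1 ms electrical 10-90% upstroke
UPSTROKE_TAU_MS = 1.0 / np.log(81.0)
#: plausible rabbit conduction velocities, mm/ms
CV_CIRCUMFERENTIAL = 0.5
CV_TRANSMURAL = 0.25


@dataclass
class VmField:
    """Transmembrane voltage per node per frame.

    ``values`` has shape (n_frames, n_nodes), mV; ``times`` are frame times
    in ms, strictly increasing with spacing <= 1 ms for paced runs (a single
    frame is allowed for shock snapshots).
    """

    values: np.ndarray
    times: np.ndarray
    rest: float = REST_MV
    amplitude: float = AMPLITUDE_MV

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if len(self.times) != len(self.values):
            raise ValueError("times/values frame count mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("V_m values must be finite")


def plane_wave_vm(mesh: TetMesh, direction, cv: float,
                  times, upstroke_tau: float = UPSTROKE_TAU_MS,
                  rest: float = REST_MV,
                  amplitude: float = AMPLITUDE_MV) -> VmField:
    """Traveling plane wave V_m(x, t) = rest + A * sigma((t - x.d/cv)/tau).

    `direction` is the propagation direction (unit vector); a node at
    projected distance ``x.d`` activates (half-amplitude) at ``x.d / cv``.
    For the slab phantoms, direction (0, 0, 1) propagates toward the
    epicardial (z = Lz) recording surface (transmural); a mostly-lateral
    direction with a small +z tilt emulates the concave circumferential
    front whose intramural layers lead the surface.
    """
    if cv <= 0:
        raise ValueError("conduction velocity must be positive")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    times = np.asarray(times, dtype=float)
    t_act = mesh.nodes @ d / cv          # (N,)
    arg = (times[:, None] - t_act[None, :]) / upstroke_tau
    sig = 1.0 / (1.0 + np.exp(-np.clip(arg, -500, 500)))
    return VmField(values=rest + amplitude * sig, times=times,
                   rest=rest, amplitude=amplitude)


@dataclass
class VesselElectrode:
    """Dipolar virtual-electrode pattern around a cylindrical cavity.

    The vessel axis runs along y at ``(x, z) = center``; ``radius`` is the
    cavity radius (mm).  The polar angle phi is measured from the +z (toward
    the epicardium) direction, so the term is ``+ve_amp`` on the cavity wall
    at the epicardial side and ``-ve_amp`` on the distal side, decaying as
    ``(a/r) exp(-(r-a)/ve_lam)`` into the tissue.  ``ve_amp`` grows with
    nominal shock strength.
    """

    center: tuple[float, float]  # (x, z), mm
    radius: float                # mm
    ve_amp: float                # mV
    ve_lam: float = 0.3          # mm


def shock_vm(mesh: TetMesh, e_dep: float, e_hyp: float, lam: float,
             vessel: VesselElectrode | None = None,
             base: float = REST_MV,
             v_cap: float | None = None) -> VmField:
    """Single-frame shock-end polarization snapshot.

    ``V(x) = base + e_dep exp(-d_epi/lam) - e_hyp exp(-d_endo/lam)
    + vessel term``, with d_epi/d_endo the distances to the epicardial
    (z max) and endocardial (z min) tissue surfaces.  ``e_dep``/``e_hyp``
    are positive magnitudes (mV) of the surface polarizations; ``lam`` is
    the boundary-layer decay constant (mm).

    ``v_cap`` (mV), if given, clips the field from above: the membrane's
    depolarized-side response saturates under strong shocks (already
    strongly depolarized tissue cannot depolarize much further), while
    hyperpolarization keeps growing — the asymmetry behind the observed
    decrease of optical polarization above vessels with shock strength.
    """
    if lam <= 0:
        raise ValueError("decay constant lam must be positive")
    tissue_nodes = np.unique(mesh.elements[mesh.region_tag == REGION_TISSUE])
    z_epi = mesh.nodes[tissue_nodes][:, 2].max()
    z_endo = mesh.nodes[tissue_nodes][:, 2].min()
    x = mesh.nodes[:, 0]
    z = mesh.nodes[:, 2]
    v = base + e_dep * np.exp(-(z_epi - z) / lam) \
        - e_hyp * np.exp(-(z - z_endo) / lam)
    if vessel is not None:
        xc, zc = vessel.center
        a = vessel.radius
        r = np.hypot(x - xc, z - zc)
        r_safe = np.maximum(r, a)
        cos_phi = np.where(r > 1e-12, (z - zc) / np.maximum(r, 1e-12), 0.0)
        v = v + vessel.ve_amp * (a / r_safe) * cos_phi \
            * np.exp(-np.maximum(r - a, 0.0) / vessel.ve_lam)
    if v_cap is not None:
        v = np.minimum(v, v_cap)
    return VmField(values=v[None, :], times=np.array([0.0]), rest=base)


def vessel_electrode_for(spec, ve_amp: float,
                         ve_lam: float = 0.3) -> VesselElectrode:
    """VesselElectrode matching a slab spec's cavity (errors if none)."""
    if spec.vessel is None:
        raise ValueError("slab spec has no vessel cavity")
    return VesselElectrode(center=spec.vessel_center,
                           radius=spec.vessel.diameter / 2.0,
                           ve_amp=ve_amp, ve_lam=ve_lam)


def shock_drive_series(drives=(10.0, 20.0, 40.0), e_dep_0: float = 100.0,
                       e_dep_slope: float = 1.5, e_hyp_gain: float = 8.0,
                       ve_gain: float = 15.0):
    """Surface and virtual-electrode amplitudes vs nominal shock drive (V).

    Anchored to the magnitudes bidomain shock simulations report: the
    epicardial depolarization exceeds 100 mV already at moderate shocks
    and keeps growing modestly (``e_dep = e_dep_0 + slope * D``); the
    endocardial hyperpolarization and the cavity virtual-electrode
    amplitude grow in proportion to the drive (``e_hyp = e_hyp_gain * D``,
    ``ve_amp = ve_gain * D`` — beyond +/-150 mV around the cavity at
    20 V).  The saturation of the depolarized-side *membrane response* is
    separate and lives in ``shock_vm``'s ``v_cap`` ceiling.  Returns a
    list of ``(drive, e_dep, e_hyp, ve_amp)``.
    """
    return [(float(d), float(e_dep_0 + e_dep_slope * d),
             float(e_hyp_gain * d), float(ve_gain * d)) for d in drives]


def read_vm(path, mesh: TetMesh | None = None) -> VmField:
    """Read a V_m field (wide CSV or binary+sidecar, by extension)."""
    from . import io

    path = str(path)
    if path.endswith(".csv"):
        times, values = io.read_vm_csv(path)
    else:
        times, values = io.read_vm_binary(path)
    field = VmField(values=values, times=times)
    if mesh is not None and field.values.shape[1] != mesh.n_nodes:
        raise ValueError(
            f"V_m has {field.values.shape[1]} nodes, mesh has {mesh.n_nodes}")
    return field


def write_vm(path, field: VmField) -> None:
    from . import io

    path = str(path)
    if path.endswith(".csv"):
        io.write_vm_csv(path, field.times, field.values)
    else:
        io.write_vm_binary(path, field.times, field.values)
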
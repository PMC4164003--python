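"""Optical-trace synthesis and upstroke / shock-polarization metrics.

The optical signal of a pixel is the scattering-volume-weighted average of
the transmembrane voltage:

    V_opt(t) = sum_e w_e Vbar_e(t) / sum_e w_e,

with ``w_e`` the pixel's per-element scattering-volume contribution and
``Vbar_e`` the mean of the element's four node voltages.  A spatially
uniform V_m is a fixed point of this average, so V_opt keeps V_m's units
and is bounded by the V_m extrema over contributing elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emission import ScatteringVolume
from .mesh import TetMesh
from .vm import VmField


@dataclass
class OpticalTrace:
    """Synthesized optical signal per frame for one pixel."""

    v_opt: np.ndarray
    times: np.ndarray
    pixel: object | None = None

    def __post_init__(self) -> None:
        self.v_opt = np.atleast_1d(np.asarray(self.v_opt, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if len(self.v_opt) != len(self.times):
            raise ValueError("trace/times length mismatch")
        if not np.all(np.isfinite(self.v_opt)):
            raise ValueError("trace values must be finite")


def synthesize_vopt(sv: ScatteringVolume, vm: VmField, mesh: TetMesh,
                    fractional_change: float | None = None) -> OpticalTrace:
    """Convolve a scattering volume with a V_m field into an optical trace.

    If `fractional_change` is given (e.g. 0.1), the normalized trace is
    re-expressed as a fractional fluorescence change on a unit background,
    replicating the experimental ~10%-of-background modulation; by default
    V_opt stays in mV.
    """
    if vm.values.shape[1] != mesh.n_nodes:
        raise ValueError("V_m field and mesh node counts differ")
    if sv.contribution.shape[0] != mesh.n_elements:
        raise ValueError("scattering volume and mesh element counts differ")
    idx = np.nonzero(sv.contribution > 0)[0]
    if idx.size == 0:
        raise ValueError("scattering volume has no contributing elements")
    w = sv.contribution[idx]
    # element-mean voltage, frames x contributing elements
    vbar = vm.values[:, mesh.elements[idx]].mean(axis=2)
    v_opt = vbar @ w / w.sum()
    if fractional_change is not None:
        lo, hi = v_opt.min(), v_opt.max()
        if hi > lo:
            v_opt = 1.0 + fractional_change * (v_opt - lo) / (hi - lo)
    return OpticalTrace(v_opt=v_opt, times=vm.times, pixel=sv.pixel)


def normalize_ap(trace: OpticalTrace) -> OpticalTrace:
    """Normalize an action potential between rest and peak depolarization.

    The resting level is the mean over the pre-upstroke frames (those before
    the signal first exceeds 1% of its full range above the minimum); the
    result rises from ~0 to 1.
    """
    v = trace.v_opt
    rng = v.max() - v.min()
    if rng <= 0:
        raise ValueError("flat trace cannot be normalized")
    above = v > v.min() + 0.01 * rng
    first = int(np.argmax(above))
    baseline = v[:first].mean() if first > 0 else v[0]
    denom = v.max() - baseline
    if denom <= 0:
        raise ValueError("trace has no depolarization above baseline")
    return OpticalTrace(v_opt=(v - baseline) / denom, times=trace.times,
                        pixel=trace.pixel)


def _first_upward_crossing(t: np.ndarray, v: np.ndarray,
                           level: float) -> float:
    """Time of the first upward crossing of `level`, linearly interpolated."""
    if v[0] >= level:
        return float(t[0])
    for i in range(1, len(v)):
        if v[i] >= level and v[i - 1] < level:
            f = (level - v[i - 1]) / (v[i] - v[i - 1])
            return float(t[i - 1] + f * (t[i] - t[i - 1]))
    raise ValueError(f"trace never crosses level {level}")


def upstroke_duration(trace: OpticalTrace) -> float:
    """10-90% depolarization interval of a (normalized) trace, ms.

    Uses the *first* upward crossing of each level so that a hump between
    the 10% and 90% levels does not reset the measurement.
    """
    n = normalize_ap(trace) if trace.v_opt.max() > 1.5 or trace.v_opt.min() < -0.5 \
        else trace
    t10 = _first_upward_crossing(n.times, n.v_opt, 0.1)
    t90 = _first_upward_crossing(n.times, n.v_opt, 0.9)
    return t90 - t10


def shock_polarization(trace_shock: OpticalTrace,
                       paced_reference: OpticalTrace) -> float:
    """Shock-end optical polarization as percent of paced AP amplitude.

    ``100 * (V_opt(shock-end) - v_rest) / APA`` with the resting level and
    amplitude taken from the paced reference trace of the same pixel.
    """
    v = paced_reference.v_opt
    rng = v.max() - v.min()
    if rng <= 0:
        raise ValueError("flat paced reference")
    above = v > v.min() + 0.01 * rng
    first = int(np.argmax(above))
    v_rest = v[:first].mean() if first > 0 else v[0]
    amplitude = v.max() - v_rest
    if amplitude <= 0:
        raise ValueError("paced reference has zero AP amplitude")
    v_shock = float(trace_shock.v_opt[-1])
    return 100.0 * (v_shock - v_rest) / amplitude
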
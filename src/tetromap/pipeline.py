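"""Pipeline driver: configuration, stage caching and reproducibility.

A run is described by a single YAML/JSON config with nested stage sections
(mesh / illumination / emission / vm / signal).  One global seed expands
deterministically into per-stage seeds, so re-running any stage in
isolation reproduces it bit-for-bit.  Every artifact gets a JSON sidecar
recording the seed and the hash of the config section that produced it;
stages whose inputs and section hash are unchanged are reused from cache.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import yaml

from .builder import SlabSpec, VesselSpec, build_slab_mesh
from .emission import central_pixels, run_emission
from .illumination import IlluminationConfig, run_illumination
from .mesh import EMISSION_669, ILLUMINATION_488, SALINE_BATH, \
    build_face_adjacency
from .signal import normalize_ap, synthesize_vopt, upstroke_duration
from .transport import TransportConfig
from .vm import CV_TRANSMURAL, plane_wave_vm
from . import io

log = logging.getLogger("tetromap")

_DEFAULTS: dict = {
    "seed": 0,
    "mesh": {"dims": [4.0, 4.0, 2.0], "spacing": 0.1, "bath_width": 0.1,
             "vessel_diameter": None, "vessel_depth": None},
    "transport": {"roulette_threshold": 1e-4, "roulette_survival": 0.1,
                  "index_matched": True, "n_exterior": 1.33},
    "illumination": {"total_packets": 200_000, "theta_illum": 0.0},
    "emission": {"total_packets": 500_000, "pixel_edges": [0.16, 0.32, 0.64]},
    "vm": {"mode": "plane", "direction": [0.0, 0.0, 1.0],
           "cv": CV_TRANSMURAL, "t_max": 30.0, "dt": 0.5},
    "output_dir": "tetromap_out",
}


def _merge(defaults: dict, user: dict) -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge(v, user.get(k, {}) if isinstance(user.get(k), dict) else {})
        else:
            out[k] = user.get(k, v)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return out


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration (defaults merged)."""

    raw: dict = dfield(default_factory=lambda: json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def load(cls, path=None, overrides: dict | None = None) -> "RunConfig":
        user = {}
        if path is not None:
            user = yaml.safe_load(Path(path).read_text()) or {}
        if overrides:
            user = {**user, **overrides}
        return cls(raw=_merge(_DEFAULTS, user))

    def section_hash(self, *sections: str) -> str:
        payload = {s: self.raw[s] for s in sections}
        payload["seed"] = self.raw["seed"]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.raw['seed']}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def _sidecar(path: Path, cfg: RunConfig, sections, seed: int) -> None:
    meta = {"config_hash": cfg.section_hash(*sections), "seed": seed,
            "sections": list(sections)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def _cached(path: Path, cfg: RunConfig, sections) -> bool:
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not (path.exists() and meta_path.exists()):
        return False
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError:
        return False
    return meta.get("config_hash") == cfg.section_hash(*sections)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute build-mesh -> illuminate -> emit -> make-vm -> signal.

    Returns a dict of artifact paths; cached stages are reused when their
    config sections and the global seed are unchanged.
    """
    out = Path(cfg.raw["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.json").write_text(json.dumps(cfg.raw, indent=2))
    artifacts = {"config": out / "config.resolved.json"}

    # --- mesh ---------------------------------------------------------------
    mcfg = cfg.raw["mesh"]
    vessel = None
    if mcfg["vessel_diameter"]:
        vessel = VesselSpec(diameter=mcfg["vessel_diameter"],
                            depth=mcfg["vessel_depth"])
    spec = SlabSpec(dims=tuple(mcfg["dims"]), spacing=mcfg["spacing"],
                    vessel=vessel, bath_width=mcfg["bath_width"])
    mesh_path = out / "mesh.vtu"
    if _cached(mesh_path, cfg, ["mesh"]):
        log.info("mesh: cache hit")
        mesh = io.read_vtu(mesh_path)[0]
    else:
        mesh = build_slab_mesh(spec)
        io.write_vtu(mesh_path, mesh)
        _sidecar(mesh_path, cfg, ["mesh"], cfg.raw["seed"])
    artifacts["mesh"] = mesh_path
    adjacency = build_face_adjacency(mesh)
    media_illum = [ILLUMINATION_488, SALINE_BATH]
    media_emis = [EMISSION_669, SALINE_BATH]
    tcfg = cfg.raw["transport"]

    def transport(stage):
        return TransportConfig(seed=cfg.stage_seed(stage), **tcfg)

    # --- illumination -------------------------------------------------------
    illum_path = out / "illum.vtu"
    if _cached(illum_path, cfg, ["mesh", "transport", "illumination"]):
        log.info("illumination: cache hit")
        _, cd = io.read_vtu(illum_path)
        absorbed = cd["absorbed_weight"]
    else:
        icfg = cfg.raw["illumination"]
        fld = run_illumination(
            mesh, adjacency, media_illum,
            IlluminationConfig(total_packets=icfg["total_packets"],
                               theta_illum=icfg["theta_illum"]),
            transport("illumination"))
        absorbed = fld.absorbed_weight
        io.write_vtu(illum_path, mesh,
                     {"absorbed_weight": absorbed, "density": fld.density})
        _sidecar(illum_path, cfg, ["mesh", "transport", "illumination"],
                 cfg.stage_seed("illumination"))
    artifacts["illumination"] = illum_path

    # --- emission -----------------------------------------------------------
    ecfg = cfg.raw["emission"]
    pixels = central_pixels(mesh, edges=ecfg["pixel_edges"])
    sv_path = out / "scattering_volumes.h5"
    if _cached(sv_path, cfg, ["mesh", "transport", "illumination", "emission"]):
        log.info("emission: cache hit")
        svs = _read_sv_h5(sv_path, pixels)
    else:
        seed = cfg.stage_seed("emission")
        svs, _stats = run_emission(
            mesh, adjacency, absorbed, media_emis, pixels,
            total_packets=ecfg["total_packets"],
            transport=transport("emission"),
            rng=np.random.default_rng(seed))
        _write_sv_h5(sv_path, svs)
        _sidecar(sv_path, cfg,
                 ["mesh", "transport", "illumination", "emission"], seed)
    artifacts["scattering_volumes"] = sv_path

    # --- vm + signal --------------------------------------------------------
    vcfg = cfg.raw["vm"]
    times = np.arange(0.0, vcfg["t_max"] + 1e-9, vcfg["dt"])
    vmf = plane_wave_vm(mesh, vcfg["direction"], vcfg["cv"], times)
    traces_path = out / "traces.csv"
    metrics = {}
    cols = {"time_ms": times}
    for sv in svs:
        tr = synthesize_vopt(sv, vmf, mesh)
        name = f"pixel_{sv.pixel.edge * 1000:.0f}um"
        cols[name] = tr.v_opt
        try:
            metrics[name] = {"upstroke_ms": upstroke_duration(normalize_ap(tr))}
        except ValueError:
            metrics[name] = {"upstroke_ms": None}
    import pandas as pd

    pd.DataFrame(cols).to_csv(traces_path, index=False)
    _sidecar(traces_path, cfg, list(cfg.raw.keys() - {"output_dir"})
             if isinstance(cfg.raw, dict) else [], cfg.raw["seed"])
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    artifacts["traces"] = traces_path
    artifacts["metrics"] = out / "metrics.json"
    return artifacts


def _write_sv_h5(path, svs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for i, sv in enumerate(svs):
            grp = f.create_group(f"pixel_{i}")
            grp.attrs["center"] = sv.pixel.center
            grp.attrs["edge"] = sv.pixel.edge
            grp.attrs["total_signal"] = sv.total_signal
            nz = np.nonzero(sv.contribution)[0]
            grp.create_dataset("element", data=nz)
            grp.create_dataset("contribution", data=sv.contribution[nz])
            grp.attrs["n_elements"] = len(sv.contribution)


def _read_sv_h5(path, pixels=None):
    import h5py

    from .emission import DetectorPixel, ScatteringVolume

    svs = []
    with h5py.File(path, "r") as f:
        for i in range(len(f)):
            grp = f[f"pixel_{i}"]
            contrib = np.zeros(int(grp.attrs["n_elements"]))
            contrib[grp["element"][:]] = grp["contribution"][:]
            svs.append(ScatteringVolume(
                pixel=DetectorPixel(center=tuple(grp.attrs["center"]),
                                    edge=float(grp.attrs["edge"])),
                contribution=contrib,
                total_signal=float(grp.attrs["total_signal"])))
    return svs
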
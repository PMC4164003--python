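"""Monte Carlo photon-packet transport on tetrahedral meshes.

Physics (the MCML weight scheme, walked tetrahedron-by-tetrahedron):

* free-flight step length ``s = -ln(xi) / mu_t`` with
  ``mu_t = mu_a + mu_s``,
* at the end of each step the packet deposits ``dW = W mu_a / mu_t`` in the
  element it occupies and scatters by a Henyey-Greenstein deflection angle
  (``<cos theta> = g``) with uniform azimuth,
* a step crossing element faces is chained through neighbours; faces between
  different media trigger Snell/Fresnel reflection-or-transmission (skipped
  entirely in index-matched mode),
* non-scattering (bath) elements are crossed in straight lines with the
  remaining step length and weight frozen,
* packets below the roulette threshold survive with probability ``p`` and
  weight boost ``1/p``, else terminate — keeping the expectation unbiased.

All kernels are numba-jitted and consume flat arrays produced by
``mesh.build_face_adjacency``.  Randomness is one Mersenne-Twister stream
per packet, seeded from ``(seed, packet index)`` through a splitmix64 hash,
so results are reproducible and independent of launch order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .mesh import EXTERIOR, FaceAdjacency, TetMesh, media_arrays

# packet fates
ABSORBED = 0   # terminated by roulette (weight fully deposited in expectation)
EXITED = 1     # left the domain through an exterior face
ABORTED = 2    # event-count guard tripped (suspected traversal loop)

_NUDGE = 1e-7  # mm, advance past a crossed face before re-testing planes


@dataclass
class TransportConfig:
    """Engine configuration.

    ``index_matched=True`` disables all Fresnel physics (every interface is
    transparent); otherwise refraction/reflection uses the per-medium
    refractive indices and ``n_exterior`` outside the domain.
    """

    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    index_matched: bool = True
    n_exterior: float = 1.33
    max_events: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.roulette_threshold < 1.0:
            raise ValueError("roulette_threshold must lie in [0, 1)")
        if not 0.0 < self.roulette_survival <= 1.0:
            raise ValueError("roulette_survival must lie in (0, 1]")


# ---------------------------------------------------------------------------
# elementary pieces (jitted, directly unit-testable)
# ---------------------------------------------------------------------------

@njit(cache=True)
def packet_seed(base: np.int64, i: np.int64) -> np.int64:
    """splitmix64 hash of (base, i) folded to a 31-bit MT seed."""
    x = (np.uint64(base) + np.uint64(0x9E3779B97F4A7C15) * np.uint64(i + 1))
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    x = x ^ (x >> np.uint64(31))
    return np.int64(x & np.uint64(0x7FFFFFFF))


@njit(cache=True)
def sample_step(xi: float, mu_t: float) -> float:
    """Free-flight step length s = -ln(xi)/mu_t, mm (xi in (0, 1])."""
    return -math.log(xi) / mu_t


@njit(cache=True)
def hg_cos_theta(g: float, xi: float) -> float:
    """Henyey-Greenstein deflection cosine from one uniform draw."""
    if abs(g) < 1e-8:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def rotate_direction(ux: float, uy: float, uz: float,
                     ct: float, psi: float):
    """Rotate a unit direction by deflection cos(theta)=ct, azimuth psi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(psi)
    sp = math.sin(psi)
    if abs(uz) > 1.0 - 1e-12:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def fresnel_reflectance(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for |cos| of the incidence angle.

    Returns 1.0 beyond the critical angle (total internal reflection).
    """
    if n1 == n2:
        return 0.0
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    if sin_i < 1e-6:  # normal incidence limit
        r = (n1 - n2) / (n1 + n2)
        return r * r
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def refract(ux, uy, uz, nx, ny, nz, n1, n2):
    """Snell-refracted direction; the normal must oppose the incident ray."""
    cos_i = -(ux * nx + uy * ny + uz * nz)
    eta = n1 / n2
    sin2t = eta * eta * (1.0 - cos_i * cos_i)
    cos_t = math.sqrt(max(0.0, 1.0 - sin2t))
    k = eta * cos_i - cos_t
    tx = eta * ux + k * nx
    ty = eta * uy + k * ny
    tz = eta * uz + k * nz
    norm = math.sqrt(tx * tx + ty * ty + tz * tz)
    return tx / norm, ty / norm, tz / norm


@njit(cache=True)
def _exit_face(px, py, pz, ux, uy, uz, normals, offsets, elem):
    """Lowest positive distance to an exit plane of `elem` and its face.

    Exit candidates are faces whose inward normal opposes the direction of
    travel.  Returns (-1, 0.0) when grazing leaves no candidate; the caller
    nudges the packet and retries.
    """
    tmin = 1.0e30
    fmin = -1
    for f in range(4):
        nx = normals[elem, f, 0]
        ny = normals[elem, f, 1]
        nz = normals[elem, f, 2]
        ndu = nx * ux + ny * uy + nz * uz
        if ndu < -1e-12:
            t = (offsets[elem, f] - (nx * px + ny * py + nz * pz)) / ndu
            if t < tmin:
                tmin = t
                fmin = f
    if fmin < 0:
        return -1, 0.0
    if tmin < 0.0:
        tmin = 0.0
    return fmin, tmin


# ---------------------------------------------------------------------------
# single-packet trace (the heart of the engine)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trace(px, py, pz, ux, uy, uz, w, elem,
           normals, offsets, neighbor, medium_id,
           mu_a_m, mu_t_m, g_m, n_m, scat_m,
           index_matched, n_ext,
           r_thresh, r_surv, max_events,
           absorbed, record_absorb, stats):
    """Trace one packet to termination.

    Returns (fate, x, y, z, ux, uy, uz, weight).  `stats` accumulates
    [absorbed_w, exited_w, roulette_killed_w, roulette_gain_w, aborted_n].
    """
    s_rem = 0.0
    events = 0
    while events < max_events:
        events += 1
        mid = medium_id[elem]
        scattering = scat_m[mid]
        if scattering:
            if s_rem <= 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                s_rem = -math.log(xi) / mu_t_m[mid]
            fmin, tmin = _exit_face(px, py, pz, ux, uy, uz,
                                    normals, offsets, elem)
            if fmin < 0:  # grazing degeneracy: nudge and retry
                px += ux * _NUDGE
                py += uy * _NUDGE
                pz += uz * _NUDGE
                continue
            if s_rem < tmin:
                # step ends inside this element: absorb, roulette, scatter
                px += ux * s_rem
                py += uy * s_rem
                pz += uz * s_rem
                s_rem = 0.0
                dw = w * mu_a_m[mid] / mu_t_m[mid]
                if record_absorb:
                    absorbed[elem] += dw
                stats[0] += dw
                w -= dw
                if w < r_thresh:
                    if np.random.random() < r_surv:
                        gain = w / r_surv - w
                        stats[3] += gain
                        w = w / r_surv
                    else:
                        stats[2] += w
                        return ABSORBED, px, py, pz, ux, uy, uz, 0.0
                ct = hg_cos_theta(g_m[mid], np.random.random())
                psi = 2.0 * math.pi * np.random.random()
                ux, uy, uz = rotate_direction(ux, uy, uz, ct, psi)
                continue
            # face crossing
            px += ux * tmin
            py += uy * tmin
            pz += uz * tmin
            s_rem -= tmin
        else:
            # bath free flight: straight ray, weight and s_rem frozen
            fmin, tmin = _exit_face(px, py, pz, ux, uy, uz,
                                    normals, offsets, elem)
            if fmin < 0:
                px += ux * _NUDGE
                py += uy * _NUDGE
                pz += uz * _NUDGE
                continue
            px += ux * tmin
            py += uy * tmin
            pz += uz * tmin

        nxt = neighbor[elem, fmin]
        if nxt == EXTERIOR:
            if index_matched or n_m[mid] == n_ext:
                stats[1] += w
                return EXITED, px, py, pz, ux, uy, uz, w
            cos_i = -(ux * normals[elem, fmin, 0]
                      + uy * normals[elem, fmin, 1]
                      + uz * normals[elem, fmin, 2])
            refl = fresnel_reflectance(n_m[mid], n_ext, cos_i)
            if np.random.random() < refl:
                dot = (ux * normals[elem, fmin, 0]
                       + uy * normals[elem, fmin, 1]
                       + uz * normals[elem, fmin, 2])
                ux -= 2.0 * dot * normals[elem, fmin, 0]
                uy -= 2.0 * dot * normals[elem, fmin, 1]
                uz -= 2.0 * dot * normals[elem, fmin, 2]
            else:
                ux, uy, uz = refract(ux, uy, uz,
                                     normals[elem, fmin, 0],
                                     normals[elem, fmin, 1],
                                     normals[elem, fmin, 2],
                                     n_m[mid], n_ext)
                stats[1] += w
                return EXITED, px, py, pz, ux, uy, uz, w
        else:
            nmid = medium_id[nxt]
            if nmid != mid and (not index_matched) and n_m[nmid] != n_m[mid]:
                cos_i = -(ux * normals[elem, fmin, 0]
                          + uy * normals[elem, fmin, 1]
                          + uz * normals[elem, fmin, 2])
                refl = fresnel_reflectance(n_m[mid], n_m[nmid], cos_i)
                if np.random.random() < refl:
                    dot = (ux * normals[elem, fmin, 0]
                           + uy * normals[elem, fmin, 1]
                           + uz * normals[elem, fmin, 2])
                    ux -= 2.0 * dot * normals[elem, fmin, 0]
                    uy -= 2.0 * dot * normals[elem, fmin, 1]
                    uz -= 2.0 * dot * normals[elem, fmin, 2]
                else:
                    ux, uy, uz = refract(ux, uy, uz,
                                         normals[elem, fmin, 0],
                                         normals[elem, fmin, 1],
                                         normals[elem, fmin, 2],
                                         n_m[mid], n_m[nmid])
                    elem = nxt
            else:
                elem = nxt
        px += ux * _NUDGE
        py += uy * _NUDGE
        pz += uz * _NUDGE
    stats[4] += 1.0
    return ABORTED, px, py, pz, ux, uy, uz, w


# ---------------------------------------------------------------------------
# batch drivers
# ---------------------------------------------------------------------------

@njit(cache=True)
def illumination_kernel(seed, packet_tri, tri_pts, tri_elem,
                        dx, dy, dz, w0,
                        normals, offsets, neighbor, medium_id,
                        mu_a_m, mu_t_m, g_m, n_m, scat_m,
                        index_matched, n_ext, r_thresh, r_surv, max_events,
                        absorbed, stats):
    """Launch one packet per entry of `packet_tri` from the surface triangles.

    Launch points are uniform (barycentric) within each triangle; the launch
    direction is the common beam direction (dx, dy, dz); packets start with
    weight `w0` just inside the surface element of their triangle.
    """
    n = packet_tri.size
    for i in range(n):
        np.random.seed(packet_seed(seed, i))
        tr = packet_tri[i]
        r1 = np.random.random()
        r2 = np.random.random()
        if r1 + r2 > 1.0:
            r1 = 1.0 - r1
            r2 = 1.0 - r2
        ax = tri_pts[tr, 0, 0]
        ay = tri_pts[tr, 0, 1]
        az = tri_pts[tr, 0, 2]
        px = ax + r1 * (tri_pts[tr, 1, 0] - ax) + r2 * (tri_pts[tr, 2, 0] - ax)
        py = ay + r1 * (tri_pts[tr, 1, 1] - ay) + r2 * (tri_pts[tr, 2, 1] - ay)
        pz = az + r1 * (tri_pts[tr, 1, 2] - az) + r2 * (tri_pts[tr, 2, 2] - az)
        px += dx * _NUDGE
        py += dy * _NUDGE
        pz += dz * _NUDGE
        _trace(px, py, pz, dx, dy, dz, w0, tri_elem[tr],
               normals, offsets, neighbor, medium_id,
               mu_a_m, mu_t_m, g_m, n_m, scat_m,
               index_matched, n_ext, r_thresh, r_surv, max_events,
               absorbed, True, stats)


@njit(cache=True)
def emission_kernel(seed, src_elem, nodes, elements,
                    normals, offsets, neighbor, medium_id,
                    mu_a_m, mu_t_m, g_m, n_m, scat_m,
                    index_matched, n_ext, r_thresh, r_surv, max_events,
                    pix_cx, pix_cy, pix_half, z_epi,
                    contrib, totals, absorbed, stats):
    """Launch isotropic fluorescence packets from `src_elem` and detect exits.

    A packet exiting the domain with an upward trajectory is projected along
    its straight exterior ray onto the epicardial plane z = `z_epi`; if the
    intersection falls inside a pixel footprint (half-open square), the exit
    weight is credited to that pixel's scattering volume at the packet's
    origin element.
    """
    n = src_elem.size
    npix = pix_cx.size
    for i in range(n):
        np.random.seed(packet_seed(seed, i))
        e = src_elem[i]
        # uniform barycentric point in the source tetrahedron (folding trick)
        s = np.random.random()
        t = np.random.random()
        u = np.random.random()
        if s + t > 1.0:
            s = 1.0 - s
            t = 1.0 - t
        if t + u > 1.0:
            tmp = u
            u = 1.0 - s - t
            t = 1.0 - tmp
        elif s + t + u > 1.0:
            tmp = u
            u = s + t + u - 1.0
            s = 1.0 - t - tmp
        a = 1.0 - s - t - u
        n0 = elements[e, 0]
        n1 = elements[e, 1]
        n2 = elements[e, 2]
        n3 = elements[e, 3]
        px = (a * nodes[n0, 0] + s * nodes[n1, 0]
              + t * nodes[n2, 0] + u * nodes[n3, 0])
        py = (a * nodes[n0, 1] + s * nodes[n1, 1]
              + t * nodes[n2, 1] + u * nodes[n3, 1])
        pz = (a * nodes[n0, 2] + s * nodes[n1, 2]
              + t * nodes[n2, 2] + u * nodes[n3, 2])
        # isotropic direction
        cz = 2.0 * np.random.random() - 1.0
        phi = 2.0 * math.pi * np.random.random()
        sz = math.sqrt(max(0.0, 1.0 - cz * cz))
        ux = sz * math.cos(phi)
        uy = sz * math.sin(phi)
        uz = cz
        fate, qx, qy, qz, vx, vy, vz, w = _trace(
            px, py, pz, ux, uy, uz, 1.0, e,
            normals, offsets, neighbor, medium_id,
            mu_a_m, mu_t_m, g_m, n_m, scat_m,
            index_matched, n_ext, r_thresh, r_surv, max_events,
            absorbed, False, stats)
        if fate == EXITED and vz > 1e-12:
            tq = (z_epi - qz) / vz
            xq = qx + vx * tq
            yq = qy + vy * tq
            for p in range(npix):
                if (pix_cx[p] - pix_half[p] <= xq < pix_cx[p] + pix_half[p]
                        and pix_cy[p] - pix_half[p] <= yq
                        < pix_cy[p] + pix_half[p]):
                    contrib[p, e] += w
                    totals[p] += w


# ---------------------------------------------------------------------------
# python-level wrappers
# ---------------------------------------------------------------------------

def _kernel_args(mesh: TetMesh, adjacency: FaceAdjacency, media, cfg):
    mu_a, _mu_s, mu_t, g, n, scat = media_arrays(media)
    return (adjacency.normals, adjacency.offsets, adjacency.neighbor,
            mesh.medium_id, mu_a, mu_t, g, n, scat,
            cfg.index_matched, cfg.n_exterior,
            cfg.roulette_threshold, cfg.roulette_survival, cfg.max_events)


def trace_packet(mesh: TetMesh, adjacency: FaceAdjacency, media,
                 position, direction, element: int,
                 cfg: TransportConfig | None = None,
                 weight: float = 1.0, seed: int = 0,
                 field: np.ndarray | None = None):
    """Trace one packet to termination (test / inspection entry point).

    Returns ``(fate, exit_position, exit_direction, exit_weight, stats)``
    where stats = [absorbed, exited, roulette_killed, roulette_gain,
    aborted].  If `field` is given, absorbed weight is deposited into it.
    """
    cfg = cfg or TransportConfig()
    record = field is not None
    if field is None:
        field = np.zeros(1)
    stats = np.zeros(5)
    np.random.seed(int(packet_seed(cfg.seed, seed)))
    px, py, pz = (float(v) for v in position)
    ux, uy, uz = (float(v) for v in direction)
    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("direction must be unit-norm")
    fate, qx, qy, qz, vx, vy, vz, w = _trace(
        px, py, pz, ux, uy, uz, float(weight), int(element),
        *_kernel_args(mesh, adjacency, media, cfg)[:14],
        field, record, stats)
    return fate, np.array([qx, qy, qz]), np.array([vx, vy, vz]), w, stats


def scatter_hg(direction, g: float, rng: np.random.Generator):
    """Sample a Henyey-Greenstein scattered direction (numpy RNG driven)."""
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be unit-norm")
    ct = hg_cos_theta(g, rng.random())
    psi = 2.0 * math.pi * rng.random()
    return np.array(rotate_direction(d[0], d[1], d[2], ct, psi))


def fresnel_event(n1: float, n2: float, direction, normal,
                  rng: np.random.Generator):
    """One reflect-or-transmit decision at an interface.

    `normal` must oppose the incident direction (point back into the
    incident medium).  Returns ``("reflected"|"transmitted", new_direction)``.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = float(-np.dot(d, n))
    refl = fresnel_reflectance(n1, n2, cos_i)
    if rng.random() < refl:
        return "reflected", d - 2.0 * np.dot(d, n) * n
    return "transmitted", np.array(refract(d[0], d[1], d[2],
                                           n[0], n[1], n[2], n1, n2))


def roulette(weight: float, cfg: TransportConfig, rng: np.random.Generator):
    """Russian roulette below threshold: (survives, new_weight)."""
    if weight >= cfg.roulette_threshold or cfg.roulette_threshold == 0.0:
        return True, weight
    if rng.random() < cfg.roulette_survival:
        return True, weight / cfg.roulette_survival
    return False, 0.0


def deposit_absorption(weight: float, medium, field: np.ndarray,
                       element: int) -> float:
    """Deposit dW = W mu_a/(mu_a+mu_s) into `field[element]`; returns dW."""
    if not medium.scattering:
        raise ValueError("absorption deposit requested in a bath medium")
    dw = weight * medium.mu_a / medium.mu_t
    field[element] += dw
    return dw
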
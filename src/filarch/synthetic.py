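"""Synthetic cytoskeleton scenes and meshwork images with known ground truth.

The 3D generator emulates the architecture of the thin cell periphery as
seen in binned tomograms: two parallel PM voxel slabs bounding a
190-260 nm gap, actin filaments that are mostly PM-parallel and mostly
PM-anchored, bundles as parallel ladders at ~12.5 nm spacing, a
controllable quasi-orthogonal fraction, "netlike" (mutually crossing at
60-90 deg) versus "blooming" (radial, near-parallel) anchored
architectures, spherical insulin granules, and gently curved MTs.
Filaments are straight segments — at the 120-600 nm lengths simulated,
actin's ~10 um persistence length makes curvature negligible.

Every scene is deterministic given the spec seed; independent random
streams per component (filaments, granules, MTs) keep, e.g., granule
counts from perturbing the filament layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meshwork import MeshworkImage, DEFAULT_PIXEL_SIZE_NM
from .models import (
    Condition,
    Filament,
    FilamentKind,
    MaskRole,
    SceneBundle,
    VolumeMask,
)

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "generate_meshwork"]

PM_THICKNESS_NM = 13.4      # one tracing-template diameter worth of membrane
PM_BOTTOM_CENTER_NM = 50.0  # z of the lower membrane slab center
SITE_SPACING_NM = 220.0     # anchor-site lattice; keeps clusters > 120 nm apart
SITE_JITTER_NM = 40.0


@dataclass
class SceneSpec:
    """Generation parameters for one synthetic tomogram-equivalent scene.

    Defaults describe a basal-like periphery: 300 actin filaments, 97%
    PM-parallel, 90% anchored, 70% bundled at 12.5 nm spacing, netlike
    anchored architecture, 190.5 nm periphery height.
    """

    seed: int
    n_actin: int = 300
    n_mt: int = 4
    quasi_orthogonal_fraction: float = 0.03
    bundle_fraction: float = 0.70
    bundle_spacing: float = 12.5        # nm
    bundle_jitter_sd: float = 0.4       # nm
    bundle_size: int = 5                # filaments per ladder
    architecture: str = "netlike"       # netlike | blooming | mixed
    anchored_fraction: float = 0.90
    periphery_height: float = 190.5     # nm, slab center to slab center
    n_isg: int = 8
    isg_radius_mean: float = 150.0      # nm
    isg_radius_sd: float = 25.0
    extent: tuple[float, float, float] = (1800.0, 1300.0, 360.0)  # nm, xyz
    voxel_size: float = 2.68            # nm
    condition: str = "synthetic"
    scene_id: str = "synthetic_scene"
    rasterize_masks: bool = True

    def __post_init__(self) -> None:
        for name in ("quasi_orthogonal_fraction", "bundle_fraction",
                     "anchored_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.extent) <= 0 or self.voxel_size <= 0:
            raise ValueError("extent and voxel_size must be positive")
        if self.architecture not in ("netlike", "blooming", "mixed"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        top = PM_BOTTOM_CENTER_NM + self.periphery_height + PM_THICKNESS_NM
        if top > self.extent[2]:
            raise ValueError(
                f"periphery_height {self.periphery_height} nm does not fit "
                f"the z extent {self.extent[2]} nm")

    @classmethod
    def preset(cls, condition: str, seed: int, **overrides) -> "SceneSpec":
        """Basal or phase2 study conditions as generator parameters."""
        base = {
            "basal": dict(quasi_orthogonal_fraction=0.03, architecture="netlike",
                          periphery_height=190.5, anchored_fraction=0.90,
                          condition="basal"),
            "phase2": dict(quasi_orthogonal_fraction=0.15,
                           architecture="blooming",
                           periphery_height=258.4, anchored_fraction=0.71,
                           condition="phase2"),
        }[condition]
        base.update(overrides)
        return cls(seed=seed, **base)


@dataclass
class GroundTruth:
    """Per-filament true classes plus the scene-level scalars."""

    filaments: pd.DataFrame        # filament_id, bundled, reoriented, anchored
    architecture: str
    periphery_height: float
    granules: pd.DataFrame = field(default_factory=pd.DataFrame)
    # centers (x,y,z) and radii in nm

    @property
    def quasi_orthogonal_fraction(self) -> float:
        return float(self.filaments["reoriented"].mean())


def _spherical_dir(azimuth_rad: float, elevation_rad: float) -> np.ndarray:
    c = np.cos(elevation_rad)
    return np.array([c * np.cos(azimuth_rad), c * np.sin(azimuth_rad),
                     np.sin(elevation_rad)])


def _cap_length(start: np.ndarray, direction: np.ndarray, length: float,
                extent: np.ndarray, margin: float = 5.0) -> float:
    """Largest usable length so the segment stays inside the extent box."""
    t_max = length
    for ax in range(3):
        d = direction[ax]
        if d > 1e-12:
            t_max = min(t_max, (extent[ax] - margin - start[ax]) / d)
        elif d < -1e-12:
            t_max = min(t_max, (margin - start[ax]) / d)
    return max(t_max, 0.0)


def _segment_filament(fid: str, kind: FilamentKind, start: np.ndarray,
                      direction: np.ndarray, length: float,
                      node_step: float = 30.0) -> Filament:
    n = max(int(np.ceil(length / node_step)), 1)
    t = np.linspace(0.0, length, n + 1)
    nodes = start[None, :] + t[:, None] * direction[None, :]
    return Filament(fid, kind, nodes)


def _seg_min_dist(p0: np.ndarray, d0: np.ndarray, l0: float,
                  p1: np.ndarray, d1: np.ndarray, l1: float) -> float:
    """Minimum distance between two 3D segments (closed form)."""
    u = d0 * l0
    v = d1 * l1
    w0 = p0 - p1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    den = a * c - b * b
    if den > 1e-12:
        s = np.clip((b * e - c * d) / den, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(w0 + u * s - v * t))


class _Clearance:
    """Registry of placed axis segments with exclusion halos.

    Distance checks are vectorized over all registered segments (one
    Gauss-Seidel refinement of the unconstrained minimizer, exact for
    interior-crossing pairs and conservative enough for packing).
    """

    def __init__(self, clearance: float = 20.0) -> None:
        self._P: list[np.ndarray] = []
        self._D: list[np.ndarray] = []
        self._L: list[float] = []
        self._H: list[float] = []
        self.clearance = clearance

    def ok(self, p: np.ndarray, d: np.ndarray, length: float,
           halo: float = 0.0) -> bool:
        if not self._P:
            return True
        P = np.asarray(self._P)
        V = np.asarray(self._D) * np.asarray(self._L)[:, None]
        u = np.asarray(d, float) * float(length)
        W0 = np.asarray(p, float)[None, :] - P
        a = float(u @ u)
        b = V @ u
        c = np.einsum("ij,ij->i", V, V)
        dd = W0 @ u
        e = np.einsum("ij,ij->i", V, W0)
        den = a * c - b * b
        s = np.where(den > 1e-12, (b * e - c * dd) / np.maximum(den, 1e-12),
                     0.0)
        s = np.clip(s, 0.0, 1.0)
        t = np.clip((b * s + e) / np.maximum(c, 1e-12), 0.0, 1.0)
        if a > 1e-12:
            s = np.clip((b * t - dd) / a, 0.0, 1.0)
        diff = W0 + s[:, None] * u[None, :] - t[:, None] * V
        dist = np.linalg.norm(diff, axis=1)
        return bool(np.all(dist >= np.asarray(self._H) + halo
                           + self.clearance))

    def add(self, p: np.ndarray, d: np.ndarray, length: float,
            halo: float = 0.0) -> None:
        self._P.append(np.asarray(p, float))
        self._D.append(np.asarray(d, float))
        self._L.append(float(length))
        self._H.append(float(halo))


def _anchor_sites(extent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    margin = 80.0
    xs = np.arange(margin, extent[0] - margin + 1e-9, SITE_SPACING_NM)
    ys = np.arange(margin, extent[1] - margin + 1e-9, SITE_SPACING_NM)
    sites = np.array([(x, y) for x in xs for y in ys])
    rng.shuffle(sites)
    return sites


def generate_scene(spec: SceneSpec) -> tuple[SceneBundle, GroundTruth]:
    """Generate one scene plus its ground truth; deterministic given seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_f, rng_g, rng_m = (np.random.default_rng(c) for c in ss.spawn(3))
    extent = np.asarray(spec.extent, dtype=float)

    n_qo = int(round(spec.quasi_orthogonal_fraction * spec.n_actin))
    n_par = spec.n_actin - n_qo
    n_anchored_target = int(round(spec.anchored_fraction * spec.n_actin))
    # quasi-orthogonal filaments are always anchored: in a <=260 nm gap a
    # >=120 nm filament at >=45 deg elevation cannot keep both ends 60 nm
    # from both membranes
    a_par = int(np.clip(n_anchored_target - n_qo, 0, n_par))
    n_bundled = min(int(round(spec.bundle_fraction * spec.n_actin)), a_par)

    z_bot_inner = PM_BOTTOM_CENTER_NM + PM_THICKNESS_NM / 2
    z_top_inner = PM_BOTTOM_CENTER_NM + spec.periphery_height \
        - PM_THICKNESS_NM / 2
    gap = z_top_inner - z_bot_inner
    mid_lo, mid_hi = z_bot_inner + 70.0, z_top_inner - 70.0
    if mid_hi <= mid_lo and (n_par - a_par) > 0:
        raise ValueError(
            "infeasible packing: periphery too thin for the requested "
            f"number of non-anchored filaments (free band "
            f"{mid_hi - mid_lo:.1f} nm)")

    sites = _anchor_sites(extent, rng_f)
    n_qo_clusters = max(n_qo // 2, 0)
    needed_sites = n_qo_clusters + 1
    if len(sites) < needed_sites:
        raise ValueError(
            f"infeasible packing: {needed_sites} anchor clusters but only "
            f"{len(sites)} sites fit the {extent[:2]} nm extent")

    filaments: list[Filament] = []
    truth_rows: list[dict] = []
    fid_counter = 0
    crowded = {"ladder": 0, "pair": 0}

    def new_fid() -> str:
        nonlocal fid_counter
        fid_counter += 1
        return f"actin_{fid_counter:04d}"

    def add(fil: Filament, bundled: bool, reoriented: bool, anchored: bool):
        filaments.append(fil)
        truth_rows.append({"filament_id": fil.filament_id, "bundled": bundled,
                           "reoriented": reoriented, "anchored": anchored})

    # --- quasi-orthogonal anchored clusters -------------------------------
    site_idx = 0
    placed_qo = 0
    cluster_arch = []
    for c in range(n_qo_clusters):
        if spec.architecture == "mixed":
            cluster_arch.append("netlike" if c % 2 == 0 else "blooming")
        else:
            cluster_arch.append(spec.architecture)
    for c in range(n_qo_clusters):
        site = sites[site_idx]; site_idx += 1
        base = np.array([site[0], site[1], 0.0])
        base[:2] += rng_f.uniform(-SITE_JITTER_NM / 4, SITE_JITTER_NM / 4, 2)
        k_members = 2 if placed_qo + 2 <= n_qo else 1
        phi0 = rng_f.uniform(0, 2 * np.pi)
        if cluster_arch[c] == "netlike":
            # target a crossing angle gamma in the netlike 60-90 band;
            # for nearly opposite azimuths the directed angle is close to
            # 180 - (theta1 + theta2)
            azimuths = [phi0, phi0 + np.radians(rng_f.uniform(174.0, 180.0))]
            gamma = rng_f.uniform(63.0, 84.0)
            t_lo = max(48.0, 180.0 - gamma - 72.0)
            t_hi = min(72.0, 180.0 - gamma - 48.0)
            th1 = rng_f.uniform(t_lo, t_hi)
            thetas = [th1, 180.0 - gamma - th1]
        else:  # blooming: radial near-parallel projections, mostly steep
            azimuths = [phi0 + np.radians(rng_f.uniform(-8.0, 8.0))
                        for _ in range(k_members)]
            mean_t = rng_f.uniform(58.0, 78.0)
            thetas = [float(np.clip(mean_t + rng_f.uniform(-4.0, 4.0),
                                    48.0, 80.0)) for _ in range(k_members)]
        offsets = [np.zeros(2)] + [
            rng_f.uniform(15.0, 45.0) * _unit2(rng_f)
            for _ in range(k_members - 1)]
        for mmb in range(k_members):
            theta = np.radians(thetas[mmb])
            z_anchor = z_bot_inner + rng_f.uniform(2.0, 30.0)
            start = base + np.array([offsets[mmb][0], offsets[mmb][1],
                                     z_anchor])
            direction = _spherical_dir(azimuths[mmb], theta)
            # the thin gap caps reoriented filaments near ~100-140 nm:
            # far ends stay >= 70 nm below the top membrane
            max_len = (z_top_inner - 70.0 - z_anchor) / np.sin(theta)
            length = min(rng_f.uniform(120.0, 170.0), max_len)
            length = _cap_length(start, direction, length, extent)
            if length < 60.0:  # pathological corner: recenter the member
                start[:2] = extent[:2] / 2
                length = min(rng_f.uniform(120.0, 170.0), max_len,
                             _cap_length(start, direction, 170.0, extent))
            add(_segment_filament(new_fid(), FilamentKind.ACTIN, start,
                                  direction, length),
                bundled=False, reoriented=True, anchored=True)
            placed_qo += 1
    while placed_qo < n_qo:  # leftover: isolated quasi-orthogonal filament
        if site_idx >= len(sites):
            raise ValueError("infeasible packing: not enough anchor sites "
                             "for the quasi-orthogonal clusters")
        site = sites[site_idx]; site_idx += 1
        theta = np.radians(rng_f.uniform(48.0, 58.0))
        start = np.array([site[0], site[1], z_bot_inner +
                          rng_f.uniform(2.0, 30.0)])
        direction = _spherical_dir(rng_f.uniform(0, 2 * np.pi), theta)
        length = _cap_length(start, direction,
                             rng_f.uniform(120.0, 170.0), extent)
        add(_segment_filament(new_fid(), FilamentKind.ACTIN, start,
                              direction, length),
            bundled=False, reoriented=True, anchored=True)
        placed_qo += 1

    # register the quasi-orthogonal filaments so parallel structures keep
    # their distance (protects the 12.5 nm bundle-spacing signal)
    registry = _Clearance(clearance=20.0)
    for f in filaments:
        registry.add(f.nodes[0], f.chord(), f.arc_length)

    # --- bundled anchored ladders ----------------------------------------
    n_ladders = int(np.ceil(n_bundled / spec.bundle_size)) if n_bundled else 0
    remaining = n_bundled
    for lad in range(n_ladders):
        k_members = min(spec.bundle_size, remaining)
        remaining -= k_members
        span = (k_members - 1) * spec.bundle_spacing
        halo = span / 2 + 2.0
        placed = False
        candidate = None
        for _try in range(80):
            theta = np.radians(rng_f.uniform(2.0, 12.0))
            phi = rng_f.uniform(0, 2 * np.pi)
            direction = _spherical_dir(phi, theta)
            u = np.array([-np.sin(phi), np.cos(phi), 0.0])  # ladder axis
            z_anchor = z_bot_inner + rng_f.uniform(2.0, 30.0)
            base = np.array([rng_f.uniform(30, extent[0] - 30),
                             rng_f.uniform(30, extent[1] - 30), z_anchor])
            length = min(rng_f.uniform(250.0, 420.0),
                         (z_top_inner - 70.0 - z_anchor)
                         / max(np.sin(theta), 1e-9))
            corners = (base, base + u * span)
            if any(np.any(c[:2] < 10.0) or np.any(c[:2] > extent[:2] - 10.0)
                   for c in corners):
                continue  # ladder axis would start outside the box
            for corner in corners:
                length = _cap_length(corner, direction, length, extent)
            if length < 200.0 and not (candidate and length >= 120.0):
                continue
            axis0 = base + u * (span / 2)
            candidate = (base, direction, u, length, axis0)
            if length >= 200.0 and registry.ok(axis0, direction, length,
                                               halo):
                placed = True
                break
        if candidate is None:  # extent too cramped even for one ladder
            raise ValueError("infeasible packing: ladder of span "
                             f"{span:.0f} nm cannot fit extent {extent}")
        base, direction, u, length, axis0 = candidate
        if not placed:
            crowded["ladder"] += 1
        registry.add(axis0, direction, length, halo)
        for mmb in range(k_members):
            off = mmb * spec.bundle_spacing + \
                rng_f.normal(0.0, spec.bundle_jitter_sd)
            start = base + u * off
            add(_segment_filament(new_fid(), FilamentKind.ACTIN, start,
                                  direction, length),
                bundled=True, reoriented=False, anchored=True)

    # --- single anchored parallel filaments, in antiparallel pairs --------
    # pairs of opposite-sense filaments whose PM-near ends sit 25-80 nm
    # apart populate the 150-180 deg peak of the parallel-host histogram
    n_singles = a_par - n_bundled
    queue = [2] * (n_singles // 2) + ([1] if n_singles % 2 else [])
    for k_members in queue:
        phi = rng_f.uniform(0, 2 * np.pi)
        members = []
        placed = False
        for _try in range(81):
            check_clearance = _try < 80  # last pass: accept any placement
            members = []
            base = np.array([rng_f.uniform(30, extent[0] - 30),
                             rng_f.uniform(30, extent[1] - 30), 0.0])
            ok = True
            for mmb in range(k_members):
                theta = np.radians(rng_f.uniform(2.0, 15.0))
                az = phi if mmb == 0 else \
                    phi + np.pi + np.radians(rng_f.uniform(-10.0, 10.0))
                z_anchor = z_bot_inner + rng_f.uniform(2.0, 40.0)
                start = base + np.array([0.0, 0.0, z_anchor])
                if mmb == 1:
                    start[:2] += rng_f.uniform(25.0, 80.0) * _unit2(rng_f)
                    if np.any(start[:2] < 10.0) or \
                            np.any(start[:2] > extent[:2] - 10.0):
                        ok = False
                        break
                direction = _spherical_dir(az, theta)
                length = min(rng_f.uniform(150.0, 450.0),
                             (z_top_inner - 70.0 - z_anchor)
                             / max(np.sin(theta), 1e-9))
                length = _cap_length(start, direction, length, extent)
                if length < 119.0 or (check_clearance and
                                      not registry.ok(start, direction,
                                                      length)):
                    ok = False
                    break
                members.append((start, direction, length))
            if ok and len(members) == k_members:
                placed = True
                break
        if not placed:
            crowded["pair"] += 1
        while len(members) < k_members:  # last-resort center placement
            theta = np.radians(8.0)
            z_anchor = z_bot_inner + 20.0
            start = np.array([extent[0] / 2 + rng_f.uniform(-50, 50),
                              extent[1] / 2 + rng_f.uniform(-50, 50),
                              z_anchor])
            direction = _spherical_dir(rng_f.uniform(0, 2 * np.pi), theta)
            members.append((start, direction,
                            _cap_length(start, direction, 150.0, extent)))
        for start, direction, length in members:
            registry.add(start, direction, length)
            add(_segment_filament(new_fid(), FilamentKind.ACTIN, start,
                                  direction, length),
                bundled=False, reoriented=False, anchored=True)

    # --- dispersed non-anchored parallel filaments ------------------------
    for _ in range(n_par - a_par):
        want = rng_f.uniform(120.0, 300.0)
        band = max(mid_hi - mid_lo, 1.0)
        theta_max = np.degrees(np.arcsin(min(band * 0.9 / want, 0.5)))
        theta = np.radians(rng_f.uniform(0.0, min(theta_max, 30.0)))
        length = 0.0
        for _try in range(60):
            phi = rng_f.uniform(0, 2 * np.pi)
            direction = _spherical_dir(phi, theta)
            z_hi = max(mid_hi - want * np.sin(theta), mid_lo)
            start = np.array([rng_f.uniform(20, extent[0] - 20),
                              rng_f.uniform(20, extent[1] - 20),
                              rng_f.uniform(mid_lo, z_hi)])
            length = _cap_length(start, direction, want, extent)
            if length >= 119.0 and registry.ok(start, direction, length):
                break
        if length < 10.0:  # degenerate corner case: place through the center
            direction = _spherical_dir(rng_f.uniform(0, 2 * np.pi), 0.0)
            start = np.array([extent[0] / 2, extent[1] / 2,
                              (mid_lo + mid_hi) / 2])
            length = _cap_length(start, direction, 120.0, extent)
        registry.add(start, direction, length)
        add(_segment_filament(new_fid(), FilamentKind.ACTIN, start,
                              direction, length),
            bundled=False, reoriented=False, anchored=False)

    if any(crowded.values()):
        warnings.warn(
            f"{crowded['ladder']} ladder(s) and {crowded['pair']} anchored "
            "pair(s) placed without full clearance (extent near packing "
            "capacity); expect some sub-bundle-spacing contacts",
            stacklevel=2)

    # --- microtubules: long, gently curved, mid-gap -----------------------
    for k in range(spec.n_mt):
        phi = rng_m.uniform(0, 2 * np.pi)
        direction = _spherical_dir(phi, 0.0)
        start = np.array([extent[0] / 2, extent[1] / 2,
                          rng_m.uniform(mid_lo, mid_hi)
                          if mid_hi > mid_lo else (z_bot_inner + gap / 2)])
        start[:2] += rng_m.uniform(-100, 100, 2)
        back = _cap_length(start, -direction, 300.0, extent)
        start = start - direction * back
        length = _cap_length(start, direction, rng_m.uniform(420.0, 540.0),
                             extent)
        t = np.arange(0.0, length + 1e-9, 20.0)
        u = np.array([-np.sin(phi), np.cos(phi), 0.0])
        amp = rng_m.uniform(8.0, 18.0)
        wav = rng_m.uniform(500.0, 900.0)
        nodes = start[None, :] + t[:, None] * direction[None, :] \
            + amp * np.sin(2 * np.pi * t / wav)[:, None] * u[None, :]
        nodes[:, 0] = np.clip(nodes[:, 0], 2.0, extent[0] - 2.0)
        nodes[:, 1] = np.clip(nodes[:, 1], 2.0, extent[1] - 2.0)
        if len(nodes) >= 2:
            filaments.append(Filament(f"mt_{k:02d}", FilamentKind.MT, nodes))

    # --- granules ---------------------------------------------------------
    granule_rows = []
    centers: list[np.ndarray] = []
    for g in range(spec.n_isg):
        r = float(np.clip(rng_g.normal(spec.isg_radius_mean,
                                       spec.isg_radius_sd), 60.0, 220.0))
        for _try in range(60):
            cx = rng_g.uniform(r * 0.4, extent[0] - r * 0.4)
            cy = rng_g.uniform(r * 0.4, extent[1] - r * 0.4)
            cz = z_bot_inner + gap / 2 + rng_g.uniform(-0.15, 0.15) * gap
            c = np.array([cx, cy, cz])
            if all(np.linalg.norm(c - p) > 0.9 * (r + q)
                   for p, q in zip(centers, [row["radius"] for row in
                                             granule_rows])):
                break
        centers.append(c)
        granule_rows.append({"granule_id": g + 1, "x": c[0], "y": c[1],
                             "z": c[2], "radius": r})

    # --- rasterize masks --------------------------------------------------
    masks: dict[MaskRole, VolumeMask] = {}
    if spec.rasterize_masks:
        vs = spec.voxel_size
        shape = tuple(int(np.ceil(e / vs)) for e in extent[::-1])  # (z, y, x)
        zc = (np.arange(shape[0]) + 0.5) * vs
        pm = np.zeros(shape, dtype=np.int16)
        for center in (PM_BOTTOM_CENTER_NM,
                       PM_BOTTOM_CENTER_NM + spec.periphery_height):
            sel = np.abs(zc - center) <= PM_THICKNESS_NM / 2
            pm[sel, :, :] = 1
        masks[MaskRole.PM] = VolumeMask(pm, vs, MaskRole.PM)
        if spec.n_isg > 0:
            isg = np.zeros(shape, dtype=np.int16)
            axes = [(np.arange(s) + 0.5) * vs for s in shape]  # z, y, x
            for row in granule_rows:
                c = np.array([row["z"], row["y"], row["x"]])
                r = row["radius"]
                lo = [max(int((c[d] - r) / vs) - 1, 0) for d in range(3)]
                hi = [min(int((c[d] + r) / vs) + 2, shape[d])
                      for d in range(3)]
                zz, yy, xx = np.meshgrid(
                    axes[0][lo[0]:hi[0]], axes[1][lo[1]:hi[1]],
                    axes[2][lo[2]:hi[2]], indexing="ij")
                inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 \
                    + (xx - c[2]) ** 2 <= r * r
                sub = isg[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                sub[inside] = row["granule_id"]
            masks[MaskRole.ISG] = VolumeMask(isg, vs, MaskRole.ISG)

    scene = SceneBundle(
        scene_id=spec.scene_id,
        filaments=filaments,
        masks=masks,
        condition=Condition(spec.condition),
        tomogram_extent=extent,
    )
    truth = GroundTruth(
        filaments=pd.DataFrame(truth_rows),
        architecture=spec.architecture,
        periphery_height=spec.periphery_height,
        granules=pd.DataFrame(granule_rows),
    )
    return scene, truth


def _unit2(rng: np.random.Generator) -> np.ndarray:
    a = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(a), np.sin(a)])


# ---------------------------------------------------------------------------
# 2D meshwork generator

def generate_meshwork(length_target: float, junction_target: int,
                      pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
                      seed: int = 0, shape: tuple[int, int] = (32, 32),
                      noise_sd: float = 0.0, foreground: float = 200.0,
                      background: float = 10.0,
                      ) -> tuple[MeshworkImage, dict]:
    """Random planar line network with analytically known skeleton stats.

    Draws m horizontal and n vertical 1-px lines (m*n = junction_target)
    whose spans cover every crossing, so the true junction count is m*n
    and the true skeleton length is the sum of inter-pixel steps times
    ``pixel_size`` — both exact on the noiseless render.  Axis-aligned
    segments keep the digital geodesic length equal to the Euclidean
    length; oblique segments would bias it by up to 8% (chessboard
    metric).  Additive Gaussian noise is optional.
    """
    if length_target <= 0 or junction_target < 0:
        raise ValueError("targets must be positive")
    rng = np.random.default_rng(seed)
    H, W = shape

    if junction_target == 0:
        m, n = 1, 0
    else:
        m = int(np.sqrt(junction_target))
        while junction_target % m:
            m -= 1
        n = junction_target // m
        if rng.random() < 0.5:
            m, n = n, m

    target_px = length_target / pixel_size

    def minimal_total(k: int) -> float:
        # covering spans with line spacing k and 3-px end overhangs
        return m * (max(n - 1, 0) * k + 6) + n * (max(m - 1, 0) * k + 6)

    # spacing >= 4 keeps the 8-connected junction clusters of adjacent
    # crossings separate; 3-px overhangs keep terminal branches above the
    # 1-px filter, so the analytic truth stays exact
    spacing = 4
    for k in (6, 5, 4):
        if minimal_total(k) <= 0.95 * target_px and \
                max(m, n) * k + 10 < min(H, W):
            spacing = k
            break

    def pick_positions(count, size):
        block = (count - 1) * spacing
        if block + 8 >= size:
            raise ValueError("infeasible line layout for image size")
        start = int(rng.integers(4, size - 4 - block))
        return [start + i * spacing for i in range(count)]

    rows = pick_positions(m, H)
    cols = pick_positions(n, W) if n else []

    # minimal covering spans: each horizontal line crosses every vertical
    hspan = []
    for r in rows:
        lo = (min(cols) if cols else int(rng.integers(2, W // 2))) - 3
        hi = (max(cols) if cols else lo + 6) + 3
        hspan.append([max(lo, 1), min(hi, W - 2)])
    vspan = [[max(min(rows) - 3, 1), min(max(rows) + 3, H - 2)]
             for _ in cols]

    def total_steps():
        return (sum(b - a for a, b in hspan) + sum(b - a for a, b in vspan))

    target_px = length_target / pixel_size
    if target_px < total_steps():
        raise ValueError(
            f"length target {length_target:.0f} nm below the minimal "
            f"covering length {total_steps() * pixel_size:.0f} nm")
    # grow spans randomly toward the target
    stalled = 0
    while total_steps() < target_px and stalled < 200:
        grew = False
        which = rng.integers(0, len(hspan) + len(vspan))
        if which < len(hspan):
            span, limit = hspan[which], W - 1
        else:
            span, limit = vspan[which - len(hspan)], H - 1
        side = rng.integers(0, 2)
        if side == 0 and span[0] > 0:
            span[0] -= 1; grew = True
        elif side == 1 and span[1] < limit:
            span[1] += 1; grew = True
        stalled = 0 if grew else stalled + 1
    if total_steps() < target_px - max(2.0, 0.04 * target_px):
        raise ValueError(
            f"length target {length_target:.0f} nm infeasible in a "
            f"{H}x{W} image at {pixel_size} nm/px")

    img = np.full(shape, background, dtype=float)
    for r, (a, b) in zip(rows, hspan):
        img[r, a:b + 1] = foreground
    for c, (a, b) in zip(cols, vspan):
        img[a:b + 1, c] = foreground
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)

    truth = {
        "n_junctions": m * n,
        "total_length_nm": total_steps() * pixel_size,
        "rows": rows, "cols": cols,
        "hspan": hspan, "vspan": vspan,
    }
    return MeshworkImage(img, pixel_size=pixel_size,
                         image_id=f"mesh_{seed}"), truth
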
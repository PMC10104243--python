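"""Arc-length resampling, angle computations, and distance queries.

These primitives are shared by every 3D analysis: filaments are resampled
to equal arc-length chains (default 4 nm) before any distance statistic,
orientations are measured on the end-to-end chord of the original
polyline, and mask-surface distances go through a Euclidean distance
transform of the voxel grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .models import Filament, FilamentKind, ValidationError, VolumeMask

__all__ = [
    "ResampledFilament",
    "resample",
    "angle_between_chords",
    "mean_segment_direction",
    "angle_to_reference_plane",
    "nearest_point_distances",
    "SurfaceDistanceField",
    "distance_to_mask_surface",
]

DEFAULT_INTERVAL = 4.0  # nm


@dataclass(frozen=True)
class ResampledFilament:
    """Equal-arc-length point chain plus the original end-to-end chord."""

    filament_id: str
    kind: FilamentKind
    points: np.ndarray   # (m, 3), nm
    interval: float      # nm
    chord: np.ndarray    # unit 3-vector, original end nodes

    def __len__(self) -> int:
        return len(self.points)


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError(f"{name} has zero length")
    return v / n


def resample(filament: Filament, interval: float = DEFAULT_INTERVAL
             ) -> ResampledFilament:
    """Resample a polyline at fixed arc-length spacing.

    Points are placed at arc lengths 0, interval, 2*interval, ...; the
    original terminal node is appended iff its arc distance from the last
    regular sample is at least ``interval / 2`` (unbiased length
    coverage).  The chord is computed from the *original* end nodes.
    """
    if not interval > 0:
        raise ValueError(f"interval must be > 0, got {interval}")
    nodes = filament.nodes
    seg = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    if interval >= total:
        warnings.warn(
            f"filament {filament.filament_id!r}: interval {interval} nm >= "
            f"arc length {total:.3g} nm; returning end nodes only",
            stacklevel=2,
        )
        pts = np.vstack([nodes[0], nodes[-1]])
    else:
        s = np.arange(0.0, total, interval)
        # interpolate each arc-length position along the polyline
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        pts = nodes[idx] + frac[:, None] * seg[idx]
        residual = total - s[-1]
        if residual >= interval / 2:
            pts = np.vstack([pts, nodes[-1]])
    chord = _unit(nodes[-1] - nodes[0], f"chord of {filament.filament_id!r}")
    return ResampledFilament(
        filament_id=filament.filament_id,
        kind=filament.kind,
        points=pts,
        interval=float(interval),
        chord=chord,
    )


def mean_segment_direction(filament: Filament) -> np.ndarray:
    """Unweighted mean of per-segment unit tangents, normalized.

    An alternative to the end-to-end chord for strongly kinked
    polylines (a length-weighted mean would reduce to the chord); the
    chord remains the default orientation everywhere.
    """
    seg = np.diff(filament.nodes, axis=0)
    units = seg / np.linalg.norm(seg, axis=1)[:, None]
    mean = units.mean(axis=0)
    n = np.linalg.norm(mean)
    if n == 0.0:
        raise ValidationError(
            f"filament {filament.filament_id!r}: degenerate mean direction")
    return mean / n


def angle_between_chords(a: np.ndarray, b: np.ndarray,
                         mode: str = "undirected") -> float:
    """Angle in degrees between two unit direction vectors.

    ``undirected`` folds orientation: arccos(|a.b|) in [0, 90]; this is the
    filament-pair angle, symmetric in its arguments and in sign flips.
    ``directed`` keeps orientation: arccos(a.b) in [0, 180]; used for
    PM-anchored filament vectors which have a defined near-to-far sense.
    """
    a = _unit(a, "a")
    b = _unit(b, "b")
    dot = float(np.dot(a, b))
    if mode == "undirected":
        c = min(abs(dot), 1.0)
        return float(np.degrees(np.arccos(c)))
    if mode == "directed":
        c = min(max(dot, -1.0), 1.0)
        return float(np.degrees(np.arccos(c)))
    raise ValueError(f"mode must be 'undirected' or 'directed', got {mode!r}")


def angle_to_reference_plane(chord: np.ndarray,
                             plane_normal: np.ndarray = (0.0, 0.0, 1.0)
                             ) -> float:
    """Elevation of a chord out of a reference plane, degrees in [0, 90].

    With the default normal (z axis) this is the filament orientation
    relative to the tomogram XY plane, the proxy for the PM plane.
    """
    c = _unit(chord, "chord")
    n = _unit(plane_normal, "plane_normal")
    s = min(abs(float(np.dot(c, n))), 1.0)
    return float(np.degrees(np.arcsin(s)))


def nearest_point_distances(query: ResampledFilament,
                            others: list[ResampledFilament],
                            ) -> list[tuple[int, float, str, int]]:
    """Per-point nearest-neighbor distances to all *other* filaments.

    Returns one record ``(point_index, distance_nm, nearest_filament_id,
    nearest_point_index)`` per resampled point of ``query``.  The
    accelerated KD-tree search returns exactly the brute-force minimum;
    ties are broken by lowest filament id, then lowest point index.
    """
    others = [o for o in others if o.filament_id != query.filament_id]
    if not others:
        warnings.warn(
            f"filament {query.filament_id!r}: no other filaments to "
            "compare against", stacklevel=2,
        )
        return []
    pts = np.vstack([o.points for o in others])
    fids = np.concatenate([[o.filament_id] * len(o) for o in others])
    pidx = np.concatenate([np.arange(len(o)) for o in others])
    # sort so that among equal distances the KD-tree returns the lowest
    # (filament_id, point_index) first
    order = np.lexsort((pidx, fids))
    pts, fids, pidx = pts[order], fids[order], pidx[order]
    tree = cKDTree(pts)
    d, j = tree.query(query.points, k=1)
    out = []
    for i in range(len(query.points)):
        # resolve exact ties deterministically: find all candidates at the
        # minimal distance (exact float equality, as brute force would)
        cand = tree.query_ball_point(query.points[i], d[i] + 1e-12)
        dd = np.linalg.norm(pts[cand] - query.points[i], axis=1)
        exact = [c for c, w in zip(cand, dd) if w == dd.min()]
        best = min(exact, key=lambda c: (fids[c], pidx[c]))
        out.append((i, float(np.linalg.norm(pts[best] - query.points[i])),
                    str(fids[best]), int(pidx[best])))
    return out


def pairwise_nearest(points_by_filament: dict[str, np.ndarray]
                     ) -> tuple[dict[str, np.ndarray], list[str]]:
    """Vectorized all-filament nearest-foreign-point distances.

    For each filament id, returns an array ``(m, 2)`` of
    ``(distance_nm, index_into_ids)`` where the second column indexes the
    sorted id list of the *nearest foreign* filament.  Used by the scene
    analyses where per-record tie metadata is not needed.
    """
    ids = sorted(points_by_filament)
    pts = np.vstack([points_by_filament[i] for i in ids])
    owner = np.concatenate([
        np.full(len(points_by_filament[i]), k) for k, i in enumerate(ids)
    ])
    tree = cKDTree(pts)
    result: dict[str, np.ndarray] = {}
    for k, fid in enumerate(ids):
        q = points_by_filament[fid]
        kq = 8
        d = np.full(len(q), np.inf)
        nb = np.full(len(q), -1, dtype=int)
        unresolved = np.arange(len(q))
        while len(unresolved):
            dd, jj = tree.query(q[unresolved], k=min(kq, len(pts)))
            dd, jj = np.atleast_2d(dd), np.atleast_2d(jj)
            foreign = owner[jj] != k
            ok = foreign.any(axis=1)
            first = foreign.argmax(axis=1)
            rows = np.arange(len(unresolved))
            sel = unresolved[ok]
            d[sel] = dd[rows[ok], first[ok]]
            nb[sel] = owner[jj[rows[ok], first[ok]]]
            if kq >= len(pts):
                # exhausted: any still-unresolved point has no foreign point
                break
            unresolved = unresolved[~ok]
            kq *= 4
        result[fid] = np.column_stack([d, nb.astype(float)])
    return result, ids


@dataclass
class SurfaceDistanceField:
    """Sampled Euclidean distance (nm) to the nearest mask surface voxel.

    Built once per mask from a distance transform of the background;
    queries interpolate trilinearly.  Points inside the nonzero region are
    at distance 0; points outside the grid extent are evaluated at clamped
    coordinates and flagged.
    """

    mask: VolumeMask
    _edt: np.ndarray = None  # voxel-center distances in nm, lazy

    def __post_init__(self) -> None:
        if not np.any(self.mask.grid):
            raise ValidationError("cannot build a distance field on an empty mask")
        bg = self.mask.grid == 0
        self._edt = ndimage.distance_transform_edt(
            bg, sampling=self.mask.voxel_size)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distances (nm) and an out-of-grid flag per xyz point."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        # voxel-center coordinates: center of voxel i is at (i + 0.5) * vs
        coords = (p - self.mask.origin) / self.mask.voxel_size - 0.5
        coords = coords[:, ::-1].T  # (3, n) in (z, y, x) order
        shape = np.asarray(self._edt.shape)
        outside = np.any((coords < -0.5) | (coords > (shape[:, None] - 0.5)),
                         axis=0)
        clamped = np.clip(coords, 0, shape[:, None] - 1)
        d = ndimage.map_coordinates(self._edt, clamped, order=1,
                                    mode="nearest")
        # points whose containing voxel is foreground are inside: distance 0
        vox = np.clip(np.floor(coords + 0.5).astype(int), 0,
                      shape[:, None] - 1)
        inside = self.mask.grid[vox[0], vox[1], vox[2]] != 0
        d = np.where(inside & ~outside, 0.0, d)
        return d, outside


def distance_to_mask_surface(points: np.ndarray, mask: VolumeMask
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Distance (nm) from each point to the nearest mask boundary voxel center.

    Convenience wrapper building a :class:`SurfaceDistanceField` once.
    Returns (distances, out_of_grid_flags).
    """
    return SurfaceDistanceField(mask).query(points)


def boundary_voxel_indices(grid: np.ndarray) -> np.ndarray:
    """(z, y, x) indices of foreground voxels with a 6-neighbor background."""
    fg = grid != 0
    eroded = ndimage.binary_erosion(fg, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    return np.argwhere(fg & ~eroded)
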
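"""PM-anchoring analysis: anchored-filament detection, directed
neighbor angles, periphery height, and the netlike/blooming contrast.

A filament is anchored when the nearer of its two end nodes lies within
60 nm (the actin tracing-unit length) of the PM mask surface.  Anchored
filaments carry a directed vector from the PM-near end to the far end;
neighboring anchored filaments — same PM component, near-end separation
under 120 nm — contribute directed angles in [0, 180].  Netlike networks
(basal) put quasi-orthogonal-host mass at 60-90 deg; blooming networks
(post-remodeling) shift it below 30 deg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import geometry
from .models import (
    FilamentKind,
    MaskRole,
    RecordTable,
    SceneBundle,
    ValidationError,
    VolumeMask,
)
from .architecture import classify_orientation

__all__ = [
    "label_pm_components",
    "find_anchored",
    "neighbor_angles",
    "anchored_angle_histograms",
    "classify_architecture",
    "local_pm_plane_normal",
    "periphery_height",
]

ANCHOR_THRESHOLD_NM = 60.0
NEIGHBOR_THRESHOLD_NM = 120.0


def label_pm_components(mask: VolumeMask) -> tuple[np.ndarray, int]:
    """Label 26-connected PM components 1..k; returns (labels, k)."""
    if mask.role is not MaskRole.PM:
        raise ValueError(f"expected a PM mask, got role={mask.role}")
    if not np.any(mask.grid):
        raise ValidationError("empty PM mask")
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, k = ndimage.label(mask.grid != 0, structure=structure)
    return labels, int(k)


def find_anchored(scene: SceneBundle,
                  threshold: float = ANCHOR_THRESHOLD_NM,
                  kind: FilamentKind = FilamentKind.ACTIN) -> RecordTable:
    """Per-filament anchoring records against the scene's PM mask.

    Both end nodes are measured against the PM surface (nearest boundary
    voxel center); the filament is anchored iff the smaller distance is
    <= threshold.  ``pm_component_id`` is the 26-connected component of
    that nearest boundary voxel.
    """
    pm = scene.masks.get(MaskRole.PM)
    if pm is None:
        raise ValidationError(f"scene {scene.scene_id!r} has no PM mask")
    labels, _k = label_pm_components(pm)
    bidx = geometry.boundary_voxel_indices(pm.grid)
    centers = pm.voxel_centers_nm(bidx)
    comp_of_boundary = labels[bidx[:, 0], bidx[:, 1], bidx[:, 2]]
    # boundary sets run to ~10^6 voxels; skip tree balancing for build speed
    tree = cKDTree(centers, balanced_tree=False, compact_nodes=False)

    rows = []
    for f in scene.of_kind(kind):
        ends = np.vstack(f.end_points)
        d, j = tree.query(ends)
        near = int(np.argmin(d))
        far = 1 - near
        near_end, far_end = ends[near], ends[far]
        v = far_end - near_end
        nv = np.linalg.norm(v)
        rows.append({
            "scene_id": scene.scene_id,
            "filament_id": f.filament_id,
            "anchored": bool(d[near] <= threshold),
            "end_pm_distance": float(d[near]),
            "pm_component_id": int(comp_of_boundary[j[near]]),
            "near_x": near_end[0], "near_y": near_end[1], "near_z": near_end[2],
            "far_x": far_end[0], "far_y": far_end[1], "far_z": far_end[2],
            "dir_x": v[0] / nv, "dir_y": v[1] / nv, "dir_z": v[2] / nv,
            "angle_to_pm": geometry.angle_to_reference_plane(f.chord()),
        })
    df = pd.DataFrame(rows)
    prov = {
        "scene_id": scene.scene_id,
        "anchor_threshold_nm": threshold,
        "n_filaments": int(len(df)),
        "n_anchored": int(df["anchored"].sum()) if len(df) else 0,
        "percent_anchored": float(100.0 * df["anchored"].mean()) if len(df) else np.nan,
    }
    return RecordTable("anchor", df, prov)


def neighbor_angles(anchors: RecordTable,
                    neighbor_threshold: float = NEIGHBOR_THRESHOLD_NM,
                    ) -> RecordTable:
    """Directed angles between neighboring PM-anchored filaments.

    Neighbors share a PM component and have near-end separation strictly
    below the threshold (twice the 60 nm tracing unit).  Both ordered
    directions (a, b) and (b, a) are recorded so per-host-class
    histograms are well defined.
    """
    df = anchors.data
    a = df[df["anchored"]].reset_index(drop=True) if len(df) else df
    prov = dict(anchors.provenance)
    prov["neighbor_threshold_nm"] = neighbor_threshold
    if len(a) < 2:
        warnings.warn("fewer than two anchored filaments; no neighbor pairs",
                      stacklevel=2)
        return RecordTable("neighbor_angle", pd.DataFrame(), prov)
    near = a[["near_x", "near_y", "near_z"]].to_numpy()
    vec = a[["dir_x", "dir_y", "dir_z"]].to_numpy()
    comp = a["pm_component_id"].to_numpy()
    tree = cKDTree(near)
    pairs = tree.query_pairs(neighbor_threshold, output_type="ndarray")
    rows = []
    for i, j in pairs:
        sep = float(np.linalg.norm(near[i] - near[j]))
        if sep >= neighbor_threshold or comp[i] != comp[j]:
            continue
        ang = geometry.angle_between_chords(vec[i], vec[j], "directed")
        for x, y in ((i, j), (j, i)):
            rows.append({
                "scene_id": a.loc[x, "scene_id"],
                "filament_id_a": a.loc[x, "filament_id"],
                "filament_id_b": a.loc[y, "filament_id"],
                "near_end_separation": sep,
                "directed_angle": ang,
                "host_angle_to_pm": float(a.loc[x, "angle_to_pm"]),
                "host_orientation_class": classify_orientation(
                    float(a.loc[x, "angle_to_pm"])),
                "neighbor_orientation_class": classify_orientation(
                    float(a.loc[y, "angle_to_pm"])),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["filament_id_a", "filament_id_b"]).reset_index(drop=True)
    return RecordTable("neighbor_angle", out, prov)


def anchored_angle_histograms(records: RecordTable, bin_width: float = 15.0
                              ) -> RecordTable:
    """Normalized directed-angle histograms over [0, 180] per host class."""
    if len(records) == 0:
        raise ValueError("no neighbor-angle records")
    df = records.data
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    edges[-1] = 180.0 + 1e-9
    frames, omitted = [], []
    for cls in ("parallel", "quasi_orthogonal"):
        sub = df[df["host_orientation_class"] == cls]["directed_angle"]
        if len(sub) == 0:
            omitted.append(cls)
            continue
        counts, _ = np.histogram(sub, bins=edges)
        frames.append(pd.DataFrame({
            "host_orientation_class": cls,
            "bin_left": edges[:-1],
            "bin_right": np.minimum(edges[1:], 180.0),
            "probability": counts / counts.sum(),
        }))
    prov = dict(records.provenance)
    prov.update({"bin_width_deg": bin_width, "omitted_classes": omitted})
    return RecordTable("anchored_angle_hist",
                       pd.concat(frames, ignore_index=True), prov)


def classify_architecture(records: RecordTable,
                          host_class: str = "quasi_orthogonal",
                          restrict_neighbor_class: bool = True) -> str:
    """Label a scene 'netlike' or 'blooming' from anchored-angle mass.

    Compares directed-angle histogram mass in [60, 90) against [0, 30)
    for the given host orientation class (the quasi-orthogonal hosts
    carry the netlike-vs-blooming contrast): crossing-dominated networks
    are netlike, aligned radial projections blooming.  By default only
    pairs whose neighbor is also quasi-orthogonal enter the rule — the
    netlike/blooming distinction describes how the reoriented filaments
    relate to *each other*, and mixed pairs with parallel bystanders
    only blur it.
    """
    df = records.data
    sub = df[df["host_orientation_class"] == host_class]
    if restrict_neighbor_class and len(sub):
        both = sub[sub["neighbor_orientation_class"] == host_class]
        if len(both):
            sub = both
    sub = sub["directed_angle"] if len(sub) else df["directed_angle"]
    if len(sub) == 0:
        raise ValueError("no neighbor-angle records to classify")
    ang = sub.to_numpy()
    mass_cross = np.mean((ang >= 60.0) & (ang < 90.0))
    mass_aligned = np.mean(ang < 30.0)
    return "netlike" if mass_cross > mass_aligned else "blooming"


def local_pm_plane_normal(pm: VolumeMask, point: np.ndarray,
                          radius: float = 100.0) -> np.ndarray:
    """Unit normal of a plane fit to PM boundary voxels near a point.

    Fits by PCA over the boundary-voxel centers within ``radius`` nm of
    the boundary voxel nearest to ``point``; the normal is the smallest
    principal axis, oriented with a positive z component.  An optional
    alternative to the fixed z-normal orientation proxy for curved or
    tilted membranes.
    """
    bidx = geometry.boundary_voxel_indices(pm.grid)
    centers = pm.voxel_centers_nm(bidx)
    tree = cKDTree(centers)
    _, j = tree.query(np.asarray(point, float))
    near = centers[tree.query_ball_point(centers[j], radius)]
    if len(near) < 3:
        raise ValidationError(
            f"fewer than 3 PM boundary voxels within {radius} nm; "
            "cannot fit a plane")
    centered = near - near.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    return normal


def periphery_height(scene: SceneBundle) -> float:
    """Height of the cell periphery (nm) from the PM mask.

    Defined as the difference between the mean z of the boundary voxels
    of the uppermost and lowermost 26-connected PM components (top and
    bottom membranes of the thin cell edge).  Requires >= 2 components.
    """
    pm = scene.masks.get(MaskRole.PM)
    if pm is None:
        raise ValidationError(f"scene {scene.scene_id!r} has no PM mask")
    labels, k = label_pm_components(pm)
    if k < 2:
        raise ValidationError(
            "periphery height needs >= 2 PM components (top and bottom "
            f"membranes); found {k}. For single-membrane scenes configure "
            "an explicit cytoplasm extent instead.")
    bidx = geometry.boundary_voxel_indices(pm.grid)
    comp = labels[bidx[:, 0], bidx[:, 1], bidx[:, 2]]
    z_nm = (bidx[:, 0] + 0.5) * pm.voxel_size + pm.origin[2]
    mean_z = [float(z_nm[comp == c].mean()) for c in range(1, k + 1)]
    return float(max(mean_z) - min(mean_z))
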
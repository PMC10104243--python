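"""Per-scene orchestration and cross-condition comparison.

A scene on disk is a directory holding ``filaments.tsv`` (node table,
nm), optional ``pm.mrc`` / ``isg.mrc`` masks, and ``scene.json``
metadata (scene id, condition, tomogram extent).  ``run_scene`` executes
every analysis whose inputs are present — missing masks skip the
dependent analyses with a logged warning — and writes record tables with
full parameter provenance.  ``compare_conditions`` aggregates per-scene
scalar metrics into per-condition mean +/- SEM and significance tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import anchoring, architecture, io, proximity
from .models import (
    Condition,
    FilamentKind,
    MaskRole,
    RecordTable,
    SceneBundle,
)
from .stats import group_compare
from .synthetic import GroundTruth

log = logging.getLogger("filarch")

__all__ = [
    "AnalysisParams",
    "save_scene",
    "load_scene",
    "run_scene",
    "scene_summary",
    "compare_conditions",
]


@dataclasses.dataclass
class AnalysisParams:
    """All tunable thresholds, frozen to the study defaults."""

    resample_interval: float = 4.0        # nm
    anchor_threshold: float = 60.0        # nm
    neighbor_threshold: float = 120.0     # nm
    proximity_cutoff: float = 200.0       # nm
    orientation_bin: float = 10.0         # deg
    pair_distance_bin: float = 10.0       # nm
    anchored_angle_bin: float = 15.0      # deg
    actin_isg_bin: float = 75.0           # nm
    mt_isg_bin: float = 100.0             # nm
    bundle_angle_max: float = 15.0        # deg
    bundle_dist_range: tuple[float, float] = (8.0, 17.0)  # nm

    @classmethod
    def from_mapping(cls, m: dict[str, Any] | None) -> "AnalysisParams":
        m = dict(m or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(m) - known
        if unknown:
            raise ValueError(f"unknown analysis parameters: {sorted(unknown)}")
        if "bundle_dist_range" in m:
            m["bundle_dist_range"] = tuple(m["bundle_dist_range"])
        return cls(**m)

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["bundle_dist_range"] = list(d["bundle_dist_range"])
        return d


def config_hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scene persistence

def save_scene(scene: SceneBundle, directory: str | Path,
               truth: GroundTruth | None = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    io.write_filaments(scene.filaments, d / "filaments.tsv")
    for role, mask in scene.masks.items():
        io.write_mask(mask, d / f"{role.value}.mrc")
    meta = {
        "scene_id": scene.scene_id,
        "condition": scene.condition.value,
        "tomogram_extent_nm": scene.tomogram_extent.tolist(),
        "masks": sorted(r.value for r in scene.masks),
    }
    (d / "scene.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    if truth is not None:
        truth.filaments.to_csv(d / "truth_filaments.tsv", sep="\t",
                               index=False)
        truth.granules.to_csv(d / "truth_granules.tsv", sep="\t", index=False)
        (d / "truth.json").write_text(json.dumps({
            "architecture": truth.architecture,
            "periphery_height_nm": truth.periphery_height,
        }, indent=2, sort_keys=True))
    return d


def load_scene(directory: str | Path) -> SceneBundle:
    d = Path(directory)
    meta = json.loads((d / "scene.json").read_text())
    filaments = io.read_filaments(d / "filaments.tsv")
    masks = {}
    for role in MaskRole:
        p = d / f"{role.value}.mrc"
        if p.exists():
            masks[role] = io.read_mask(p, role)
    return SceneBundle(
        scene_id=meta["scene_id"],
        filaments=filaments,
        masks=masks,
        condition=Condition(meta["condition"]),
        tomogram_extent=np.asarray(meta["tomogram_extent_nm"]),
    )


# ---------------------------------------------------------------------------
# per-scene analysis

def run_scene(scene: SceneBundle, params: AnalysisParams,
              out_dir: str | Path) -> dict[str, RecordTable]:
    """Run every applicable analysis for one scene; write all tables.

    Returns the tables keyed by name.  Analyses whose inputs are missing
    (no PM mask, no ISGs, no MTs) are skipped with a warning; the rest
    proceed.  Re-running with identical inputs is bit-identical.
    """
    out = Path(out_dir) / scene.scene_id
    out.mkdir(parents=True, exist_ok=True)
    prov = {"scene_id": scene.scene_id, "condition": scene.condition.value,
            "params": params.as_dict(),
            "config_hash": config_hash(params.as_dict())}
    tables: dict[str, RecordTable] = {}

    hist, recs = architecture.orientation_distribution(
        scene, params.orientation_bin)
    tables["orientation_hist"] = hist
    tables["orientation"] = recs

    n_actin = len(scene.of_kind(FilamentKind.ACTIN))
    if n_actin >= 2:
        pair = architecture.pair_distance_angle(
            scene, interval=params.resample_interval)
        tables["pair_point"] = pair
        if len(pair):
            tables["pair_distance_hist"] = \
                architecture.distance_histograms_by_class(
                    pair, params.pair_distance_bin)
    else:
        log.warning("scene %s: <2 actin filaments, pairwise analysis skipped",
                    scene.scene_id)

    if MaskRole.PM in scene.masks:
        anchors = anchoring.find_anchored(scene, params.anchor_threshold)
        tables["anchor"] = anchors
        nbr = anchoring.neighbor_angles(anchors, params.neighbor_threshold)
        tables["neighbor_angle"] = nbr
        if len(nbr):
            tables["anchored_angle_hist"] = \
                anchoring.anchored_angle_histograms(
                    nbr, params.anchored_angle_bin)
    else:
        log.warning("scene %s: no PM mask, anchoring analysis skipped",
                    scene.scene_id)

    if MaskRole.ISG in scene.masks and np.any(
            scene.masks[MaskRole.ISG].grid):
        for kind, bin_w in ((FilamentKind.ACTIN, params.actin_isg_bin),
                            (FilamentKind.MT, params.mt_isg_bin)):
            if not scene.of_kind(kind):
                continue
            raw, hist_t = proximity.filament_to_isg(
                scene, kind, params.resample_interval,
                params.proximity_cutoff, bin_w)
            tables[f"{kind.value}_isg"] = raw
            tables[f"{kind.value}_isg_hist"] = hist_t
    else:
        log.warning("scene %s: no ISG mask, proximity analysis skipped",
                    scene.scene_id)

    if scene.of_kind(FilamentKind.MT) and n_actin:
        pt, per_fil = proximity.actin_to_mt(scene, params.resample_interval)
        tables["actin_mt_point"] = pt
        tables["actin_mt_filament"] = per_fil

    for name, table in tables.items():
        table.provenance = {**prov, **table.provenance}
        io.write_records(table, out / f"{name}.tsv")
    summary = scene_summary(scene, tables, params)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    return tables


def scene_summary(scene: SceneBundle, tables: dict[str, RecordTable],
                  params: AnalysisParams) -> dict[str, Any]:
    """Scalar per-scene metrics feeding the cross-condition comparison."""
    s: dict[str, Any] = {
        "scene_id": scene.scene_id,
        "condition": scene.condition.value,
        "n_actin": len(scene.of_kind(FilamentKind.ACTIN)),
        "n_mt": len(scene.of_kind(FilamentKind.MT)),
        "actin_volume_ratio": architecture.volume_ratio(
            scene, FilamentKind.ACTIN),
        "mt_volume_ratio": architecture.volume_ratio(scene, FilamentKind.MT),
    }
    hist = tables.get("orientation_hist")
    if hist is not None and len(hist):
        for key in ("fraction_parallel", "fraction_quasi_orthogonal",
                    "fraction_60_90"):
            s[key] = hist.provenance.get(key)
    anchors = tables.get("anchor")
    if anchors is not None and len(anchors):
        s["n_anchored"] = anchors.provenance["n_anchored"]
        s["percent_anchored"] = anchors.provenance["percent_anchored"]
    pair = tables.get("pair_point")
    if pair is not None and len(pair):
        flags, frac = architecture.bundle_flags(
            pair, params.bundle_angle_max, params.bundle_dist_range)
        s["bundle_point_fraction"] = frac
    if MaskRole.PM in scene.masks:
        try:
            s["periphery_height_nm"] = anchoring.periphery_height(scene)
        except Exception as e:  # single-component PM: documented limitation
            log.warning("scene %s: periphery height unavailable (%s)",
                        scene.scene_id, e)
    return s


# ---------------------------------------------------------------------------
# cross-condition comparison

COMPARE_METRICS = [
    "actin_volume_ratio", "mt_volume_ratio",
    "fraction_parallel", "fraction_quasi_orthogonal", "fraction_60_90",
    "n_anchored", "percent_anchored", "bundle_point_fraction",
    "periphery_height_nm",
]


def compare_conditions(summaries: list[dict[str, Any]],
                       design: str = "anova_tukey",
                       ) -> tuple[pd.DataFrame, dict[str, RecordTable]]:
    """Per-condition mean +/- SEM and significance tests per metric.

    ``summaries`` are per-scene dictionaries from :func:`scene_summary`.
    Conditions with a single scene are reported descriptively but
    excluded from the tests.  Returns (summary frame, per-metric stats).
    """
    df = pd.DataFrame(summaries)
    if "condition" not in df or df["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions to compare")
    counts = df.groupby("condition").size()
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"conditions with no scenes: {empty}")
    testable = [c for c, n in counts.items() if n >= 2]
    rows, stats_tables = [], {}
    for metric in COMPARE_METRICS:
        if metric not in df:
            continue
        sub = df[["condition", metric]].dropna()
        if sub.empty:
            continue
        for cond, grp in sub.groupby("condition"):
            v = grp[metric].to_numpy(dtype=float)
            rows.append({
                "metric": metric, "condition": cond, "n": len(v),
                "mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(len(v)))
                if len(v) > 1 else np.nan,
                "in_tests": cond in testable,
            })
        groups = {c: g[metric].to_numpy(dtype=float)
                  for c, g in sub.groupby("condition") if c in testable}
        groups = {c: v for c, v in groups.items()
                  if len(v) >= 2 and np.isfinite(v).all()}
        if len(groups) >= 2 and not (
                design in ("ttest", "ftest") and len(groups) != 2):
            try:
                stats_tables[metric] = group_compare(groups, design)
            except ValueError as e:
                log.warning("metric %s: comparison failed (%s)", metric, e)
    return pd.DataFrame(rows), stats_tables


# ---------------------------------------------------------------------------
# config

def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    for scene in cfg.get("scenes", []):
        p = Path(scene["path"])
        if not p.exists():
            raise FileNotFoundError(f"scene path does not exist: {p}")
    return cfg
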
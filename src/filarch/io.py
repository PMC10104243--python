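"""Readers and writers for segmentation artifacts.

Supported formats:

* filament tables — tab-separated, one row per node with columns
  ``filament_id  kind  node_index  x  y  z``;
* Amira ASCII spatial graphs (the ``AmiraMesh 3D ASCII`` SpatialGraph
  dialect with VertexCoordinates / EdgeConnectivity / NumEdgePoints /
  EdgePointCoordinates sections), the export format of common
  filament-tracing software;
* MRC2014 volumes for masks (via gemmi), voxel size taken from the map
  header and converted from angstroms to nm;
* record tables — tab-separated with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import gemmi
import numpy as np
import pandas as pd

from .models import (
    Filament,
    FilamentKind,
    MaskRole,
    RecordTable,
    ValidationError,
    VolumeMask,
)

__all__ = [
    "read_filaments",
    "write_filaments",
    "read_amira_spatial_graph",
    "read_mask",
    "write_mask",
    "write_records",
    "read_records",
]

FILAMENT_COLUMNS = ["filament_id", "kind", "node_index", "x", "y", "z"]


def _build_filaments(df: pd.DataFrame, units: str,
                     voxel_size: float | None) -> list[Filament]:
    if units not in ("nm", "voxel"):
        raise ValueError(f"units must be 'nm' or 'voxel', got {units!r}")
    if units == "voxel":
        if voxel_size is None or not voxel_size > 0:
            raise ValueError("voxel units require a positive voxel_size")
        scale = float(voxel_size)
    else:
        scale = 1.0

    filaments: list[Filament] = []
    errors: list[str] = []
    for fid, grp in df.groupby("filament_id", sort=False):
        grp = grp.sort_values("node_index")
        kinds = grp["kind"].unique()
        if len(kinds) != 1:
            errors.append(f"filament {fid!r}: inconsistent kind labels {list(kinds)}")
            continue
        try:
            kind = FilamentKind(str(kinds[0]).lower())
        except ValueError:
            errors.append(f"filament {fid!r}: unknown kind {kinds[0]!r}")
            continue
        nodes = grp[["x", "y", "z"]].to_numpy(dtype=float) * scale
        try:
            filaments.append(Filament(str(fid), kind, nodes))
        except ValidationError as e:
            errors.append(str(e))
    if errors:
        raise ValidationError(
            "rejected {} filament(s):\n  {}".format(len(errors), "\n  ".join(errors))
        )
    return filaments


def read_filaments(path: str | Path, units: str = "nm",
                   voxel_size: float | None = None) -> list[Filament]:
    """Read a tab-separated filament node table.

    Coordinates are converted to nm at ingest (``units='voxel'`` scales by
    ``voxel_size``).  Filaments violating the structural invariants are
    rejected with an itemized :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValidationError(f"malformed filament table {path}: {e}") from e
    missing = [c for c in FILAMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    bad = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0, 0])
        raise ValidationError(
            f"{path}: non-numeric coordinate at data row {row} "
            f"(line {row + 2} of the file)"
        )
    return _build_filaments(df, units, voxel_size)


def write_filaments(filaments: list[Filament], path: str | Path) -> None:
    """Write filaments as a node table (nm), the inverse of read_filaments."""
    rows = []
    for f in filaments:
        for i, (x, y, z) in enumerate(f.nodes):
            rows.append((f.filament_id, f.kind.value, i, x, y, z))
    df = pd.DataFrame(rows, columns=FILAMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Amira ASCII spatial graph

_SECTION_RE = re.compile(
    r"(VERTEX|EDGE|POINT)\s*\{\s*(?:float|int)\s*(?:\[\s*(\d+)\s*\])?\s*"
    r"(\w+)\s*\}\s*@(\d+)"
)


def read_amira_spatial_graph(path: str | Path, units: str = "nm",
                             voxel_size: float | None = None,
                             kind: FilamentKind | str = FilamentKind.ACTIN,
                             ) -> list[Filament]:
    """Read filament centerlines from an AmiraMesh ASCII SpatialGraph file.

    Only the sections needed to recover per-edge point chains are parsed:
    EdgeConnectivity is read for completeness but ordering comes from
    NumEdgePoints / EdgePointCoordinates.  All filaments receive the given
    ``kind`` (tracing exports are per-class files).
    """
    kind = FilamentKind(kind)
    text = Path(path).read_text()
    if "AmiraMesh" not in text.split("\n", 1)[0]:
        raise ValidationError(f"{path}: not an AmiraMesh ASCII file")

    markers: dict[str, str] = {}
    for m in _SECTION_RE.finditer(text):
        markers[m.group(3)] = m.group(4)
    needed = ["NumEdgePoints", "EdgePointCoordinates"]
    for name in needed:
        if name not in markers:
            raise ValidationError(f"{path}: missing section {name}")

    # data blocks: "@N" on its own line, numbers follow until next @ or EOF
    blocks: dict[str, list[float]] = {}
    current: str | None = None
    for line in text.splitlines():
        s = line.strip()
        if re.fullmatch(r"@\d+", s):
            current = s[1:]
            blocks[current] = []
            continue
        if current is not None and s:
            try:
                blocks[current].extend(float(tok) for tok in s.split())
            except ValueError:
                current = None  # left the data section
    counts = np.asarray(blocks[markers["NumEdgePoints"]], dtype=int)
    coords = np.asarray(blocks[markers["EdgePointCoordinates"]], dtype=float)
    coords = coords.reshape(-1, 3)
    if counts.sum() != len(coords):
        raise ValidationError(
            f"{path}: NumEdgePoints total {counts.sum()} != "
            f"{len(coords)} edge points"
        )
    scale = 1.0
    if units == "voxel":
        if voxel_size is None or not voxel_size > 0:
            raise ValueError("voxel units require a positive voxel_size")
        scale = float(voxel_size)
    filaments = []
    offset = 0
    for i, n in enumerate(counts):
        pts = coords[offset:offset + n] * scale
        offset += n
        # tracing exports occasionally duplicate consecutive points; drop them
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
        pts = pts[keep]
        if len(pts) < 2:
            continue
        filaments.append(Filament(f"edge_{i}", kind, pts))
    return filaments


# ---------------------------------------------------------------------------
# MRC masks

def read_mask(path: str | Path, role: MaskRole | str,
              voxel_size_override: float | None = None) -> VolumeMask:
    """Read a labeled MRC2014 volume as a :class:`VolumeMask`.

    The voxel size comes from the map header (Å, converted to nm).  A
    missing/zero header voxel size must be overridden explicitly;
    anisotropic voxels are rejected.
    """
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    spacing = np.asarray(m.grid.spacing, dtype=float)  # Å
    if voxel_size_override is not None:
        vs_nm = float(voxel_size_override)
    else:
        if np.any(spacing <= 0):
            raise ValidationError(
                f"{path}: header voxel size is missing/zero; pass an "
                "explicit voxel_size_override (nm)"
            )
        if not np.allclose(spacing, spacing[0], rtol=1e-4):
            raise ValidationError(
                f"{path}: anisotropic voxels {spacing} Å are not supported"
            )
        vs_nm = float(spacing[0]) / 10.0
    grid = np.rint(arr).astype(np.int32)
    mask = VolumeMask(grid=grid, voxel_size=vs_nm, role=MaskRole(role))
    return mask


def write_mask(mask: VolumeMask, path: str | Path) -> None:
    """Write a mask as an MRC2014 map (labels as float32, voxel size in Å)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(mask.grid, dtype=np.float32))
    n0, n1, n2 = mask.grid.shape
    a = mask.voxel_size * 10.0  # nm -> Å
    m.grid.unit_cell = gemmi.UnitCell(n0 * a, n1 * a, n2 * a, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Record tables

def write_records(table: RecordTable, path: str | Path,
                  extra_meta: dict[str, Any] | None = None) -> None:
    """Write a record table as TSV plus a ``.meta.json`` sidecar.

    Numeric values round-trip losslessly (shortest-repr float formatting),
    and repeated writes of the same table are byte-identical.
    """
    path = Path(path)
    table.data.to_csv(path, sep="\t", index=False)
    meta = {
        "schema_name": table.schema_name,
        "n_rows": int(len(table.data)),
        "columns": list(map(str, table.data.columns)),
        "provenance": _jsonable(table.provenance),
    }
    if extra_meta:
        meta.update(_jsonable(extra_meta))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_records(path: str | Path) -> RecordTable:
    """Read back a table written by :func:`write_records`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    schema, prov = "unknown", {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        schema = meta.get("schema_name", schema)
        prov = meta.get("provenance", {})
    return RecordTable(schema, df, prov)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value
    return obj
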
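"""Domain data model for filament-architecture analysis.

All geometry is expressed in nanometers.  Unit conversion (voxels or
angstroms to nm) happens exactly once, at ingest, so every downstream
threshold (4 nm resampling, 60 nm anchoring, 120 nm neighborhood,
200 nm proximity cutoff) is applied in physical units.

Conventions
-----------
* Volume grids are indexed ``grid[i0, i1, i2]`` with axis 2 = x, axis 1 = y,
  axis 0 = z (the usual tomogram array layout).  A voxel index maps to the
  physical position of its *center*: ``origin + (index + 0.5) * voxel_size``.
* Voxels are isotropic; anisotropic volumes are rejected at ingest rather
  than silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilamentKind",
    "MaskRole",
    "Condition",
    "Filament",
    "VolumeMask",
    "SceneBundle",
    "RecordTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


class FilamentKind(str, Enum):
    ACTIN = "actin"
    MT = "mt"


class MaskRole(str, Enum):
    PM = "pm"
    ISG = "isg"
    TOMOGRAM = "tomogram"


class Condition(str, Enum):
    BASAL = "basal"
    PHASE1 = "phase1"
    PHASE2 = "phase2"
    SYNTHETIC = "synthetic"


#: nominal tracing template length, metadata only (nm)
SOURCE_UNIT_LENGTH = {FilamentKind.ACTIN: 60.0, FilamentKind.MT: 100.0}

#: nominal cylinder radius used by the volume-ratio model (nm);
#: half of the 8 nm / 15 nm tracing template diameters
DEFAULT_RADIUS = {FilamentKind.ACTIN: 4.0, FilamentKind.MT: 7.5}


@dataclass(frozen=True)
class Filament:
    """One traced centerline with a class label.

    Parameters
    ----------
    filament_id : str
        Opaque identifier, unique within a scene.
    kind : FilamentKind
        ``actin`` or ``mt``.
    nodes : ndarray, shape (n, 3)
        Ordered node coordinates in nm.  Consecutive nodes must be
        strictly distinct and all coordinates finite.
    """

    filament_id: str
    kind: FilamentKind
    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 2 or nodes.shape[1] != 3 or nodes.shape[0] < 2:
            raise ValidationError(
                f"filament {self.filament_id!r}: needs >=2 3D nodes, "
                f"got array of shape {nodes.shape}"
            )
        if not np.all(np.isfinite(nodes)):
            raise ValidationError(
                f"filament {self.filament_id!r}: non-finite coordinates"
            )
        steps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValidationError(
                f"filament {self.filament_id!r}: duplicated consecutive node"
            )

    @property
    def source_unit_length(self) -> float:
        """Tracing template length in nm (60 actin, 100 MT); metadata only."""
        return SOURCE_UNIT_LENGTH[self.kind]

    @property
    def arc_length(self) -> float:
        """Total polyline length in nm."""
        return float(
            np.linalg.norm(np.diff(self.nodes, axis=0), axis=1).sum()
        )

    @property
    def end_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes[0], self.nodes[-1]

    def chord(self) -> np.ndarray:
        """Unit end-to-end direction vector of the original polyline."""
        v = self.nodes[-1] - self.nodes[0]
        n = np.linalg.norm(v)
        if n == 0.0:
            raise ValidationError(
                f"filament {self.filament_id!r}: coincident end points, "
                "chord undefined"
            )
        return v / n


@dataclass
class VolumeMask:
    """Axis-aligned labeled voxel grid with physical metadata.

    ``grid`` holds integer labels, 0 = background.  For role ``isg``
    nonzero labels identify individual granules; for role ``pm`` the
    nonzero voxels form the membrane.
    """

    grid: np.ndarray
    voxel_size: float
    role: MaskRole
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValidationError("mask grid must be a non-empty 3D array")
        if not self.voxel_size > 0:
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.role = MaskRole(self.role)
        if self.role is MaskRole.PM and not np.any(self.grid):
            raise ValidationError("PM mask has no nonzero voxels")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        u = np.unique(self.grid)
        return u[u != 0]

    def voxel_centers_nm(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (nm, xyz order) of voxels given (z, y, x) indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        zyx = (idx + 0.5) * self.voxel_size
        xyz = zyx[:, ::-1] + self.origin
        return xyz

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Containing voxel (z, y, x) indices of xyz points in nm (unclipped)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.floor(p[:, ::-1] / self.voxel_size).astype(int)


@dataclass
class SceneBundle:
    """One tomogram-equivalent unit: filaments + masks + condition label."""

    scene_id: str
    filaments: list[Filament]
    masks: dict[MaskRole, VolumeMask]
    condition: Condition
    tomogram_extent: np.ndarray  # (3,) box size in nm, xyz

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.tomogram_extent = np.asarray(self.tomogram_extent, dtype=float)
        if self.tomogram_extent.shape != (3,) or np.any(self.tomogram_extent <= 0):
            raise ValidationError("tomogram_extent must be a positive 3-vector")
        self.masks = {MaskRole(k): v for k, v in self.masks.items()}
        tol = max((m.voxel_size for m in self.masks.values()), default=1.0)
        lo, hi = -tol, self.tomogram_extent + tol
        for f in self.filaments:
            if np.any(f.nodes < lo) or np.any(f.nodes > hi):
                raise ValidationError(
                    f"filament {f.filament_id!r} leaves the tomogram extent"
                )

    def of_kind(self, kind: FilamentKind) -> list[Filament]:
        kind = FilamentKind(kind)
        return [f for f in self.filaments if f.kind is kind]

    @property
    def extent_volume(self) -> float:
        return float(np.prod(self.tomogram_extent))


@dataclass
class RecordTable:
    """Long-format analysis output: a DataFrame plus provenance.

    ``provenance`` records the scene id and the parameters that produced
    the rows, and is written next to the table as a JSON sidecar.
    """

    schema_name: str
    data: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)

    def __len__(self) -> int:
        return len(self.data)


def concat_tables(tables: Iterable[RecordTable], schema_name: str,
                  provenance: Mapping[str, Any] | None = None) -> RecordTable:
    """Stack same-schema tables from several scenes into one."""
    tables = list(tables)
    frames = [t.data for t in tables if len(t)]
    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return RecordTable(schema_name, data, dict(provenance or {}))
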
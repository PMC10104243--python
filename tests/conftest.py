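"""Shared fixtures: tiny hand-built scenes and mask constructors."""

from __future__ import annotations

import numpy as np
import pytest

from filarch.models import (
    Condition,
    Filament,
    FilamentKind,
    MaskRole,
    SceneBundle,
    VolumeMask,
)


def straight(fid: str, start, end, kind=FilamentKind.ACTIN, n_nodes=2):
    """Straight filament from start to end with n_nodes nodes."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    t = np.linspace(0.0, 1.0, n_nodes)
    return Filament(fid, kind, start + t[:, None] * (end - start))


def make_scene(filaments, masks=None, extent=(1000, 1000, 1000),
               scene_id="test", condition=Condition.SYNTHETIC):
    return SceneBundle(scene_id=scene_id, filaments=list(filaments),
                       masks=masks or {}, condition=condition,
                       tomogram_extent=np.asarray(extent, float))


def sphere_mask(center, radius, shape, voxel_size, role=MaskRole.ISG,
                label=1):
    """Rasterized sphere: voxel centers within radius of center (nm, xyz)."""
    zz, yy, xx = np.meshgrid(*[(np.arange(s) + 0.5) * voxel_size
                               for s in shape], indexing="ij")
    cx, cy, cz = center
    grid = (((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
            <= radius ** 2).astype(np.int16) * label
    return VolumeMask(grid, voxel_size, role)


def slab_mask(z_centers, thickness, shape, voxel_size, role=MaskRole.PM):
    """Horizontal slabs centered at the given z positions (nm)."""
    grid = np.zeros(shape, dtype=np.int16)
    zc = (np.arange(shape[0]) + 0.5) * voxel_size
    for c in z_centers:
        grid[np.abs(zc - c) <= thickness / 2, :, :] = 1
    return VolumeMask(grid, voxel_size, role)


@pytest.fixture
def parallel_pair_scene():
    """Two parallel actin filaments along x, 12.5 nm apart in y."""
    f1 = straight("a", (100, 100, 100), (400, 100, 100), n_nodes=4)
    f2 = straight("b", (100, 112.5, 100), (400, 112.5, 100), n_nodes=4)
    return make_scene([f1, f2])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
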
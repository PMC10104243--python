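"""PM anchoring: component labeling, anchor detection, neighbor angles,
periphery height, netlike/blooming discrimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from filarch import anchoring as anc
from filarch import synthetic
from filarch.models import MaskRole, RecordTable, ValidationError, VolumeMask
from conftest import make_scene, slab_mask, straight


VS = 4.0
SHAPE = (100, 50, 50)  # z, y, x at 4 nm: 400 x 200 x 200 nm


def pm_scene(filaments, z_centers=(20.0, 220.0), thickness=8.0):
    pm = slab_mask(z_centers, thickness, SHAPE, VS)
    return make_scene(filaments, {MaskRole.PM: pm}, extent=(200, 200, 400))


def test_single_slab_one_component():
    pm = slab_mask([100.0], 8.0, SHAPE, VS)
    _, k = anc.label_pm_components(pm)
    assert k == 1


def test_two_slabs_two_components():
    pm = slab_mask([20.0, 220.0], 8.0, SHAPE, VS)
    _, k = anc.label_pm_components(pm)
    assert k == 2


def test_component_count_matches_flood_fill_oracle(rng):
    grid = (rng.random((14, 14, 14)) < 0.07).astype(np.int16)
    grid[0, 0, 0] = 1
    mask = VolumeMask(grid, VS, MaskRole.PM)
    _, k = anc.label_pm_components(mask)

    # oracle: BFS flood fill with 26-connectivity
    seen = np.zeros_like(grid, dtype=bool)
    comps = 0
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
            for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(grid != 0)):
        if seen[start]:
            continue
        comps += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < grid.shape[i] for i in range(3)) \
                        and grid[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
    assert k == comps


# ---------------------------------------------------------------------------
# anchoring

def test_anchor_threshold_boundary():
    # bottom slab surface voxel centers top out at z = 22 nm
    near = straight("near", (100, 100, 72), (100, 100, 190))   # end 50 nm off
    far = straight("far", (100.02, 100, 83.1), (100.02, 100, 190))  # 61 nm off
    table = anc.find_anchored(pm_scene([near, far], z_centers=(20.0,)))
    d = table.data.set_index("filament_id")
    assert d.loc["near", "anchored"]
    assert d.loc["near", "end_pm_distance"] == pytest.approx(50.0, abs=VS)
    assert not d.loc["far", "anchored"]
    assert table.provenance["percent_anchored"] == pytest.approx(50.0)


def test_near_far_rule_and_directed_vector():
    # both ends within threshold: near end is the closer one (10 nm vs 40)
    f = straight("f", (100, 100, 32), (100, 160, 62))
    table = anc.find_anchored(pm_scene([f], z_centers=(20.0,)))
    row = table.data.iloc[0]
    assert row["anchored"]
    assert row["near_z"] == pytest.approx(32.0)
    assert row["far_z"] == pytest.approx(62.0)
    assert row["dir_z"] > 0  # points away from the PM


def test_missing_pm_mask_raises():
    scene = make_scene([straight("f", (0, 0, 0), (100, 0, 0))])
    with pytest.raises(ValidationError):
        anc.find_anchored(scene)


# ---------------------------------------------------------------------------
# neighbor angles

def anchor_frame(rows):
    cols = ["scene_id", "filament_id", "anchored", "end_pm_distance",
            "pm_component_id", "near_x", "near_y", "near_z",
            "far_x", "far_y", "far_z", "dir_x", "dir_y", "dir_z",
            "angle_to_pm"]
    return RecordTable("anchor", pd.DataFrame(rows, columns=cols))


def mk_anchor(fid, near, vec, comp=1, angle=80.0):
    v = np.asarray(vec, float); v = v / np.linalg.norm(v)
    far = np.asarray(near, float) + v * 100
    return ("s", fid, True, 10.0, comp, *near, *far, *v, angle)


def test_neighbor_pairing_threshold_and_angles():
    a = anchor_frame([
        mk_anchor("a", (0, 0, 0), (0, 0, 1)),
        mk_anchor("b", (100, 0, 0), (0, 0, 1)),     # 100 nm: neighbor
        mk_anchor("c", (230, 0, 0), (0, 0, -1)),    # 130 from b: not
    ])
    out = anc.neighbor_angles(a)
    pairs = set(map(tuple, out.data[["filament_id_a", "filament_id_b"]]
                    .to_numpy()))
    assert pairs == {("a", "b"), ("b", "a")}
    np.testing.assert_allclose(out.data["directed_angle"], 0.0, atol=1e-9)


def test_antiparallel_neighbors_directed_angle_180():
    a = anchor_frame([
        mk_anchor("a", (0, 0, 0), (0, 0, 1)),
        mk_anchor("b", (50, 0, 0), (0, 0, -1)),
    ])
    out = anc.neighbor_angles(a)
    np.testing.assert_allclose(out.data["directed_angle"], 180.0, atol=1e-9)


def test_different_pm_components_are_not_neighbors():
    a = anchor_frame([
        mk_anchor("a", (0, 0, 0), (0, 0, 1), comp=1),
        mk_anchor("b", (50, 0, 0), (0, 0, 1), comp=2),
    ])
    with pytest.warns(UserWarning):
        out = anc.neighbor_angles(anchor_frame([]))  # empty -> warning
    out = anc.neighbor_angles(a)
    assert len(out) == 0


def test_ordered_records_come_in_symmetric_pairs():
    a = anchor_frame([
        mk_anchor("a", (0, 0, 0), (0, 0, 1), angle=80.0),
        mk_anchor("b", (40, 0, 0), (1, 0, 1), angle=30.0),
        mk_anchor("c", (80, 0, 0), (0, 1, 1), angle=60.0),
    ])
    out = anc.neighbor_angles(a).data
    assert len(out) % 2 == 0
    for _, row in out.iterrows():
        mirror = out[(out["filament_id_a"] == row["filament_id_b"])
                     & (out["filament_id_b"] == row["filament_id_a"])]
        assert len(mirror) == 1
        assert mirror.iloc[0]["directed_angle"] == \
            pytest.approx(row["directed_angle"])


def test_histogram_masses_and_all_identical_vectors():
    a = anchor_frame([mk_anchor(f"f{k}", (20 * k, 0, 0), (0, 0, 1),
                                angle=80.0) for k in range(4)])
    out = anc.neighbor_angles(a)
    hist = anc.anchored_angle_histograms(out)
    qo = hist.data[hist.data["host_orientation_class"] == "quasi_orthogonal"]
    assert qo["probability"].sum() == pytest.approx(1.0)
    assert qo.iloc[0]["probability"] == 1.0  # all mass in [0, 15)


# ---------------------------------------------------------------------------
# architecture discrimination on generated scenes

ARCH_SPEC = dict(n_actin=75, n_mt=0, n_isg=0, extent=(900.0, 650.0, 360.0))


@pytest.mark.parametrize("architecture,band", [
    ("netlike", (60.0, 90.0)),
    ("blooming", (0.0, 30.0)),
])
def test_generated_architecture_histogram_mode(architecture, band):
    spec = synthetic.SceneSpec(seed=11, architecture=architecture,
                               **ARCH_SPEC)
    scene, truth = synthetic.generate_scene(spec)
    nb = anc.neighbor_angles(anc.find_anchored(scene))
    d = nb.data
    qq = d[(d["host_orientation_class"] == "quasi_orthogonal")
           & (d["neighbor_orientation_class"] == "quasi_orthogonal")]
    ang = qq["directed_angle"].to_numpy()
    assert len(ang) > 0
    assert np.mean((ang >= band[0]) & (ang < band[1])) > 0.5
    assert anc.classify_architecture(nb) == architecture


def test_local_pm_plane_normal_flat_and_tilted():
    flat = slab_mask([40.0], 8.0, (40, 50, 50), VS)
    n = anc.local_pm_plane_normal(flat, (100.0, 100.0, 60.0), radius=60.0)
    assert abs(n[2]) == pytest.approx(1.0, abs=0.05)

    shape = (60, 50, 50)
    zz, yy, _ = np.meshgrid(*[(np.arange(s) + 0.5) * VS for s in shape],
                            indexing="ij")
    grid = np.zeros(shape, dtype=np.int16)
    t = np.tan(np.radians(20.0))
    grid[np.abs(zz - (40.0 + t * yy)) <= 4.0] = 1
    tilted = VolumeMask(grid, VS, MaskRole.PM)
    n = anc.local_pm_plane_normal(tilted, (100.0, 100.0, 120.0),
                                  radius=80.0)
    tilt = np.degrees(np.arccos(abs(n[2])))
    assert tilt == pytest.approx(20.0, abs=3.0)


# ---------------------------------------------------------------------------
# periphery height

def test_height_of_flat_slabs():
    scene = pm_scene([], z_centers=(20.0, 220.0))
    assert anc.periphery_height(scene) == pytest.approx(200.0, abs=VS)


def test_height_needs_two_components():
    scene = pm_scene([], z_centers=(100.0,))
    with pytest.raises(ValidationError, match="components"):
        anc.periphery_height(scene)


def test_tilted_slabs_height_follows_mean_z_definition():
    # parallel slabs tilted 10 deg about x, 200 nm apart along their
    # normal: the z-based height reads 200 / cos(10 deg)
    shape = (120, 50, 50)
    vs = 4.0
    zz, yy, _ = np.meshgrid(*[(np.arange(s) + 0.5) * vs for s in shape],
                            indexing="ij")
    grid = np.zeros(shape, dtype=np.int16)
    t = np.tan(np.radians(10.0))
    dz = 200.0 / np.cos(np.radians(10.0))
    for z0 in (40.0, 40.0 + dz):
        grid[np.abs(zz - (z0 + t * yy)) <= 4.0] = 1
    pm = VolumeMask(grid, vs, MaskRole.PM)
    scene = make_scene([], {MaskRole.PM: pm}, extent=(200, 200, 480))
    expected = 200.0 / np.cos(np.radians(10.0))
    assert anc.periphery_height(scene) == pytest.approx(expected, abs=2 * vs)


def test_generated_height_recovered_within_one_voxel():
    spec = synthetic.SceneSpec(seed=9, periphery_height=250.0, n_isg=0,
                               n_mt=0, n_actin=60,
                               extent=(900.0, 650.0, 360.0))
    scene, truth = synthetic.generate_scene(spec)
    h = anc.periphery_height(scene)
    assert h == pytest.approx(250.0, abs=spec.voxel_size)
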
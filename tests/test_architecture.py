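"""Orientation distributions, volume ratios, pairwise structure, bundles."""

import numpy as np
import pytest
from scipy import stats as sps

from filarch import architecture as arch
from filarch import geometry, synthetic
from filarch.models import FilamentKind, RecordTable
from conftest import make_scene, straight


def chords_scene(elevations_deg, length=200.0):
    """One straight filament per requested elevation angle."""
    fils = []
    for k, e in enumerate(elevations_deg):
        dx = length * np.cos(np.radians(e))
        dz = length * np.sin(np.radians(e))
        fils.append(straight(f"f{k}", (50 + 0.01 * k, 500, 100),
                             (50 + 0.01 * k + dx, 500, 100 + dz)))
    return make_scene(fils)


def test_orientation_fractions_mirror_97_3_split():
    scene = chords_scene([5.0] * 97 + [88.0] * 3)
    hist, recs = arch.orientation_distribution(scene)
    assert hist.provenance["fraction_parallel"] == pytest.approx(0.97)
    assert hist.provenance["fraction_quasi_orthogonal"] == pytest.approx(0.03)
    assert hist.data["fraction"].sum() == pytest.approx(1.0)


def test_exactly_45_degrees_is_quasi_orthogonal():
    scene = chords_scene([45.0] * 4)
    hist, recs = arch.orientation_distribution(scene)
    assert hist.provenance["fraction_quasi_orthogonal"] == 1.0
    assert set(recs.data["orientation_class"]) == {"quasi_orthogonal"}


def test_generator_fraction_recovered_within_binomial_interval():
    spec = synthetic.SceneSpec(seed=77, n_actin=400,
                               quasi_orthogonal_fraction=0.15,
                               rasterize_masks=False, n_isg=0, n_mt=0)
    scene, truth = synthetic.generate_scene(spec)
    hist, _ = arch.orientation_distribution(scene)
    k = round(hist.provenance["fraction_quasi_orthogonal"] * 400)
    lo, hi = sps.binom.interval(0.95, 400, 0.15)
    assert lo <= k <= hi


# ---------------------------------------------------------------------------
# volume ratio

def test_volume_ratio_cylinder_closed_form():
    scene = make_scene([straight("f", (100, 500, 500), (700, 500, 500))])
    ratio = arch.volume_ratio(scene, FilamentKind.ACTIN)
    assert ratio == pytest.approx(np.pi * 16 * 600 / 1e9, rel=1e-12)


def test_volume_ratio_empty_scene_is_zero():
    scene = make_scene([])
    assert arch.volume_ratio(scene, FilamentKind.ACTIN) == 0.0
    assert arch.volume_ratio(scene, FilamentKind.MT) == 0.0


def test_volume_ratio_additive_over_filaments(rng):
    fils = [straight(f"f{k}", rng.uniform(100, 400, 3),
                     rng.uniform(500, 900, 3)) for k in range(50)]
    scene = make_scene(fils)
    total = arch.volume_ratio(scene, FilamentKind.ACTIN)
    per = sum(arch.volume_ratio(make_scene([f]), FilamentKind.ACTIN)
              for f in fils)
    assert total == pytest.approx(per, rel=1e-12)


def test_mt_volume_ratio_uses_mt_radius():
    f = straight("m", (100, 500, 500), (700, 500, 500), kind=FilamentKind.MT)
    scene = make_scene([f])
    assert arch.volume_ratio(scene, FilamentKind.MT) == pytest.approx(
        np.pi * 7.5 ** 2 * 600 / 1e9, rel=1e-12)


# ---------------------------------------------------------------------------
# pairwise distance vs angle

def test_parallel_bundle_pair_distance_and_angle(parallel_pair_scene):
    table = arch.pair_distance_angle(parallel_pair_scene)
    assert len(table) > 0
    np.testing.assert_allclose(table.data["nn_distance"], 12.5, atol=1e-9)
    np.testing.assert_allclose(table.data["pair_angle"], 0.0, atol=1e-9)


def test_orthogonal_crossing_minimum_distance_and_angle():
    f1 = straight("a", (100, 500, 100), (900, 500, 100), n_nodes=5)
    f2 = straight("b", (500, 100, 120), (500, 900, 120), n_nodes=5)
    scene = make_scene([f1, f2])
    table = arch.pair_distance_angle(scene)
    dmin = table.data["nn_distance"].min()
    assert dmin == pytest.approx(20.0, abs=1e-9)
    at_min = table.data.loc[table.data["nn_distance"].idxmin()]
    assert at_min["pair_angle"] == pytest.approx(90.0)


def test_pair_table_equals_brute_force_oracle(rng):
    fils = [straight(f"f{k}", rng.uniform(0, 400, 3), rng.uniform(0, 400, 3))
            for k in range(5)]
    scene = make_scene(fils, extent=(500, 500, 500))
    table = arch.pair_distance_angle(scene)
    rs = {f.filament_id: geometry.resample(f, 4.0) for f in fils}
    for _, row in table.data.iterrows():
        p = rs[row["host_filament_id"]].points[int(row["point_index"])]
        expected = min(
            float(np.linalg.norm(p - q))
            for fid, r in rs.items() if fid != row["host_filament_id"]
            for q in r.points)
        assert row["nn_distance"] == pytest.approx(expected, abs=1e-12)


def test_single_filament_yields_empty_pair_table():
    scene = make_scene([straight("a", (0, 0, 0), (100, 0, 0))])
    with pytest.warns(UserWarning):
        table = arch.pair_distance_angle(scene)
    assert len(table) == 0


# ---------------------------------------------------------------------------
# histograms and bundle criterion

def test_distance_histogram_single_bin(parallel_pair_scene):
    table = arch.pair_distance_angle(parallel_pair_scene)
    hist = arch.distance_histograms_by_class(table, bin_width=10.0)
    par = hist.data[hist.data["host_orientation_class"] == "parallel"]
    peak = par.loc[par["probability"].idxmax()]
    assert peak["bin_left"] == 10.0
    assert peak["probability"] == pytest.approx(1.0)
    assert "quasi_orthogonal" in hist.provenance["omitted_classes"]


def test_uniform_distances_fill_bins_uniformly(rng):
    n = 5000
    df = {
        "nn_distance": rng.uniform(0, 100, n),
        "host_orientation_class": ["parallel"] * n,
    }
    hist = arch.distance_histograms_by_class(
        RecordTable("pair_point", df), bin_width=10.0, max_distance=100.0)
    counts = hist.data["probability"].to_numpy() * n
    chi2 = ((counts - n / 10) ** 2 / (n / 10)).sum()
    assert sps.chi2.sf(chi2, df=9) > 0.01


def test_bundle_flags_box_rule(parallel_pair_scene):
    table = arch.pair_distance_angle(parallel_pair_scene)
    flags, frac = arch.bundle_flags(table)
    assert frac == 1.0
    # same distance but orthogonal chords: outside the bundle box
    f1 = straight("a", (100, 500, 100), (900, 500, 100), n_nodes=5)
    f2 = straight("b", (500, 100, 112.5), (500, 900, 112.5), n_nodes=5)
    t2 = arch.pair_distance_angle(make_scene([f1, f2]))
    _, frac2 = arch.bundle_flags(t2)
    assert frac2 == 0.0


def test_bundle_fraction_recovered_from_generator():
    spec = synthetic.SceneSpec(seed=5, n_actin=300, bundle_fraction=0.7,
                               rasterize_masks=False, n_isg=0, n_mt=0)
    scene, truth = synthetic.generate_scene(spec)
    table = arch.pair_distance_angle(scene)
    flags, _ = arch.bundle_flags(table)
    per_fil = table.data.assign(flag=flags) \
        .groupby("host_filament_id")["flag"].mean() >= 0.5
    tf = truth.filaments.set_index("filament_id")["bundled"]
    recovered = per_fil.reindex(tf.index).fillna(False)
    n = len(tf)
    lo, hi = sps.binom.interval(0.95, n, 0.7)
    assert lo <= recovered.sum() <= hi


def test_invalid_bundle_box_rejected(parallel_pair_scene):
    table = arch.pair_distance_angle(parallel_pair_scene)
    with pytest.raises(ValueError):
        arch.bundle_flags(table, dist_range=(17.0, 8.0))
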
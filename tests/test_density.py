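"""Density maps: exact voxel-count semantics, edge policies, co-occurrence."""

import numpy as np
import pytest
from geomutil import density_node_oracle, digitized_ball

import fibmorph as fm
from fibmorph.density import DensityMap
from fibmorph.errors import ConfigurationError, IncompatibilityError


def _vol(arr, spacing=(100.0, 100.0, 100.0), name="junctions"):
    return fm.LabeledVolume(np.asarray(arr).astype(np.uint8), spacing, name)


def test_fully_occupied_saturates():
    dm = fm.compute_density_map(_vol(np.ones((24, 24, 24))), kernel_radius_um=0.5, step_um=0.4)
    assert np.all(dm.values[dm.valid] == pytest.approx(1.0))
    assert dm.valid.any()


def test_empty_volume_is_zero():
    dm = fm.compute_density_map(_vol(np.zeros((24, 24, 24))), kernel_radius_um=0.5, step_um=0.4)
    assert np.all(dm.values == 0.0)


def test_concentric_ball_ratio():
    """ball radius 0.5 um centred on a node, kernel 1.0 um: value ~ (0.5)^3 = 0.125."""
    occ = np.zeros((41, 41, 41), dtype=bool)
    occ |= digitized_ball(10, margin=10)[:41, :41, :41]  # radius 10 voxels = 0.5 um at 50 nm
    vol = _vol(occ, spacing=(50.0, 50.0, 50.0))
    dm = fm.compute_density_map(vol, kernel_radius_um=1.0, step_um=0.25)
    # ball is centred at voxel (20,20,20) -> physical 1.025 um; nearest node index 4 (1.0 um)
    node = dm.values[4, 4, 4]
    n_occ, n_in = density_node_oracle(occ, (0.05, 0.05, 0.05), (1.0, 1.0, 1.0), 1.0)
    assert node == pytest.approx(n_occ / n_in, abs=1e-12)
    assert node == pytest.approx(0.125, rel=0.08)  # voxelization tolerance


def test_matches_direct_counting_oracle():
    """implementation equals full-volume direct counting to 1e-9 relative."""
    rng = np.random.default_rng(2)
    occ = rng.random((32, 32, 32)) < 0.3
    vol = _vol(occ, spacing=(100.0, 100.0, 100.0))
    dm = fm.compute_density_map(vol, kernel_radius_um=0.6, step_um=0.5)
    nodes = np.argwhere(dm.valid)
    rng.shuffle(nodes)
    for w, v, u in nodes[:40]:
        n_occ, n_in = density_node_oracle(
            occ, (0.1, 0.1, 0.1), (u * 0.5, v * 0.5, w * 0.5), 0.6
        )
        assert dm.values[w, v, u] == pytest.approx(n_occ / n_in, rel=1e-9)


def test_mean_matches_global_fraction():
    """stationary random mask: interior mean within a 3-sigma binomial bound."""
    p = 0.3
    rng = np.random.default_rng(9)
    occ = rng.random((40, 40, 40)) < p
    dm = fm.compute_density_map(_vol(occ), kernel_radius_um=0.5, step_um=0.25, edge_policy="strict")
    vals = dm.values[dm.valid]
    kernel_voxels = 4 / 3 * np.pi * 0.5**3 / 0.1**3
    bound = 3 * np.sqrt(p * (1 - p) / kernel_voxels)
    assert abs(vals.mean() - p) < bound


def test_monotone_in_occupancy():
    rng = np.random.default_rng(4)
    occ = rng.random((24, 24, 24)) < 0.2
    extra = occ | (rng.random((24, 24, 24)) < 0.1)
    a = fm.compute_density_map(_vol(occ), kernel_radius_um=0.5, step_um=0.4)
    b = fm.compute_density_map(_vol(extra), kernel_radius_um=0.5, step_um=0.4)
    assert np.all(b.values >= a.values - 1e-12)


def test_edge_policies():
    occ = np.ones((20, 20, 20), dtype=bool)
    strict = fm.compute_density_map(_vol(occ), kernel_radius_um=0.5, step_um=0.25, edge_policy="strict")
    renorm = fm.compute_density_map(_vol(occ), kernel_radius_um=0.5, step_um=0.25)
    # corner nodes: clipped kernel -> invalid under strict, valid+renormalized otherwise
    assert not strict.valid[0, 0, 0]
    assert renorm.values[0, 0, 0] == pytest.approx(1.0)
    assert strict.valid.sum() < renorm.valid.sum()


def test_kernel_smaller_than_voxel_rejected():
    with pytest.raises(ConfigurationError):
        fm.compute_density_map(_vol(np.ones((8, 8, 8))), kernel_radius_um=0.05, step_um=0.25)


def test_overlap_score_self_and_complement():
    rng = np.random.default_rng(1)
    values = rng.random((6, 6, 6))
    valid = np.ones_like(values, dtype=bool)
    dm = DensityMap(values, valid, 0.25, 1.0)
    anti = DensityMap(1 - values, valid, 0.25, 1.0)
    assert fm.overlap_score(dm, dm) == pytest.approx(1.0)
    assert fm.overlap_score(dm, anti) == pytest.approx(-1.0)


def test_overlap_grid_mismatch():
    dm = DensityMap(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool), 0.25, 1.0)
    other = DensityMap(np.zeros((5, 5, 5)), np.ones((5, 5, 5), bool), 0.25, 1.0)
    with pytest.raises(IncompatibilityError):
        fm.overlap_score(dm, other)


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    dm = DensityMap(rng.random((5, 6, 7)), rng.random((5, 6, 7)) < 0.8, 0.25, 1.0, class_name="junctions")
    dm.save(tmp_path / "d.h5")
    back = DensityMap.load(tmp_path / "d.h5")
    assert np.array_equal(back.values, dm.values)
    assert np.array_equal(back.valid, dm.valid)
    assert back.kernel_radius_um == dm.kernel_radius_um


def test_cooccurrence_separates_coseeded_from_uniform():
    """junctions seeded near the lumen co-occur with actin bundles (which line
    the lumen); junctions uniform on all interfaces score lower, seed by seed."""
    deltas = []
    for seed in range(4):
        scores = {}
        for placement in ("apical", "uniform"):
            spec = fm.SyntheticSpec(
                morphology="mixed",
                shape=(72, 72, 72),
                spacing_nm=(100.0, 100.0, 100.0),
                n_cells=12,
                lumen_fraction_target=0.08,
                nucleus_axes_um=None,
                n_junctions=100,
                junction_placement=placement,
                apical_band_um=0.6,
                fiber_density_per_um2=1.5,
                seed=seed,
            )
            scene = fm.generate_organoid(spec)
            maps = {
                name: fm.compute_density_map(
                    scene.volumes[name], kernel_radius_um=0.5, step_um=0.4
                )
                for name in ("junctions", "actin_bundles")
            }
            scores[placement] = fm.overlap_score(maps["junctions"], maps["actin_bundles"])
        deltas.append(scores["apical"] - scores["uniform"])
    assert all(d > 0 for d in deltas)
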
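"""Synthetic organoid generator: determinism, containment, parameter recovery."""

import numpy as np
import pytest
from geomutil import brute_force_nn
from scipy import ndimage, stats

import fibmorph as fm
from fibmorph.errors import FeasibilityError, ValidationError
from fibmorph.synthetic import rasterize_ellipsoid


def _small_spec(**overrides):
    base = dict(
        morphology="compact",
        shape=(48, 48, 48),
        spacing_nm=(100.0, 100.0, 100.0),
        n_cells=4,
        nucleus_axes_um=(0.5, 0.45, 0.4),
        n_mito_per_cell=3,
        mito_volume_lognormal=(0.01, 0.6),
        seed=0,
    )
    base.update(overrides)
    return fm.SyntheticSpec(**base)


def test_spec_validation():
    with pytest.raises(ValidationError):
        fm.SyntheticSpec(morphology="spherical").validate()
    with pytest.raises(ValidationError):
        fm.SyntheticSpec(morphology="compact", lumen_fraction_target=0.2).validate()
    with pytest.raises(ValidationError):
        fm.SyntheticSpec(morphology="monolayer", lumen_fraction_target=0.0).validate()
    with pytest.raises(ValidationError):
        fm.SyntheticSpec(lumen_fraction_target=0.9).validate()


def test_same_seed_bit_identical_different_seed_not():
    a = fm.generate_organoid(_small_spec(seed=1))
    b = fm.generate_organoid(_small_spec(seed=1))
    c = fm.generate_organoid(_small_spec(seed=2))
    for name in a.volumes:
        assert np.array_equal(a.volumes[name].labels, b.volumes[name].labels)
    assert any(
        not np.array_equal(a.volumes[n].labels, c.volumes[n].labels) for n in a.volumes
    )


def test_monolayer_postconditions():
    """12 cells, lumen fraction 0.6 +- 0.05, a single connected lumen."""
    spec = fm.SyntheticSpec(
        morphology="monolayer",
        shape=(80, 80, 80),
        spacing_nm=(100.0, 100.0, 100.0),
        n_cells=12,
        lumen_fraction_target=0.6,
        nucleus_axes_um=None,
        seed=7,
    )
    scene = fm.generate_organoid(spec)
    cells = scene.volumes["cells"].labels
    assert set(np.unique(cells)) == set(range(13))
    assert 0.55 <= scene.ground_truth["achieved_lumen_fraction"] <= 0.65
    _, n_lumen = ndimage.label(scene.volumes["lumen"].labels > 0)
    assert n_lumen == 1


def test_compact_has_no_lumen():
    scene = fm.generate_organoid(_small_spec())
    assert scene.volumes["lumen"].labels.sum() == 0


def test_infeasible_packing_raises():
    with pytest.raises(FeasibilityError):
        fm.generate_organoid(_small_spec(shape=(16, 16, 16), n_cells=50))


@pytest.mark.parametrize("seed", range(20))
def test_containment_invariants_across_seeds(seed):
    """nuclei/mitochondria stay inside their parent cell and the lumen stays
    disjoint from cells, for every seed."""
    morph = ("compact", "monolayer", "mixed")[seed % 3]
    f = {"compact": 0.0, "monolayer": 0.3, "mixed": 0.12}[morph]
    scene = fm.generate_organoid(
        _small_spec(
            morphology=morph,
            shape=(56, 56, 56),
            n_cells=5,
            lumen_fraction_target=f,
            nucleus_axes_um=(0.45, 0.4, 0.35),
            seed=seed,
        )
    )
    cells = scene.volumes["cells"].labels
    nuclei = scene.volumes["nuclei"].labels
    mito = scene.volumes["mitochondria"].labels
    lumen = scene.volumes["lumen"].labels
    assert np.all(cells[nuclei > 0] == nuclei[nuclei > 0])  # nucleus in its own cell
    assert np.all(cells[mito > 0] > 0)
    assert not np.any((lumen > 0) & (cells > 0))
    if f > 0:
        assert abs(scene.ground_truth["achieved_lumen_fraction"] - f) <= 0.05


def test_ellipsoid_rasterization_volume():
    """voxelized ellipsoid volume matches (4/3) pi abc within 3% for smallest
    semi-axis >= 10 voxels."""
    for axes_um in [(1.2, 1.1, 1.0), (2.0, 1.3, 1.0)]:
        mask = rasterize_ellipsoid((64, 64, 64), (0.1, 0.1, 0.1), (3.2, 3.2, 3.2), axes_um)
        analytic = 4 / 3 * np.pi * np.prod(axes_um)
        assert mask.sum() * 0.1**3 == pytest.approx(analytic, rel=0.03)


def test_nucleus_volume_fraction_recovery():
    """programmed 25% nuclear fraction recovered per cell within +-0.02."""
    scene = fm.generate_organoid(
        _small_spec(shape=(64, 64, 64), n_cells=5, nucleus_volume_fraction=0.25, seed=3)
    )
    nuclei = fm.split_instances(scene.volumes["nuclei"])
    frac = fm.volume_fraction(nuclei, scene.volumes["cells"])
    per_cell = frac[frac["parent_id"] > 0]["fraction"]
    assert len(per_cell) == 5
    assert np.all(np.abs(per_cell - 0.25) <= 0.02)


# -- junction process ----------------------------------------------------


def test_junction_forced_centroids():
    """explicit centroids (0,0,0), (1,0,0), (3,0,0) um give NN (1, 1, 2)."""
    spec = _small_spec(n_junctions=3, junction_radius_um=0.0)
    interface = fm.LabeledVolume(np.ones((48, 48, 48), np.uint8), (100, 100, 100))
    pts = np.array([[0.05, 0.05, 0.05], [1.05, 0.05, 0.05], [3.05, 0.05, 0.05]])
    vol, truth = fm.generate_junction_process(spec, interface, centroids_um=pts)
    d, _ = brute_force_nn(np.asarray(truth["centroids_xyz_um"]))
    assert d == pytest.approx([1.0, 1.0, 2.0])
    assert vol.labels.sum() == 3  # one voxel per junction


def test_junction_feasibility_error():
    scene = fm.generate_organoid(_small_spec(n_cells=2))
    interface = scene.volumes["interface"]
    spec = _small_spec(n_junctions=10**6)
    with pytest.raises(FeasibilityError):
        fm.generate_junction_process(spec, interface)


def test_junction_empty_interface_error():
    spec = _small_spec(n_junctions=5)
    empty = fm.LabeledVolume(np.zeros((8, 8, 8), np.uint8), (100, 100, 100))
    with pytest.raises(FeasibilityError):
        fm.generate_junction_process(spec, empty)


def test_junction_hard_core_and_tuning_both_branches():
    """the placement respects the hard minimum separation, and the bisection
    tuner reaches targets below (clustered) and above (repulsive) the
    uniform baseline within 5%."""
    scene = fm.generate_organoid(
        _small_spec(morphology="compact", shape=(80, 80, 80), n_cells=14,
                    nucleus_axes_um=None, n_mito_per_cell=0, seed=5)
    )
    interface = scene.volumes["interface"]
    base_spec = _small_spec(n_junctions=250, junction_radius_um=0.05)
    _, truth = fm.generate_junction_process(base_spec, interface)
    pts = np.asarray(truth["centroids_xyz_um"])
    d, _ = brute_force_nn(pts)
    h0 = 2 * 0.05 + 2.2 * 0.1
    assert d.min() >= h0 - 1e-9
    baseline = float(np.percentile(d, 90))
    for target_rel in (0.6, 1.03):
        target = target_rel * baseline
        spec = _small_spec(n_junctions=250, junction_radius_um=0.05, junction_nn_scale_um=target)
        _, truth = fm.generate_junction_process(spec, interface)
        d, _ = brute_force_nn(np.asarray(truth["centroids_xyz_um"]))
        assert np.percentile(d, 90) == pytest.approx(target, rel=0.05)
    # far above the baseline the hard-core process saturates: explicit error
    spec = fm.SyntheticSpec(**{**base_spec.__dict__, "junction_nn_scale_um": 1.5 * baseline})
    with pytest.raises(FeasibilityError):
        fm.generate_junction_process(spec, interface)


# -- tile tables ---------------------------------------------------------


def test_tile_table_binomial_recovery():
    """8 organoids x 50 tiles at damage rate 0.2: each preserved fraction
    within the 99% binomial band around 0.8."""
    table = fm.generate_tile_table(8, 0.8, seed=21)
    frac = fm.preservation_fraction(table)
    lo = stats.binom.ppf(0.005, 50, 0.8) / 50
    hi = stats.binom.ppf(0.995, 50, 0.8) / 50
    assert len(frac) == 8
    assert np.all((frac["preserved_fraction"] >= lo) & (frac["preserved_fraction"] <= hi))


def test_tile_table_zero_damage():
    table = fm.generate_tile_table(5, 1.0, seed=1)
    frac = fm.preservation_fraction(table)
    assert np.all(frac["preserved_fraction"] == 1.0)


def test_tile_table_determinism():
    a = fm.generate_tile_table(4, 0.7, packing_density_slope_um2=20, seed=9)
    b = fm.generate_tile_table(4, 0.7, packing_density_slope_um2=20, seed=9)
    assert a.tiles.equals(b.tiles) and a.organoids.equals(b.organoids)


def test_zero_slope_gives_null_correlation():
    """with no programmed coupling, |R| stays below 0.3 for ~95% of seeds
    (exact binomial bound at the 0.5% level: at most 5 exceedances in 40)."""
    n_exceed = 0
    for seed in range(40):
        table = fm.generate_tile_table(
            50, 0.5, packing_density_slope_um2=0.0, organoid_sd=0.15, seed=seed
        )
        summary = fm.summarize_preservation(table)
        if abs(summary["pearson_r"]) >= 0.3:
            n_exceed += 1
    assert n_exceed <= 5


def test_programmed_correlation_recovered():
    """mean estimated R over 20 seeds lands within +-0.15 of the generator's
    asymptotic value at n = 50 organoids."""
    slope, mean, sd, noise = 25.8, 0.5, 0.15, 10.0
    target = fm.expected_pearson_r(slope, mean, 50, organoid_sd=sd, packing_noise_um2=noise)
    rs = []
    for seed in range(20):
        table = fm.generate_tile_table(
            50, mean, packing_density_slope_um2=slope, organoid_sd=sd,
            packing_noise_um2=noise, seed=100 + seed,
        )
        rs.append(fm.summarize_preservation(table)["pearson_r"])
    assert np.mean(rs) == pytest.approx(target, abs=0.15)
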
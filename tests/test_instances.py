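"""Instance splitting and morphometrics against analytic and brute-force oracles."""

import numpy as np
import pytest
from geomutil import (
    canonical_labels,
    digitized_ball,
    digitized_box,
    digitized_ellipsoid,
    flood_fill_components,
    spheroid_surface_area,
)

import fibmorph as fm
from fibmorph.errors import ConfigurationError, DomainError, InsufficientDataError


def _vol(mask_or_labels, spacing=(10.0, 10.0, 10.0), name="test"):
    return fm.LabeledVolume(np.asarray(mask_or_labels).astype(np.uint16), spacing, name)


# -- splitting -----------------------------------------------------------


def test_disjoint_objects_split():
    labels = np.zeros((20, 20, 20), dtype=np.uint8)
    labels[2:7, 2, 2] = 1  # 5-voxel rod
    labels[12:17, 12, 12] = 1
    inst = fm.split_instances(_vol(labels))
    assert len(inst) == 2
    assert sorted(inst.table["voxel_count"]) == [5, 5]


def test_corner_touch_depends_on_connectivity():
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    labels[0, 0, 0] = 1
    labels[1, 1, 1] = 1
    assert len(fm.split_instances(_vol(labels), connectivity=26)) == 1
    assert len(fm.split_instances(_vol(labels), connectivity=6)) == 2


@pytest.mark.parametrize("connectivity", [6, 26])
def test_components_match_flood_fill_oracle(connectivity):
    """random volumes partition identically to an independent BFS flood fill."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48, 48)) < 0.25
        inst = fm.split_instances(_vol(mask), connectivity=connectivity)
        oracle = flood_fill_components(mask, connectivity)
        assert np.array_equal(
            canonical_labels(inst.volume.labels), canonical_labels(oracle)
        )


def test_partition_property(random_label_volume):
    inst = fm.split_instances(random_label_volume)
    assert inst.table["voxel_count"].sum() == int((random_label_volume.labels > 0).sum())
    # semantic classes never merge
    for _, row in inst.table.iterrows():
        owners = random_label_volume.labels[inst.volume.labels == row["id"]]
        assert len(np.unique(owners)) == 1


def test_border_objects_flagged():
    labels = np.zeros((10, 10, 10), dtype=np.uint8)
    labels[0:2, 0:2, 0:2] = 1  # touches three faces
    labels[4:6, 4:6, 4:6] = 1  # interior
    inst = fm.split_instances(_vol(labels))
    assert sorted(inst.table["border"]) == [False, True]


def test_empty_volume_gives_empty_set():
    inst = fm.split_instances(_vol(np.zeros((5, 5, 5))))
    assert len(inst) == 0


# -- basic measures ------------------------------------------------------


def test_single_voxel_volume_and_centroid():
    labels = np.zeros((3, 3, 3), dtype=np.uint8)
    labels[0, 0, 0] = 1
    inst = fm.measure_basic(fm.split_instances(_vol(labels, spacing=(20.0, 15.0, 15.0))))
    row = inst.table.iloc[0]
    assert row["volume_um3"] == pytest.approx(4.5e-6)
    assert (row["centroid_x_um"], row["centroid_y_um"], row["centroid_z_um"]) == pytest.approx(
        (0.0075, 0.0075, 0.010)
    )


def test_cube_centroid_at_center():
    labels = np.zeros((6, 6, 6), dtype=np.uint8)
    labels[2:4, 2:4, 2:4] = 1
    inst = fm.measure_basic(fm.split_instances(_vol(labels)))
    row = inst.table.iloc[0]
    assert row["voxel_count"] == 8
    assert row["volume_um3"] * 1e9 == pytest.approx(8000.0)  # nm^3
    assert (row["centroid_x_um"], row["centroid_y_um"], row["centroid_z_um"]) == pytest.approx(
        (0.03, 0.03, 0.03)
    )


def test_ellipsoid_volume_within_3_percent():
    """digitized (2, 1, 1) um ellipsoid at 40 nm voxels vs (4/3) pi abc."""
    mask = digitized_ellipsoid((25, 25, 50))  # voxels, (z, y, x)
    inst = fm.measure_basic(fm.split_instances(_vol(mask, spacing=(40.0, 40.0, 40.0))))
    analytic = 4 / 3 * np.pi * 2 * 1 * 1
    assert inst.table.iloc[0]["volume_um3"] == pytest.approx(analytic, rel=0.03)


# -- surface area and sphericity ----------------------------------------


def test_ball_area_within_5_percent():
    mask = digitized_ball(20)
    a = fm.measure_surface_area(fm.split_instances(_vol(mask))).table.iloc[0]["area_um2"]
    true = 4 * np.pi * (20 * 0.01) ** 2  # 10 nm voxels
    assert a == pytest.approx(true, rel=0.05)


def test_box_area_within_5_percent():
    mask = digitized_box(20, 12, 8)
    a = fm.measure_surface_area(fm.split_instances(_vol(mask))).table.iloc[0]["area_um2"]
    true = 2 * (20 * 12 + 12 * 8 + 20 * 8) * 0.01**2
    assert a == pytest.approx(true, rel=0.05)


def test_face_counting_overestimates_sphere_by_half():
    """naive face counting lands near the known 3/2 overestimate (negative control)."""
    mask = digitized_ball(20)
    a = fm.measure_surface_area(fm.split_instances(_vol(mask)), method="face").table.iloc[0][
        "area_um2"
    ]
    true = 4 * np.pi * (20 * 0.01) ** 2
    assert a / true == pytest.approx(1.5, abs=0.06)


def test_ball_area_error_converges_with_radius():
    """phase-averaged |relative error| decreases over radii 10 -> 20 -> 40
    and is under 5% from radius 20 on."""
    errors = []
    offsets = [(0.0, 0.0, 0.0), (0.31, 0.47, 0.11), (0.73, 0.19, 0.57)]
    for r in (10, 20, 40):
        errs = []
        for off in offsets:
            mask = digitized_ball(r, offset=off)
            a = fm.measure_surface_area(fm.split_instances(_vol(mask))).table.iloc[0]["area_um2"]
            errs.append(abs(a / (4 * np.pi * (r * 0.01) ** 2) - 1))
        errors.append(np.mean(errs))
    assert errors[0] > errors[1] > errors[2]
    assert errors[1] <= 0.05 and errors[2] <= 0.05


def test_anisotropic_ball_area():
    """a physical ball digitized on a 2:1 anisotropic grid keeps its area."""
    sp = (20.0, 10.0, 10.0)
    r_um = 0.2
    nz, ny, nx = 31, 51, 51
    zz, yy, xx = np.mgrid[:nz, :ny, :nx]
    d2 = (
        ((zz - nz // 2) * 0.02) ** 2
        + ((yy - ny // 2) * 0.01) ** 2
        + ((xx - nx // 2) * 0.01) ** 2
    )
    inst = fm.split_instances(_vol(d2 <= r_um**2, spacing=sp))
    a = fm.measure_surface_area(inst).table.iloc[0]["area_um2"]
    assert a == pytest.approx(4 * np.pi * r_um**2, rel=0.05)


def test_sphericity_closed_forms():
    assert fm.sphericity(4 / 3 * np.pi, 4 * np.pi) == pytest.approx(1.0)
    assert fm.sphericity(1.0, 6.0) == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)
    with pytest.raises(DomainError):
        fm.sphericity(0.0, 1.0)


def test_sphericity_decreases_with_elongation():
    """prolate ellipsoids (2,1,1) then (4,1,1): psi matches the numeric
    surface-integral oracle and decreases with elongation."""
    measured = []
    for ax_z in (50, 100):  # 40 nm voxels: semi-axes (2,1,1) and (4,1,1) um
        mask = digitized_ellipsoid((ax_z, 25, 25))
        inst = fm.measure_surface_area(
            fm.split_instances(_vol(mask, spacing=(40.0, 40.0, 40.0)))
        )
        psi = inst.table.iloc[0]["sphericity"]
        a_um, b_um = ax_z * 0.04, 1.0
        v_oracle = 4 / 3 * np.pi * a_um * b_um**2
        psi_oracle = (6 * np.sqrt(np.pi) * v_oracle) ** (2 / 3) / spheroid_surface_area(a_um, b_um)
        assert psi == pytest.approx(psi_oracle, abs=0.03)
        measured.append(psi)
    assert measured[1] < measured[0] < 1.0


def test_sphericity_bounded_for_convex_bodies():
    """psi <= 1 + estimator tolerance for balls, boxes and ellipsoids."""
    bodies = [digitized_ball(15), digitized_box(24, 16, 12), digitized_ellipsoid((12, 18, 24))]
    for mask in bodies:
        inst = fm.measure_surface_area(fm.split_instances(_vol(mask)))
        assert inst.table.iloc[0]["sphericity"] <= 1.05


def test_unit_invariance_of_measures():
    """scaling the spacing by lambda scales V by l^3, A by l^2, psi unchanged."""
    mask = digitized_ball(12)
    lam = 3.7
    a = fm.measure_surface_area(fm.split_instances(_vol(mask, spacing=(10, 10, 10))))
    b = fm.measure_surface_area(
        fm.split_instances(_vol(mask, spacing=(10 * lam, 10 * lam, 10 * lam)))
    )
    ra, rb = a.table.iloc[0], b.table.iloc[0]
    assert rb["volume_um3"] == pytest.approx(ra["volume_um3"] * lam**3, rel=1e-12)
    assert rb["area_um2"] == pytest.approx(ra["area_um2"] * lam**2, rel=1e-9)
    assert rb["sphericity"] == pytest.approx(ra["sphericity"], rel=1e-9)


def test_unknown_surface_method_rejected():
    mask = digitized_ball(5)
    with pytest.raises(ConfigurationError):
        fm.measure_surface_area(fm.split_instances(_vol(mask)), method="exotic")


# -- outliers and volume fractions --------------------------------------


def _instances_with_volumes(volumes_um3):
    import pandas as pd

    table = pd.DataFrame(
        {"id": np.arange(1, len(volumes_um3) + 1), "volume_um3": volumes_um3}
    )
    vol = fm.LabeledVolume(np.zeros((2, 2, 2), dtype=np.uint8), (10, 10, 10))
    return fm.InstanceSet(vol, table)


def test_outlier_flagging_threshold():
    assert list(fm.flag_volume_outliers(_instances_with_volumes([1, 1, 1, 1, 150]))) == [5]
    assert list(fm.flag_volume_outliers(_instances_with_volumes([1, 1, 1, 1, 50]))) == []
    with pytest.raises(InsufficientDataError):
        fm.flag_volume_outliers(_instances_with_volumes([1, 2]))


def test_volume_fraction_count_ratio():
    parents = np.zeros((10, 10, 10), dtype=np.uint8)
    parents[:, :, :5] = 1
    parents[:, :, 5:] = 2
    child = np.zeros_like(parents)
    child[2:4, 2:7, 2:4] = 1  # 20 voxels in parent 1 only
    frac = fm.volume_fraction(_vol(child), _vol(parents))
    by_parent = frac.set_index("parent_id")
    assert by_parent.loc[1, "fraction"] == pytest.approx(20 / 500)
    assert by_parent.loc[2, "fraction"] == pytest.approx(0.0)


def test_volume_fraction_reports_orphans():
    parents = np.zeros((6, 6, 6), dtype=np.uint8)
    parents[:3] = 1
    child = np.zeros_like(parents)
    child[4, 0, 0] = 1  # outside every parent
    frac = fm.volume_fraction(_vol(child), _vol(parents))
    orphan = frac[frac["parent_id"] == 0]
    assert len(orphan) == 1 and orphan.iloc[0]["child_voxels"] == 1
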
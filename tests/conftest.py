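import numpy as np
import pytest

from fibmorph import LabeledVolume, SyntheticSpec, generate_organoid


@pytest.fixture(scope="session")
def small_monolayer_scene():
    """A small monolayer organoid with every structure class populated."""
    spec = SyntheticSpec(
        morphology="monolayer",
        shape=(96, 96, 96),
        spacing_nm=(80.0, 80.0, 80.0),
        n_cells=10,
        lumen_fraction_target=0.35,
        nucleus_axes_um=(0.8, 0.7, 0.6),
        nucleus_volume_fraction=0.25,
        n_junctions=120,
        junction_placement="apical",
        fiber_density_per_um2=0.5,
        n_mito_per_cell=4,
        mito_volume_lognormal=(0.04, 0.6),
        seed=7,
    )
    return generate_organoid(spec)


@pytest.fixture(scope="session")
def mito_outlier_scene():
    """Compact scene with two planted 120x-median mitochondria."""
    spec = SyntheticSpec(
        morphology="compact",
        shape=(120, 120, 120),
        spacing_nm=(80.0, 80.0, 80.0),
        n_cells=6,
        nucleus_axes_um=None,
        n_mito_per_cell=20,
        mito_volume_lognormal=(0.02, 0.5),
        outlier_mito=(2, 120.0),
        seed=13,
    )
    return generate_organoid(spec)


@pytest.fixture()
def random_label_volume():
    rng = np.random.default_rng(42)
    labels = rng.integers(0, 4, size=(32, 32, 32))
    return LabeledVolume(labels, (40.0, 30.0, 30.0), class_name="random")
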
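import numpy as np
import pytest

import phenoplate as pp


@pytest.fixture(scope="session")
def small_plate() -> pp.SyntheticPlate:
    """A small synthetic docking plate shared across tests: 4 wells x 2 sites,
    96x96 px, ~10 cells per image, elevated mitotic fraction so every class
    is populated."""
    spec = pp.PlateSpec(
        wells=("A01", "A02", "B01", "B02"),
        images_per_well=2,
        image_size=96,
        cells_per_image=10,
        mitotic_fraction=0.25,
        seed=11,
    )
    return pp.generate_plate(spec)


@pytest.fixture(scope="session")
def nuclei_table(small_plate) -> pp.ObjectTable:
    return small_plate.measure(kinds=("intensity",))


@pytest.fixture(scope="session")
def blob_model():
    """3-class model on well-separated Gaussian blobs, with its data."""
    X, y = pp.generate_feature_blobs(30, k=3, separation=8.0, n_features=4, seed=5)
    model = pp.train_model(X, y, C=10.0, gamma=0.5)
    return model, X, y


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
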
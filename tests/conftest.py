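import numpy as np
import pandas as pd
import pytest

from cytoniche.simulate import SyntheticTissueConfig, generate_image


@pytest.fixture(scope="session")
def small_config():
    return SyntheticTissueConfig.make(
        {"tumour": 0.4, "macrophage": 0.35, "tcell": 0.25},
        shape_px=(160, 160),
        n_cells=80,
    )


@pytest.fixture(scope="session")
def rendered_image(small_config):
    """One small rendered core: (stack, segmentation, truth table)."""
    return generate_image(small_config, seed=7, image_id="fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_cells(rng, n, types=("a", "b", "c"), side_um=300.0, image_id="img"):
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "image_id": image_id,
            "centroid_x_um": rng.uniform(0, side_um, n),
            "centroid_y_um": rng.uniform(0, side_um, n),
            "lineage": rng.choice(list(types), size=n),
        }
    )
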
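import numpy as np
import pytest

from spotfactor import simulate_joint_data, simulate_tissue_image


@pytest.fixture(scope="session")
def small_joint_data():
    """Well-separated 4-region joint dataset, moderate noise."""
    return simulate_joint_data(m=80, n=120, f=24, k=4, snr_rna=10, snr_img=10, seed=11)


@pytest.fixture(scope="session")
def noiseless_joint_data():
    return simulate_joint_data(
        m=60, n=100, f=20, k=3, snr_rna=np.inf, snr_img=np.inf, seed=7
    )


@pytest.fixture(scope="session")
def tissue_scene():
    """Coordinates, region labels, and a painted two-region image."""
    expr, feats, truth = simulate_joint_data(
        m=36, n=50, f=10, k=2, snr_rna=10, snr_img=10, seed=21
    )
    image = simulate_tissue_image(
        truth.coords, truth.region_labels, truth.spot_diameter_px, palette_seed=21
    )
    return expr, truth, image
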
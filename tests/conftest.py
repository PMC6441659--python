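import numpy as np
import pytest

from shrubshape.io import PointCloud
from shrubshape.synthetic import BushSpec, FieldSpec, generate_bush, \
    generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform(-5, 5, size=(1000, 3)), source_id="random")


@pytest.fixture(scope="session")
def clean_bush_cloud():
    """A noiseless single bush at the origin (crown base at z = 0)."""
    cloud, truth = generate_bush(BushSpec(seed=7))
    return cloud, truth


@pytest.fixture(scope="session")
def small_field():
    """2 rows x 3 bushes on a 5-degree slope with weeds and outliers."""
    spec = FieldSpec(
        bush_specs=[[BushSpec(lambda_true=lam, noise_sigma_m=0.01,
                              n_outliers=50) for lam in (0.7, 1.0, 1.4)]] * 2,
        ground_slope_deg=5.0, ground_roughness_m=0.02,
        row_heading_deg=20.0, n_weed_clusters=3, seed=11,
    )
    return generate_field(spec)
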
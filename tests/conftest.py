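import warnings

import numpy as np
import pytest

from guvmech import synthetic as syn

warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def noiseless_series():
    """One noiseless aspiration series at K_A = 500 mN/m (shared, read-only)."""
    return syn.gen_aspiration_series(syn.default_aspiration_spec(ka_true=500.0, seed=1))


@pytest.fixture(scope="session")
def bilayer_frames_324():
    """Paper-scale synthetic bilayer: 324 lipids/leaflet, 20 frames."""
    spec = syn.BilayerSimSpec(
        n_per_leaflet=324, hpp_true=3.83, z_sigma=0.3, chain_overlap=1.0,
        n_frames=20, seed=2,
    )
    return syn.gen_bilayer_frames(spec)


def circle_points(cx, cy, r, n, phase=0.0):
    th = phase + np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
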
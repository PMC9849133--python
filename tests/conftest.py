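import numpy as np
import pytest

import vpngrad as v


@pytest.fixture(scope="session")
def pair_connectome():
    """Antiparallel-pair study conditions: 60 cells, Poisson noise, baseline 20."""
    cfg = v.SyntheticConfig(seed=1, partner_specs=v.antiparallel_pair_specs())
    arbors, matrix, sites, truth = v.generate_connectome(cfg)
    return cfg, arbors, matrix, sites, truth


@pytest.fixture(scope="session")
def noiseless_pair_connectome():
    cfg = v.SyntheticConfig(seed=2, partner_specs=v.antiparallel_pair_specs(), count_noise="none")
    arbors, matrix, sites, truth = v.generate_connectome(cfg)
    return cfg, arbors, matrix, sites, truth


@pytest.fixture(scope="session")
def full_connectome():
    """Default 5-partner conditions (two antiparallel pairs + one uniform)."""
    cfg = v.SyntheticConfig(seed=1)
    arbors, matrix, sites, truth = v.generate_connectome(cfg)
    return cfg, arbors, matrix, sites, truth


@pytest.fixture(scope="session")
def lobula_plane():
    """The generating cut-plane of the synthetic lobula sheet (z = 0)."""
    return v.CutPlane(anchor=[0.0, 0.0, -1.0], normal=[0.0, 0.0, 1.0], axes=[[1, 0, 0], [0, 1, 0]])


@pytest.fixture(scope="session")
def tiling_rf_population():
    """A uniformly tiling Gaussian RF population over the hemifield."""
    rfs = []
    for az in np.arange(-10.0, 141.0, 5.0):
        for el in np.arange(-40.0, 41.0, 5.0):
            rfs.append(v.GaussianRF(centre=(az, el), sigma_deg=10.0))
    return rfs
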
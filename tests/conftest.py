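import numpy as np
import pytest

from odeqtl import (
    FitConfig, OdeParams, SimConfig,
    GENOTYPE1_PARAMS, GENOTYPE2_PARAMS,
    simulate_dataset,
)
from odeqtl.simulate import small_linkage_map


@pytest.fixture(scope="session")
def tiny_map():
    """Three markers, 10 cM apart, one linkage group."""
    return small_linkage_map(n_markers=3, spacing_cm=10.0)


@pytest.fixture(scope="session")
def marker_qtl_dataset(tiny_map):
    """Moderate-noise dataset with the QTL exactly at the middle marker."""
    cfg = SimConfig(seed=11, n_rils=60, linkage_map=tiny_map,
                    qtl_group="g01", qtl_cm=10.0, h2=0.4)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset(tiny_map):
    """Essentially noise-free dataset (sigma = 1e-6 g) at the middle marker."""
    cfg = SimConfig(seed=7, n_rils=40, linkage_map=tiny_map,
                    qtl_group="g01", qtl_cm=10.0,
                    sigma=np.array([1e-6, 1e-6, 1e-6]))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fast_fit_config():
    """Single-start config keeping fit times suitable for unit tests."""
    return FitConfig(n_starts=1, simplex_maxfev=0, outer_rounds=1,
                     max_outer_iter=150)


@pytest.fixture(scope="session")
def generating_pair():
    return GENOTYPE1_PARAMS, GENOTYPE2_PARAMS
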
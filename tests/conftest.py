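import logging

import numpy as np
import pytest

from glycolevels.fixtures import (
    fc2_backbone,
    heavy_chain_backbone,
    intact_backbone,
    peptide_backbone,
)
from glycolevels.simulate import nistmab_truth
from glycolevels.spectra import Scan, SpectrumSeries


@pytest.fixture(autouse=True)
def _quiet_overlap_warnings(caplog):
    # window-overlap warnings are expected study conditions at the intact
    # level; keep test output readable
    logging.getLogger("glycolevels.quant").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def backbones():
    return {
        "peptide": peptide_backbone(),
        "fc2": fc2_backbone(),
        "heavy_chain": heavy_chain_backbone(),
        "intact": intact_backbone(),
    }


@pytest.fixture(scope="session")
def truth_clean():
    """NISTmAb-like study conditions, no glycation."""
    return nistmab_truth(seed=7)


@pytest.fixture(scope="session")
def truth_glycated():
    """Same conditions with 10 % per-site glycation."""
    return nistmab_truth(seed=7, glycation_g=0.1)


def make_series(n_scans=3, n_points=50, rt0=1.0, centroid=False, seed=0):
    rng = np.random.default_rng(seed)
    mz = np.linspace(100.0, 110.0, n_points)
    return SpectrumSeries(
        [
            Scan(rt0 + 0.5 * i, mz, rng.random(n_points), centroid=centroid)
            for i in range(n_scans)
        ]
    )


@pytest.fixture
def small_series():
    return make_series()
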
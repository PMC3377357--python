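import numpy as np
import pytest

from bcmpbpk.kinetics import MetabolicParamsTwoPathway, MetabolicParamsTwoSite
from bcmpbpk.model import ClosedChamberConfig
from bcmpbpk.physiology import ChemicalParams, PhysiologicalParams


@pytest.fixture
def phys():
    return PhysiologicalParams()


@pytest.fixture
def chem():
    return ChemicalParams()


@pytest.fixture
def cfg_two_pathway():
    """Canonical two-pathway configuration at the 500 ppm reference exposure."""
    return ClosedChamberConfig(c0_ppm=500.0, hypothesis="two_pathway",
                               metabolic=MetabolicParamsTwoPathway())


@pytest.fixture
def cfg_two_site():
    return ClosedChamberConfig(c0_ppm=500.0, hypothesis="two_site",
                               metabolic=MetabolicParamsTwoSite())


@pytest.fixture
def coarse_obs_times():
    """Small observation grid for fast estimation tests (24 points)."""
    return np.round(np.arange(0.25, 6.001, 0.25), 10)
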
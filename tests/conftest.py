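import numpy as np
import pytest

from pixlrt import (
    PopulationScenario,
    RelativeRiskModel,
    Subpopulation,
)


@pytest.fixture
def boys_maf30_rb2():
    """500 affected-son triads, one HWE population, MAF 0.3, R_B = 2."""
    return PopulationScenario(
        subpops=(Subpopulation(1.0, 0.3, 0.02, 0.02),),
        rr=RelativeRiskModel(r_boy=2.0),
        n_families=500, sex_design="boys_only")


@pytest.fixture
def girls_maf30_logadd2():
    """500 affected-daughter triads, MAF 0.3, girls log-additive R_G1 = 2."""
    return PopulationScenario(
        subpops=(Subpopulation(1.0, 0.3, 0.02, 0.02),),
        rr=RelativeRiskModel.logadditive(2.0),
        n_families=500, sex_design="girls_only")


@pytest.fixture
def null_scenario():
    """Homogeneous null population, both offspring sexes."""
    return PopulationScenario(
        subpops=(Subpopulation(1.0, 0.3, 0.02, 0.02),),
        rr=RelativeRiskModel(),
        n_families=500, sex_design="both_proportional")


@pytest.fixture
def admixed_null_s1():
    """Two equal HWE subpopulations, all relative risks 1: the admixture
    setting in which mating-type-sharing across sexes is misspecified."""
    return PopulationScenario(
        subpops=(Subpopulation(0.5, 0.3, 0.02, 0.02),
                 Subpopulation(0.5, 0.2, 0.01, 0.02)),
        rr=RelativeRiskModel(), n_families=1000,
        sex_design="both_proportional")


@pytest.fixture
def rng():
    return np.random.default_rng(20150210)
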
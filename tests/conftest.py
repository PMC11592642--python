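import numpy as np
import pytest

from icroc.families import Family, ParamVector
from icroc.roc import BiDistributionPair
from icroc.synth import SyntheticTableSpec, make_feature_table

# one representative valid parameterization per family, reused across tests
FAMILY_SPECS = {
    Family.NORMAL: ParamVector(Family.NORMAL, {"mu": 0.5, "sigma": 1.3}),
    Family.EXPONENTIAL: ParamVector(Family.EXPONENTIAL, {"mu": 2.0}),
    Family.WEIBULL: ParamVector(Family.WEIBULL, {"alpha": 2.0, "beta": 1.5}),
    Family.GAMMA: ParamVector(Family.GAMMA, {"alpha": 2.5, "beta": 1.5}),
    Family.EV: ParamVector(Family.EV, {"mu": 1.0, "sigma": 0.8}),
    Family.GEV: ParamVector(Family.GEV, {"k": 0.2, "sigma": 1.0, "mu": 0.5}),
    Family.GP: ParamVector(Family.GP, {"k": 0.1, "sigma": 1.0, "mu": 0.0}),
}


@pytest.fixture(scope="session")
def family_specs():
    return FAMILY_SPECS


@pytest.fixture
def binormal_pair():
    return BiDistributionPair.from_params(
        ParamVector(Family.NORMAL, {"mu": 1.0, "sigma": 1.0}),
        ParamVector(Family.NORMAL, {"mu": 0.0, "sigma": 1.0}),
    )


@pytest.fixture
def identical_pair():
    spec = ParamVector(Family.EXPONENTIAL, {"mu": 1.0})
    return BiDistributionPair.from_params(spec, spec)


@pytest.fixture(scope="session")
def planted_table():
    """569x30 two-class Gaussian table with 5 informative features (effect 2)."""
    return make_feature_table(SyntheticTableSpec(seed=7))


@pytest.fixture(scope="session")
def small_planted_table():
    """A lighter planted-signal table for slower estimators."""
    return make_feature_table(
        SyntheticTableSpec(n_instances=300, n_features=12, n_informative=4, seed=11)
    )
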
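import numpy as np
import pytest

from lomaxtan import LomaxTangent, load_dataset


@pytest.fixture(scope="session")
def wheaton():
    return load_dataset("wheaton").values


@pytest.fixture(scope="session")
def glass():
    return load_dataset("glass_fibre").values


@pytest.fixture(scope="session")
def glass_mles():
    # LT-W glass-fibre MLEs (verified: they maximize the sample log-likelihood)
    return dict(s=7.5220, k=0.755, xi=(1.1863, 3.8308))


@pytest.fixture(scope="session")
def lt_exp_unit():
    return LomaxTangent("exponential", s=1.0, k=1.0, xi=(1.0,))


# parameter sets spanning the simulation scenarios, keyed (baseline, s, k, xi)
PARAM_GRID = [
    ("weibull", 0.5, 0.2, (1.2, 0.8)),
    ("weibull", 1.2, 0.8, (1.8, 1.5)),
    ("weibull", 1.8, 1.5, (2.6, 2.1)),
    ("weibull", 0.7, 1.1, (3.5, 3.0)),
    ("weibull", 2.0, 2.0, (1.0, 2.0)),
    ("weibull", 13.7781, 2.9651, (13.4326, 0.8301)),
    ("gamma", 1.0, 1.0, (2.0,)),
    ("gamma", 3.0, 0.5, (0.8,)),
    ("rayleigh", 0.5, 0.3, (1.0,)),
    ("rayleigh", 2.0, 1.5, (0.5,)),
    ("exponential", 1.0, 1.0, (1.0,)),
    ("exponential", 5.0, 0.4, (2.0,)),
]


@pytest.fixture(params=PARAM_GRID, ids=lambda p: f"{p[0]}-s{p[1]}-k{p[2]}")
def grid_dist(request):
    name, s, k, xi = request.param
    return LomaxTangent(name, s=s, k=k, xi=xi)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
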
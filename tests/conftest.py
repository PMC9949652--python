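import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmcdyn.fixtures import bistable_parameters, default_grid
from cmcdyn.reduction import Extremum, PotentialProfile, build_potential
from cmcdyn.stochastic import define_states

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bistable_params():
    return bistable_parameters()


@pytest.fixture(scope="session")
def bistable_profile(bistable_params):
    """Bistable landscape on the default working grid."""
    return build_potential(bistable_params, default_grid(), method="oracle")


@pytest.fixture(scope="session")
def bistable_wide_profile(bistable_params):
    """Bistable landscape on a wide grid (confines moderate-noise densities)."""
    return build_potential(bistable_params, np.linspace(0.0, 9.0, 3600), method="oracle")


@pytest.fixture(scope="session")
def bistable_states(bistable_wide_profile):
    return define_states(bistable_wide_profile)


def make_quartic_double_well(a=4.0, center=1.5, half=0.7, R_upper=4.0, n=2001):
    """Sharp synthetic double well U = a((x-c)^2 - half^2)^2, analytic extrema.

    Wells at c +- half, barrier at c; stiff curvatures make Monte-Carlo escape
    statistics cheap, so this is the workhorse landscape for stochastic unit
    tests (the physically derived landscapes are much softer).
    """
    grid = np.linspace(0.0, R_upper, n)
    y = grid - center
    U = a * (y**2 - half**2) ** 2
    U -= U[0]
    drift = -4.0 * a * y * (y**2 - half**2)
    k_min = 8.0 * a * half**2
    k_max = -4.0 * a * half**2
    minima = [
        Extremum(center - half, k_min),
        Extremum(center + half, k_min),
    ]
    maxima = [Extremum(center, k_max)]
    return PotentialProfile(
        grid, U, drift, minima=minima, maxima=maxima,
        provenance={"method": "analytic", "form": "quartic double well"},
    )


@pytest.fixture(scope="session")
def quartic_profile():
    return make_quartic_double_well()
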
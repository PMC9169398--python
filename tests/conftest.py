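import numpy as np
import pytest

from phenorate import (
    CALIMA,
    JAMAPA,
    EnvironmentVector,
    default_parameters,
)


@pytest.fixture(scope="session")
def params():
    """The packaged fitted 25-coefficient parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def warm_short_day():
    """Tavg 25 C, 8 C amplitude, short photoperiod (the temperature-sweep endpoint)."""
    return EnvironmentVector(DL=11.5, Srad=18.2719, Tmax=29.0, Tmin=21.0)


@pytest.fixture(scope="session")
def mild_short_day():
    """Tavg 22 C, short photoperiod (the day-length-sweep base point)."""
    return EnvironmentVector(DL=11.5, Srad=18.2719, Tmax=26.0, Tmin=18.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def literal_rate_oracle(env, operators, p):
    """Brute-force rate evaluation looping over every coefficient row literally.

    Kept independent of the library's vector path: plain floats, explicit
    centering subtraction per factor, explicit sign products.
    """
    centers = {
        "DL": p.centering.DL_m,
        "Srad": p.centering.Srad_m,
        "Tmax": p.centering.Tmax_m,
        "Tmin": p.centering.Tmin_m,
    }
    envmap = {"DL": env.DL, "Srad": env.Srad, "Tmax": env.Tmax, "Tmin": env.Tmin}
    total = p.mu_c
    for factor, coef in p.alpha.items():
        total += coef * (envmap[factor] - centers[factor])
    for i, (locus, coef) in enumerate(p.beta.items()):
        total += coef * operators[int(locus[2:]) - 1]
    for (a, b), coef in p.theta.items():
        total += coef * operators[int(a[2:]) - 1] * operators[int(b[2:]) - 1]
    for (factor, locus), coef in p.gamma.items():
        total += coef * (envmap[factor] - centers[factor]) * operators[int(locus[2:]) - 1]
    return total
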
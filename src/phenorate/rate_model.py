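"""The centered linear rate-of-development function.

The daily rate of progress toward flowering for genotype *g* on a day with
environment *f* is

    RF = mu_c + sum_i alpha_i f_i^c + sum_j beta_j TF_j
         + sum_{j<j*} theta_{jj*} TF_j TF_{j*} + sum_{ij} gamma_{ij} f_i^c TF_j

where f_i^c are the four environmental drivers (day length, solar radiation,
Tmax, Tmin) centered on their across-site means, and TF_j are the +-1 allele
operators.  The packaged default is the fitted 25-coefficient set for the
Jamapa x Calima family; the interaction structure (which theta and gamma
terms exist) is data, so alternative structures fit without code changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .genetics import LOCUS_NAMES, QTLGenotype

log = logging.getLogger(__name__)

#: Fixed order of the environmental factors everywhere in the package.
FACTOR_NAMES: tuple[str, ...] = ("DL", "Srad", "Tmax", "Tmin")


@dataclass(frozen=True)
class CenteringConstants:
    """Across-site means used to center the environmental drivers.

    Units: DL_m hours, Srad_m MJ m-2 d-1, Tmax_m / Tmin_m degrees C.
    """

    DL_m: float = 12.37
    Srad_m: float = 18.218
    Tmax_m: float = 27.458
    Tmin_m: float = 16.128

    def __post_init__(self) -> None:
        vals = (self.DL_m, self.Srad_m, self.Tmax_m, self.Tmin_m)
        if not all(np.isfinite(vals)):
            raise ValueError("centering constants must be finite")
        if self.Tmax_m <= self.Tmin_m:
            raise ValueError("Tmax_m must exceed Tmin_m")

    def as_array(self) -> np.ndarray:
        return np.array([self.DL_m, self.Srad_m, self.Tmax_m, self.Tmin_m])


DEFAULT_CENTERING = CenteringConstants()


@dataclass(frozen=True)
class EnvironmentVector:
    """One day's (or one constant run's) environmental drivers.

    DL in hours [0, 24]; Srad in MJ m-2 d-1, non-negative; Tmax >= Tmin (C).
    """

    DL: float
    Srad: float
    Tmax: float
    Tmin: float

    def __post_init__(self) -> None:
        vals = (self.DL, self.Srad, self.Tmax, self.Tmin)
        if not all(np.isfinite(vals)):
            raise ValueError("environment values must be finite")
        if not 0 <= self.DL <= 24:
            raise ValueError(f"day length must be in [0, 24] h, got {self.DL}")
        if self.Srad < 0:
            raise ValueError(f"solar radiation must be >= 0, got {self.Srad}")
        if self.Tmax < self.Tmin:
            raise ValueError(f"Tmax ({self.Tmax}) < Tmin ({self.Tmin})")

    @property
    def Tavg(self) -> float:
        return 0.5 * (self.Tmax + self.Tmin)

    def as_array(self) -> np.ndarray:
        return np.array([self.DL, self.Srad, self.Tmax, self.Tmin])


@dataclass(frozen=True)
class RateModelParameters:
    """The coefficient set of the rate function plus its centering constants.

    ``theta`` maps ordered locus pairs, ``gamma`` maps (factor, locus) pairs;
    both carry only the terms present in the model.  The default structure
    has 1 + 4 + 12 + 1 + 7 = 25 coefficients.
    """

    mu_c: float
    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    theta: Mapping[tuple[str, str], float]
    gamma: Mapping[tuple[str, str], float]
    centering: CenteringConstants = field(default_factory=CenteringConstants)

    def __post_init__(self) -> None:
        if set(self.alpha) != set(FACTOR_NAMES):
            raise ValueError(f"alpha must cover exactly {FACTOR_NAMES}")
        if set(self.beta) != set(LOCUS_NAMES):
            raise ValueError("beta must cover exactly TF1..TF12")
        for a, b in self.theta:
            if a not in LOCUS_NAMES or b not in LOCUS_NAMES:
                raise ValueError(f"theta pair ({a}, {b}) names an unknown locus")
        for f, l in self.gamma:
            if f not in FACTOR_NAMES or l not in LOCUS_NAMES:
                raise ValueError(f"gamma pair ({f}, {l}) is not (factor, locus)")
        object.__setattr__(self, "alpha", dict(self.alpha))
        object.__setattr__(self, "beta", dict(self.beta))
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "gamma", dict(self.gamma))

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.alpha) + len(self.beta) + len(self.theta) + len(self.gamma)

    def with_centering(self, centering: CenteringConstants) -> "RateModelParameters":
        return replace(self, centering=centering)

    # -- term enumeration shared by the design matrix and the evaluator ------

    def term_labels(self) -> list[str]:
        """Column labels in the fixed design order: intercept, alpha, beta,
        theta, gamma."""
        labels = ["mu_c"]
        labels += [f"alpha[{f}]" for f in FACTOR_NAMES]
        labels += [f"beta[{l}]" for l in LOCUS_NAMES]
        labels += [f"theta[{a}:{b}]" for a, b in self.theta]
        labels += [f"gamma[{f}:{l}]" for f, l in self.gamma]
        return labels

    def coefficient_vector(self) -> np.ndarray:
        """Coefficients in the same fixed order as :meth:`term_labels`."""
        vec = [self.mu_c]
        vec += [self.alpha[f] for f in FACTOR_NAMES]
        vec += [self.beta[l] for l in LOCUS_NAMES]
        vec += list(self.theta.values())
        vec += list(self.gamma.values())
        return np.asarray(vec)

    def with_coefficient_vector(self, vec: np.ndarray) -> "RateModelParameters":
        """Rebuild a parameter set from a vector in design order."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_coefficients:
            raise ValueError(
                f"expected {self.n_coefficients} coefficients, got {vec.size}"
            )
        i = 0
        mu_c = float(vec[i]); i += 1
        alpha = {f: float(vec[i + k]) for k, f in enumerate(FACTOR_NAMES)}
        i += len(FACTOR_NAMES)
        beta = {l: float(vec[i + k]) for k, l in enumerate(LOCUS_NAMES)}
        i += len(LOCUS_NAMES)
        theta = {p: float(vec[i + k]) for k, p in enumerate(self.theta)}
        i += len(self.theta)
        gamma = {p: float(vec[i + k]) for k, p in enumerate(self.gamma)}
        return RateModelParameters(mu_c, alpha, beta, theta, gamma, self.centering)


def _parse_param_rows(rows: Iterable[tuple[str, str, str, str]]) -> RateModelParameters:
    mu_c = None
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    theta: dict[tuple[str, str], float] = {}
    gamma: dict[tuple[str, str], float] = {}
    centering: dict[str, float] = {}
    for term, factor, locus, value in rows:
        v = float(value)
        if term == "center":
            mu_c = v
        elif term == "alpha":
            alpha[factor] = v
        elif term == "beta":
            beta[locus] = v
        elif term == "theta":
            a, b = locus.split(":")
            theta[(a, b)] = v
        elif term == "gamma":
            gamma[(factor, locus)] = v
        elif term == "centering":
            centering[factor] = v
        else:
            raise ValueError(f"unknown parameter term {term!r}")
    if mu_c is None:
        raise ValueError("parameter file lacks the 'center' row")
    if set(centering) != set(FACTOR_NAMES):
        raise ValueError("parameter file must supply all four centering constants")
    cc = CenteringConstants(
        DL_m=centering["DL"], Srad_m=centering["Srad"],
        Tmax_m=centering["Tmax"], Tmin_m=centering["Tmin"],
    )
    return RateModelParameters(mu_c, alpha, beta, theta, gamma, cc)


def read_parameters(path: str | Path) -> RateModelParameters:
    """Read a parameter file (tab-separated term/factor/locus/value rows)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "term":
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed parameter row: {line!r}")
            rows.append(tuple(parts))
    return _parse_param_rows(rows)


def write_parameters(p: RateModelParameters, path: str | Path) -> None:
    """Write a parameter file that round-trips bit-exactly."""
    with open(path, "w") as fh:
        fh.write("term\tfactor\tlocus\tvalue\n")
        fh.write(f"center\t.\t.\t{p.mu_c!r}\n")
        for f in FACTOR_NAMES:
            fh.write(f"alpha\t{f}\t.\t{p.alpha[f]!r}\n")
        for l in LOCUS_NAMES:
            fh.write(f"beta\t.\t{l}\t{p.beta[l]!r}\n")
        for (a, b), v in p.theta.items():
            fh.write(f"theta\t.\t{a}:{b}\t{v!r}\n")
        for (f, l), v in p.gamma.items():
            fh.write(f"gamma\t{f}\t{l}\t{v!r}\n")
        c = p.centering
        for f, v in zip(FACTOR_NAMES, (c.DL_m, c.Srad_m, c.Tmax_m, c.Tmin_m)):
            fh.write(f"centering\t{f}\t.\t{v!r}\n")


def default_parameters() -> RateModelParameters:
    """The packaged fitted 25-coefficient set with its centering constants."""
    ref = resources.files("phenorate.data").joinpath("rate_parameters_v1.tsv")
    rows = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("term\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"malformed packaged parameter row: {line!r}")
        rows.append(tuple(parts))
    return _parse_param_rows(rows)


def center_environment(
    env: EnvironmentVector, c: CenteringConstants
) -> np.ndarray:
    """Centered 4-vector (DL - DL_m, Srad - Srad_m, Tmax - Tmax_m, Tmin - Tmin_m)."""
    return env.as_array() - c.as_array()


def development_rate(
    env: EnvironmentVector, g: QTLGenotype, p: RateModelParameters
) -> float:
    """Daily rate of progress toward flowering (d-1) for one genotype-day.

    Evaluates the fixed part of the rate function; residual structure lives
    in the fitting module.  Deterministic and order-stable to float
    round-off.
    """
    f = dict(zip(FACTOR_NAMES, center_environment(env, p.centering)))
    tf = {l: g.operator(l) for l in LOCUS_NAMES}
    r = p.mu_c
    r += sum(p.alpha[k] * f[k] for k in FACTOR_NAMES)
    r += sum(p.beta[l] * tf[l] for l in LOCUS_NAMES)
    r += sum(v * tf[a] * tf[b] for (a, b), v in p.theta.items())
    r += sum(v * f[k] * tf[l] for (k, l), v in p.gamma.items())
    return float(r)


def clamp_rate(rate: float, policy: str = "clamp-to-zero") -> float:
    """Apply the negative-rate policy.

    The linear rate function can extrapolate below zero outside the fitted
    environmental range; a negative rate would make cumulative progress
    non-monotone, so the default clamps to zero (with a warning the first
    times it fires).  ``allow-negative`` is the identity.
    """
    if not np.isfinite(rate):
        raise ValueError(f"rate must be finite, got {rate}")
    if policy == "allow-negative":
        return rate
    if policy != "clamp-to-zero":
        raise ValueError(f"unknown clamp policy {policy!r}")
    if rate < 0:
        warnings.warn(
            f"negative development rate {rate:.3e} clamped to 0 "
            "(environment outside the fitted range)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return rate
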
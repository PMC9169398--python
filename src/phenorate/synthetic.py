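"""Synthetic genotypes, weather and trial observations.

Everything the fitting, simulation and evaluation stages consume can be
generated here with the statistical structure the model assumes: +-1 allele
operators drawn per locus (optionally correlated within chromosomes),
seasonal daily weather with AR(1) day-to-day noise, astronomical day
length, and rate-scale residuals drawn multivariate-normal across sites.
Every generator is a pure function of (configuration, seed).

The five default site profiles mimic the qualitative contrasts of the
study's trial network — warm short-day, cool highland short-day, and
long-day temperate sites — without claiming to replicate actual weather.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import ResidualModel, TrialObservation
from .genetics import LOCUS_CATALOG, LOCUS_NAMES, N_LOCI, QTLGenotype
from .phenology import DailyWeatherSeries, simulate_flowering
from .rate_model import EnvironmentVector, RateModelParameters


@dataclass(frozen=True)
class SiteProfile:
    """Configuration of one synthetic site's season of daily weather."""

    label: str
    latitude: float  # degrees, |lat| <= 66
    planting_doy: int
    season_length: int = 160  # days
    tavg_mean: float = 22.0  # C, seasonal mean of daily average temperature
    tavg_amplitude: float = 3.0  # C, seasonal sinusoid half-range
    diurnal_range: float = 10.0  # C, Tmax - Tmin
    srad_mean: float = 18.0  # MJ m-2 d-1
    srad_amplitude: float = 3.0
    temp_noise_sd: float = 1.5  # C, day-to-day AR(1) innovation scale
    srad_noise_sd: float = 2.5
    autocorrelation: float = 0.6

    def __post_init__(self) -> None:
        if abs(self.latitude) > 66:
            raise ValueError(f"|latitude| must be <= 66, got {self.latitude}")
        if self.season_length < 30:
            raise ValueError("season length must be >= 30 days")
        if min(self.temp_noise_sd, self.srad_noise_sd) < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.autocorrelation < 1:
            raise ValueError("autocorrelation must be in [0, 1)")


#: Five sites spanning warm short-day, cool short-day and long-day
#: temperate conditions, with plantings that put the season in the local
#: growing window.
DEFAULT_SITE_PROFILES: tuple[SiteProfile, ...] = (
    SiteProfile("EQW", latitude=3.5, planting_doy=170, tavg_mean=24.0,
                tavg_amplitude=0.5, diurnal_range=11.0),
    SiteProfile("EQC", latitude=2.5, planting_doy=170, tavg_mean=18.5,
                tavg_amplitude=0.5, diurnal_range=12.0, srad_mean=16.5),
    SiteProfile("SUB", latitude=18.3, planting_doy=35, tavg_mean=23.0,
                tavg_amplitude=1.5, diurnal_range=10.0),
    SiteProfile("WTM", latitude=29.4, planting_doy=75, tavg_mean=21.0,
                tavg_amplitude=3.5, diurnal_range=12.0, srad_mean=19.0),
    SiteProfile("NTL", latitude=47.0, planting_doy=150, tavg_mean=19.0,
                tavg_amplitude=3.0, diurnal_range=12.0, srad_mean=20.0),
)


@dataclass(frozen=True)
class SimulationTruth:
    """The ground truth recorded beside every synthetic dataset."""

    parameters: RateModelParameters
    residual: ResidualModel
    seed: int


def generate_family_genotypes(
    n: int,
    n_loci: int = N_LOCI,
    seed: int | np.random.Generator = 0,
    linkage: float | None = None,
) -> list[QTLGenotype]:
    """Draw an inbred family: +-1 operators, fair coin per locus.

    With ``linkage`` in (0, 1], loci on the same chromosome are correlated:
    each locus after the first on a chromosome copies its neighbour's
    operator with probability ``linkage`` and re-draws otherwise
    (linkage=1 makes chromosomes inherit as blocks).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chrom = [LOCUS_CATALOG[i].chromosome for i in range(n_loci)]
    genos = []
    for i in range(n):
        ops = rng.choice((-1, 1), size=n_loci)
        if linkage:
            for j in range(1, n_loci):
                if chrom[j] == chrom[j - 1] and rng.random() < linkage:
                    ops[j] = ops[j - 1]
        full = tuple(int(o) for o in ops) + (-1,) * (N_LOCI - n_loci)
        genos.append(QTLGenotype(f"SRIL{i + 1:04d}", full))
    return genos


def day_length(latitude: float, day_of_year: float) -> float:
    """Astronomical day length (hours) at a latitude and day of year.

    Sun-center horizon-crossing convention: daylight is the fraction of the
    day with the solar zenith below 90 degrees, from the solar declination
    sinusoid.  Rejects polar latitudes where the formula degenerates.
    """
    if abs(latitude) > 66:
        raise ValueError(f"polar latitude {latitude} not supported (|lat| <= 66)")
    phi = np.radians(latitude)
    decl = np.radians(-23.44) * np.cos(2 * np.pi * (day_of_year + 10.0) / 365.0)
    cos_h = -np.tan(phi) * np.tan(decl)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return float(24.0 / np.pi * np.arccos(cos_h))


def generate_weather(
    profile: SiteProfile, seed: int | np.random.Generator = 0
) -> DailyWeatherSeries:
    """One season of daily weather at a site.

    Daily average temperature follows a seasonal sinusoid (peak at the
    local midsummer) plus AR(1) noise; Tmax/Tmin split the diurnal range
    symmetrically; radiation follows its own seasonal sinusoid, floored at
    0.1 MJ m-2 d-1; day length is astronomical.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = profile.season_length
    doys = profile.planting_doy + np.arange(1, n + 1)
    # midsummer DOY ~172 in the north, ~355 in the south; the equator gets a
    # flat annual cycle via its small amplitude
    peak = 172.0 if profile.latitude >= 0 else 355.0
    season = np.cos(2 * np.pi * (doys - peak) / 365.0)
    tavg = profile.tavg_mean + profile.tavg_amplitude * season
    srad = profile.srad_mean + profile.srad_amplitude * season

    rho = profile.autocorrelation
    innov_sd = profile.temp_noise_sd * np.sqrt(1 - rho**2)
    noise = np.empty(n)
    noise[0] = rng.normal(0, profile.temp_noise_sd)
    for t in range(1, n):
        noise[t] = rho * noise[t - 1] + rng.normal(0, innov_sd)
    tavg = tavg + noise
    srad = np.maximum(srad + rng.normal(0, profile.srad_noise_sd, size=n), 0.1)

    half = profile.diurnal_range / 2.0
    jitter = np.abs(rng.normal(0, 0.3, size=n))  # keeps Tmax >= Tmin
    tmax = tavg + half + jitter
    tmin = tavg - half - jitter
    days = tuple(
        EnvironmentVector(
            DL=day_length(profile.latitude, float(d)),
            Srad=float(s),
            Tmax=float(hi),
            Tmin=float(lo),
        )
        for d, s, hi, lo in zip(doys, srad, tmax, tmin)
    )
    return DailyWeatherSeries(profile.label, days)


def default_residual_model(
    sites: Sequence[str], sd: float = 0.0012, correlation: float = 0.3
) -> ResidualModel:
    """Exchangeable-start residual covariance on the rate scale.

    The default sd (~1.2e-3 d-1) is roughly 5% of a typical development
    rate (1/40 d-1), comparable to the residual scatter the rate model
    leaves in multi-site trials.
    """
    S = len(sites)
    R = np.full((S, S), correlation * sd**2)
    np.fill_diagonal(R, sd**2)
    return ResidualModel(tuple(sites), R)


def simulate_observations(
    genotypes: Sequence[QTLGenotype],
    weather_by_site: dict[str, DailyWeatherSeries],
    truth: SimulationTruth,
    horizon: int = 200,
) -> tuple[list[TrialObservation], dict]:
    """Noisy trial observations from the dynamic model plus MVN residuals.

    For each genotype the noiseless dynamic simulation at each site gives a
    mean rate (1/interpolated flowering day); a residual vector across
    sites is drawn from MVN(0, R) and added on the rate scale; the observed
    R1 is the rounded reciprocal (>= 1 day), and the mean-environment
    fields are planting-to-R1 averages of the daily weather.  Genotypes
    whose noisy rate is non-positive at a site are dropped there and
    counted in the returned diagnostics.
    """
    sites = truth.residual.sites
    missing = [s for s in sites if s not in weather_by_site]
    if missing:
        raise ValueError(f"no weather for residual-model sites: {missing}")
    rng = np.random.default_rng(truth.seed)
    L = np.linalg.cholesky(truth.residual.covariance)
    obs: list[TrialObservation] = []
    dropped = 0
    not_flowered = 0
    for g in genotypes:
        resid = L @ rng.standard_normal(len(sites))
        for s_i, site in enumerate(sites):
            weather = weather_by_site[site]
            res = simulate_flowering(weather, g, truth.parameters, horizon=horizon)
            if not res.flowered:
                not_flowered += 1
                continue
            rate_obs = 1.0 / res.day_interpolated + resid[s_i]
            if rate_obs <= 0:
                dropped += 1
                continue
            r1 = max(1, round(1.0 / rate_obs))
            r1 = min(r1, len(weather))
            env = weather.days[:r1]
            env_mean = EnvironmentVector(
                DL=float(np.mean([e.DL for e in env])),
                Srad=float(np.mean([e.Srad for e in env])),
                Tmax=float(np.mean([e.Tmax for e in env])),
                Tmin=float(np.mean([e.Tmin for e in env])),
            )
            obs.append(TrialObservation(g.id, site, float(r1), env_mean, g))
    info = {"n_dropped_nonpositive": dropped, "n_not_flowered": not_flowered}
    return obs, info


def rate_scale_observations(
    genotypes: Sequence[QTLGenotype],
    env_by_site: dict[str, EnvironmentVector | DailyWeatherSeries],
    truth: SimulationTruth,
) -> list[TrialObservation]:
    """Observations on the exact rate scale (no day rounding).

    The static-design counterpart of :func:`simulate_observations`: the
    response is development_rate(mean env) + residual, and R1 = 1/rate
    without rounding.  This is the generator parameter-recovery studies
    use, since rounding days injects heteroscedastic noise that is not part
    of the model being recovered.

    A site may map to a single :class:`EnvironmentVector` (every line sees
    the same mean environment) or to a :class:`DailyWeatherSeries`, in
    which case each line's mean environment is averaged over its own
    noiseless planting-to-flowering window — mirroring how the trial
    records differ per line and giving the environmental coefficients
    within-site leverage.
    """
    from .rate_model import development_rate

    sites = truth.residual.sites
    rng = np.random.default_rng(truth.seed)
    L = np.linalg.cholesky(truth.residual.covariance)
    obs = []
    for g in genotypes:
        resid = L @ rng.standard_normal(len(sites))
        for s_i, site in enumerate(sites):
            env = env_by_site[site]
            if isinstance(env, DailyWeatherSeries):
                res = simulate_flowering(env, g, truth.parameters)
                if not res.flowered:
                    continue
                window = env.days[: res.day_integer]
                env = EnvironmentVector(
                    DL=float(np.mean([e.DL for e in window])),
                    Srad=float(np.mean([e.Srad for e in window])),
                    Tmax=float(np.mean([e.Tmax for e in window])),
                    Tmin=float(np.mean([e.Tmin for e in window])),
                )
            r = development_rate(env, g, truth.parameters) + resid[s_i]
            if r <= 0:
                continue
            obs.append(TrialObservation(g.id, site, 1.0 / r, env, g))
    return obs


def mean_environments(
    weather_by_site: dict[str, DailyWeatherSeries], n_days: int = 45
) -> dict[str, EnvironmentVector]:
    """Planting-to-day-n mean environment per site (typical vegetative window)."""
    out = {}
    for site, w in weather_by_site.items():
        env = w.days[: min(n_days, len(w))]
        out[site] = EnvironmentVector(
            DL=float(np.mean([e.DL for e in env])),
            Srad=float(np.mean([e.Srad for e in env])),
            Tmax=float(np.mean([e.Tmax for e in env])),
            Tmin=float(np.mean([e.Tmin for e in env])),
        )
    return out
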
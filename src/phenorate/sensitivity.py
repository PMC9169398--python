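"""Sensitivity experiments on the flowering module.

Three experiment shapes: constant-environment temperature sweeps (average
temperature varied, diurnal amplitude fixed, symmetric split about the
mean), day-length sweeps (temperatures and radiation fixed), and TTF
distributions over genotype families (e.g. the 4096-member factorial
family).  All results come from direct simulator calls — no caching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genetics import QTLGenotype
from .phenology import (
    DEFAULT_HORIZON,
    DailyWeatherSeries,
    simulate_constant_environment,
    simulate_flowering,
)
from .rate_model import EnvironmentVector, RateModelParameters

#: Defaults of the day-length experiment: Tmax 26 C / Tmin 18 C (Tavg 22 C),
#: radiation at the trial mean, 15 grid points from 11.5 to 18.5 h.
DAYLENGTH_DEFAULT_TMAX = 26.0
DAYLENGTH_DEFAULT_TMIN = 18.0
TRIAL_MEAN_SRAD = 18.2719
DAYLENGTH_DEFAULT_GRID = tuple(np.linspace(11.5, 18.5, 15))

#: Defaults of the temperature experiment: Tavg 11..25 C with an 8 C
#: diurnal amplitude split symmetrically.
TEMPERATURE_DEFAULT_GRID = tuple(np.arange(11.0, 26.0, 1.0))
TEMPERATURE_DEFAULT_AMPLITUDE = 8.0


@dataclass(frozen=True)
class SweepSpec:
    """A declared sweep: which variable, its grid, and what is held fixed."""

    variable: str  # "temperature" (average daily) or "daylength"
    grid: tuple[float, ...]
    genotypes: tuple[QTLGenotype, ...]
    day_length: float = 11.5  # fixed DL for temperature sweeps (h)
    srad: float = TRIAL_MEAN_SRAD
    tmax: float = DAYLENGTH_DEFAULT_TMAX  # fixed temps for day-length sweeps
    tmin: float = DAYLENGTH_DEFAULT_TMIN
    diurnal_amplitude: float = TEMPERATURE_DEFAULT_AMPLITUDE
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if self.variable not in ("temperature", "daylength"):
            raise ValueError(
                f"variable must be 'temperature' or 'daylength', got {self.variable!r}"
            )
        grid = tuple(float(v) for v in self.grid)
        if not grid or list(grid) != sorted(grid):
            raise ValueError("grid must be non-empty and sorted ascending")
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal amplitude must be >= 0")
        if not self.genotypes:
            raise ValueError("at least one genotype is required")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "genotypes", tuple(self.genotypes))


def _sweep(spec: SweepSpec, p: RateModelParameters) -> pd.DataFrame:
    rows = []
    for g in spec.genotypes:
        for v in spec.grid:
            rec: dict = {"genotype": g.id, "value": v}
            try:
                if spec.variable == "temperature":
                    half = spec.diurnal_amplitude / 2.0
                    env = EnvironmentVector(
                        DL=spec.day_length, Srad=spec.srad,
                        Tmax=v + half, Tmin=v - half,
                    )
                else:
                    env = EnvironmentVector(
                        DL=v, Srad=spec.srad, Tmax=spec.tmax, Tmin=spec.tmin
                    )
                res = simulate_constant_environment(env, g, p, horizon=spec.horizon)
                rec.update(
                    flowered=res.flowered,
                    day_integer=res.day_integer,
                    day_interpolated=res.day_interpolated,
                    error=None,
                )
            except ValueError as exc:
                rec.update(
                    flowered=None, day_integer=None, day_interpolated=None,
                    error=str(exc),
                )
            rows.append(rec)
    df = pd.DataFrame(rows)
    df.attrs["spec"] = spec
    return df


def temperature_sweep(spec: SweepSpec, p: RateModelParameters) -> pd.DataFrame:
    """Constant-environment TTF across a grid of average daily temperatures.

    Each grid value Tavg becomes Tmax = Tavg + amplitude/2 and
    Tmin = Tavg - amplitude/2; day length and radiation stay at the spec's
    fixed values.  One row per genotype x grid value.
    """
    if spec.variable != "temperature":
        raise ValueError("spec.variable must be 'temperature'")
    return _sweep(spec, p)


def daylength_sweep(spec: SweepSpec, p: RateModelParameters) -> pd.DataFrame:
    """Constant-environment TTF across a day-length grid (temperatures fixed)."""
    if spec.variable != "daylength":
        raise ValueError("spec.variable must be 'daylength'")
    return _sweep(spec, p)


def default_temperature_spec(
    genotypes: Sequence[QTLGenotype], day_length: float = 11.5
) -> SweepSpec:
    return SweepSpec(
        variable="temperature",
        grid=TEMPERATURE_DEFAULT_GRID,
        genotypes=tuple(genotypes),
        day_length=day_length,
    )


def default_daylength_spec(genotypes: Sequence[QTLGenotype]) -> SweepSpec:
    return SweepSpec(
        variable="daylength",
        grid=DAYLENGTH_DEFAULT_GRID,
        genotypes=tuple(genotypes),
    )


def family_distribution(
    genotypes: Sequence[QTLGenotype],
    environment: EnvironmentVector | DailyWeatherSeries,
    p: RateModelParameters,
    horizon: int = DEFAULT_HORIZON,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> tuple[pd.DataFrame, dict]:
    """TTF of every genotype in a family under one environment.

    Returns the per-genotype table (interpolated and integer days) and a
    summary dict (count, flowered count, min/max, quantiles of the
    interpolated day).  Non-flowering genotypes are counted separately,
    never dropped silently.
    """
    if not genotypes:
        raise ValueError("family must be non-empty")
    rows = []
    for g in genotypes:
        if isinstance(environment, DailyWeatherSeries):
            res = simulate_flowering(environment, g, p, horizon=horizon)
        else:
            res = simulate_constant_environment(environment, g, p, horizon=horizon)
        rows.append(
            {
                "genotype": g.id,
                "flowered": res.flowered,
                "day_integer": res.day_integer,
                "day_interpolated": res.day_interpolated,
            }
        )
    df = pd.DataFrame(rows)
    fl = df[df["flowered"] == True]  # noqa: E712
    days = fl["day_interpolated"].to_numpy(dtype=float)
    summary = {
        "n": len(df),
        "n_flowered": int(len(fl)),
        "n_not_flowered": int(len(df) - len(fl)),
    }
    if len(fl):
        summary.update(
            min=float(days.min()),
            max=float(days.max()),
            quantiles={q: float(np.quantile(days, q)) for q in quantiles},
        )
    return df, summary
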
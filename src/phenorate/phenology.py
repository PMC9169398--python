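"""Daily integration of the development rate to time-to-flowering.

The simulator accumulates the daily rate (one Euler step per calendar day,
day 1 = first full day after planting, progress evaluated at end of day)
until cumulative progress exceeds 1.02, then interpolates the real-valued
day on which progress crossed the biological threshold of 1.0.  Under a
constant environment the interpolated day is exactly 1/RF and the reported
integer day is ceiling(1/RF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetics import QTLGenotype
from .rate_model import (
    EnvironmentVector,
    RateModelParameters,
    clamp_rate,
    development_rate,
)

#: Accumulation stops once progress exceeds this, guaranteeing a day above
#: the biological threshold of 1.0 to interpolate against.
STOP_THRESHOLD = 1.02
FLOWERING_THRESHOLD = 1.0
DEFAULT_HORIZON = 200


@dataclass(frozen=True)
class DailyWeatherSeries:
    """Consecutive daily environments at one site, day 1 = first day after planting."""

    site: str
    days: tuple[EnvironmentVector, ...]
    year: int | None = None

    def __post_init__(self) -> None:
        if len(self.days) < 1:
            raise ValueError(f"weather series for {self.site!r} is empty")
        object.__setattr__(self, "days", tuple(self.days))

    def __len__(self) -> int:
        return len(self.days)

    @staticmethod
    def constant(env: EnvironmentVector, n_days: int, site: str = "constant") -> "DailyWeatherSeries":
        return DailyWeatherSeries(site, (env,) * n_days)


@dataclass(frozen=True)
class ProgressTrajectory:
    """Per-day daily rate and end-of-day cumulative progress."""

    rate: tuple[float, ...]
    cumulative: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": np.arange(1, len(self.rate) + 1),
                "rate": self.rate,
                "cumulative": self.cumulative,
            }
        )


@dataclass(frozen=True)
class FloweringResult:
    """Outcome of one genotype-by-weather simulation.

    ``day_integer`` is the first calendar day whose end-of-day progress
    reaches 1.0; ``day_interpolated`` the real-valued crossing time of the
    threshold.  Both are None when the threshold is not reached within the
    horizon; ``series_exhausted`` flags runs cut short by the weather series
    rather than the horizon.
    """

    genotype_id: str
    site: str
    flowered: bool
    day_integer: int | None
    day_interpolated: float | None
    trajectory: ProgressTrajectory = field(repr=False)
    series_exhausted: bool = False


def simulate_flowering(
    weather: DailyWeatherSeries,
    g: QTLGenotype,
    p: RateModelParameters,
    horizon: int = DEFAULT_HORIZON,
    clamp_policy: str = "clamp-to-zero",
) -> FloweringResult:
    """Integrate daily rates over a weather series until flowering.

    Euler accumulation P_t = P_{t-1} + RF_t; stops once P_t > 1.02 or at
    min(horizon, series length).  The flowering day is interpolated between
    the days flanking P = 1.0:  t-1 + (1 - P_{t-1}) / RF_t.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    n = min(horizon, len(weather))
    rates: list[float] = []
    cum: list[float] = []
    progress = 0.0
    for t in range(n):
        r = development_rate(weather.days[t], g, p)
        if not np.isfinite(r):
            raise ValueError(
                f"non-finite rate on day {t + 1} for genotype {g.id!r}"
            )
        r = clamp_rate(r, clamp_policy)
        progress += r
        rates.append(r)
        cum.append(progress)
        if progress > STOP_THRESHOLD:
            break
    traj = ProgressTrajectory(tuple(rates), tuple(cum))
    # locate the first end-of-day >= 1.0 (float-safe: cum is non-decreasing
    # under the default clamp policy)
    day_int = None
    for t, ptot in enumerate(cum):
        if ptot >= FLOWERING_THRESHOLD:
            day_int = t + 1
            break
    if day_int is None:
        return FloweringResult(
            g.id, weather.site, False, None, None, traj,
            series_exhausted=len(weather) < horizon,
        )
    prev = cum[day_int - 2] if day_int >= 2 else 0.0
    day_interp = (day_int - 1) + (FLOWERING_THRESHOLD - prev) / rates[day_int - 1]
    return FloweringResult(g.id, weather.site, True, day_int, day_interp, traj)


def simulate_constant_environment(
    env: EnvironmentVector,
    g: QTLGenotype,
    p: RateModelParameters,
    horizon: int = DEFAULT_HORIZON,
    clamp_policy: str = "clamp-to-zero",
) -> FloweringResult:
    """Flowering under a time-invariant environment.

    Equivalent to :func:`simulate_flowering` on a constant series; when the
    rate is positive the interpolated day is 1/RF exactly.
    """
    series = DailyWeatherSeries.constant(env, horizon, site="constant")
    return simulate_flowering(series, g, p, horizon=horizon, clamp_policy=clamp_policy)


def closed_form_constant_day(
    env: EnvironmentVector, g: QTLGenotype, p: RateModelParameters
) -> float | None:
    """1/RF when the (clamped) constant-environment rate is positive, else None."""
    r = clamp_rate(development_rate(env, g, p), "clamp-to-zero")
    return 1.0 / r if r > 0 else None


def predict_family(
    weather_by_site: dict[str, DailyWeatherSeries] | Iterable[DailyWeatherSeries],
    genotypes: Sequence[QTLGenotype],
    p: RateModelParameters,
    horizon: int = DEFAULT_HORIZON,
    clamp_policy: str = "clamp-to-zero",
) -> pd.DataFrame:
    """Simulate every genotype at every site; one row per genotype x site.

    Missing or failing sites produce per-row error records (``error``
    column), never a global failure.  Row order is deterministic:
    genotypes in given order within sites in given order.
    """
    if not isinstance(weather_by_site, dict):
        weather_by_site = {w.site: w for w in weather_by_site}
    rows = []
    for site, weather in weather_by_site.items():
        for g in genotypes:
            rec: dict = {"genotype": g.id, "site": site}
            try:
                res = simulate_flowering(
                    weather, g, p, horizon=horizon, clamp_policy=clamp_policy
                )
                rec.update(
                    flowered=res.flowered,
                    day_integer=res.day_integer,
                    day_interpolated=res.day_interpolated,
                    error=None,
                )
            except (ValueError, KeyError) as exc:
                rec.update(
                    flowered=None, day_integer=None, day_interpolated=None,
                    error=str(exc),
                )
            rows.append(rec)
    return pd.DataFrame(rows)
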
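"""Readers and writers for the study's delimited-text dialects.

Two dialects: the ten-field daily weather table (SrNO, Site, Year, DOY,
DAP, Srad, DayLhr, Tmax, Tavg, Tmin) and the 19-field trial observation
table (RIL, Site, R1, TF1..TF12, Srad_m, DL_m, Tmin_m, Tmax_m).  Readers
are lenient on formatting (comma or tab delimiters, any column order,
case-insensitive headings) and strict on semantics (every invariant
violation is an error naming the row and field).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import TrialObservation
from .genetics import LOCUS_NAMES, QTLGenotype
from .phenology import DailyWeatherSeries
from .rate_model import EnvironmentVector

WEATHER_FIELDS = (
    "SrNO", "Site", "Year", "DOY", "DAP", "Srad", "DayLhr", "Tmax", "Tavg", "Tmin",
)
OBSERVATION_FIELDS = ("RIL", "Site", "R1") + LOCUS_NAMES + (
    "Srad_m", "DL_m", "Tmin_m", "Tmax_m",
)


def _read_table(path: str | Path, fields: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower().strip(): c for c in df.columns}
    missing = [f for f in fields if f.lower() not in lower]
    if missing:
        raise ValueError(f"{path}: missing required field(s): {', '.join(missing)}")
    return df.rename(columns={lower[f.lower()]: f for f in fields})[list(fields)]


def read_weather(path: str | Path) -> dict[tuple[str, int], DailyWeatherSeries]:
    """Read a weather file into series keyed by (Site, Year).

    Within a site-year, rows are ordered by DAP and must be consecutive
    with no duplicate DOY; Tmin <= Tavg <= Tmax is enforced per row.
    """
    df = _read_table(path, WEATHER_FIELDS)
    out: dict[tuple[str, int], DailyWeatherSeries] = {}
    for (site, year), grp in df.groupby(["Site", "Year"], sort=True):
        grp = grp.sort_values("DAP")
        if grp["DOY"].duplicated().any():
            doy = int(grp.loc[grp["DOY"].duplicated(), "DOY"].iloc[0])
            raise ValueError(f"{path}: duplicate DOY {doy} for {site}/{year}")
        dap = grp["DAP"].to_numpy()
        if np.any(dap < 0):
            raise ValueError(f"{path}: negative DAP for {site}/{year}")
        if np.any(np.diff(dap) != 1):
            raise ValueError(f"{path}: DAP not consecutive for {site}/{year}")
        days = []
        for _, row in grp.iterrows():
            if not row["Tmin"] <= row["Tavg"] <= row["Tmax"]:
                raise ValueError(
                    f"{path}: Tmin <= Tavg <= Tmax violated at row "
                    f"{int(row['SrNO'])} ({site}/{year})"
                )
            days.append(
                EnvironmentVector(
                    DL=float(row["DayLhr"]), Srad=float(row["Srad"]),
                    Tmax=float(row["Tmax"]), Tmin=float(row["Tmin"]),
                )
            )
        out[(str(site), int(year))] = DailyWeatherSeries(
            str(site), tuple(days), year=int(year)
        )
    return out


def write_weather(
    series: dict[tuple[str, int], DailyWeatherSeries] | Sequence[DailyWeatherSeries],
    path: str | Path,
) -> None:
    """Write weather series in the ten-field dialect (Tavg = (Tmax+Tmin)/2)."""
    if not isinstance(series, dict):
        series = {(w.site, w.year or 1): w for w in series}
    rows = []
    sr = 1
    for (site, year), w in series.items():
        for dap, env in enumerate(w.days, start=1):
            rows.append(
                {
                    "SrNO": sr, "Site": site, "Year": year, "DOY": dap, "DAP": dap,
                    "Srad": env.Srad, "DayLhr": env.DL, "Tmax": env.Tmax,
                    "Tavg": env.Tavg, "Tmin": env.Tmin,
                }
            )
            sr += 1
    pd.DataFrame(rows, columns=list(WEATHER_FIELDS)).to_csv(path, index=False)


def read_observations(path: str | Path) -> list[TrialObservation]:
    """Read a 19-field trial observation file.

    Allele operators must be literal +1/-1; anything else is rejected with
    the row and locus named (residual heterozygosity is not silently
    accepted).
    """
    df = _read_table(path, OBSERVATION_FIELDS)
    obs = []
    for i, row in df.iterrows():
        ops = []
        for locus in LOCUS_NAMES:
            v = row[locus]
            if v not in (1, -1, 1.0, -1.0):
                raise ValueError(
                    f"{path}: row {i + 1}: operator {v!r} at {locus} is not +1/-1"
                )
            ops.append(int(v))
        g = QTLGenotype(str(row["RIL"]), tuple(ops))
        env = EnvironmentVector(
            DL=float(row["DL_m"]), Srad=float(row["Srad_m"]),
            Tmax=float(row["Tmax_m"]), Tmin=float(row["Tmin_m"]),
        )
        obs.append(
            TrialObservation(str(row["RIL"]), str(row["Site"]), float(row["R1"]), env, g)
        )
    return obs


def write_observations(obs: Sequence[TrialObservation], path: str | Path) -> None:
    rows = []
    for o in obs:
        rec = {"RIL": o.ril, "Site": o.site, "R1": o.r1}
        rec.update({l: o.genotype.operator(l) for l in LOCUS_NAMES})
        rec.update(
            Srad_m=o.env_mean.Srad, DL_m=o.env_mean.DL,
            Tmin_m=o.env_mean.Tmin, Tmax_m=o.env_mean.Tmax,
        )
        rows.append(rec)
    pd.DataFrame(rows, columns=list(OBSERVATION_FIELDS)).to_csv(path, index=False)


def write_genotypes(genotypes: Sequence[QTLGenotype], path: str | Path) -> None:
    """Genotype matrix as CSV columns id, TF1..TF12 with literal +1/-1."""
    rows = [
        {"id": g.id, **{l: g.operator(l) for l in LOCUS_NAMES}} for g in genotypes
    ]
    pd.DataFrame(rows, columns=["id", *LOCUS_NAMES]).to_csv(path, index=False)


def read_genotypes(path: str | Path) -> list[QTLGenotype]:
    df = _read_table(path, ("id",) + LOCUS_NAMES)
    out = []
    for i, row in df.iterrows():
        ops = []
        for locus in LOCUS_NAMES:
            v = row[locus]
            if v not in (1, -1, 1.0, -1.0):
                raise ValueError(
                    f"{path}: row {i + 1}: operator {v!r} at {locus} is not +1/-1"
                )
            ops.append(int(v))
        out.append(QTLGenotype(str(row["id"]), tuple(ops)))
    return out


def write_covariance(sites: Sequence[str], R: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(R, index=list(sites), columns=list(sites)).to_csv(path)


def write_fit_report(model, path: str | Path) -> None:
    """Fit diagnostics as key/value text."""
    lines = [
        f"method\t{model.method}",
        f"log_likelihood\t{model.log_likelihood!r}",
        f"converged\t{model.converged}",
        f"n_iterations\t{model.n_iterations}",
        f"gradient_norm\t{model.gradient_norm!r}",
        f"n_observations\t{model.n_observations}",
        f"n_fixed_parameters\t{model.n_fixed_parameters}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
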
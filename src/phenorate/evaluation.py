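"""Model-evaluation statistics: model efficiency, R-squared, adjusted
R-squared, RMSE, and side-by-side comparison tables.

Model efficiency ME = 1 - SSE/SST measures predictive skill against the
mean-of-observations predictor (1 = perfect, 0 = no better than the mean,
negative = worse).  R-squared here is the squared Pearson correlation of
observed and predicted (the 1:1-plot usage), kept distinct from ME; the
adjusted variant penalizes the parameter count k relative to sample size n.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _pair(observed: Sequence[float], predicted: Sequence[float]):
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(
            f"observed and predicted must be equal-length 1-d series, "
            f"got {y.shape} and {yhat.shape}"
        )
    return y, yhat


def model_efficiency(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """ME = 1 - sum((y - yhat)^2) / sum((y - ybar)^2)."""
    y, yhat = _pair(observed, predicted)
    if y.size < 2:
        raise ValueError("model efficiency needs at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError(
            "model efficiency undefined: observed values are all identical"
        )
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y, yhat = _pair(observed, predicted)
    if y.size < 2:
        raise ValueError("R-squared needs at least 2 observations")
    sy, syh = y.std(), yhat.std()
    if sy == 0 or syh == 0:
        raise ValueError("R-squared undefined: a series is constant")
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r * r


def r2_adjusted(r2: float, n: int, k: int) -> float:
    """Adjusted R-squared: 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    if not 0 <= r2 <= 1:
        raise ValueError(f"R-squared must be in [0, 1], got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (got n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared prediction error, in the units of the series."""
    y, yhat = _pair(observed, predicted)
    if y.size < 1:
        raise ValueError("RMSE needs at least 1 observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def evaluation_report(
    observed: Sequence[float], predicted: Sequence[float], k: int
) -> dict[str, float]:
    """All metrics for one observed/predicted set with k model parameters."""
    y, yhat = _pair(observed, predicted)
    n = y.size
    r2 = r_squared(y, yhat)
    r2a = r2_adjusted(r2, n, k)
    return {
        "n": n,
        "k": k,
        "ME": model_efficiency(y, yhat),
        "R2": r2,
        "R2_adjusted": r2a,
        "R2_adjusted_over_R2": r2a / r2,
        "RMSE": rmse(y, yhat),
    }


def comparison_report(
    groups: dict[str, tuple[Sequence[float], Sequence[float], int]]
) -> pd.DataFrame:
    """Side-by-side comparison of named (observed, predicted, k) groups.

    One row per group with columns Count, ME, R2, R2_adjusted and the
    R2_adjusted/R2 ratio; full precision is retained, display rounding is
    the caller's choice.
    """
    rows = []
    for name, (obs, pred, k) in groups.items():
        rep = evaluation_report(obs, pred, k)
        rows.append(
            {
                "Model": name,
                "Count": rep["n"],
                "ME": rep["ME"],
                "R2": rep["R2"],
                "R2_adjusted": rep["R2_adjusted"],
                "R2_adjusted/R2": rep["R2_adjusted_over_R2"],
            }
        )
    return pd.DataFrame(rows).set_index("Model")
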
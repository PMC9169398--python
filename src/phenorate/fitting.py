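"""Estimation of the rate model from multi-environment trial observations.

The response is the rate of development 1/TTF (d-1).  Fixed effects are the
25 terms of the rate function; residuals of the same line across sites are
jointly multivariate normal with an unstructured S x S covariance R.  The
fit profiles the fixed effects out by generalized least squares and
maximizes the (restricted) log-likelihood over a Cholesky parameterization
of R with a quasi-Newton optimizer.  Lines observed at a subset of sites
contribute through the matching sub-blocks of R — no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .genetics import LOCUS_NAMES, QTLGenotype
from .rate_model import (
    FACTOR_NAMES,
    CenteringConstants,
    EnvironmentVector,
    RateModelParameters,
    center_environment,
    default_parameters,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialObservation:
    """One line x site record: observed TTF and the planting-to-flowering
    mean environment.

    ``r1`` is the observed number of days from planting to first anthesis;
    the model response is the rate 1/r1.  ``env_mean`` carries the mean
    day length, solar radiation, Tmax and Tmin over that interval.
    """

    ril: str
    site: str
    r1: float
    env_mean: EnvironmentVector
    genotype: QTLGenotype

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r1) and self.r1 > 0):
            raise ValueError(
                f"RIL {self.ril!r} at {self.site!r}: R1 must be positive, got {self.r1}"
            )

    @property
    def rate(self) -> float:
        return 1.0 / self.r1


@dataclass(frozen=True)
class ResidualModel:
    """Unstructured residual covariance of one line's rates across sites."""

    sites: tuple[str, ...]
    covariance: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.covariance, dtype=float)
        S = len(self.sites)
        if R.shape != (S, S):
            raise ValueError(f"covariance must be {S}x{S}, got {R.shape}")
        if not np.allclose(R, R.T, rtol=0, atol=1e-12 * max(1.0, np.abs(R).max())):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(R) <= 0):
            raise ValueError("covariance must be positive-definite")
        object.__setattr__(self, "covariance", R)
        object.__setattr__(self, "sites", tuple(self.sites))

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.covariance))
        return self.covariance / np.outer(d, d)


@dataclass(frozen=True)
class FittedModel:
    """A fitted rate model: coefficients, residual covariance, diagnostics."""

    parameters: RateModelParameters
    residual: ResidualModel
    log_likelihood: float
    method: str  # "REML" or "ML"
    converged: bool
    n_iterations: int
    gradient_norm: float
    n_observations: int
    n_fixed_parameters: int
    coefficient_labels: tuple[str, ...] = field(repr=False)

    def predict_rate(self, obs: TrialObservation) -> float:
        from .rate_model import development_rate

        return development_rate(obs.env_mean, obs.genotype, self.parameters)


def build_design_matrix(
    observations: Sequence[TrialObservation],
    structure: RateModelParameters | None = None,
    centering: CenteringConstants | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix and response vector for the rate model.

    Columns in fixed order: intercept; 4 centered mean-environment factors;
    12 allele operators; the declared QTL x QTL products; the declared
    centered-factor x operator products.  Response is 1/R1.  ``structure``
    supplies the interaction term maps (default: the packaged 25-term
    model); its coefficient values are ignored here.
    """
    if structure is None:
        structure = default_parameters()
    if centering is None:
        centering = structure.centering
    labels = structure.term_labels()
    n, k = len(observations), structure.n_coefficients
    X = np.empty((n, k))
    y = np.empty(n)
    fidx = {f: i for i, f in enumerate(FACTOR_NAMES)}
    lidx = {l: i for i, l in enumerate(LOCUS_NAMES)}
    for r, obs in enumerate(observations):
        f = center_environment(obs.env_mean, centering)
        tf = obs.genotype.as_array()
        row = [1.0]
        row += list(f)
        row += list(tf)
        row += [tf[lidx[a]] * tf[lidx[b]] for a, b in structure.theta]
        row += [f[fidx[fa]] * tf[lidx[l]] for fa, l in structure.gamma]
        X[r] = row
        y[r] = obs.rate
    if n >= k:
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            # name the columns involved in the deficiency via QR pivoting
            _, Rq, piv = _qr_pivot(X)
            bad = [labels[j] for j in piv[rank:]]
            raise ValueError(
                f"design matrix is rank-deficient (rank {rank} < {k}); "
                f"offending columns: {', '.join(bad)}"
            )
    return X, y, labels


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


# ----------------------------------------------------------------------------
# REML / ML machinery

# large finite penalty for infeasible covariance proposals; keeps the
# finite-difference gradient well defined
_BIG = 1e12


def _group_by_pattern(site_idx: np.ndarray, ril_codes: np.ndarray):
    """Group observation rows by (line, observed-site pattern).

    Returns, per unique site pattern, the row indices arranged as a
    (n_lines, n_sites_in_pattern) array so the likelihood vectorizes over
    lines sharing a pattern.
    """
    by_ril: dict[int, list[int]] = {}
    for row, rc in enumerate(ril_codes):
        by_ril.setdefault(rc, []).append(row)
    patterns: dict[tuple[int, ...], list[list[int]]] = {}
    # iterate lines in code order and emit patterns sorted, so the summation
    # order — and hence the likelihood to the last bit — is independent of
    # how the observations were ordered on input
    for rc in sorted(by_ril):
        rows = by_ril[rc]
        order = np.argsort([site_idx[r] for r in rows])
        rows = [rows[o] for o in order]
        pat = tuple(int(site_idx[r]) for r in rows)
        if len(set(pat)) != len(pat):
            raise ValueError(
                f"a line has duplicate observations at one site (pattern {pat})"
            )
        patterns.setdefault(pat, []).append(rows)
    return {
        pat: np.asarray(patterns[pat], dtype=int) for pat in sorted(patterns)
    }


def _chol_from_theta(theta: np.ndarray, S: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from the packed parameter vector
    (log-diagonal, free off-diagonal)."""
    L = np.zeros((S, S))
    d = np.exp(theta[:S])
    L[np.diag_indices(S)] = d
    if S > 1:
        L[np.tril_indices(S, -1)] = theta[S:]
    return L


def _theta_from_cov(R: np.ndarray) -> np.ndarray:
    S = R.shape[0]
    L = np.linalg.cholesky(R)
    theta = np.concatenate([np.log(np.diag(L)), L[np.tril_indices(S, -1)]])
    return theta


def _neg2ll(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    patterns: dict,
    S: int,
    reml: bool,
):
    """-2 log-likelihood (up to an additive constant) and the GLS solution."""
    L = _chol_from_theta(theta, S)
    R = L @ L.T
    k = X.shape[1]
    XtViX = np.zeros((k, k))
    XtViy = np.zeros(k)
    logdet = 0.0
    cache = []
    for pat, rows in patterns.items():
        idx = list(pat)
        Rs = R[np.ix_(idx, idx)]
        try:
            cs = np.linalg.cholesky(Rs)
        except np.linalg.LinAlgError:
            return _BIG, None, None
        A = np.linalg.inv(Rs)  # small (<= S x S); explicit inverse is fine
        sign, ld = np.linalg.slogdet(Rs)
        if sign <= 0:
            return _BIG, None, None
        G = rows.shape[0]
        Xp = X[rows]  # (G, m, k)
        yp = y[rows]  # (G, m)
        XtViX += np.einsum("gmk,mn,gnl->kl", Xp, A, Xp, optimize=True)
        XtViy += np.einsum("gmk,mn,gn->k", Xp, A, yp, optimize=True)
        logdet += G * ld
        cache.append((A, Xp, yp))
        del cs
    try:
        b = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return _BIG, None, None
    quad = 0.0
    for A, Xp, yp in cache:
        rres = yp - Xp @ b
        quad += np.einsum("gm,mn,gn->", rres, A, rres, optimize=True)
    n2 = logdet + quad
    if reml:
        sign, ldx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return _BIG, None, None
        n2 += ldx
    return n2, b, XtViX


def fit_rate_model(
    observations: Sequence[TrialObservation],
    structure: RateModelParameters | None = None,
    centering: CenteringConstants | None = None,
    method: str = "REML",
    max_iter: int = 500,
) -> FittedModel:
    """Fit the rate model by REML (default) or ML.

    Fixed effects are profiled out by GLS given R; R is optimized over its
    Cholesky factor with L-BFGS-B, initialized from the OLS residual
    covariance.  Convergence: relative change in the objective below 1e-10
    (via the optimizer's ftol) and projected-gradient norm below 1e-6.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be 'REML' or 'ML', got {method!r}")
    if structure is None:
        structure = default_parameters()
    if centering is None:
        centering = structure.centering
    X, y, labels = build_design_matrix(observations, structure, centering)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than fixed parameters ({k})")
    sites = tuple(sorted({o.site for o in observations}))
    S = len(sites)
    smap = {s: i for i, s in enumerate(sites)}
    site_idx = np.array([smap[o.site] for o in observations])
    rils = sorted({o.ril for o in observations})
    rmap = {r: i for i, r in enumerate(rils)}
    ril_codes = np.array([rmap[o.ril] for o in observations])
    patterns = _group_by_pattern(site_idx, ril_codes)

    # deterministic start: OLS residual covariance (pairwise-complete),
    # floored to be comfortably positive-definite
    b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b_ols
    R0 = _empirical_residual_cov(resid, site_idx, ril_codes, S)
    theta0 = _theta_from_cov(R0)

    reml = method == "REML"
    obj = lambda th: _neg2ll(th, X, y, patterns, S, reml)[0]
    res = optimize.minimize(
        obj,
        theta0,
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "ftol": 1e-11,  # relative objective change, cf. the 1e-10 criterion
            "gtol": 1e-7,
        },
    )
    n2, b, XtViX = _neg2ll(res.x, X, y, patterns, S, reml)
    if b is None:
        raise RuntimeError(
            f"likelihood evaluation failed at the optimizer's last iterate: {res.message}"
        )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success)
    if not converged:
        log.warning("REML optimizer did not report convergence: %s", res.message)
    L = _chol_from_theta(res.x, S)
    Rhat = L @ L.T
    const = n * np.log(2 * np.pi)
    if reml:
        const = (n - k) * np.log(2 * np.pi)
    ll = -0.5 * (n2 + const)
    params = structure.with_coefficient_vector(b).with_centering(centering)
    return FittedModel(
        parameters=params,
        residual=ResidualModel(sites, Rhat),
        log_likelihood=float(ll),
        method=method,
        converged=converged,
        n_iterations=int(res.nit),
        gradient_norm=grad_norm,
        n_observations=n,
        n_fixed_parameters=k,
        coefficient_labels=tuple(labels),
    )


def _empirical_residual_cov(
    resid: np.ndarray, site_idx: np.ndarray, ril_codes: np.ndarray, S: int
) -> np.ndarray:
    """Pairwise-complete covariance of per-line residual vectors across sites."""
    n_ril = ril_codes.max() + 1
    M = np.full((n_ril, S), np.nan)
    M[ril_codes, site_idx] = resid
    R = np.empty((S, S))
    for i in range(S):
        for j in range(i, S):
            both = ~np.isnan(M[:, i]) & ~np.isnan(M[:, j])
            if both.sum() >= 2:
                R[i, j] = R[j, i] = np.mean(M[both, i] * M[both, j])
            else:
                R[i, j] = R[j, i] = 0.0
    # floor eigenvalues so the starting covariance is safely PD even for
    # (near-)noiseless data
    w, V = np.linalg.eigh(R)
    scale = max(np.abs(w).max(), np.mean(resid**2), 1e-12)
    w = np.maximum(w, 1e-8 * scale)
    return (V * w) @ V.T


def predict_static(
    model: FittedModel | RateModelParameters, obs: TrialObservation
) -> float | None:
    """Static-mode TTF prediction: 1 / rate at the mean environment.

    Evaluates the fixed part of the rate function at the observation's
    planting-to-flowering mean environment.  Returns None when the
    predicted rate is non-positive (no finite flowering time).
    """
    from .rate_model import development_rate

    p = model.parameters if isinstance(model, FittedModel) else model
    r = development_rate(obs.env_mean, obs.genotype, p)
    if r <= 0:
        log.warning(
            "non-positive predicted rate %.3e for %s at %s; no TTF",
            r, obs.ril, obs.site,
        )
        return None
    return 1.0 / r
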
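"""Negative-binomial abundance models with fixed-df smooth terms.

The per-species model is

    y_i ~ NB(mu_i, theta),   log mu_i = b0 + b_ALAN * x_i + sum_j f_j(z_ij)

with ``x`` the buffer-median night-lights radiance at the checklist, the
``f_j`` centred regression-spline smooths of the effort/detectability
covariates, and NB2 variance ``mu + mu^2 / theta``.

Fitting alternates (i) iteratively reweighted least squares for the
coefficients at fixed dispersion with (ii) one-dimensional maximisation of
the profile log-likelihood in ``log theta`` at fixed means.  Standard
errors come from the expected information ``(X' W X)^{-1}`` at the optimum
with ``theta`` held at its estimate, which is standard NB-GLM practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .basis import SmoothSpec, build_smooth_matrix, default_smooths
from .exceptions import DegenerateResponseError, InsufficientDataError

_ETA_CLIP = 30.0


@dataclass
class NBGAMFit:
    """A fitted negative-binomial regression with smooth terms."""

    coef: np.ndarray
    se: np.ndarray
    theta: float
    deviance: float
    converged: bool
    n_used: int
    colnames: list[str] = field(default_factory=list)
    n_dropped: int = 0
    n_outer: int = 0
    alan_index: int | None = None

    @property
    def beta_alan(self) -> float:
        if self.alan_index is None:
            raise AttributeError("fit has no night-lights term")
        return float(self.coef[self.alan_index])

    @property
    def se_alan(self) -> float:
        if self.alan_index is None:
            raise AttributeError("fit has no night-lights term")
        return float(self.se[self.alan_index])

    def to_json(self) -> str:
        """Serialise the fit (coefficients, SEs, dispersion, diagnostics)."""
        return json.dumps(
            {
                "coef": self.coef.tolist(),
                "se": self.se.tolist(),
                "theta": self.theta,
                "deviance": self.deviance,
                "converged": self.converged,
                "n_used": self.n_used,
                "colnames": self.colnames,
                "n_dropped": self.n_dropped,
                "n_outer": self.n_outer,
                "alan_index": self.alan_index,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "NBGAMFit":
        d = json.loads(payload)
        d["coef"] = np.asarray(d["coef"])
        d["se"] = np.asarray(d["se"])
        return cls(**d)

    def summary_frame(self) -> pd.DataFrame:
        z = np.divide(self.coef, self.se, out=np.zeros_like(self.coef), where=self.se > 0)
        return pd.DataFrame(
            {"term": self.colnames, "estimate": self.coef, "se": self.se, "z": z}
        )


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood (full, including constants)."""
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 deviance; the ``y log(y/mu)`` term is zero at y = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def fit_poisson_glm(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Plain Poisson log-link IRLS; used for initialisation and as the
    large-dispersion limit of the NB fit."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8)) if np.allclose(X[:, 0], 1.0) else 0.0
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * np.sum(
                np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0) - (y - mu)
            )
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    return beta


def _profile_theta(y: np.ndarray, mu: np.ndarray, log_theta0: float) -> float:
    """Maximise the NB log-likelihood over log(theta) at fixed means.

    The ``gammaln(y + theta)`` sum is aggregated over the distinct count
    values (counts repeat heavily), and ``y``-only terms are dropped, so
    each evaluation costs one log over the data vector.
    """
    n = y.size
    yv, cnt = np.unique(y, return_counts=True)
    s_ylogmu = float(np.sum(y * np.log(mu)))

    def nll(lt: float) -> float:
        th = np.exp(lt)
        log_thmu = np.log(th + mu)
        ll = (
            float(cnt @ gammaln(yv + th))
            - n * gammaln(th)
            + n * th * lt
            - th * np.sum(log_thmu)
            + s_ylogmu
            - float(y @ log_thmu)
        )
        return -ll

    res = minimize_scalar(nll, bounds=(-10.0, 25.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def fit_nb_glm(
    X: np.ndarray,
    y: np.ndarray,
    init: np.ndarray | None = None,
    theta: float | None = None,
    max_outer: int = 100,
    tol_dev: float = 1e-8,
    tol_logtheta: float = 1e-6,
    colnames: list[str] | None = None,
    check_rank: bool = True,
) -> NBGAMFit:
    """Fit an NB2 GLM with log link by IRLS + profile-likelihood dispersion.

    Parameters
    ----------
    X
        Full-rank design matrix (include the intercept column yourself).
    y
        Non-negative integer counts.
    theta
        Fix the dispersion instead of estimating it (used for limit checks).

    Raises
    ------
    DegenerateResponseError
        If all counts are zero (the log-mean is unbounded below).

    Notes
    -----
    Convergence requires a relative deviance change below ``tol_dev`` and a
    ``log theta`` step below ``tol_logtheta`` within ``max_outer`` outer
    iterations; a fit that fails this is returned flagged, not raised.
    Each IRLS step is step-halved if it would increase the deviance, so the
    deviance is non-increasing across iterations.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} rows for p={p} coefficients")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integers")
    if not np.any(y > 0):
        raise DegenerateResponseError("all counts are zero")
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    beta = init if init is not None else fit_poisson_glm(X, y)
    if theta is not None:
        if theta <= 0:
            raise ValueError("theta must be > 0")
        log_theta = np.log(theta)
        estimate_theta = False
    else:
        mu0 = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
        var_excess = max(np.mean((y - mu0) ** 2 - mu0), 1e-8)
        log_theta = float(np.log(np.clip(np.mean(mu0**2) / var_excess, 1e-3, 1e4)))
        estimate_theta = True

    def irls(beta: np.ndarray, th: float, max_iter: int = 50) -> tuple[np.ndarray, float]:
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev = nb_deviance(y, mu, th)
        for _ in range(max_iter):
            w = mu / (1.0 + mu / th)
            z = eta + (y - mu) / mu
            WX = X * w[:, None]
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            step = beta_new - beta
            # step-halving keeps the deviance monotone
            for _h in range(30):
                cand = beta + step
                eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
                mu_c = np.exp(eta_c)
                dev_c = nb_deviance(y, mu_c, th)
                if dev_c <= dev + 1e-12:
                    break
                step *= 0.5
            else:
                return beta, dev
            if abs(dev - dev_c) < tol_dev * (abs(dev_c) + 0.1):
                return cand, dev_c
            beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        return beta, dev

    converged = False
    n_outer = 0
    dev = np.inf
    for n_outer in range(1, max_outer + 1):
        beta, dev_new = irls(beta, np.exp(log_theta))
        if estimate_theta:
            mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
            log_theta_new = _profile_theta(y, mu, log_theta)
        else:
            log_theta_new = log_theta
        dev_ok = np.isfinite(dev) and abs(dev - dev_new) < tol_dev * (abs(dev_new) + 0.1)
        theta_ok = abs(log_theta_new - log_theta) < tol_logtheta
        log_theta = log_theta_new
        dev = dev_new
        if dev_ok and theta_ok:
            converged = True
            break

    th = float(np.exp(log_theta))
    mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
    w = mu / (1.0 + mu / th)
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    se = np.sqrt(np.diag(cov))
    return NBGAMFit(
        coef=beta,
        se=se,
        theta=th,
        deviance=nb_deviance(y, mu, th),
        converged=converged,
        n_used=n,
        colnames=colnames or [f"b{j}" for j in range(p)],
        n_outer=n_outer,
    )


def build_species_design(
    dataset: pd.DataFrame,
    smooths: tuple[SmoothSpec, ...] | None = None,
    alan_col: str = "x_alan",
    count_col: str = "count",
    log_alan: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Assemble the abundance-model design for one species' dataset.

    Returns ``(X, y, colnames, kept)`` where ``kept`` is the covariate-
    complete subset of ``dataset`` aligned row-wise with ``X``.  Smooth
    bases are evaluated on the full covariate-complete data, so a row
    subset of ``X`` keeps the same smooth functions (the resampling loop
    relies on this: the smooths are properties of the species' data, the
    runs differ only in which rows enter the likelihood).
    """
    if smooths is None:
        smooths = default_smooths()
    df = dataset.copy()
    if "day_of_year" not in df.columns and "date" in df.columns:
        df["day_of_year"] = pd.to_datetime(df["date"]).dt.dayofyear.astype(float)
    needed = [alan_col, count_col] + sorted(
        {c for sp in smooths for c in sp.covariates}
    )
    df = df.dropna(subset=[c for c in needed if c in df.columns]).reset_index(drop=True)
    x = df[alan_col].to_numpy(float)
    if log_alan:
        x = np.log1p(x)
    S, snames = build_smooth_matrix(df, smooths)
    X = np.column_stack([np.ones(len(df)), x, S])
    colnames = ["(intercept)", "alan"] + snames
    y = df[count_col].to_numpy(float)
    return X, y, colnames, df


def fit_species_gam(
    dataset: pd.DataFrame,
    smooths: tuple[SmoothSpec, ...] | None = None,
    alan_col: str = "x_alan",
    count_col: str = "count",
    min_rows: int = 100,
    log_alan: bool = False,
    theta: float | None = None,
) -> NBGAMFit:
    """Fit the per-species abundance model on a (subsampled) dataset.

    The design is intercept + linear radiance term + the centred smooth
    bases of ``smooths`` (default: observers, joint lat/lon, duration,
    day of year, distance — thin-plate df 4 — and a cyclic df-5 time-of-day
    term).  Rows missing any covariate are dropped and counted on the fit.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_rows`` rows remain after dropping.
    """
    X, y, colnames, kept = build_species_design(
        dataset, smooths, alan_col, count_col, log_alan
    )
    if len(kept) < min_rows:
        raise InsufficientDataError(
            f"{len(kept)} rows after covariate dropping (< {min_rows})"
        )
    fit = fit_nb_glm(X, y, colnames=colnames, theta=theta)
    fit.alan_index = 1
    fit.n_dropped = len(dataset) - len(kept)
    return fit
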
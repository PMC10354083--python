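"""Fixed-rank smooth bases for the abundance model.

Two constructions are provided, both returning centred (sum-to-zero) column
blocks that combine with an explicit intercept:

* :func:`thinplate_basis` — a low-rank thin-plate regression spline: the
  radial thin-plate system is built on a deterministic knot subset, its
  polynomial-orthogonal part eigendecomposed, and the leading eigenvectors
  retained so that linear-covariate columns plus ``df - d - 1`` nonlinear
  columns give ``df - 1`` centred columns (``d`` covariate dimensions).
  Affine functions of the covariates are reproduced exactly by
  intercept + basis.
* :func:`cyclic_cubic_basis` — a periodic cubic regression spline on evenly
  spaced knots over the period; every basis function matches in value and
  first two derivatives across the seam, suiting time-of-day effects.

The bases are used unpenalised at small fixed rank (df 4 for thin-plate
terms, 5 for the cyclic term), i.e. as regression splines rather than
penalised smooths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import DomainError, RankError

_MAX_KNOTS = 100


@dataclass(frozen=True)
class SmoothSpec:
    """One smooth term of the abundance model."""

    name: str
    covariates: tuple[str, ...]
    basis: str = "thin-plate"  # or "cyclic-cubic"
    df: int = 4
    period: float | None = None

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValueError("smooth df must be >= 2")
        if self.basis == "cyclic-cubic" and self.period is None:
            raise ValueError("cyclic basis requires a period")
        if self.basis == "cyclic-cubic" and len(self.covariates) != 1:
            raise ValueError("cyclic basis is univariate")


def default_smooths() -> tuple[SmoothSpec, ...]:
    """The standard effort/detectability smooth set for checklist models."""
    return (
        SmoothSpec("n_observers", ("n_observers",), "thin-plate", 4),
        SmoothSpec("latlon", ("lon", "lat"), "thin-plate", 4),
        SmoothSpec("duration", ("duration_min",), "thin-plate", 4),
        SmoothSpec("day_of_year", ("day_of_year",), "thin-plate", 4),
        SmoothSpec("distance", ("distance_km",), "thin-plate", 4),
        SmoothSpec("time_started", ("time_started_min",), "cyclic-cubic", 5, 1440.0),
    )


def _tps_eta(r: np.ndarray, d: int) -> np.ndarray:
    """Thin-plate radial kernel (order m=2) in d dimensions, scale-free."""
    if d == 1:
        return r**3
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r**2 * np.log(r)
    return np.where(r == 0, 0.0, out)


def _pick_knots(xs: np.ndarray, m: int) -> np.ndarray:
    """Deterministic knot subset: evenly spaced over lexicographically
    sorted unique covariate rows."""
    uniq = np.unique(xs, axis=0)
    if len(uniq) <= m:
        return uniq
    idx = np.linspace(0, len(uniq) - 1, m).round().astype(int)
    return uniq[np.unique(idx)]


def thinplate_basis(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Centred low-rank thin-plate regression spline basis.

    Parameters
    ----------
    x
        Covariate values, shape ``(n,)`` or ``(n, d)`` with d in {1, 2}.
    df
        Basis dimension k; the returned matrix has ``k - 1`` sum-to-zero
        columns (the intercept's share of the basis is removed).

    Raises
    ------
    RankError
        If fewer than ``df`` distinct covariate values are available.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if d not in (1, 2):
        raise ValueError("thin-plate basis supports 1-D or 2-D covariates")
    if not np.all(np.isfinite(x)):
        raise DomainError("non-finite covariate values")
    uniq = np.unique(x, axis=0)
    if len(uniq) < df:
        raise RankError(
            f"need >= {df} distinct covariate values, have {len(uniq)}"
        )
    M = d + 1  # polynomial null-space dimension for m=2
    if df < M + 1:
        raise RankError(f"df={df} too small for a {d}-D thin-plate term")

    # scale covariates to unit range for numeric conditioning (affects the
    # eigen-column span only through rounding; the affine part is exact)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    xs = (x - lo) / span

    knots = _pick_knots(xs, _MAX_KNOTS)
    m = len(knots)
    rk = np.linalg.norm(knots[:, None, :] - knots[None, :, :], axis=-1)
    E = _tps_eta(rk, d)
    T = np.column_stack([np.ones(m), knots])
    # project out the polynomial space, eigendecompose the remainder
    Q, _ = np.linalg.qr(T)
    P = np.eye(m) - Q @ Q.T
    Et = P @ E @ P
    w, V = np.linalg.eigh(Et)
    order = np.argsort(np.abs(w))[::-1]
    U = V[:, order[: df - M]]

    rn = np.linalg.norm(xs[:, None, :] - knots[None, :, :], axis=-1)
    Phi = _tps_eta(rn, d) @ U
    # residualise the nonlinear columns against [1, covariates] at the data
    # so affine content lives only in the explicit linear columns
    A = np.column_stack([np.ones(n), xs])
    coef, *_ = np.linalg.lstsq(A, Phi, rcond=None)
    Phi = Phi - A @ coef
    sd = Phi.std(axis=0)
    Phi = Phi / np.where(sd > 0, sd, 1.0)

    linear = xs - xs.mean(axis=0)
    lsd = linear.std(axis=0)
    linear = linear / np.where(lsd > 0, lsd, 1.0)
    return np.column_stack([linear, Phi])


def cyclic_cubic_basis(
    t: np.ndarray, df: int = 5, period: float = 1440.0
) -> np.ndarray:
    """Centred periodic cubic regression spline basis.

    ``df`` evenly spaced knots cover ``[0, period)``; the basis functions are
    the periodic cubic spline interpolants of the knot indicator vectors.
    They sum to the constant 1, so after sum-to-zero centring one redundant
    column is dropped, leaving ``df - 1`` columns.

    Raises
    ------
    DomainError
        For values outside ``[0, period)``.
    """
    t = np.asarray(t, dtype=float)
    if df < 3:
        raise ValueError("cyclic basis needs df >= 3")
    if not np.all(np.isfinite(t)) or np.any(t < 0) or np.any(t >= period):
        raise DomainError(f"time values must lie in [0, {period})")
    knots = np.linspace(0.0, period, df + 1)  # df interior knots + seam copy
    cols = []
    for j in range(df):
        vals = np.zeros(df + 1)
        vals[j] = 1.0
        if j == 0:
            vals[-1] = 1.0  # periodic closure
        spl = CubicSpline(knots, vals, bc_type="periodic")
        cols.append(spl(t))
    B = np.column_stack(cols)
    B = B - B.mean(axis=0)
    return B[:, :-1]


def build_smooth_matrix(
    data, smooths: tuple[SmoothSpec, ...]
) -> tuple[np.ndarray, list[str]]:
    """Evaluate every smooth on a data frame; returns (matrix, column names)."""
    blocks, names = [], []
    for sp in smooths:
        if sp.basis == "thin-plate":
            xv = data[list(sp.covariates)].to_numpy(dtype=float)
            block = thinplate_basis(xv, sp.df)
        elif sp.basis == "cyclic-cubic":
            tv = data[sp.covariates[0]].to_numpy(dtype=float)
            block = cyclic_cubic_basis(tv, sp.df, sp.period)
        else:
            raise ValueError(f"unknown basis {sp.basis!r}")
        blocks.append(block)
        names.extend(f"s({sp.name}).{i + 1}" for i in range(block.shape[1]))
    if not blocks:
        return np.empty((len(data), 0)), []
    return np.column_stack(blocks), names
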
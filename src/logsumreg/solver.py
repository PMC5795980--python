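"""Cyclic coordinate descent for penalized multiple linear regression.

The fitted objective, on standardized data, is

    (1 / 2n) * ||y - X b||^2  +  Pen_lam(b)

where every column of X has mean 0 and mean-square 1 and y is
centered.  Under that scaling the coordinate update for b_j is exactly
the univariate thresholding operator applied to the partial-residual
correlation

    w_j = (1/n) * sum_i x_ij * (y_i - sum_{k != j} x_ik b_k),

so the solver works with any of the six operators from
:mod:`logsumreg.thresholding`.  The sweep is compiled with numba and
uses the usual active-set refinement (iterate on the current support
until it stabilizes, then confirm with a full sweep), which leaves the
fixed point of the plain cyclic algorithm unchanged.

Coefficients are reported back on the original descriptor scale with
the intercept recovered from the stored standardization constants; the
intercept itself is never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .thresholding import PenaltySpec, _apply, penalty_total

__all__ = [
    "Dataset",
    "FitResult",
    "FitDivergedError",
    "standardize",
    "partial_residual_correlation",
    "fit",
    "predict",
]

_ZERO_VAR_TOL = 1e-12


class FitDivergedError(RuntimeError):
    """Raised when non-finite values appear during coordinate descent."""


@dataclass
class Dataset:
    """A design matrix of molecular descriptors with a response.

    Rows are compounds, columns are descriptors, ``y`` is the measured
    biological activity.  After :func:`standardize` the standardization
    constants are stored so fitted coefficients can be mapped back to
    the original descriptor scale.
    """

    X: np.ndarray
    y: np.ndarray
    names: Optional[list[str]] = None
    column_means: Optional[np.ndarray] = None
    column_scales: Optional[np.ndarray] = None
    y_mean: Optional[float] = None
    active: Optional[np.ndarray] = None  # False marks zero-variance columns

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 samples and p >= 1 descriptors, got {n}x{p}")
        if len(self.y) != n:
            raise ValueError(f"y has {len(self.y)} entries for {n} rows of X")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("X and y must be free of NaN/Inf")
        if self.names is not None and len(self.names) != p:
            raise ValueError("names length must equal the number of descriptors")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def is_standardized(self) -> bool:
        return self.column_scales is not None

    def subset(self, rows: Sequence[int]) -> "Dataset":
        """A raw (non-standardized) dataset restricted to ``rows``."""
        rows = np.asarray(rows)
        return Dataset(X=self.X[rows], y=self.y[rows], names=self.names)


@dataclass
class FitResult:
    """Coefficients and diagnostics of a penalized regression fit."""

    beta: np.ndarray          # original descriptor scale
    intercept: float
    beta_std: np.ndarray      # standardized scale (used for ranking)
    n_iter: int               # coordinate sweeps performed
    converged: bool
    objective: float          # objective value on the standardized scale
    names: Optional[list[str]] = None

    @property
    def selected(self) -> np.ndarray:
        """Indices of descriptors with nonzero coefficients."""
        return np.flatnonzero(self.beta_std)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.beta_std))


def standardize(data: Dataset) -> Dataset:
    """Center and scale so each column has mean 0 and mean-square 1.

    Zero-variance columns are flagged inactive (their coefficients are
    pinned to 0 by the solver) and y is centered.  The operation is
    idempotent and records the constants needed to restore the original
    scale.
    """
    if data.is_standardized:
        return data
    X = data.X
    means = X.mean(axis=0)
    Xc = X - means
    scales = np.sqrt((Xc**2).mean(axis=0))
    active = scales > _ZERO_VAR_TOL
    if not active.any():
        raise ValueError("all descriptor columns are constant; nothing to fit")
    safe = np.where(active, scales, 1.0)
    Xs = np.asfortranarray(Xc / safe)
    Xs[:, ~active] = 0.0
    y_mean = float(data.y.mean())
    return Dataset(
        X=Xs,
        y=data.y - y_mean,
        names=data.names,
        column_means=means,
        column_scales=safe,
        y_mean=y_mean,
        active=active,
    )


def partial_residual_correlation(data: Dataset, beta: np.ndarray, j: int) -> float:
    """w_j = (1/n) * x_j . (y - sum_{k != j} x_k beta_k) on standardized data.

    ``j`` is a 0-based column index.
    """
    if not data.is_standardized:
        raise ValueError("partial residuals are defined on standardized data")
    beta = np.asarray(beta, dtype=float)
    partial = data.y - data.X @ beta + data.X[:, j] * beta[j]
    return float(data.X[:, j] @ partial / data.n)


@njit(cache=False)
def _cd_kernel(X, y, beta, active, code, lam, shape, max_sweeps, tol):
    """Cyclic coordinate descent with active-set refinement.

    Returns (sweeps_used, converged, finite).  Both full and restricted
    sweeps count toward ``max_sweeps``.  Convergence is declared when a
    *full* sweep moves no coefficient by tol or more.
    """
    n, p = X.shape
    r = y.copy()
    for j in range(p):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * bj
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        # full sweep over all active coordinates
        maxd = 0.0
        for j in range(p):
            if not active[j]:
                continue
            bj = beta[j]
            wj = 0.0
            for i in range(n):
                wj += X[i, j] * r[i]
            wj = wj / n + bj
            bnew = _apply(code, wj, lam, shape)
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bnew
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        sweeps += 1
        if not np.isfinite(maxd):
            return sweeps, False, False
        if maxd < tol:
            converged = True
            break
        # restricted sweeps on the current support
        while sweeps < max_sweeps:
            maxd_in = 0.0
            for j in range(p):
                if not active[j] or beta[j] == 0.0:
                    continue
                bj = beta[j]
                wj = 0.0
                for i in range(n):
                    wj += X[i, j] * r[i]
                wj = wj / n + bj
                bnew = _apply(code, wj, lam, shape)
                d = bnew - bj
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bnew
                    ad = abs(d)
                    if ad > maxd_in:
                        maxd_in = ad
            sweeps += 1
            if not np.isfinite(maxd_in):
                return sweeps, False, False
            if maxd_in < tol:
                break
    return sweeps, converged, True


def fit(
    data: Dataset,
    spec: PenaltySpec,
    max_sweeps: int = 1000,
    tol: float = 1e-5,
    warm_start: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit penalized linear regression by cyclic coordinate descent.

    Parameters
    ----------
    data:
        Raw or standardized :class:`Dataset`; raw data is standardized
        internally.
    spec:
        Penalty specification with ``lam`` set.
    max_sweeps, tol:
        Sweep budget and convergence tolerance on the maximum absolute
        coefficient change of a full sweep (standardized scale).
    warm_start:
        Optional initial coefficients on the *standardized* scale, as
        produced in ``FitResult.beta_std`` (used along lambda paths).
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be at least 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    spec = spec.resolved()
    sdata = standardize(data)
    p = sdata.p
    if warm_start is not None:
        beta = np.array(warm_start, dtype=float).copy()
        if beta.shape != (p,):
            raise ValueError("warm_start must have one entry per descriptor")
    else:
        beta = np.zeros(p)
    active = sdata.active.astype(np.bool_)
    beta[~active] = 0.0
    sweeps, converged, finite = _cd_kernel(
        sdata.X,
        sdata.y,
        beta,
        active,
        spec.code,
        float(spec.lam),
        float(spec.shape),
        int(max_sweeps),
        float(tol),
    )
    if not finite or not np.isfinite(beta).all():
        raise FitDivergedError(f"non-finite coefficients encountered at sweep {sweeps}")
    resid = sdata.y - sdata.X @ beta
    objective = float(0.5 * (resid @ resid) / sdata.n + penalty_total(beta, spec))
    beta_orig = beta / sdata.column_scales
    beta_orig[~active] = 0.0
    intercept = float(sdata.y_mean - sdata.column_means @ beta_orig)
    return FitResult(
        beta=beta_orig,
        intercept=intercept,
        beta_std=beta,
        n_iter=int(sweeps),
        converged=bool(converged),
        objective=objective,
        names=sdata.names,
    )


def predict(fit_result: FitResult, Xnew: np.ndarray) -> np.ndarray:
    """Predicted activities for descriptor rows on the original scale."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew.reshape(1, -1)
    if Xnew.shape[1] != len(fit_result.beta):
        raise ValueError(
            f"Xnew has {Xnew.shape[1]} columns, model expects {len(fit_result.beta)}"
        )
    return Xnew @ fit_result.beta + fit_result.intercept
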
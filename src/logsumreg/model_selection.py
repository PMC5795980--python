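"""Regularization paths and data-driven choice of the penalty strength.

The penalty strength lambda is chosen on a log-spaced grid anchored at

    lambda_max = max_j |(1/n) x_j . y|

(the smallest lambda at which the L1 solution is empty on standardized
data), fitting the path from the largest lambda down with warm starts.
Two selection criteria are offered:

* ``cv``  - K-fold cross-validation (default 10-fold) minimizing the
  pooled held-out squared error,
* ``bic`` - n * log(RSS / n) + log(n) * df with df = number of
  selected descriptors.

For the log-sum penalty the offset eps follows lambda along the path
(eps = lambda / 10 unless set explicitly), which keeps the
0 < eps < lambda constraint valid at every grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .solver import Dataset, FitResult, fit, predict, standardize
from .thresholding import PenaltySpec

__all__ = ["PathResult", "lambda_grid", "fit_path", "select_lambda", "tune"]

DEFAULT_N_LAMBDA = 100
DEFAULT_RATIO = 1e-3
DEFAULT_N_FOLDS = 10


@dataclass
class PathResult:
    """Fits along a strictly decreasing lambda grid."""

    lambdas: np.ndarray
    fits: list[FitResult]
    criterion_values: Optional[np.ndarray] = None
    chosen_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.fits) != len(self.lambdas):
            raise ValueError("one fit per lambda required")
        if len(self.lambdas) > 1 and not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")

    @property
    def best_fit(self) -> FitResult:
        if self.chosen_index is None:
            raise ValueError("no lambda has been selected yet")
        return self.fits[self.chosen_index]

    @property
    def best_lambda(self) -> float:
        if self.chosen_index is None:
            raise ValueError("no lambda has been selected yet")
        return float(self.lambdas[self.chosen_index])

    def to_tsv(self) -> str:
        lines = ["lambda\tn_selected\tcriterion"]
        crit = (
            self.criterion_values
            if self.criterion_values is not None
            else [float("nan")] * len(self.lambdas)
        )
        for lam, f, c in zip(self.lambdas, self.fits, crit):
            lines.append(f"{lam!r}\t{f.n_selected}\t{float(c)!r}")
        return "\n".join(lines) + "\n"


def lambda_grid(
    data: Dataset, n_lambda: int = DEFAULT_N_LAMBDA, ratio: float = DEFAULT_RATIO
) -> np.ndarray:
    """Log-spaced grid from lambda_max down to ratio * lambda_max."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    sdata = standardize(data)
    corr = np.abs(sdata.X.T @ sdata.y) / sdata.n
    lam_max = float(corr.max())
    if lam_max <= 0:
        raise ValueError("response is orthogonal to every descriptor; degenerate y")
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def fit_path(
    data: Dataset,
    spec: PenaltySpec,
    grid: np.ndarray,
    max_sweeps: int = 1000,
    tol: float = 1e-5,
    warm: Optional[bool] = None,
) -> PathResult:
    """Fit the model at every grid point, largest lambda first.

    For the convex penalties each fit is warm-started from the
    previous solution.  For the non-convex penalties the default is a
    cold start (beta = 0, the algorithm's own initialization) at every
    grid point: carrying a non-convex solution down the path can trap
    the solver in local minima where spurious variables absorbed the
    signal early and never exit.  ``warm`` overrides the default.
    """
    grid = np.asarray(grid, dtype=float)
    if warm is None:
        warm = spec.is_convex
    sdata = standardize(data)
    fits: list[FitResult] = []
    start = None
    for lam in grid:
        try:
            res = fit(sdata, spec.resolved(lam), max_sweeps=max_sweeps, tol=tol, warm_start=start)
        except Exception as exc:
            raise RuntimeError(f"path fit failed at lambda={lam:g}") from exc
        fits.append(res)
        if warm:
            start = res.beta_std
    return PathResult(lambdas=grid, fits=fits)


def _cv_criterion(
    data: Dataset,
    spec: PenaltySpec,
    grid: np.ndarray,
    n_folds: int,
    seed: int,
    max_sweeps: int,
    tol: float,
) -> np.ndarray:
    """Pooled held-out squared error at each lambda over seeded folds."""
    n = data.n
    if n_folds < 2 or n_folds > n:
        raise ValueError("fold count must lie in [2, n]")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, n_folds)
    warm = spec.is_convex
    sq_err = np.zeros(len(grid))
    for held in folds:
        train_rows = np.setdiff1d(np.arange(n), held)
        train = data.subset(train_rows)
        strain = standardize(train)
        start = None
        for k, lam in enumerate(grid):
            res = fit(strain, spec.resolved(lam), max_sweeps=max_sweeps, tol=tol, warm_start=start)
            if warm:
                start = res.beta_std
            pred = predict(res, data.X[held])
            sq_err[k] += float(np.sum((data.y[held] - pred) ** 2))
    return sq_err / n


def select_lambda(
    path: PathResult,
    method: str = "cv",
    data: Optional[Dataset] = None,
    spec: Optional[PenaltySpec] = None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    max_sweeps: int = 1000,
    tol: float = 1e-5,
) -> int:
    """Choose a grid point; fills ``criterion_values`` and
    ``chosen_index`` on the path and returns the index.

    Ties (including a constant criterion) resolve to the smallest
    index, i.e. the largest lambda.
    """
    if method == "cv":
        if data is None or spec is None:
            raise ValueError("cv selection needs the training data and the penalty spec")
        crit = _cv_criterion(data, spec, path.lambdas, n_folds, seed, max_sweeps, tol)
    elif method == "bic":
        if data is None:
            raise ValueError("bic selection needs the training data")
        n = data.n
        crit = np.empty(len(path.lambdas))
        for k, f in enumerate(path.fits):
            resid = data.y - predict(f, data.X)
            rss = float(resid @ resid)
            crit[k] = n * np.log(max(rss, 1e-300) / n) + np.log(n) * f.n_selected
    else:
        raise ValueError(f"unknown selection method {method!r}")
    if not np.isfinite(crit).any():
        raise RuntimeError("criterion failed at every lambda")
    idx = int(np.nanargmin(crit))
    path.criterion_values = crit
    path.chosen_index = idx
    return idx


def tune(
    data: Dataset,
    spec: PenaltySpec,
    n_lambda: int = DEFAULT_N_LAMBDA,
    ratio: float = DEFAULT_RATIO,
    method: str = "cv",
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    max_sweeps: int = 1000,
    tol: float = 1e-5,
) -> PathResult:
    """Grid construction, path fitting and lambda selection in one call."""
    grid = lambda_grid(data, n_lambda=n_lambda, ratio=ratio)
    path = fit_path(data, spec, grid, max_sweeps=max_sweeps, tol=tol)
    select_lambda(
        path,
        method=method,
        data=data,
        spec=spec,
        n_folds=n_folds,
        seed=seed,
        max_sweeps=max_sweeps,
        tol=tol,
    )
    return path
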
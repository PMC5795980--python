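"""Synthetic regression benchmark with a known sparse support.

The generator reproduces the support-recovery study design: a design
matrix of i.i.d. standard-normal descriptors in which columns 2-6 are
made correlated with column 1 through the mixture

    x_ij  <-  rho * x_i1 + (1 - rho) * x_ij,      j = 2, ..., 6,

a preset coefficient vector with exactly 20 nonzero entries
(2, -2, -1, 1.5, 3, 2.5, 3 followed by thirteen 2s) padded with zeros,
and the response

    y = X beta + sigma * eps,        eps ~ N(0, 1).

``rho`` controls the collinearity among the first six variables and
``sigma`` the noise level.  Each replicate draws a fresh X and eps;
the (seed, replicate) pair fully determines the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .solver import Dataset

__all__ = ["SimulationConfig", "SimulatedDataset", "default_beta", "generate", "write_csv"]

# mixture corr(x_1, x_j) = rho / sqrt(rho^2 + (1-rho)^2), j in 2..6
N_CORRELATED = 5
N_NONZERO = 20
_LEAD_COEFS = (2.0, -2.0, -1.0, 1.5, 3.0, 2.5, 3.0)


@dataclass
class SimulationConfig:
    """Study conditions for one simulation cell.

    Defaults follow the benchmark grid: p = 2000 variables with 20
    preset nonzero coefficients, 100 replicates per cell; ``n``,
    ``rho`` (in [0, 1)) and ``sigma`` vary across cells.
    """

    n: int
    p: int = 2000
    rho: float = 0.2
    sigma: float = 0.3
    beta_true: Optional[np.ndarray] = None
    seed: int = 0
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1:
            raise ValueError("need n >= 2 and p >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.beta_true is None:
            self.beta_true = default_beta(self.p)
        else:
            self.beta_true = np.asarray(self.beta_true, dtype=float)
            if self.beta_true.shape != (self.p,):
                raise ValueError("beta_true must have length p")


@dataclass
class SimulatedDataset:
    """A generated dataset together with its ground truth."""

    data: Dataset
    beta_true: np.ndarray
    true_support: np.ndarray  # 0-based indices of nonzero coefficients
    replicate: int


def default_beta(p: int) -> np.ndarray:
    """The preset sparse coefficient vector.

    Positions 1-7 (1-based) hold 2, -2, -1, 1.5, 3, 2.5, 3; positions
    8-20 hold 2; the remaining p - 20 entries are zero, giving exactly
    20 nonzero coefficients.
    """
    if p < N_NONZERO:
        raise ValueError(f"default coefficient vector needs p >= {N_NONZERO}, got {p}")
    beta = np.zeros(p)
    beta[: len(_LEAD_COEFS)] = _LEAD_COEFS
    beta[len(_LEAD_COEFS) : N_NONZERO] = 2.0
    return beta


def generate(config: SimulationConfig, replicate: int = 1) -> SimulatedDataset:
    """Draw one replicate of the benchmark dataset.

    The random stream is seeded with (config.seed, replicate), so every
    replicate is individually reproducible and replicates are mutually
    independent.
    """
    if not 1 <= replicate <= max(config.n_replicates, 1):
        raise ValueError(
            f"replicate must lie in 1..{config.n_replicates}, got {replicate}"
        )
    rng = np.random.default_rng([int(config.seed), int(replicate)])
    X = rng.standard_normal((config.n, config.p))
    hi = min(1 + N_CORRELATED, config.p)
    if config.rho > 0 and hi > 1:
        X[:, 1:hi] = config.rho * X[:, [0]] + (1.0 - config.rho) * X[:, 1:hi]
    eps = rng.standard_normal(config.n)
    y = X @ config.beta_true + config.sigma * eps
    names = [f"v{j + 1}" for j in range(config.p)]
    return SimulatedDataset(
        data=Dataset(X=X, y=y, names=names),
        beta_true=config.beta_true.copy(),
        true_support=np.flatnonzero(config.beta_true),
        replicate=replicate,
    )


def write_csv(sim: SimulatedDataset, path: str) -> None:
    """Export a replicate as CSV (columns v1..vp plus 'y') for
    cross-language checking."""
    frame = pd.DataFrame(sim.data.X, columns=sim.data.names)
    frame["y"] = sim.data.y
    frame.to_csv(path, index=False)
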
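"""Model-evaluation metrics, support-recovery bookkeeping and ranking.

The QSAR evaluation protocol reports six quantities for a fitted
model: R^2 and RMSE on the training set, leave-one-out
cross-validated Q^2_LOO and RMSE_CV, and R^2 and RMSE on a held-out
test set obtained from a seeded 80/20 random split.  Conventions:

* R^2 = 1 - SS_res / SS_tot (can go negative out of sample),
* Q^2_LOO = 1 - PRESS / SS_tot with SS_tot about the full-sample mean,
* RMSE_CV = sqrt(PRESS / n), all on the raw activity scale.

For the simulation benchmark, support-recovery accuracy is the ratio
of the *average* number of true-support selections to the *average*
total number of selections across replicates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .solver import Dataset, FitResult, fit, predict, standardize
from .thresholding import PenaltySpec

__all__ = [
    "EvaluationReport",
    "SupportRecovery",
    "rmse",
    "r_squared",
    "q2_loo",
    "selection_accuracy",
    "aggregate_recovery",
    "rank_descriptors",
    "split_train_test",
]


@dataclass
class EvaluationReport:
    """The six regression-evaluation metrics plus the selected subset."""

    r2_train: float
    rmse_train: float
    q2_loo: float
    rmse_cv: float
    r2_test: float
    rmse_test: float
    n_selected: int
    selected_names: list[str] = field(default_factory=list)

    _TSV_ORDER = (
        ("R2train", "r2_train"),
        ("RMSEtrain", "rmse_train"),
        ("Q2LOO", "q2_loo"),
        ("RMSECV", "rmse_cv"),
        ("R2test", "r2_test"),
        ("RMSEtest", "rmse_test"),
        ("n_selected", "n_selected"),
    )

    def to_json(self) -> str:
        payload = {col: getattr(self, attr) for col, attr in self._TSV_ORDER}
        payload["selected_names"] = self.selected_names
        return json.dumps(payload)

    def tsv_header(self) -> str:
        return "\t".join(col for col, _ in self._TSV_ORDER)

    def to_tsv_row(self) -> str:
        vals = []
        for _, attr in self._TSV_ORDER:
            v = getattr(self, attr)
            vals.append(str(v) if isinstance(v, int) else repr(float(v)))
        return "\t".join(vals)


@dataclass
class SupportRecovery:
    """Replicate-averaged selection counts and their ratio."""

    n_selected_total: float
    n_selected_true: float
    accuracy: float  # in [0, 1]


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat) or len(y) < 1:
        raise ValueError("y and yhat must be equal-length, nonempty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("y and yhat must be equal-length vectors, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("response has zero variance; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def q2_loo(
    data: Dataset,
    spec: PenaltySpec,
    max_sweeps: int = 1000,
    tol: float = 1e-5,
    warm_start: bool = True,
) -> tuple[float, float]:
    """Leave-one-out Q^2 and RMSE_CV at a fixed penalty.

    Each fold refits the model on the remaining n-1 samples (by
    default warm-started from the full-data solution) and predicts the
    held-out sample.  Q^2 = 1 - PRESS / SS_tot with SS_tot about the
    full-sample mean; RMSE_CV = sqrt(PRESS / n).  Folds that fail to
    converge are still used but trigger a warning.
    """
    if data.is_standardized:
        raise ValueError("q2_loo refits each fold and expects raw data")
    n = data.n
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    start = None
    if warm_start:
        start = fit(data, spec, max_sweeps=max_sweeps, tol=tol).beta_std
    press = 0.0
    bad_folds = []
    for i in range(n):
        rows = np.delete(np.arange(n), i)
        fold = data.subset(rows)
        res = fit(fold, spec, max_sweeps=max_sweeps, tol=tol, warm_start=start)
        if not res.converged:
            bad_folds.append(i)
        yhat = predict(res, data.X[i])
        press += float((data.y[i] - yhat[0]) ** 2)
    if bad_folds:
        warnings.warn(
            f"{len(bad_folds)} leave-one-out folds did not converge "
            f"(first: sample {bad_folds[0]})"
        )
    ss_tot = float(np.sum((data.y - data.y.mean()) ** 2))
    return 1.0 - press / ss_tot, math.sqrt(press / n)


def selection_accuracy(
    selected: Sequence[int], true_support: Sequence[int]
) -> SupportRecovery:
    """Counts for one replicate: total selected, selected within the
    true support, and their ratio (0 when nothing is selected)."""
    sel = set(int(j) for j in selected)
    truth = set(int(j) for j in true_support)
    n_total = len(sel)
    n_true = len(sel & truth)
    acc = n_true / n_total if n_total > 0 else 0.0
    return SupportRecovery(float(n_total), float(n_true), acc)


def aggregate_recovery(per_replicate: Iterable[SupportRecovery]) -> SupportRecovery:
    """Average counts over replicates; accuracy is the ratio of the
    averaged counts (mean true selections / mean total selections)."""
    recs = list(per_replicate)
    if not recs:
        raise ValueError("no replicates to aggregate")
    mean_total = float(np.mean([r.n_selected_total for r in recs]))
    mean_true = float(np.mean([r.n_selected_true for r in recs]))
    acc = mean_true / mean_total if mean_total > 0 else 0.0
    return SupportRecovery(mean_total, mean_true, acc)


def rank_descriptors(fit_result: FitResult, k: int) -> list[str]:
    """The top-k selected descriptors by |standardized coefficient|.

    Ties are broken by column order.  Asking for more descriptors than
    were selected returns all of them with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if fit_result.names is None:
        raise ValueError("fit has no descriptor names to rank")
    sel = fit_result.selected
    if len(sel) == 0:
        return []
    if k > len(sel):
        warnings.warn(f"requested top {k} but only {len(sel)} descriptors are selected")
        k = len(sel)
    mags = np.abs(fit_result.beta_std[sel])
    # stable sort on -|coef| keeps column order among ties
    order = np.argsort(-mags, kind="stable")[:k]
    return [fit_result.names[j] for j in sel[order]]


def split_train_test(
    data: Dataset,
    fraction: float = 0.8,
    seed: int = 0,
    mode: str = "ceil",
) -> tuple[Dataset, Dataset]:
    """Seeded random split into disjoint, exhaustive train/test sets.

    ``mode`` controls how the train size is rounded from
    fraction * n: "ceil" (default), "round" or "floor".
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if data.is_standardized:
        raise ValueError("split raw data, then standardize each part")
    n = data.n
    raw = fraction * n
    if mode == "ceil":
        n_train = math.ceil(raw)
    elif mode == "floor":
        n_train = math.floor(raw)
    elif mode == "round":
        n_train = round(raw)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    n_train = min(n_train, n - 1)
    if n_train < 2:
        raise ValueError("training split would have fewer than 2 samples")
    perm = np.random.default_rng(seed).permutation(n)
    return data.subset(np.sort(perm[:n_train])), data.subset(np.sort(perm[n_train:]))
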
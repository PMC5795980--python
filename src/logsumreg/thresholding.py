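"""Penalty functions and their univariate thresholding operators.

Every operator in this module returns the solution of the scalar
penalized least-squares subproblem

    minimize_b   g(b) = 1/2 (b - w)^2 + pen(b)

where ``w`` is the partial-residual correlation of one coordinate and
``pen`` is the penalty evaluated at a single coefficient.  For the
convex penalties (L1 lasso, LEN elastic net) the operator is the global
minimizer.  For the non-convex penalties (SCAD, MCP, half/L1/2,
log-sum) the operator returns the sparsest nonzero stationary point
when one exists and zero otherwise, which is the update rule used by
the coordinate-descent solver.

Six penalties are supported:

``l1``      pen(b) = lam * |b|
``len``     pen(b) = lam * ((1-a)/2 * b^2 + a * |b|),     0 <= a <= 1
``scad``    smoothly clipped absolute deviation, shape a > 2
``mcp``     minimax concave penalty, shape gamma > 1
``half``    pen(b) = lam * |b|^(1/2)
``logsum``  pen(b) = lam * log(|b| + eps),                0 < eps < lam

The scalar kernels are compiled with numba so that the coordinate
descent solver can call them from inside its compiled sweep.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "Penalty",
    "PenaltySpec",
    "soft_threshold",
    "len_threshold",
    "scad_threshold",
    "mcp_threshold",
    "half_threshold",
    "logsum_threshold",
    "threshold",
    "penalty_value",
    "penalty_total",
]


class Penalty(str, enum.Enum):
    """The six supported penalty families."""

    L1 = "l1"
    LEN = "len"
    SCAD = "scad"
    MCP = "mcp"
    HALF = "half"
    LOGSUM = "logsum"


# integer codes used by the compiled kernels
_CODE = {
    Penalty.L1: 0,
    Penalty.LEN: 1,
    Penalty.SCAD: 2,
    Penalty.MCP: 3,
    Penalty.HALF: 4,
    Penalty.LOGSUM: 5,
}

# literature-standard shape defaults; all overridable per spec instance
DEFAULT_LEN_A = 0.5
DEFAULT_SCAD_A = 3.7
DEFAULT_MCP_GAMMA = 3.0
# default eps for log-sum, as a fraction of lambda: keeps 0 < eps < lam
# valid at every point of a regularization path
DEFAULT_EPS_RATIO = 0.1


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family together with its hyperparameters.

    Parameters
    ----------
    kind:
        Penalty family.
    lam:
        Penalty strength lambda >= 0.  May be left ``None`` in a
        template that is resolved along a regularization path.
    a:
        Elastic-net mixing weight in [0, 1] (``len``) or SCAD shape
        parameter > 2 (``scad``).  Ignored otherwise.
    gamma:
        MCP shape parameter > 1.  Ignored otherwise.
    eps:
        Log-sum offset, 0 < eps < lam.  ``None`` means lam/10.
    allow_large_eps:
        Relaxation flag: when True the ``eps < lam`` check for the
        log-sum penalty is skipped (the operator formula remains well
        defined for any eps > 0).
    """

    kind: Penalty
    lam: Optional[float] = None
    a: Optional[float] = None
    gamma: Optional[float] = None
    eps: Optional[float] = None
    allow_large_eps: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Penalty(self.kind))
        if self.lam is not None:
            self.validate()

    def resolved(self, lam: Optional[float] = None) -> "PenaltySpec":
        """Return a fully-specified copy with defaults filled in."""
        lam = self.lam if lam is None else float(lam)
        if lam is None:
            raise ValueError("penalty strength lam must be set")
        spec = replace(self, lam=lam)
        if spec.kind is Penalty.LEN and spec.a is None:
            spec = replace(spec, a=DEFAULT_LEN_A)
        if spec.kind is Penalty.SCAD and spec.a is None:
            spec = replace(spec, a=DEFAULT_SCAD_A)
        if spec.kind is Penalty.MCP and spec.gamma is None:
            spec = replace(spec, gamma=DEFAULT_MCP_GAMMA)
        if spec.kind is Penalty.LOGSUM and spec.eps is None:
            spec = replace(spec, eps=DEFAULT_EPS_RATIO * lam)
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.lam is None or not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be a finite nonnegative real, got {self.lam}")
        if self.kind is Penalty.LEN and self.a is not None and not 0.0 <= self.a <= 1.0:
            raise ValueError(f"elastic-net mixing weight a must lie in [0, 1], got {self.a}")
        if self.kind is Penalty.SCAD and self.a is not None and self.a <= 2.0:
            raise ValueError(f"SCAD shape parameter a must exceed 2, got {self.a}")
        if self.kind is Penalty.MCP and self.gamma is not None and self.gamma <= 1.0:
            raise ValueError(f"MCP shape parameter gamma must exceed 1, got {self.gamma}")
        if self.kind is Penalty.LOGSUM and self.eps is not None:
            if self.eps <= 0:
                raise ValueError(f"log-sum eps must be positive, got {self.eps}")
            if not self.allow_large_eps and self.lam is not None and self.eps >= self.lam:
                raise ValueError(
                    f"log-sum requires 0 < eps < lam (eps={self.eps}, lam={self.lam}); "
                    "set allow_large_eps=True to relax"
                )

    @property
    def is_convex(self) -> bool:
        """True for the convex penalties (L1, elastic net)."""
        return self.kind in (Penalty.L1, Penalty.LEN)

    @property
    def code(self) -> int:
        """Integer code of the penalty family for the compiled kernels."""
        return _CODE[self.kind]

    @property
    def shape(self) -> float:
        """The single shape parameter consumed by the compiled kernels."""
        if self.kind is Penalty.LEN:
            return self.a if self.a is not None else DEFAULT_LEN_A
        if self.kind is Penalty.SCAD:
            return self.a if self.a is not None else DEFAULT_SCAD_A
        if self.kind is Penalty.MCP:
            return self.gamma if self.gamma is not None else DEFAULT_MCP_GAMMA
        if self.kind is Penalty.LOGSUM:
            if self.eps is None:
                raise ValueError("log-sum eps unresolved; call resolved() first")
            return self.eps
        return 0.0


# ---------------------------------------------------------------------------
# compiled scalar kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _soft(w: float, lam: float) -> float:
    if w > lam:
        return w - lam
    if w < -lam:
        return w + lam
    return 0.0


@njit(cache=False)
def _len(w: float, lam: float, a: float) -> float:
    return _soft(w, lam * a) / (1.0 + lam * (1.0 - a))


@njit(cache=False)
def _scad(w: float, lam: float, a: float) -> float:
    aw = abs(w)
    if aw <= 2.0 * lam:
        return _soft(w, lam)
    if aw <= a * lam:
        return _soft(w, a * lam / (a - 1.0)) / (1.0 - 1.0 / (a - 1.0))
    return w


@njit(cache=False)
def _mcp(w: float, lam: float, gamma: float) -> float:
    if abs(w) <= gamma * lam:
        return _soft(w, lam) / (1.0 - 1.0 / gamma)
    return w


@njit(cache=False)
def _half(w: float, lam: float) -> float:
    # Nonzero stationary points of 1/2 (b-w)^2 + lam*sqrt(|b|) exist
    # exactly when |w| > 3*(lam/4)^(2/3); the largest root of the
    # resulting cubic (in sqrt(|b|)) is the local minimum.
    if lam == 0.0:
        return w
    aw = abs(w)
    if aw <= 3.0 * (0.25 * lam) ** (2.0 / 3.0):
        return 0.0
    phi = math.acos(0.25 * lam * (aw / 3.0) ** (-1.5))
    return (2.0 / 3.0) * w * (1.0 + math.cos(2.0 * (math.pi - phi) / 3.0))


@njit(cache=False)
def _logsum(w: float, lam: float, eps: float) -> float:
    aw = abs(w)
    c1 = aw - eps
    c2 = c1 * c1 - 4.0 * (lam - aw * eps)
    if c2 <= 0.0:
        return 0.0
    root = 0.5 * (c1 + math.sqrt(c2))
    if root <= 0.0:
        # the quadratic's larger root is non-positive: dead zone
        return 0.0
    if w > 0.0:
        return root
    return -root


@njit(cache=False)
def _apply(code: int, w: float, lam: float, shape: float) -> float:
    if code == 0:
        return _soft(w, lam)
    elif code == 1:
        return _len(w, lam, shape)
    elif code == 2:
        return _scad(w, lam, shape)
    elif code == 3:
        return _mcp(w, lam, shape)
    elif code == 4:
        return _half(w, lam)
    else:
        return _logsum(w, lam, shape)


# ---------------------------------------------------------------------------
# public scalar operators
# ---------------------------------------------------------------------------


def soft_threshold(w: float, lam: float) -> float:
    """L1 soft-thresholding: sign(w) * max(|w| - lam, 0)."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    return float(_soft(float(w), float(lam)))


def len_threshold(w: float, lam: float, a: float = DEFAULT_LEN_A) -> float:
    """Elastic-net operator S(w, lam*a) / (1 + lam*(1-a)).

    Reduces to soft thresholding at a=1 and to the ridge shrink
    w / (1 + lam) at a=0.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if not 0.0 <= a <= 1.0:
        raise ValueError("mixing weight a must lie in [0, 1]")
    return float(_len(float(w), float(lam), float(a)))


def scad_threshold(w: float, lam: float, a: float = DEFAULT_SCAD_A) -> float:
    """SCAD operator: soft for |w| <= 2*lam, rescaled soft in the middle
    region, identity for |w| > a*lam."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if a <= 2.0:
        raise ValueError("SCAD shape parameter a must exceed 2")
    return float(_scad(float(w), float(lam), float(a)))


def mcp_threshold(w: float, lam: float, gamma: float = DEFAULT_MCP_GAMMA) -> float:
    """MCP operator: S(w, lam) / (1 - 1/gamma) for |w| <= gamma*lam,
    identity beyond."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if gamma <= 1.0:
        raise ValueError("MCP shape parameter gamma must exceed 1")
    return float(_mcp(float(w), float(lam), float(gamma)))


def half_threshold(w: float, lam: float) -> float:
    """L1/2 half-thresholding operator.

    Zero for |w| <= 3*(lam/4)^(2/3); otherwise the closed trigonometric
    form of the largest root of the stationarity cubic of
    1/2 (b - w)^2 + lam*sqrt(|b|), which is its nonzero local minimum.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    return float(_half(float(w), float(lam)))


def logsum_threshold(
    w: float,
    lam: float,
    eps: float,
    exact: bool = False,
    allow_large_eps: bool = False,
) -> float:
    """Log-sum thresholding operator D(w, lam, eps).

    With c1 = |w| - eps and c2 = c1^2 - 4*(lam - |w|*eps), returns
    sign(w) * (c1 + sqrt(c2)) / 2 when c2 > 0 (a stationary point of
    1/2 (b - |w|)^2 + lam*log(b + eps) on b > 0) and 0 otherwise.

    Parameters
    ----------
    exact:
        When True the objective at the nonzero root is compared against
        the objective at 0 and the argmin is returned; the default
        returns the root whenever it exists, which is the update used
        by the coordinate-descent solver.
    allow_large_eps:
        Skip the ``eps < lam`` precondition check.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if not allow_large_eps and eps >= lam:
        raise ValueError("log-sum requires 0 < eps < lam; pass allow_large_eps=True to relax")
    b = float(_logsum(float(w), float(lam), float(eps)))
    if exact and b != 0.0:
        aw = abs(w)
        g_root = 0.5 * (abs(b) - aw) ** 2 + lam * math.log(abs(b) + eps)
        g_zero = 0.5 * aw**2 + lam * math.log(eps)
        if g_zero < g_root:
            return 0.0
    return b


def threshold(w: float, spec: PenaltySpec) -> float:
    """Apply the thresholding operator of ``spec`` to a scalar ``w``."""
    spec = spec.resolved()
    return float(_apply(spec.code, float(w), float(spec.lam), float(spec.shape)))


# ---------------------------------------------------------------------------
# penalty values
# ---------------------------------------------------------------------------


def penalty_value(beta: float, spec: PenaltySpec) -> float:
    """Evaluate the penalty at a single coefficient.

    For L1, LEN, HALF and LOGSUM the value is returned *without* the
    lambda factor (the solver multiplies by lambda); for SCAD and MCP
    the full p_{lam, shape}(beta) is returned because lambda enters
    those penalties non-multiplicatively.
    """
    spec = spec.resolved()
    b = abs(float(beta))
    kind = spec.kind
    if kind is Penalty.L1:
        return b
    if kind is Penalty.LEN:
        return (1.0 - spec.a) * 0.5 * b * b + spec.a * b
    if kind is Penalty.HALF:
        return math.sqrt(b)
    if kind is Penalty.LOGSUM:
        # may be negative when eps < 1; returned as-is
        return math.log(b + spec.eps)
    lam = spec.lam
    if kind is Penalty.SCAD:
        a = spec.a
        if b <= lam:
            return lam * b
        if b <= a * lam:
            return (a * lam * b - 0.5 * (b * b + lam * lam)) / (a - 1.0)
        return 0.5 * lam * lam * (a + 1.0)
    # MCP
    g = spec.gamma
    if b <= g * lam:
        return lam * b - b * b / (2.0 * g)
    return 0.5 * g * lam * lam


def penalty_total(beta: np.ndarray, spec: PenaltySpec) -> float:
    """Total penalty term of the objective for a coefficient vector.

    lam * sum_j P(beta_j) for the multiplicative penalties, and
    sum_j p_lam(beta_j) for SCAD/MCP.
    """
    spec = spec.resolved()
    beta = np.abs(np.asarray(beta, dtype=float))
    kind = spec.kind
    lam = spec.lam
    if kind is Penalty.L1:
        return float(lam * beta.sum())
    if kind is Penalty.LEN:
        return float(lam * ((1.0 - spec.a) * 0.5 * (beta**2).sum() + spec.a * beta.sum()))
    if kind is Penalty.HALF:
        return float(lam * np.sqrt(beta).sum())
    if kind is Penalty.LOGSUM:
        return float(lam * np.log(beta + spec.eps).sum())
    return float(sum(penalty_value(b, spec) for b in beta))
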
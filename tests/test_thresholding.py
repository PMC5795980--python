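"""Unit and property tests for the penalty thresholding operators.

The central correctness notion: each operator output must be the
minimizer (convex penalties) or a stationary point (non-convex
penalties) of the scalar objective g(b) = 1/2 (b - w)^2 + pen(b).
"""

import math

import numpy as np
import pytest

from logsumreg import (
    Penalty,
    PenaltySpec,
    half_threshold,
    len_threshold,
    logsum_threshold,
    mcp_threshold,
    penalty_value,
    penalty_total,
    scad_threshold,
    soft_threshold,
    threshold,
)
from oracles import grid_minimizer as _grid_minimizer
from oracles import pen_and_grad as _pen_and_grad
from oracles import random_specs as _random_specs

# ---------------------------------------------------------------------------
# frozen examples
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "func, args, expected",
    [
        (soft_threshold, (2, 1), 1.0),
        (soft_threshold, (-0.5, 1), 0.0),
        (soft_threshold, (-3, 0.25), -2.75),
        (len_threshold, (2, 1, 1.0), 1.0),
        (len_threshold, (2, 1, 0.0), 1.0),
        (len_threshold, (2, 1, 0.5), 1.0),
        (scad_threshold, (10, 0.4, 3.7), 10.0),
        (scad_threshold, (1.0, 0.4, 3.7), 0.7176470588235294),
        (scad_threshold, (0.3, 0.4, 3.7), 0.0),
        (mcp_threshold, (2, 0.4, 3), 2.0),
        (mcp_threshold, (1, 0.4, 3), 0.9),
        (mcp_threshold, (-1, 0.4, 3), -0.9),
        (half_threshold, (0.1, 1), 0.0),
        (half_threshold, (5, 0.5), 4.886910359828353),
        (logsum_threshold, (0.5, 1, 0.1), 0.0),
        (logsum_threshold, (3, 1, 0.1), 2.6342719282327014),
        (logsum_threshold, (-3, 1, 0.1), -2.6342719282327014),
    ],
)
def test_operator_examples(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=1e-12)


def test_half_is_stationary_point():
    """The nonzero half-threshold output solves b - w + lam/(2 sqrt(b)) = 0."""
    b = half_threshold(5, 0.5)
    assert abs(b - 5 + 0.5 / (2 * math.sqrt(b))) < 1e-10


def test_logsum_matches_grid_oracle():
    """The log-sum root is the dense-grid minimizer of its subproblem."""
    spec = PenaltySpec("logsum", lam=1.0, eps=0.1)
    b = logsum_threshold(3, 1, 0.1)
    assert abs(b - _grid_minimizer(3, spec, lo=1e-6, hi=4, step=1e-6)) < 2e-6


@pytest.mark.parametrize(
    "beta, spec, expected",
    [
        (0.0, PenaltySpec("l1", lam=1.0), 0.0),
        (0.0, PenaltySpec("logsum", lam=2.0, eps=1.0), 0.0),  # log(1) = 0
        (1.0, PenaltySpec("scad", lam=0.4, a=3.7), 0.9 / 2.7),
        (2.0, PenaltySpec("l1", lam=1.0), 2.0),
        (2.0, PenaltySpec("len", lam=1.0, a=0.5), 0.25 * 4 + 1.0),
        (2.0, PenaltySpec("half", lam=1.0), math.sqrt(2)),
    ],
)
def test_penalty_value_examples(beta, spec, expected):
    assert penalty_value(beta, spec) == pytest.approx(expected, abs=1e-12)


def test_scad_penalty_continuous_at_branch_points():
    spec = PenaltySpec("scad", lam=0.4, a=3.7)
    for knot in (0.4, 0.4 * 3.7):
        lo = penalty_value(knot - 1e-9, spec)
        hi = penalty_value(knot + 1e-9, spec)
        assert abs(lo - hi) < 1e-7


def test_mcp_penalty_continuous_at_branch_point():
    spec = PenaltySpec("mcp", lam=0.4, gamma=3.0)
    knot = 1.2
    assert abs(penalty_value(knot - 1e-9, spec) - penalty_value(knot + 1e-9, spec)) < 1e-7


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PenaltySpec("l1", lam=-0.1)
    with pytest.raises(ValueError):
        PenaltySpec("scad", lam=1.0, a=1.5)
    with pytest.raises(ValueError):
        PenaltySpec("mcp", lam=1.0, gamma=0.9)
    with pytest.raises(ValueError):
        PenaltySpec("len", lam=1.0, a=1.5)
    with pytest.raises(ValueError):
        PenaltySpec("logsum", lam=1.0, eps=2.0)
    # documented relaxation flag disables the eps < lam check
    PenaltySpec("logsum", lam=1.0, eps=2.0, allow_large_eps=True)
    b = logsum_threshold(3, 1, 1.5, allow_large_eps=True)
    assert abs((b - 3) + 1.0 / (b + 1.5)) < 1e-10  # still a stationary point
    with pytest.raises(ValueError):
        logsum_threshold(3, 1, 1.5)


def test_logsum_eps_default_is_tenth_of_lambda():
    spec = PenaltySpec("logsum").resolved(0.5)
    assert spec.eps == pytest.approx(0.05)


def test_logsum_exact_mode_prefers_zero_when_root_is_worse():
    """Near the dead zone the nonzero root can be a local-but-not-global
    minimum; exact mode returns the argmin of the subproblem."""
    lam, eps = 1.0, 0.1
    found = False
    for w in np.linspace(1.4, 2.2, 81):
        b = logsum_threshold(w, lam, eps)
        if b == 0.0:
            continue
        g_root = 0.5 * (b - w) ** 2 + lam * math.log(abs(b) + eps)
        g_zero = 0.5 * w**2 + lam * math.log(eps)
        if g_zero < g_root:
            found = True
            assert logsum_threshold(w, lam, eps, exact=True) == 0.0
    assert found, "expected at least one w where the root is not the global min"


# ---------------------------------------------------------------------------
# property tests over random draws
# ---------------------------------------------------------------------------


def test_stationarity_of_nonzero_outputs():
    """Any nonzero output solves (b - w) + pen'(b) = 0 to 1e-6 relative,
    across 1000 random (w, penalty, parameter) draws."""
    rng = np.random.default_rng(7)
    checked = 0
    for w, spec in _random_specs(rng, 1000):
        b = threshold(w, spec)
        if b == 0.0:
            continue
        _, grad = _pen_and_grad(spec)
        resid = (abs(b) - abs(w)) + grad(abs(b))
        assert abs(resid) < 1e-6 * max(1.0, abs(w)), (w, spec)
        checked += 1
    assert checked > 300


def test_convex_operators_match_grid_search():
    """L1 and elastic-net outputs equal the global grid-search minimizer."""
    rng = np.random.default_rng(8)
    for _ in range(60):
        w = float(rng.normal(0, 2))
        lam = float(rng.uniform(0.05, 1.5))
        a = float(rng.uniform(0, 1))
        for spec, val in [
            (PenaltySpec("l1", lam=lam), soft_threshold(w, lam)),
            (PenaltySpec("len", lam=lam, a=a), len_threshold(w, lam, a)),
        ]:
            oracle = _grid_minimizer(w, spec)
            assert abs(val - oracle) < 2e-4


def test_odd_symmetry_and_dead_zone():
    rng = np.random.default_rng(9)
    for w, spec in _random_specs(rng, 300):
        assert threshold(-w, spec) == pytest.approx(-threshold(w, spec), abs=1e-12)
        assert threshold(0.0, spec) == 0.0


def test_never_overshoots_the_input():
    """|f(w)| <= |w| for every operator (identity regions included)."""
    rng = np.random.default_rng(10)
    for w, spec in _random_specs(rng, 500):
        b = threshold(w, spec)
        assert abs(b) <= abs(w) + 1e-12


def test_logsum_dead_zone_monotone_in_lambda():
    """If log-sum kills w at lambda1, it also kills w at lambda2 > lambda1
    (eps held fixed)."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        w = float(rng.normal(0, 2))
        eps = float(rng.uniform(0.001, 0.05))
        lams = np.sort(rng.uniform(eps + 1e-6, 3.0, size=2))
        lo = logsum_threshold(w, float(lams[0]), eps)
        hi = logsum_threshold(w, float(lams[1]), eps)
        if lo == 0.0:
            assert hi == 0.0


def test_len_endpoints_reduce_to_soft_and_ridge():
    rng = np.random.default_rng(12)
    for _ in range(50):
        w = float(rng.normal(0, 3))
        lam = float(rng.uniform(0, 2))
        assert len_threshold(w, lam, 1.0) == pytest.approx(soft_threshold(w, lam))
        assert len_threshold(w, lam, 0.0) == pytest.approx(w / (1 + lam))


def test_penalty_total_matches_scalar_sum():
    rng = np.random.default_rng(13)
    beta = rng.normal(0, 2, size=7)
    for kind in ["l1", "len", "scad", "mcp", "half", "logsum"]:
        spec = PenaltySpec(kind).resolved(0.7)
        per = sum(penalty_value(b, spec) for b in beta)
        total = penalty_total(beta, spec)
        if spec.kind in (Penalty.SCAD, Penalty.MCP):
            assert total == pytest.approx(per, rel=1e-12)
        else:
            assert total == pytest.approx(spec.lam * per, rel=1e-12)
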
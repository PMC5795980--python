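"""Independent scalar oracles for the penalized subproblem.

These re-derive pen(b) and pen'(b) directly from the penalty
definitions and search the subproblem objective on a dense grid; they
never call the operators they are used to check.
"""

import math

import numpy as np

from logsumreg import Penalty, PenaltySpec


def pen_and_grad(spec: PenaltySpec):
    """Return pen(b) and pen'(b) for b > 0 from the penalty definitions."""
    spec = spec.resolved()
    lam = spec.lam
    k = spec.kind
    if k is Penalty.L1:
        return (lambda b: lam * b), (lambda b: lam)
    if k is Penalty.LEN:
        a = spec.a
        return (
            lambda b: lam * ((1 - a) * 0.5 * b * b + a * b),
            lambda b: lam * ((1 - a) * b + a),
        )
    if k is Penalty.SCAD:
        a = spec.a

        def pen(b):
            if b <= lam:
                return lam * b
            if b <= a * lam:
                return (a * lam * b - 0.5 * (b * b + lam * lam)) / (a - 1)
            return 0.5 * lam * lam * (a + 1)

        def grad(b):
            if b <= lam:
                return lam
            if b <= a * lam:
                return (a * lam - b) / (a - 1)
            return 0.0

        return pen, grad
    if k is Penalty.MCP:
        g = spec.gamma

        def pen(b):
            if b <= g * lam:
                return lam * b - b * b / (2 * g)
            return 0.5 * g * lam * lam

        def grad(b):
            if b <= g * lam:
                return lam - b / g
            return 0.0

        return pen, grad
    if k is Penalty.HALF:
        return (lambda b: lam * math.sqrt(b)), (lambda b: 0.5 * lam / math.sqrt(b))
    eps = spec.eps
    return (lambda b: lam * math.log(b + eps)), (lambda b: lam / (b + eps))


def grid_minimizer(w, spec, lo=None, hi=None, step=1e-4):
    """Dense grid-search minimizer of 1/2 (b - w)^2 + pen(|b|)."""
    pen, _ = pen_and_grad(spec)
    hi = hi if hi is not None else max(2 * abs(w), 1.0)
    lo = lo if lo is not None else -hi
    grid = np.arange(lo, hi + step, step)
    vals = 0.5 * (grid - w) ** 2 + np.array([pen(abs(b)) for b in grid])
    return grid[int(np.argmin(vals))]


def random_specs(rng, n_draws):
    """Random (w, spec) draws covering all six penalties."""
    for _ in range(n_draws):
        kind = rng.choice(["l1", "len", "scad", "mcp", "half", "logsum"])
        lam = float(rng.uniform(0.05, 2.0))
        spec = PenaltySpec(
            kind,
            lam=lam,
            a={"len": float(rng.uniform(0, 1)), "scad": float(rng.uniform(2.1, 5.0))}.get(kind),
            gamma=float(rng.uniform(1.2, 6.0)) if kind == "mcp" else None,
            eps=float(rng.uniform(0.01, 0.99) * lam) if kind == "logsum" else None,
        )
        yield float(rng.normal(0, 3)), spec
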
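"""Benchmark distributions with known decompositions, and random pmfs.

Four paradigmatic boolean gates with analytically known decompositions, the
Copy gate family (target = identity copy of the source triple, a purely
unique-information system), and flat-Dirichlet random joints for stochastic
validation.  :func:`deviation` is the percent error metric used to compare a
computed decomposition against a reference.
"""

from __future__ import annotations

import itertools
import numpy as np

from .distributions import JointDistribution, validate
from .model import PID_KEYS

__all__ = [
    "GATE_NAMES",
    "gate",
    "copy_gate",
    "random_joint",
    "deviation",
    "analytic_copy_reference",
    "analytic_gate_reference",
]

GATE_NAMES = ("XorDuplicate", "XorLoses", "XorMultiCoal", "AndDuplicate")


def gate(name: str) -> JointDistribution:
    """One of the paradigmatic gates, uniform over its input patterns.

    - ``XorDuplicate``: ``t = x XOR y``, ``z = x``, with x, y i.i.d. fair bits;
    - ``XorLoses``:     ``t = x XOR y`` and ``z = t``;
    - ``XorMultiCoal``: ``t = u XOR v XOR w`` with coalition sources
      ``x = (u, v)``, ``y = (u, w)``, ``z = (v, w)`` over i.i.d. bits;
    - ``AndDuplicate``: ``t = x AND y``, ``z = x``.
    """
    mass: dict = {}
    if name == "XorDuplicate":
        for x, y in itertools.product((0, 1), repeat=2):
            _acc(mass, (x ^ y, x, y, x), 0.25)
    elif name == "XorLoses":
        for x, y in itertools.product((0, 1), repeat=2):
            t = x ^ y
            _acc(mass, (t, x, y, t), 0.25)
    elif name == "XorMultiCoal":
        for u, v, w in itertools.product((0, 1), repeat=3):
            _acc(mass, (u ^ v ^ w, (u, v), (u, w), (v, w)), 0.125)
    elif name == "AndDuplicate":
        for x, y in itertools.product((0, 1), repeat=2):
            _acc(mass, (x & y, x, y, x), 0.25)
    else:
        raise ValueError(f"unknown gate {name!r}; choose one of {GATE_NAMES}")
    return validate(JointDistribution(mass))


def _acc(mass: dict, key: tuple, p: float) -> None:
    mass[key] = mass.get(key, 0.0) + p


def copy_gate(l: int, m: int, n: int) -> JointDistribution:
    """The Copy gate: (x, y, z) uniform over ``l * m * n`` triples and
    ``t = (x, y, z)`` rendered as a joined product symbol."""
    for name, v in (("l", l), ("m", m), ("n", n)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"invalid dimension {name}={v!r}: must be an integer >= 1")
    p = 1.0 / (l * m * n)
    mass = {
        (f"{x},{y},{z}", x, y, z): p
        for x, y, z in itertools.product(range(l), range(m), range(n))
    }
    return JointDistribution(mass)


def random_joint(dims: tuple[int, int, int, int], seed: int) -> JointDistribution:
    """A joint pmf of (T, X, Y, Z) drawn from the flat (unit-parameter)
    Dirichlet distribution over the full outcome simplex — the uniform
    measure on the probability space.  Deterministic given *seed*."""
    dims = tuple(int(v) for v in dims)
    if len(dims) != 4 or any(v < 1 for v in dims) or int(np.prod(dims)) < 2:
        raise ValueError(f"dims must be four positive integers with product >= 2, got {dims}")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(int(np.prod(dims))))
    outcomes = list(itertools.product(*(range(v) for v in dims)))
    return validate(JointDistribution(dict(zip(outcomes, map(float, p)))))


def _quantities(obj) -> dict[str, float]:
    if hasattr(obj, "params"):
        return {k: float(obj.params[k]) for k in PID_KEYS}
    return {k: float(obj[k]) for k in PID_KEYS}


def deviation(computed, reference) -> float:
    """Percent deviation: ``max`` over the eight decomposition quantities of
    ``100 * |computed - reference|``.  Arguments may be fitted results or
    plain mappings with the canonical keys."""
    c = _quantities(computed)
    r = _quantities(reference)
    return max(100.0 * abs(c[k] - r[k]) for k in PID_KEYS)


def analytic_copy_reference(l: int, m: int, n: int) -> dict[str, float]:
    """Exact decomposition of the Copy gate: with independent uniform
    sources copied into the target, each source contributes only unique
    information equal to its entropy ``log2`` of its alphabet size."""
    for v in (l, m, n):
        if v < 1:
            raise ValueError("dimensions must be >= 1")
    out = {k: 0.0 for k in PID_KEYS}
    out["UIX"] = float(np.log2(l))
    out["UIY"] = float(np.log2(m))
    out["UIZ"] = float(np.log2(n))
    return out


#: analytically derived gate decompositions (bits); AND entropy terms use
#: h(1/4) = 2 - (3/4) log2 3
_H14 = 2.0 - 0.75 * np.log2(3.0)            # = 0.811278124459...
_AND_MIN = _H14 - 0.5                        # = 0.311278124459...


def analytic_gate_reference(name: str) -> dict[str, float]:
    """Closed-form decompositions of the paradigmatic gates."""
    out = {k: 0.0 for k in PID_KEYS}
    if name == "XorDuplicate":
        out["CI"] = 1.0
    elif name == "XorLoses":
        out["UIZ"] = 1.0
    elif name == "XorMultiCoal":
        out["CI"] = 1.0
    elif name == "AndDuplicate":
        out["CI"] = 0.5
        out["SI"] = float(_AND_MIN)
    else:
        raise ValueError(f"unknown gate {name!r}; choose one of {GATE_NAMES}")
    return out
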
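"""Per-cascade tropical semirings and the homomorphism into ({0,1,∞}, min, +̄).

Every cascade ``l`` with dependent gene ``g`` carries a commutative semiring
on ``l ∪ {ε}``, where ε is the exogenous-environment element.  Addition picks
the "most informative" element (g absorbs, ε is neutral) and multiplication
has g neutral and collapses everything else to ε.  The map

    z: g ↦ 0,   ε ↦ ∞,   any other member ↦ 1

is a semiring homomorphism into the tropical semiring ({0,1,∞}, min, +̄)
where +̄ is truncated addition (0 neutral, ∞ absorbing, 1 +̄ 1 = ∞).  These
operations are what makes "deleting genes from a GRN" a quotient: removed
genes generate an ideal whose fiber is exactly what the restriction drops.

ε is a reserved sentinel object, so it can never collide with a gene symbol;
it is only used inside these operations and never stored in cascade sets.
"""

from __future__ import annotations

import math

from .cascades import Cascade

__all__ = ["EPSILON", "tropical_add", "tropical_mul", "z_map", "trop_add", "trop_mul"]


class _Epsilon:
    """The exogenous-environment element ε (module-level singleton)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ε"


EPSILON = _Epsilon()

#: The three tropical values. 0 is the dependent gene's image, 1 any other
#: member's, ∞ the environment's.
TROPICAL_VALUES = (0, 1, math.inf)


def _check_domain(x, ctx: Cascade):
    if ctx.dependent is None:
        raise ValueError("tropical operations need an oriented cascade context")
    if x is not EPSILON and x not in ctx.members:
        raise ValueError(f"{x!r} is not in the carrier of {ctx}")


def tropical_add(x, y, ctx: Cascade):
    """⊕ on the carrier of *ctx*: the dependent gene absorbs, ε is neutral."""
    _check_domain(x, ctx)
    _check_domain(y, ctx)
    g = ctx.dependent
    if x == g or y is EPSILON or x == y:
        return x
    # remaining cases: y == g, or x is EPSILON
    return y


def tropical_mul(x, y, ctx: Cascade):
    """⊙ on the carrier of *ctx*: the dependent gene is neutral, else ε."""
    _check_domain(x, ctx)
    _check_domain(y, ctx)
    g = ctx.dependent
    if y == g:
        return x
    if x == g:
        return y
    return EPSILON


def z_map(x, ctx: Cascade) -> float:
    """The homomorphism z: dependent ↦ 0, ε ↦ ∞, other member ↦ 1."""
    _check_domain(x, ctx)
    if x == ctx.dependent:
        return 0
    if x is EPSILON:
        return math.inf
    return 1


def trop_add(a: float, b: float) -> float:
    """Addition in the target semiring ({0,1,∞}, min, +̄)."""
    return min(a, b)


def trop_mul(a: float, b: float) -> float:
    """Truncated addition: 0 neutral, ∞ absorbing, 1 +̄ 1 = ∞."""
    if a == 0:
        return b
    if b == 0:
        return a
    return math.inf
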
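"""Strict separating hyperplanes of a signed support.

A hyperplane ``v . μ = a`` strictly separates the signed support of a
polynomial ``f`` when every positive exponent satisfies ``v . α <= a``, every
negative exponent satisfies ``v . β >= a``, and not all negative exponents lie
on the hyperplane.  Existence of such a hyperplane certifies that
``f^{-1}(R_<0)`` on the positive orthant is path connected and equals the
closure condition needed by the connectivity theorem.

Existence is decided by one exact linear program.  Writing ``d_α = (-α, 1)``
and ``d_β = (β, -1)`` as rows of ``D`` and ``c = Σ_β d_β``, a strict
separating hyperplane exists iff ``{x : D x >= 0, c . x >= 1}`` is feasible.
By Farkas' lemma the system is infeasible iff ``-c`` is a nonnegative
combination of the rows of ``D`` — in which case every point of the cone
``C = {D x >= 0}`` puts all negative exponents exactly on the hyperplane, so
no strict separator exists.  Both outcomes come with an exact certificate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from ._simplex import solve_eq_nonneg_cert
from .critpoly import SignedSupport

__all__ = ["Hyperplane", "find_strict_separating_hyperplane", "verify_hyperplane"]


@dataclass(frozen=True)
class Hyperplane:
    """A certificate ``(v, a)`` of strict separation."""

    v: tuple[Fraction, ...]
    a: Fraction

    def __str__(self) -> str:
        vec = ", ".join(str(c) for c in self.v)
        return f"({vec}) . mu = {self.a}"


def verify_hyperplane(hp: Hyperplane, ss: SignedSupport) -> bool:
    """Exact check of the three certificate conditions."""
    if len(hp.v) != ss.dimension or not any(hp.v):
        return False
    for alpha in ss.positive:
        if _dot(hp.v, alpha) > hp.a:
            return False
    slack = Fraction(0)
    for beta in ss.negative:
        d = _dot(hp.v, beta) - hp.a
        if d < 0:
            return False
        slack += d
    return slack > 0


def _dot(v, mu) -> Fraction:
    return sum((Fraction(vi) * mi for vi, mi in zip(v, mu)), Fraction(0))


def find_strict_separating_hyperplane(
    ss: SignedSupport,
) -> Optional[Hyperplane]:
    """Decide existence of a strict separating hyperplane, exactly.

    Returns a verified certificate, or ``None`` when provably no hyperplane
    exists.  Raises ``ValueError`` on an empty negative support (that case is
    a separate verdict for the caller: the polynomial is never negative).
    """
    if not ss.negative:
        raise ValueError("signed support has no negative exponents")
    k = ss.dimension
    pos = sorted(ss.positive)
    neg = sorted(ss.negative)
    # rows of D over variables (v, a)
    rows_d: list[tuple] = []
    for alpha in pos:
        rows_d.append(tuple(-x for x in alpha) + (1,))
    for beta in neg:
        rows_d.append(tuple(beta) + (-1,))
    c = [0] * (k + 1)
    for beta in neg:
        for i in range(k):
            c[i] += beta[i]
        c[k] -= 1

    # infeasibility of {Dx >= 0, c.x >= 1}  <=>  exists y >= 0 : D^T y = -c
    m = len(rows_d)
    dt_rows = [
        [Fraction(rows_d[j][i]) for j in range(m)] for i in range(k + 1)
    ]
    rhs = [Fraction(-ci) for ci in c]
    y, farkas = solve_eq_nonneg_cert(dt_rows, rhs)
    if y is not None:
        # -c in cone(rows of D): every point of C keeps sigma_- on the plane
        return None
    assert farkas is not None
    x = [-p for p in farkas]
    hp = Hyperplane(v=tuple(x[:k]), a=x[k])
    assert verify_hyperplane(hp, ss)
    return hp
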
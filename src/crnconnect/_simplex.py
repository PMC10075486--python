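"""Exact rational linear programming (phase-I revised simplex).

Everything here decides feasibility of systems ``A y = b, y >= 0`` over the
rationals, returning either a feasible point or a Farkas certificate of
infeasibility.  Bland's rule makes termination unconditional; all arithmetic
is :class:`fractions.Fraction`, so a sign is never decided in floating point.

The solver is deliberately small: the systems that arise here have few
equality constraints (at most the number of species, or the support dimension
plus one) but possibly very many nonnegative variables (one per exponent
vector of a critical polynomial), which is exactly the shape revised simplex
with early-exit Bland pricing handles well.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

__all__ = ["solve_eq_nonneg", "solve_eq_nonneg_cert"]

_ZERO = Fraction(0)
_ONE = Fraction(1)


def solve_eq_nonneg_cert(
    rows: Sequence[Sequence[Fraction]],
    b: Sequence[Fraction],
) -> tuple[Optional[list[Fraction]], Optional[list[Fraction]]]:
    """Find ``y >= 0`` with ``A y = b`` exactly.

    Returns ``(y, None)`` if feasible, else ``(None, pi)`` where ``pi`` is a
    Farkas certificate: ``pi . b > 0`` and ``pi . A_j <= 0`` for every column
    ``A_j``.
    """
    m = len(rows)
    if m == 0:
        return [], None
    nv = len(rows[0]) if rows else 0
    # columns of A, with rows flipped so that b >= 0
    flip = [(-1 if b[i] < 0 else 1) for i in range(m)]
    bb = [abs(Fraction(b[i])) for i in range(m)]
    cols = [
        tuple(flip[i] * Fraction(rows[i][j]) for i in range(m)) for j in range(nv)
    ]

    # phase-I: minimize sum of artificials; basis starts as the artificials
    basis = list(range(nv, nv + m))  # artificial i has index nv + i
    binv = [[_ONE if i == j else _ZERO for j in range(m)] for i in range(m)]
    xb = list(bb)

    def column(j: int) -> tuple:
        if j < nv:
            return cols[j]
        a = [_ZERO] * m
        a[j - nv] = _ONE
        return tuple(a)

    while True:
        # dual prices y = c_B B^{-1}; c is 1 on artificials, 0 on real vars
        y = [
            sum(binv[i][k] for i in range(m) if basis[i] >= nv)
            for k in range(m)
        ]
        enter = -1
        in_basis = set(basis)
        for j in range(nv):  # Bland: smallest index with negative reduced cost
            if j in in_basis:
                continue
            rc = -_dot(y, cols[j])
            if rc < 0:
                enter = j
                break
        if enter < 0:
            obj = sum(xb[i] for i in range(m) if basis[i] >= nv)
            if obj == 0:
                sol = [_ZERO] * nv
                for i, bi in enumerate(basis):
                    if bi < nv:
                        sol[bi] = xb[i]
                return sol, None
            # infeasible: pi with pi.b > 0, pi.A_j <= 0 (undo the row flips)
            pi = [flip[k] * y[k] for k in range(m)]
            return None, pi
        a = column(enter)
        d = [_dot(binv[i], a) for i in range(m)]
        leave = -1
        best: Optional[Fraction] = None
        for i in range(m):
            if d[i] > 0:
                ratio = xb[i] / d[i]
                if best is None or ratio < best or (
                    ratio == best and basis[i] < basis[leave]
                ):
                    best = ratio
                    leave = i
        if leave < 0:
            raise ArithmeticError("phase-I problem unbounded; inconsistent input")
        piv = d[leave]
        binv[leave] = [v / piv for v in binv[leave]]
        xb[leave] /= piv
        for i in range(m):
            if i != leave and d[i] != 0:
                f = d[i]
                row_l = binv[leave]
                binv[i] = [binv[i][k] - f * row_l[k] for k in range(m)]
                xb[i] -= f * xb[leave]
        basis[leave] = enter


def _dot(y: Sequence[Fraction], a: Sequence) -> Fraction:
    total = _ZERO
    for yi, ai in zip(y, a):
        if yi and ai:
            total += yi * ai
    return total


def solve_eq_nonneg(
    rows: Sequence[Sequence[Fraction]],
    b: Sequence[Fraction],
) -> Optional[list[Fraction]]:
    """Feasibility-only wrapper around :func:`solve_eq_nonneg_cert`."""
    sol, _ = solve_eq_nonneg_cert(rows, b)
    return sol
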
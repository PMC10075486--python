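"""Exact polyhedral geometry of the flux cone.

The flux cone of a network is ``ker(N) ∩ R_{>=0}^r``: the set of nonnegative
reaction-rate vectors at steady state.  Its extreme rays are exactly the
kernel vectors of minimal support, and every positive steady state's rate
vector is a strictly positive combination ``E λ`` of them, which is what makes
the convex parametrization work.

Rays are computed by the double description method over the rationals:
start from a basis of ``ker(N)`` (pure lineality) and intersect with one
coordinate halfspace at a time, combining positive/negative generator pairs.
No adjacency bookkeeping is used; instead the final generator set is filtered
by the minimal-support characterization of extremality, which is exact for
cones of the form subspace-intersect-orthant.  Output is canonical: primitive
integer rays, lexicographically sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd, lcm
from typing import Sequence

import sympy

__all__ = ["FluxCone", "extreme_rays", "is_consistent", "relative_interior_point"]


@dataclass(frozen=True)
class FluxCone:
    """Extreme rays of ``ker(N) ∩ R>=0^r``, as primitive integer columns."""

    rays: tuple[tuple[int, ...], ...]  # each ray has length r
    r: int

    @property
    def ell(self) -> int:
        return len(self.rays)

    @property
    def E(self) -> tuple[tuple[int, ...], ...]:
        """The r x ell matrix of extreme vectors (row-major)."""
        return tuple(
            tuple(ray[i] for ray in self.rays) for i in range(self.r)
        )


def _primitive(vec: Sequence[Fraction]) -> tuple[int, ...]:
    denom = lcm(*(Fraction(v).denominator for v in vec)) if vec else 1
    ints = [int(Fraction(v) * denom) for v in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    return tuple(ints)


def _dd_rays(lineality: list[list[Fraction]], constraints: list[list[Fraction]]):
    """Double description: rays and lineality of ``{x : a.x >= 0 for a}``
    within the affine hull spanned by ``lineality``."""
    lin = [list(v) for v in lineality]
    rays: list[list[Fraction]] = []
    for a in constraints:
        # if the constraint cuts the lineality space, split off one direction
        pivot = None
        for idx, l in enumerate(lin):
            val = sum(ai * li for ai, li in zip(a, l))
            if val != 0:
                pivot = (idx, val)
                break
        if pivot is not None:
            idx, val = pivot
            l0 = [li / val for li in lin[idx]]  # a . l0 == 1
            new_lin = []
            for k, l in enumerate(lin):
                if k == idx:
                    continue
                v = sum(ai * li for ai, li in zip(a, l))
                new_lin.append([li - v * l0i for li, l0i in zip(l, l0)])
            for i, ray in enumerate(rays):
                v = sum(ai * ri for ai, ri in zip(a, ray))
                rays[i] = [ri - v * l0i for ri, l0i in zip(ray, l0)]
            rays.append(l0)
            lin = new_lin
            continue
        vals = [sum(ai * ri for ai, ri in zip(a, ray)) for ray in rays]
        pos = [r for r, v in zip(rays, vals) if v > 0]
        zero = [r for r, v in zip(rays, vals) if v == 0]
        neg = [(r, v) for r, v in zip(rays, vals) if v < 0]
        pvals = [v for v in vals if v > 0]
        combos: list[list[Fraction]] = []
        seen: set[tuple[int, ...]] = set()
        for p, pv in zip(pos, pvals):
            for nvec, nv in neg:
                # pv * n - nv * p is a nonnegative combination on the hyperplane
                w = [pv * ni - nv * pi for ni, pi in zip(nvec, p)]
                key = _primitive(w)
                if any(key) and key not in seen:
                    seen.add(key)
                    combos.append([Fraction(x) for x in key])
        rays = pos + zero + combos
    return rays, lin


def extreme_rays(N: Sequence[Sequence[int]]) -> FluxCone:
    """Compute the extreme rays of ``ker(N) ∩ R>=0^r``.

    ``N`` must have no zero column.  The result is unique: rays are primitive
    integer vectors of minimal support, sorted lexicographically.
    """
    n = len(N)
    r = len(N[0]) if n else 0
    for j in range(r):
        if all(N[i][j] == 0 for i in range(n)):
            raise ValueError(f"column {j + 1} of N is zero")
    kernel = sympy.Matrix(N).nullspace()
    if not kernel:
        return FluxCone(rays=(), r=r)
    lineality = [
        [Fraction(int(v.p), int(v.q)) for v in vec] for vec in kernel
    ]
    constraints = [
        [Fraction(1) if j == i else Fraction(0) for j in range(r)]
        for i in range(r)
    ]
    rays, lin = _dd_rays(lineality, constraints)
    assert not lin, "flux cone must be pointed"
    # extremality = minimal support; prune generated non-extreme combinations
    prim = {_primitive(ray) for ray in rays}
    prim.discard((0,) * r)
    supports = {v: frozenset(i for i, x in enumerate(v) if x) for v in prim}
    minimal = [
        v
        for v in prim
        if not any(
            supports[u] < supports[v] for u in prim if u != v
        )
    ]
    # equal supports would mean a >1-dimensional restricted kernel; dedupe
    by_support: dict[frozenset, tuple[int, ...]] = {}
    for v in minimal:
        by_support.setdefault(supports[v], v)
    out = sorted(by_support.values())
    assert all(all(x >= 0 for x in v) for v in out)
    return FluxCone(rays=tuple(out), r=r)


def is_consistent(fc: FluxCone) -> bool:
    """True iff the ray matrix has no zero row.

    A zero row of ``E`` means some reaction carries zero flux in every steady
    state, equivalently ``ker(N)`` has no strictly positive vector and the
    network admits no positive steady state at all.
    """
    if fc.ell == 0:
        return False
    return all(any(ray[i] for ray in fc.rays) for i in range(fc.r))


def relative_interior_point(
    inequalities: Sequence[Sequence[Fraction]],
) -> tuple[Fraction, ...]:
    """A point in the relative interior of ``C = {x : a.x >= 0 for each a}``.

    Computed from the generator representation: the sum of all extreme rays
    of ``C`` (with zero lineality component) lies in the relative interior.
    Returns the zero vector iff the pointed part of ``C`` is trivial.
    """
    ineqs = [list(map(Fraction, a)) for a in inequalities]
    if not ineqs:
        raise ValueError("need at least one inequality to fix the dimension")
    k = len(ineqs[0])
    identity = [
        [Fraction(1) if j == i else Fraction(0) for j in range(k)]
        for i in range(k)
    ]
    rays, _lin = _dd_rays(identity, ineqs)
    total = [Fraction(0)] * k
    seen: set[tuple[int, ...]] = set()
    for ray in rays:
        key = _primitive(ray)
        if not any(key) or key in seen:
            continue
        seen.add(key)
        for i in range(k):
            total[i] += key[i]
    return tuple(total)
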
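"""Siphons and the exclusion of relevant boundary steady states.

A siphon is a set of species ``Z`` such that every reaction producing a
species of ``Z`` has some species of ``Z`` in its reactant: once all species
of ``Z`` are absent they can never be produced again.  "Producing" is gross
production (``b_ij > 0``), the usual Petri-net convention, so a species that
is both consumed and produced by a reaction counts as produced.

Boundary steady states on compatibility classes that meet the positive
orthant are excluded when for every minimal siphon ``Z`` there is a
conservation vector ``w >= 0`` with ``w N = 0`` whose positive entries are
exactly ``Z``.  This is sufficient, not necessary: a failure leaves the
question open.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from ._simplex import solve_eq_nonneg
from .network import ReactionNetwork, StoichiometricData

__all__ = [
    "Siphon",
    "SiphonEnumerationBound",
    "minimal_siphons",
    "siphon_witness",
    "excludes_boundary_steady_states",
]

DEFAULT_BOUND = 22


class SiphonEnumerationBound(RuntimeError):
    """Too many species for in-process siphon enumeration."""


@dataclass(frozen=True)
class Siphon:
    """An inclusion-minimal siphon, as a frozenset of species indices."""

    members: frozenset

    def names(self, net: ReactionNetwork) -> tuple[str, ...]:
        return tuple(net.species[i] for i in sorted(self.members))


def is_siphon(net: ReactionNetwork, members: frozenset) -> bool:
    """Check the defining predicate directly."""
    if not members:
        return False
    for reactant, product, _ in net.reactions:
        if any(product[i] > 0 for i in members):
            if not any(reactant[i] > 0 for i in members):
                return False
    return True


def minimal_siphons(
    net: ReactionNetwork, bound: int = DEFAULT_BOUND
) -> list[Siphon]:
    """All inclusion-minimal siphons, sorted by size then lexicographically.

    Depth-first search over species subsets: starting from each singleton,
    repeatedly pick an unmet production obligation and branch over the
    reactant species that could satisfy it.  Branches that already contain a
    previously completed siphon cannot lead to a new minimal one and are
    pruned.  Raises :class:`SiphonEnumerationBound` when the species count
    exceeds ``bound``.
    """
    n = net.n
    if n > bound:
        raise SiphonEnumerationBound(
            f"{n} species exceeds the enumeration bound {bound}"
        )
    producers: list[list[int]] = [[] for _ in range(n)]
    react_supp: list[frozenset] = []
    for j, (reactant, product, _) in enumerate(net.reactions):
        react_supp.append(frozenset(i for i in range(n) if reactant[i] > 0))
        for i in range(n):
            if product[i] > 0:
                producers[i].append(j)

    found: list[frozenset] = []
    visited: set[frozenset] = set()

    def dfs(Z: frozenset) -> None:
        if Z in visited:
            return
        visited.add(Z)
        if any(S < Z for S in found):
            return
        unmet: Optional[tuple[int, int]] = None
        for z in Z:
            for j in producers[z]:
                if not (react_supp[j] & Z):
                    unmet = (z, j)
                    break
            if unmet:
                break
        if unmet is None:
            if Z not in found:
                found.append(Z)
            return
        _, j = unmet
        if not react_supp[j]:  # produced from the empty complex: dead branch
            return
        for w in sorted(react_supp[j]):
            dfs(Z | {w})

    for i in range(n):
        dfs(frozenset({i}))

    minimal = [Z for Z in found if not any(S < Z for S in found)]
    minimal = sorted(set(minimal), key=lambda Z: (len(Z), sorted(Z)))
    result = [Siphon(members=Z) for Z in minimal]
    assert all(is_siphon(net, s.members) for s in result)
    return result


def siphon_witness(
    sd: StoichiometricData, members: frozenset
) -> Optional[tuple[Fraction, ...]]:
    """Find ``w >= 0`` with ``w N = 0`` positive exactly on ``members``.

    Entries off the siphon are fixed to zero and entries on it to ``1 + u``
    with ``u >= 0``; feasibility is decided by exact rational simplex.
    """
    idx = sorted(members)
    rows = [[Fraction(sd.N[i][j]) for i in idx] for j in range(sd.r)]
    rhs = [-sum(Fraction(sd.N[i][j]) for i in idx) for j in range(sd.r)]
    u = solve_eq_nonneg(rows, rhs)
    if u is None:
        return None
    w = [Fraction(0)] * sd.n
    for pos, i in enumerate(idx):
        w[i] = Fraction(1) + u[pos]
    return tuple(w)


def excludes_boundary_steady_states(
    net: ReactionNetwork,
    sd: StoichiometricData,
    bound: int = DEFAULT_BOUND,
) -> bool:
    """True iff every minimal siphon carries a conservation witness.

    A ``True`` certifies that no compatibility class meeting the positive
    orthant contains a boundary steady state.  ``False`` is inconclusive.
    """
    for siphon in minimal_siphons(net, bound=bound):
        if siphon_witness(sd, siphon.members) is None:
            return False
    return True
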
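"""Mass-action reaction networks and their stoichiometric objects.

A reaction network is a list of reactions ``a1 X1 + ... + an Xn -> b1 X1 + ...``
with nonnegative integer coefficients over a fixed ordered species list.  From
the network we derive, in exact rational arithmetic:

* the stoichiometric matrix ``N`` (net production, one column per reaction),
* the reactant-coefficient matrix ``A``,
* the rank ``s`` of ``N``,
* a canonical matrix of conservation relations ``W`` — the reduced
  row-echelon basis of the left kernel of ``N`` — with its pivot indices.

``W`` is canonical so that the pivot rows replaced when building the critical
matrix are well defined.  Floating point is never used: conservativity and all
later sign decisions are made over the rationals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import sympy

from ._simplex import solve_eq_nonneg

__all__ = [
    "ReactionNetwork",
    "StoichiometricData",
    "ParseError",
    "parse_network",
    "serialize",
    "stoichiometry",
    "is_conservative",
]


class ParseError(ValueError):
    """Raised when a reaction-list string cannot be parsed."""


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered list of species and of reactions.

    Each reaction is a pair of complexes (reactant, product), stored as tuples
    of nonnegative integer coefficients over ``species``, plus a rate-constant
    label.  Reactant and product must differ.
    """

    species: tuple[str, ...]
    reactions: tuple[tuple[tuple[int, ...], tuple[int, ...], str], ...]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        n = len(self.species)
        for reactant, product, label in self.reactions:
            if len(reactant) != n or len(product) != n:
                raise ValueError(f"reaction {label}: wrong coefficient length")
            if any(c < 0 or int(c) != c for c in reactant + product):
                raise ValueError(f"reaction {label}: coefficients must be nonnegative integers")
            if reactant == product:
                raise ValueError(f"reaction {label}: reactant equals product")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, lab in self.reactions)


@dataclass(frozen=True)
class StoichiometricData:
    """Stoichiometric matrix, reactant matrix and conservation relations.

    ``N = B - A`` columnwise, ``s = rank(N)``, ``W`` is the reduced
    row-echelon basis of the left kernel of ``N`` (``W N = 0``), ``pivots``
    the column index of the first nonzero entry of each row of ``W``.
    """

    N: tuple[tuple[int, ...], ...]
    A: tuple[tuple[int, ...], ...]
    s: int
    W: tuple[tuple[Fraction, ...], ...]
    pivots: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.N)

    @property
    def r(self) -> int:
        return len(self.N[0]) if self.N else 0


_TERM_RE = re.compile(r"^(?:(\d+)\s*)?([A-Za-z_][A-Za-z0-9_']*)$")


def _parse_complex(text: str, line_no: int, line: str) -> dict[str, int]:
    text = text.strip()
    if text == "0":
        return {}
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"line {line_no}: malformed term {term!r} in {line!r}")
        count = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        coeffs[name] = coeffs.get(name, 0) + count
    return coeffs


def parse_network(
    text: str,
    labels: Optional[Sequence[str]] = None,
) -> ReactionNetwork:
    """Parse a plain-text reaction list into a :class:`ReactionNetwork`.

    Format: one reaction per line, ``<complex> -> <complex>`` or
    ``<complex> <-> <complex>``; complexes are ``+``-separated ``[int] Name``
    terms, ``0`` is the empty complex; ``#`` starts a comment; an optional
    ``species: A B C`` header pins the species order.  Reversible lines expand
    to forward then reverse reactions with consecutive labels.  Default labels
    are ``k1..kr`` in expanded order; ``labels`` overrides them.
    """
    species_order: list[str] = []
    seen: set[str] = set()
    fixed_order = False
    raw: list[tuple[dict[str, int], dict[str, int]]] = []

    for line_no, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if stripped.lower().startswith("species:"):
            names = stripped.split(":", 1)[1].split()
            if len(set(names)) != len(names):
                raise ParseError(f"line {line_no}: duplicate species in header")
            species_order = list(names)
            seen = set(names)
            fixed_order = True
            continue
        if "<->" in stripped:
            lhs, rhs = stripped.split("<->", 1)
            reversible = True
        elif "->" in stripped:
            lhs, rhs = stripped.split("->", 1)
            reversible = False
        else:
            raise ParseError(f"line {line_no}: no arrow in {stripped!r}")
        reactant = _parse_complex(lhs, line_no, stripped)
        product = _parse_complex(rhs, line_no, stripped)
        if reactant == product:
            raise ParseError(f"line {line_no}: reactant equals product in {stripped!r}")
        for name in list(reactant) + list(product):
            if name not in seen:
                if fixed_order:
                    raise ParseError(f"line {line_no}: species {name!r} not in header")
                seen.add(name)
                species_order.append(name)
        raw.append((reactant, product))
        if reversible:
            raw.append((product, reactant))

    if labels is None:
        labels = [f"k{i + 1}" for i in range(len(raw))]
    if len(labels) != len(raw):
        raise ParseError(f"expected {len(raw)} labels, got {len(labels)}")

    species = tuple(species_order)
    reactions = tuple(
        (
            tuple(reactant.get(sp, 0) for sp in species),
            tuple(product.get(sp, 0) for sp in species),
            lab,
        )
        for (reactant, product), lab in zip(raw, labels)
    )
    return ReactionNetwork(species=species, reactions=reactions)


def _format_complex(coeffs: tuple[int, ...], species: tuple[str, ...]) -> str:
    terms = []
    for c, sp in zip(coeffs, species):
        if c == 0:
            continue
        terms.append(sp if c == 1 else f"{c} {sp}")
    return " + ".join(terms) if terms else "0"


def serialize(net: ReactionNetwork) -> str:
    """Write a network back to the plain-text reaction format.

    Every reaction is written on its own (irreversible) line, preceded by a
    ``species:`` header so that re-parsing reproduces the same ordering.
    """
    lines = ["species: " + " ".join(net.species)]
    for reactant, product, _ in net.reactions:
        lines.append(
            f"{_format_complex(reactant, net.species)} -> "
            f"{_format_complex(product, net.species)}"
        )
    return "\n".join(lines) + "\n"


def stoichiometry(net: ReactionNetwork) -> StoichiometricData:
    """Derive ``N``, ``A``, ``s``, ``W`` and the pivot indices of ``W``."""
    n, r = net.n, net.r
    N = tuple(
        tuple(net.reactions[j][1][i] - net.reactions[j][0][i] for j in range(r))
        for i in range(n)
    )
    A = tuple(tuple(net.reactions[j][0][i] for j in range(r)) for i in range(n))

    M = sympy.Matrix(N)
    s = M.rank()
    # left kernel = nullspace of N^T; rref makes the basis canonical
    basis = M.T.nullspace()
    if basis:
        K = sympy.Matrix.hstack(*basis).T
        R, piv = K.rref()
        W = tuple(
            tuple(Fraction(int(R[i, j].p), int(R[i, j].q)) for j in range(n))
            for i in range(R.rows)
        )
        pivots = tuple(int(p) for p in piv)
    else:
        W = ()
        pivots = ()
    assert len(W) == n - s
    return StoichiometricData(N=N, A=A, s=s, W=W, pivots=pivots)


def is_conservative(sd: StoichiometricData) -> tuple[bool, Optional[tuple[Fraction, ...]]]:
    """Decide whether some strictly positive ``w`` satisfies ``w N = 0``.

    By scale invariance this is the exact feasibility problem
    ``w N = 0, w_i >= 1``; substituting ``w = 1 + u`` with ``u >= 0`` turns it
    into ``N^T u = -N^T 1``, solved by exact rational simplex.  Returns the
    witness on success.
    """
    n, r = sd.n, sd.r
    if n == 0:
        return True, ()
    A_eq = [[Fraction(sd.N[i][j]) for i in range(n)] for j in range(r)]
    b_eq = [-sum(Fraction(sd.N[i][j]) for i in range(n)) for j in range(r)]
    u = solve_eq_nonneg(A_eq, b_eq)
    if u is None:
        return False, None
    w = tuple(Fraction(1) + ui for ui in u)
    assert all(sum(wi * sd.N[i][j] for i, wi in enumerate(w)) == 0 for j in range(r))
    return True, w
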
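"""Independent brute-force oracles used to validate the main algorithms.

Everything here is deliberately naive (exhaustive enumeration, direct
definitions) and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import sympy

from crnconnect.network import ReactionNetwork


def brute_force_minimal_siphons(net: ReactionNetwork) -> list[frozenset]:
    """All inclusion-minimal siphons by filtering every nonempty subset."""
    n = net.n
    siphons = []
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            Z = frozenset(combo)
            ok = True
            for reactant, product, _ in net.reactions:
                if any(product[i] > 0 for i in Z) and not any(
                    reactant[i] > 0 for i in Z
                ):
                    ok = False
                    break
            if ok:
                siphons.append(Z)
    return sorted(
        (Z for Z in siphons if not any(S < Z for S in siphons)),
        key=lambda Z: (len(Z), sorted(Z)),
    )


def brute_force_extreme_rays(N) -> list[tuple[int, ...]]:
    """Minimal-support kernel vectors by exhaustive support enumeration.

    For each candidate support S the restricted kernel must be
    one-dimensional with a sign-definite generator of full support S; the
    minimal such supports carry the extreme rays.
    """
    n = len(N)
    r = len(N[0])
    M = sympy.Matrix(N)
    candidates: dict[frozenset, tuple[int, ...]] = {}
    for size in range(1, r + 1):
        for combo in itertools.combinations(range(r), size):
            S = frozenset(combo)
            if any(T <= S for T in candidates):
                continue
            sub = M[:, list(combo)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            gen = [Fraction(int(v.p), int(v.q)) for v in null[0]]
            if any(v == 0 for v in gen):
                continue
            if all(v > 0 for v in gen) or all(v < 0 for v in gen):
                if gen[0] < 0:
                    gen = [-v for v in gen]
                denom = 1
                for v in gen:
                    denom = denom * v.denominator // _gcd(denom, v.denominator)
                ints = [int(v * denom) for v in gen]
                g = 0
                for v in ints:
                    g = _gcd(g, v)
                ints = [v // g for v in ints]
                full = [0] * r
                for pos, j in enumerate(combo):
                    full[j] = ints[pos]
                candidates[S] = tuple(full)
    minimal = [
        v for S, v in candidates.items() if not any(T < S for T in candidates)
    ]
    return sorted(minimal)


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return abs(a)


def brute_force_positive_left_kernel(W_rows, n: int, grid: int = 4) -> bool:
    """Search small nonnegative integer combinations of the rows of W for a
    strictly positive vector (conservativity witness)."""
    rows = [list(map(Fraction, row)) for row in W_rows]
    if not rows:
        return False
    for coeffs in itertools.product(range(grid + 1), repeat=len(rows)):
        if not any(coeffs):
            continue
        vec = [
            sum(c * row[i] for c, row in zip(coeffs, rows)) for i in range(n)
        ]
        if all(v > 0 for v in vec):
            return True
    return False


def grid_search_hyperplane(positive, negative, bound: int = 6):
    """Search integer (v, a) with entries in [-bound, bound] for a strict
    separating hyperplane of a signed support in low dimension."""
    dim = len(next(iter(positive | negative)))
    rng = range(-bound, bound + 1)
    for v in itertools.product(rng, repeat=dim):
        if not any(v):
            continue
        for a in rng:
            if all(sum(vi * x for vi, x in zip(v, alpha)) <= a for alpha in positive) and all(
                sum(vi * x for vi, x in zip(v, beta)) >= a for beta in negative
            ):
                if sum(
                    sum(vi * x for vi, x in zip(v, beta)) - a for beta in negative
                ) > 0:
                    return v, a
    return None
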
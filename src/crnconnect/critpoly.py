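"""The critical polynomial of a network under the convex parametrization.

For a consistent network the positive part of the steady-state incidence set
is the image of ``Ψ(h, λ) = (1/h, diag(h^{A_1},...,h^{A_r}) E λ)``.  Along Ψ
the Jacobian of the mass-action vector field is

    J~(h, λ) = N diag(Eλ) A^T diag(h),

and replacing row ``i_j`` (the pivot of the ``j``-th conservation relation) by
the ``j``-th row of ``W`` gives ``M~(h, λ)``.  The critical polynomial is
``(-1)^s det M~``: wherever it is negative on the positive orthant, the
corresponding ``(κ, c)`` enables multistationarity; wherever it is positive
for a whole compatibility class, multistationarity is excluded.

Determinants are expanded exactly over the rationals with a dynamic program
over column subsets (a memoized Laplace expansion), with exponent vectors
packed into integers so monomial products are single integer additions.  A
term budget converts a blow-up into a clean error instead of exhausting
memory, signalling that the network should be reduced first.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import sympy

from .fluxcone import FluxCone
from .network import ReactionNetwork, StoichiometricData

__all__ = [
    "CriticalPolynomial",
    "SignedSupport",
    "TermBudgetExceeded",
    "build_convex_matrix",
    "critical_polynomial",
    "signed_support",
    "evaluate_g",
]

Number = Union[int, Fraction]

_BITS = 6  # per-variable exponent field; degrees are bounded by s <= 63
_MASK = (1 << _BITS) - 1


class TermBudgetExceeded(RuntimeError):
    """The symbolic determinant grew past the configured term budget.

    Raised instead of exhausting memory; the usual remedy is to apply the
    reverse-reaction network reduction and recompute.
    """


def _pack(exps: Sequence[int]) -> int:
    key = 0
    for e in reversed(exps):
        key = (key << _BITS) | e
    return key


def _unpack(key: int, nvars: int) -> tuple[int, ...]:
    out = []
    for _ in range(nvars):
        out.append(key & _MASK)
        key >>= _BITS
    return tuple(out)


@dataclass(frozen=True)
class Poly:
    """Sparse exact-coefficient polynomial in h_1..h_n, λ_1..λ_ell.

    ``terms`` maps packed exponent keys to nonzero rational coefficients.
    """

    terms: dict
    n: int
    ell: int

    @property
    def nvars(self) -> int:
        return self.n + self.ell

    def __len__(self) -> int:
        return len(self.terms)

    def monomials(self) -> dict[tuple[int, ...], Number]:
        return {_unpack(k, self.nvars): c for k, c in self.terms.items()}

    def evaluate(self, point: Sequence[Number]) -> Fraction:
        if len(point) != self.nvars:
            raise ValueError("wrong number of coordinates")
        # power tables keep integer inputs in integer arithmetic throughout
        maxdeg = [0] * self.nvars
        for key in self.terms:
            k = key
            i = 0
            while k:
                e = k & _MASK
                if e > maxdeg[i]:
                    maxdeg[i] = e
                k >>= _BITS
                i += 1
        pows = [
            [x**e for e in range(d + 1)] if d else None
            for x, d in zip(point, maxdeg)
        ]
        total = 0
        for key, coef in self.terms.items():
            val = coef
            k = key
            i = 0
            while k:
                e = k & _MASK
                if e:
                    val = val * pows[i][e]
                k >>= _BITS
                i += 1
            total = total + val
        return Fraction(total)

    def as_sympy(self) -> sympy.Expr:
        hs = sympy.symbols(f"h1:{self.n + 1}") if self.n else ()
        ls = sympy.symbols(f"lam1:{self.ell + 1}") if self.ell else ()
        gens = list(hs) + list(ls)
        expr = sympy.Integer(0)
        for exps, coef in self.monomials().items():
            term = sympy.Rational(coef)
            for g, e in zip(gens, exps):
                if e:
                    term *= g**e
            expr += term
        return expr


@dataclass(frozen=True)
class CriticalPolynomial:
    """``(-1)^s det M~(h, λ)`` with exact rational coefficients."""

    poly: Poly
    n: int
    ell: int
    s: int


@dataclass(frozen=True)
class SignedSupport:
    """Exponent vectors of a polynomial split by coefficient sign."""

    positive: frozenset
    negative: frozenset
    dimension: int


def build_convex_matrix(
    sd: StoichiometricData, fc: FluxCone
) -> list[list[Poly]]:
    """Assemble ``M~(h, λ)``: ``N diag(Eλ) A^T diag(h)`` with the pivot rows
    replaced by the rows of ``W``.

    Entry ``(i, j)`` of the Jacobian part is
    ``h_j * sum_k N[i,k] A[j,k] (Eλ)_k``, linear in each variable block.
    """
    n, r = sd.n, sd.r
    ell = fc.ell
    if ell == 0:
        raise ValueError("flux cone is trivial (ell = 0); no convex parametrization")
    E = fc.E  # r x ell

    def jac_entry(i: int, j: int) -> Poly:
        lam_coeffs = [0] * ell
        for k in range(r):
            cik = sd.N[i][k] * sd.A[j][k]
            if cik:
                for m in range(ell):
                    if E[k][m]:
                        lam_coeffs[m] += cik * E[k][m]
        terms = {}
        for m, c in enumerate(lam_coeffs):
            if c:
                exps = [0] * (n + ell)
                exps[j] = 1
                exps[n + m] = 1
                terms[_pack(exps)] = c
        return Poly(terms=terms, n=n, ell=ell)

    rows: list[list[Poly]] = [
        [jac_entry(i, j) for j in range(n)] for i in range(n)
    ]
    for jrow, pivot in enumerate(sd.pivots):
        rows[pivot] = [
            _const(sd.W[jrow][j], n, ell) for j in range(n)
        ]
    return rows


def _const(c: Number, n: int, ell: int) -> Poly:
    c = Fraction(c)
    if c == 0:
        return Poly(terms={}, n=n, ell=ell)
    if c.denominator == 1:
        c = int(c)
    return Poly(terms={0: c}, n=n, ell=ell)


def _det(matrix: list[list[Poly]], term_budget: Optional[int]) -> Poly:
    """Exact determinant by subset dynamic programming.

    Rows are processed sparsest-first (tracking the permutation sign); the
    state maps used-column bitmasks to partial-minor polynomials.
    """
    n = len(matrix)
    if n == 0:
        raise ValueError("empty matrix")
    proto = matrix[0][0]

    entries = [
        [(j, row[j].terms) for j in range(n) if row[j].terms]
        for row in matrix
    ]
    order = sorted(range(n), key=lambda i: (len(entries[i]), i))
    perm_sign = _permutation_sign(order)

    states: dict[int, dict] = {0: {0: 1}}
    for i in order:
        new_states: dict[int, dict] = {}
        row = entries[i]
        for mask, poly in states.items():
            for j, eterms in row:
                bit = 1 << j
                if mask & bit:
                    continue
                sign = -1 if (mask >> (j + 1)).bit_count() & 1 else 1
                tgt = new_states.setdefault(mask | bit, {})
                for ekey, ecoef in eterms.items():
                    ec = ecoef if sign > 0 else -ecoef
                    for pkey, pcoef in poly.items():
                        k = pkey + ekey
                        cur = tgt.get(k)
                        if cur is None:
                            tgt[k] = pcoef * ec
                        else:
                            cur = cur + pcoef * ec
                            if cur:
                                tgt[k] = cur
                            else:
                                del tgt[k]
        states = {m: t for m, t in new_states.items() if t}
        if term_budget is not None:
            size = sum(len(t) for t in states.values())
            if size > term_budget:
                raise TermBudgetExceeded(
                    f"determinant exceeded {term_budget} terms at row {i + 1}; "
                    "consider reducing the network first"
                )
        if not states:
            break
    full = (1 << n) - 1
    result = states.get(full, {})
    if perm_sign < 0:
        result = {k: -c for k, c in result.items()}
    return Poly(terms=result, n=proto.n, ell=proto.ell)


def _permutation_sign(perm: Sequence[int]) -> int:
    inv = 0
    for a in range(len(perm)):
        for b in range(a + 1, len(perm)):
            if perm[a] > perm[b]:
                inv += 1
    return -1 if inv & 1 else 1


def critical_polynomial(
    sd: StoichiometricData,
    fc: FluxCone,
    term_budget: Optional[int] = 4_000_000,
) -> CriticalPolynomial:
    """Expand ``(-1)^s det M~(h, λ)`` exactly.

    Deterministic for a fixed species/reaction/ray ordering.  Raises
    :class:`TermBudgetExceeded` if the expansion grows past ``term_budget``
    monomials (``None`` disables the budget).
    """
    matrix = build_convex_matrix(sd, fc)
    det = _det(matrix, term_budget)
    if sd.s % 2:
        det = Poly(terms={k: -c for k, c in det.terms.items()}, n=det.n, ell=det.ell)
    return CriticalPolynomial(poly=det, n=sd.n, ell=fc.ell, s=sd.s)


def signed_support(cp: CriticalPolynomial) -> SignedSupport:
    """Partition the support of the critical polynomial by coefficient sign."""
    pos, neg = [], []
    nvars = cp.poly.nvars
    for key, coef in cp.poly.terms.items():
        (pos if coef > 0 else neg).append(_unpack(key, nvars))
    return SignedSupport(
        positive=frozenset(pos), negative=frozenset(neg), dimension=nvars
    )


def convex_parametrization_point(
    sd: StoichiometricData,
    fc: FluxCone,
    h: Sequence[Number],
    lam: Sequence[Number],
) -> tuple[tuple[Fraction, ...], tuple[Fraction, ...]]:
    """Evaluate ``Ψ(h, λ) = (x, κ)`` with ``x = 1/h`` and
    ``κ_j = (Eλ)_j h^{A_j}``, so that ``v_κ(x) = Eλ`` lies in the flux cone
    and ``(x, κ)`` is a positive steady-state pair."""
    n, r = sd.n, sd.r
    hq = [Fraction(v) for v in h]
    lq = [Fraction(v) for v in lam]
    if len(hq) != n or len(lq) != fc.ell:
        raise ValueError("dimension mismatch")
    if any(v <= 0 for v in hq) or any(v <= 0 for v in lq):
        raise ValueError("h and lambda must be strictly positive")
    x = tuple(1 / v for v in hq)
    E = fc.E
    kappa = []
    for j in range(r):
        v = sum(E[j][m] * lq[m] for m in range(fc.ell))
        for i in range(n):
            a = sd.A[i][j]
            if a:
                v *= hq[i] ** a
        kappa.append(v)
    return x, tuple(kappa)


def evaluate_g(
    net: ReactionNetwork,
    sd: StoichiometricData,
    x: Sequence[Number],
    kappa: Sequence[Number],
) -> Fraction:
    """The sign function of the multistationarity criterion:
    ``(-1)^s det M_κ(x)`` where ``M_κ(x)`` is the Jacobian of the mass-action
    field at ``x`` with the pivot rows replaced by the rows of ``W``.

    ``x`` and ``kappa`` must be strictly positive; exact rationals are
    accepted (floats are converted exactly).
    """
    n, r = sd.n, sd.r
    if len(x) != n or len(kappa) != r:
        raise ValueError("dimension mismatch")
    xq = [Fraction(xi) for xi in x]
    kq = [Fraction(ki) for ki in kappa]
    if any(xi <= 0 for xi in xq) or any(ki <= 0 for ki in kq):
        raise ValueError("x and kappa must be strictly positive")
    # monomial rates v_k = kappa_k * x^{A_k}
    rates = []
    for k in range(r):
        v = kq[k]
        for i in range(n):
            a = sd.A[i][k]
            if a:
                v *= xq[i] ** a
        rates.append(v)
    # Jacobian entry (i, j) = sum_k N[i,k] * v_k * A[j,k] / x_j
    M = [[Fraction(0)] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            total = Fraction(0)
            for k in range(r):
                if sd.N[i][k] and sd.A[j][k]:
                    total += sd.N[i][k] * sd.A[j][k] * rates[k]
            M[i][j] = total / xq[j]
    for jrow, pivot in enumerate(sd.pivots):
        M[pivot] = [Fraction(w) for w in sd.W[jrow]]
    det = _fraction_det(M)
    return -det if sd.s % 2 else det


def _fraction_det(M: list[list[Fraction]]) -> Fraction:
    """Gaussian elimination determinant over the rationals."""
    n = len(M)
    A = [row[:] for row in M]
    det = Fraction(1)
    for col in range(n):
        piv = next((i for i in range(col, n) if A[i][col] != 0), None)
        if piv is None:
            return Fraction(0)
        if piv != col:
            A[col], A[piv] = A[piv], A[col]
            det = -det
        det *= A[col][col]
        inv = 1 / A[col][col]
        for i in range(col + 1, n):
            if A[i][col] != 0:
                f = A[i][col] * inv
                A[i] = [a - f * b for a, b in zip(A[i], A[col])]
    return det
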
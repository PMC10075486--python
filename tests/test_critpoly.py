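import random
from fractions import Fraction

import pytest
import sympy

from crnconnect import (
    TermBudgetExceeded,
    build,
    build_convex_matrix,
    critical_polynomial,
    evaluate_g,
    extreme_rays,
    signed_support,
    stoichiometry,
)
from crnconnect.critpoly import Poly, _pack, convex_parametrization_point


def _sym(expr_str):
    h = sympy.symbols("h1:13")
    lam = sympy.symbols("lam1:13")
    ns = {f"h{i+1}": h[i] for i in range(12)}
    ns.update({f"lam{i+1}": lam[i] for i in range(12)})
    return sympy.expand(sympy.sympify(expr_str, locals=ns))


def test_convex_matrix_running_example():
    """M~ = [[1, 1], [-(lam1-lam2) h1, -(lam1+lam2) h2]] for the reference
    ray order E1 = (1,0,1), E2 = (1,1,0)."""
    sd = stoichiometry(build("running_example"))
    fc = extreme_rays(sd.N)
    M = build_convex_matrix(sd, fc)
    assert M[0][0].monomials() == {(0, 0, 0, 0): 1}
    assert M[0][1].monomials() == {(0, 0, 0, 0): 1}
    assert M[1][0].monomials() == {(1, 0, 1, 0): -1, (1, 0, 0, 1): 1}
    assert M[1][1].monomials() == {(0, 1, 1, 0): -1, (0, 1, 0, 1): -1}


def test_critical_polynomial_running_example_matches_reference():
    sd = stoichiometry(build("running_example"))
    fc = extreme_rays(sd.N)
    cp = critical_polynomial(sd, fc)
    assert cp.poly.as_sympy() - _sym("h1*lam2 - h1*lam1 + h2*lam1 + h2*lam2") == 0


def test_critical_polynomial_cell_cycle_matches_reference():
    sd = stoichiometry(build("cell_cycle"))
    fc = extreme_rays(sd.N)
    cp = critical_polynomial(sd, fc)
    ref = _sym(
        "(-h1*h3*h5 + h1*h4*h5 + h2*h4*h5 + h2*h3*h6 + h1*h4*h6 + h2*h4*h6)"
        "*lam1*lam2*lam3"
    )
    assert cp.poly.as_sympy() - ref == 0


def test_critical_polynomial_hybrid_histidine_kinase_matches_reference():
    sd = stoichiometry(build("hybrid_histidine_kinase"))
    fc = extreme_rays(sd.N)
    cp = critical_polynomial(sd, fc)
    ref = _sym(
        "h1*h2*h3*h5*lam1**3*lam2 + 3*h1*h2*h3*h5*lam1**2*lam2**2"
        " + 2*h1*h2*h3*h5*lam1*lam2**3 + h1*h2*h4*h5*lam1**2*lam2**2"
        " + h1*h2*h4*h5*lam1*lam2**3 - h2*h3*h4*h5*lam1**3*lam2"
        " - h2*h3*h4*h5*lam1**2*lam2**2 + h1*h2*h3*h6*lam1**3*lam2"
        " + 2*h1*h2*h3*h6*lam1**2*lam2**2 + h1*h2*h3*h6*lam1*lam2**3"
        " + h1*h2*h4*h6*lam1**3*lam2 + 2*h1*h2*h4*h6*lam1**2*lam2**2"
        " + h1*h2*h4*h6*lam1*lam2**3 + h1*h3*h4*h6*lam1**3*lam2"
        " + 2*h1*h3*h4*h6*lam1**2*lam2**2 + h1*h3*h4*h6*lam1*lam2**3"
        " + h2*h3*h4*h6*lam1**3*lam2 + 2*h2*h3*h4*h6*lam1**2*lam2**2"
        " + h2*h3*h4*h6*lam1*lam2**3"
    )
    assert cp.poly.as_sympy() - ref == 0


def test_signed_support_counts_and_partition():
    sd = stoichiometry(build("running_example"))
    fc = extreme_rays(sd.N)
    cp = critical_polynomial(sd, fc)
    ss = signed_support(cp)
    assert len(ss.positive) == 3 and len(ss.negative) == 1
    assert ss.positive.isdisjoint(ss.negative)
    assert len(ss.positive | ss.negative) == len(cp.poly.terms)


def test_signed_support_textbook_polynomial():
    """f = x1^2 - x1^2 x2 + 2 x1 x2 + x1^3 + x2^2."""
    terms = {
        _pack((2, 0)): 1,
        _pack((2, 1)): -1,
        _pack((1, 1)): 2,
        _pack((3, 0)): 1,
        _pack((0, 2)): 1,
    }
    poly = Poly(terms=terms, n=2, ell=0)
    from crnconnect.critpoly import CriticalPolynomial

    ss = signed_support(CriticalPolynomial(poly=poly, n=2, ell=0, s=0))
    assert ss.positive == frozenset({(2, 0), (1, 1), (3, 0), (0, 2)})
    assert ss.negative == frozenset({(2, 1)})


def test_all_positive_polynomial_has_empty_negative_support():
    from crnconnect import parse_network

    sd = stoichiometry(parse_network("A <-> B"))
    fc = extreme_rays(sd.N)
    ss = signed_support(critical_polynomial(sd, fc))
    assert ss.negative == frozenset()


def test_degree_homogeneity_in_both_blocks():
    """Each monomial has degree s in the h block and degree s in the lambda
    block: every Jacobian row of the critical matrix is linear in each."""
    for name, m in (("running_example", None), ("hybrid_histidine_kinase", None),
                    ("phospho_cycle", 2)):
        sd = stoichiometry(build(name, m=m))
        fc = extreme_rays(sd.N)
        cp = critical_polynomial(sd, fc)
        for exps in cp.poly.monomials():
            assert sum(exps[: sd.n]) == sd.s
            assert sum(exps[sd.n:]) == sd.s


def test_term_budget_raises_cleanly():
    sd = stoichiometry(build("phospho_cycle", m=2))
    fc = extreme_rays(sd.N)
    with pytest.raises(TermBudgetExceeded, match="reducing the network"):
        critical_polynomial(sd, fc, term_budget=50)


def test_ray_rescaling_preserves_signed_support_sizes():
    from crnconnect.fluxcone import FluxCone

    sd = stoichiometry(build("running_example"))
    fc = extreme_rays(sd.N)
    scaled = FluxCone(
        rays=tuple(tuple(3 * v for v in ray) for ray in fc.rays), r=fc.r
    )
    ss0 = signed_support(critical_polynomial(sd, fc))
    ss1 = signed_support(critical_polynomial(sd, scaled))
    assert len(ss0.positive) == len(ss1.positive)
    assert len(ss0.negative) == len(ss1.negative)


def test_evaluate_g_running_example_closed_form():
    """(-1)^s det M_kappa(x) = k3 x1^2 - 2 k3 x1 x2 + k1 + k2."""
    net = build("running_example")
    sd = stoichiometry(net)
    rng = random.Random(11)
    for _ in range(20):
        x = [Fraction(rng.randint(1, 9), rng.randint(1, 9)) for _ in range(2)]
        k = [Fraction(rng.randint(1, 9), rng.randint(1, 9)) for _ in range(3)]
        expected = k[2] * x[0] ** 2 - 2 * k[2] * x[0] * x[1] + k[0] + k[1]
        assert evaluate_g(net, sd, x, k) == expected


def test_evaluate_g_validates_input():
    net = build("running_example")
    sd = stoichiometry(net)
    with pytest.raises(ValueError, match="dimension"):
        evaluate_g(net, sd, [1], [1, 1, 1])
    with pytest.raises(ValueError, match="positive"):
        evaluate_g(net, sd, [1, -1], [1, 1, 1])


@pytest.mark.parametrize(
    "name, m",
    [
        ("running_example", None),
        ("cell_cycle", None),
        ("hybrid_histidine_kinase", None),
        ("allosteric_regulation", None),
        ("allosteric_reduced", None),
        ("phospho_cycle", 2),
        ("shared_kinase_reduced", None),
    ],
)
def test_critical_polynomial_agrees_with_jacobian_oracle(name, m):
    """The convex-parametrization identity: evaluating the expanded
    determinant at (h, lambda) equals the numeric sign function at
    (x, kappa) = Psi(h, lambda), and Psi lands on steady states."""
    net = build(name, m=m)
    sd = stoichiometry(net)
    fc = extreme_rays(sd.N)
    cp = critical_polynomial(sd, fc)
    rng = random.Random(13)
    for _ in range(50):
        h = [Fraction(rng.randint(1, 6), rng.randint(1, 6)) for _ in range(sd.n)]
        lam = [Fraction(rng.randint(1, 6), rng.randint(1, 6)) for _ in range(fc.ell)]
        x, kappa = convex_parametrization_point(sd, fc, h, lam)
        assert cp.poly.evaluate(list(h) + list(lam)) == evaluate_g(net, sd, x, kappa)
        # N v_kappa(x) = 0: the parametrized point is a positive steady state
        rates = []
        for j in range(sd.r):
            v = kappa[j]
            for i in range(sd.n):
                if sd.A[i][j]:
                    v *= x[i] ** sd.A[i][j]
            rates.append(v)
        for i in range(sd.n):
            assert sum(sd.N[i][j] * rates[j] for j in range(sd.r)) == 0
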
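import random
from fractions import Fraction

import pytest

from crnconnect import (
    build,
    extreme_rays,
    is_consistent,
    parse_network,
    reduce_network,
    removable_reverse_reactions,
    relative_interior_point,
    stoichiometry,
)
from crnconnect._simplex import solve_eq_nonneg
from oracles import brute_force_extreme_rays


def test_running_example_rays():
    sd = stoichiometry(build("running_example"))
    fc = extreme_rays(sd.N)
    assert fc.rays == ((1, 0, 1), (1, 1, 0))
    assert is_consistent(fc)


def test_cell_cycle_reference_ray_matrix():
    sd = stoichiometry(build("cell_cycle"))
    fc = extreme_rays(sd.N)
    # reference columns (0,0,1),(0,1,0),(0,0,1),(1,0,0),(0,1,0),(1,0,0) rowwise
    assert set(fc.rays) == {
        (0, 0, 0, 1, 0, 1),
        (0, 1, 0, 0, 1, 0),
        (1, 0, 1, 0, 0, 0),
    }


def test_hybrid_histidine_kinase_reference_ray_matrix():
    sd = stoichiometry(build("hybrid_histidine_kinase"))
    fc = extreme_rays(sd.N)
    assert set(fc.rays) == {(0, 1, 1, 0, 1, 1), (1, 1, 0, 1, 0, 1)}


def test_shared_kinase_reduced_reference_ray_matrix():
    sd = stoichiometry(build("shared_kinase_reduced"))
    fc = extreme_rays(sd.N)
    reference_rows = [
        (0, 0, 1), (0, 0, 1), (0, 0, 1), (0, 0, 1),
        (1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0),
        (1, 1, 0), (1, 1, 0),
    ]
    ref_cols = {tuple(row[j] for row in reference_rows) for j in range(3)}
    assert set(fc.rays) == ref_cols


def test_inconsistent_single_reaction():
    sd = stoichiometry(parse_network("A -> B"))
    fc = extreme_rays(sd.N)
    assert fc.ell == 0
    assert not is_consistent(fc)


def test_reversible_pair_gives_indicator_ray():
    sd = stoichiometry(parse_network("A <-> B"))
    fc = extreme_rays(sd.N)
    assert fc.rays == ((1, 1),)
    assert is_consistent(fc)


def test_zero_column_rejected():
    with pytest.raises(ValueError, match="zero"):
        extreme_rays(((0, 1), (0, -1)))


@pytest.mark.parametrize(
    "name, m",
    [
        ("running_example", None),
        ("cell_cycle", None),
        ("hybrid_histidine_kinase", None),
        ("allosteric_reduced", None),
    ],
)
def test_rays_match_minimal_support_brute_force(name, m):
    sd = stoichiometry(build(name, m=m))
    fc = extreme_rays(sd.N)
    assert sorted(fc.rays) == brute_force_extreme_rays(sd.N)


def test_rays_match_brute_force_random_matrices():
    rng = random.Random(7)
    found_nontrivial = 0
    for _ in range(25):
        n, r = rng.randint(2, 4), rng.randint(2, 6)
        N = [[rng.randint(-2, 2) for _ in range(r)] for _ in range(n)]
        if any(all(N[i][j] == 0 for i in range(n)) for j in range(r)):
            continue
        fc = extreme_rays(N)
        assert sorted(fc.rays) == brute_force_extreme_rays(N)
        found_nontrivial += fc.ell > 0
    assert found_nontrivial >= 5


def test_ray_normalization_and_support_minimality():
    from math import gcd

    sd = stoichiometry(build("phospho_cycle", m=2))
    fc = extreme_rays(sd.N)
    supports = []
    for ray in fc.rays:
        assert all(v >= 0 for v in ray) and any(ray)
        g = 0
        for v in ray:
            g = gcd(g, v)
        assert g == 1
        assert all(
            sum(sd.N[i][j] * ray[j] for j in range(sd.r)) == 0
            for i in range(sd.n)
        )
        supports.append(frozenset(j for j, v in enumerate(ray) if v))
    for a in supports:
        assert not any(b < a for b in supports)
    assert list(fc.rays) == sorted(fc.rays)


@pytest.mark.parametrize(
    "name, m",
    [("phospho_cycle", 2), ("shared_kinase", None), ("allosteric_regulation", None)],
)
def test_reversible_pair_and_reduction_embedding_properties(name, m):
    """Every reversible pair's indicator vector is an extreme ray, and every
    reduced-network ray, zero-padded at the removed reactions, is a ray of
    the full cone."""
    net = build(name, m=m)
    sd = stoichiometry(net)
    fc = extreme_rays(sd.N)
    pairs = []
    for j1 in range(net.r):
        for j2 in range(j1 + 1, net.r):
            if (
                net.reactions[j1][0] == net.reactions[j2][1]
                and net.reactions[j1][1] == net.reactions[j2][0]
            ):
                pairs.append((j1, j2))
    assert pairs, "fixture must contain reversible pairs"
    for j1, j2 in pairs:
        indicator = tuple(1 if j in (j1, j2) else 0 for j in range(net.r))
        assert indicator in fc.rays
    removable = removable_reverse_reactions(net)
    reduced = reduce_network(net, removable)
    fc_red = extreme_rays(stoichiometry(reduced).N)
    kept = [j for j in range(net.r) if j not in set(removable)]
    for ray in fc_red.rays:
        padded = [0] * net.r
        for pos, j in enumerate(kept):
            padded[j] = ray[pos]
        assert tuple(padded) in fc.rays
    assert fc.ell >= fc_red.ell + len(removable)


def test_positive_lambda_gives_positive_flux():
    """For consistent networks, E lambda with positive lambda is strictly
    positive (no zero rows in E)."""
    sd = stoichiometry(build("erk"))
    fc = extreme_rays(sd.N)
    lam = [Fraction(i + 1, 3) for i in range(fc.ell)]
    v = [
        sum(fc.E[j][k] * lam[k] for k in range(fc.ell)) for j in range(sd.r)
    ]
    assert all(x > 0 for x in v)


def test_relative_interior_point_quadrant():
    point = relative_interior_point([(1, 0), (0, 1)])
    assert point == (1, 1)


def test_relative_interior_point_halfplane():
    point = relative_interior_point([(1, 0)])
    assert point[0] > 0 and point[1] == 0


def test_relative_interior_point_trivial_cone():
    point = relative_interior_point([(1, 0), (-1, 0), (0, 1), (0, -1)])
    assert point == (0, 0)


@pytest.mark.parametrize(
    "ineqs",
    [
        [(1, 0), (0, 1)],
        [(1, 1), (1, -1)],
        [(1, 2, 0), (0, 1, 1), (1, 0, -1), (0, 0, 1)],
        [(1, 0, 0), (-1, 0, 0), (0, 1, 0)],  # implicit equality present
    ],
)
def test_relative_interior_point_strictness_pattern(ineqs):
    """The returned point satisfies every inequality, strictly exactly on the
    non-implicit ones.  Implicitness is certified independently by exact LP:
    d.x <= 0 is valid on {Dx >= 0} iff -d is a nonnegative combination of
    the rows of D."""
    point = relative_interior_point(ineqs)
    for d in ineqs:
        val = sum(Fraction(a) * x for a, x in zip(d, point))
        assert val >= 0
        rows = [[Fraction(e[i]) for e in ineqs] for i in range(len(d))]
        rhs = [Fraction(-a) for a in d]
        implicit = solve_eq_nonneg(rows, rhs) is not None
        assert (val == 0) == implicit
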
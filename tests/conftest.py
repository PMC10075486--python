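import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crnconnect import (
    build,
    critical_polynomial,
    extreme_rays,
    reduce_network,
    removable_reverse_reactions,
    signed_support,
    stoichiometry,
)


class AnalysisStore:
    """Session-wide cache of per-network derived objects.

    Critical polynomials of the larger benchmark networks are expensive
    enough that each should be expanded once per test session.
    """

    def __init__(self) -> None:
        self._cache = {}

    def get(self, name: str, m=None, reduced: bool = False):
        key = (name, m, reduced)
        if key not in self._cache:
            net = build(name, m=m)
            if reduced:
                net = reduce_network(net, removable_reverse_reactions(net))
            sd = stoichiometry(net)
            fc = extreme_rays(sd.N)
            cp = critical_polynomial(sd, fc, term_budget=None)
            ss = signed_support(cp)
            self._cache[key] = (net, sd, fc, cp, ss)
        return self._cache[key]

    def network_objects(self, name: str, m=None, reduced: bool = False):
        """Like :meth:`get` but without the polynomial (cheap path)."""
        key = ("net", name, m, reduced)
        if key not in self._cache:
            net = build(name, m=m)
            if reduced:
                net = reduce_network(net, removable_reverse_reactions(net))
            sd = stoichiometry(net)
            fc = extreme_rays(sd.N)
            self._cache[key] = (net, sd, fc)
        return self._cache[key]


@pytest.fixture(scope="session")
def store() -> AnalysisStore:
    return AnalysisStore()
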
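"""Programmatic builders for the cell-signaling benchmark networks.

Each builder returns a :class:`~crnconnect.network.ReactionNetwork` with a
pinned species and reaction order.  Where reference matrices (N, W, E) exist
for a network, the builder reproduces the ordering behind them; where only a
mechanism description exists, the builder's docstring states the
reconstruction rule and the network is validated by its invariants
(species/reaction/ray counts and signed-support sizes).

Rate labels follow the source conventions: phosphorylation cycles use the
``k_{6(i-1)+1..6}`` numbering per site, enzymatic triples use
``(catalytic, binding, unbinding) = (k_{3j-2}, k_{3j-1}, k_{3j})``.
"""

from __future__ import annotations

from typing import Optional

from .network import ReactionNetwork, parse_network

__all__ = ["build", "FIXTURE_NAMES"]


def _running_example() -> ReactionNetwork:
    """Two species, three reactions, one autocatalytic step."""
    return parse_network(
        """
        X1 -> X2
        X2 -> X1
        2 X1 + X2 -> 3 X1
        """
    )


def _cell_cycle() -> ReactionNetwork:
    """G2/M transition module: three enzyme pairs C/Cp (Cdc25), M/Mp (MPF),
    W/Wp (Wee1) in mutual activation/inactivation loops.  Species order
    C, Cp, M, Mp, W, Wp matches the reference stoichiometric matrix."""
    return parse_network(
        """
        species: C Cp M Mp W Wp
        Mp + C -> M + C
        Cp + M -> C + M
        M + W -> Mp + W
        W + M -> Wp + M
        C -> Cp
        Wp -> W
        """
    )


def _hybrid_histidine_kinase() -> ReactionNetwork:
    """Hybrid histidine kinase with embedded REC domain and phosphotransfer
    protein Hpt; species order HK00, HKp0, HK0p, HKpp, Hpt, Hptp."""
    return parse_network(
        """
        species: HK00 HKp0 HK0p HKpp Hpt Hptp
        HK00 -> HKp0
        HKp0 -> HK0p
        HK0p -> HKpp
        HK0p + Hpt -> HK00 + Hptp
        HKpp + Hpt -> HKp0 + Hptp
        Hptp -> Hpt
        """
    )


def _sub(i: int) -> str:
    return "S" + "p" * i


def _phospho_cycle(m: int) -> ReactionNetwork:
    """Sequential, distributive m-site phosphorylation cycle with one kinase
    E and one phosphatase F, Michaelis-Menten mechanism per site.  Reactions
    run up the phosphorylation chain, then down the dephosphorylation chain,
    as in the reference 18-reaction list for m = 3."""
    if m < 1:
        raise ValueError("m must be >= 1")
    lines, labels = [], []
    for i in range(m):  # site i+1 phosphorylation: k_{6i+1..3}
        b = 6 * i
        lines.append(f"{_sub(i)} + E <-> E{_sub(i)}")
        lines.append(f"E{_sub(i)} -> {_sub(i + 1)} + E")
        labels += [f"k{b + 1}", f"k{b + 2}", f"k{b + 3}"]
    for i in range(m, 0, -1):  # dephosphorylation of S_i: k_{6(i-1)+4..6}
        b = 6 * (i - 1)
        lines.append(f"{_sub(i)} + F <-> F{_sub(i)}")
        lines.append(f"F{_sub(i)} -> {_sub(i - 1)} + F")
        labels += [f"k{b + 4}", f"k{b + 5}", f"k{b + 6}"]
    return parse_network("\n".join(lines), labels=labels)


def _phospho_diff_phosphatases(m: int) -> ReactionNetwork:
    """As :func:`_phospho_cycle` but with a distinct phosphatase F_i per
    dephosphorylation step."""
    if m < 1:
        raise ValueError("m must be >= 1")
    lines, labels = [], []
    for i in range(m):
        b = 6 * i
        lines.append(f"{_sub(i)} + E <-> E{_sub(i)}")
        lines.append(f"E{_sub(i)} -> {_sub(i + 1)} + E")
        labels += [f"k{b + 1}", f"k{b + 2}", f"k{b + 3}"]
    for i in range(m, 0, -1):
        b = 6 * (i - 1)
        lines.append(f"{_sub(i)} + F{i} <-> F{i}{_sub(i)}")
        lines.append(f"F{i}{_sub(i)} -> {_sub(i - 1)} + F{i}")
        labels += [f"k{b + 4}", f"k{b + 5}", f"k{b + 6}"]
    return parse_network("\n".join(lines), labels=labels)


def _weakly_irrev_dephos() -> ReactionNetwork:
    """2-site cycle, Michaelis-Menten phosphorylation, weakly irreversible
    dephosphorylation: each dephosphorylation passes through a bound product
    complex (primed) that releases the product reversibly."""
    return parse_network(
        """
        S + E <-> ES
        ES -> Sp + E
        Sp + E <-> ESp
        ESp -> Spp + E
        Spp + F <-> FSpp
        FSpp -> FSp'
        FSp' <-> Sp + F
        Sp + F <-> FSp
        FSp -> FS'
        FS' <-> S + F
        """
    )


def _fully_weakly_irrev() -> ReactionNetwork:
    """2-site cycle with weak irreversibility in both directions: every
    catalytic step converts the substrate-enzyme complex into a bound
    product complex that releases reversibly."""
    return parse_network(
        """
        S + E <-> ES
        ES -> ESp'
        ESp' <-> Sp + E
        Sp + E <-> ESp
        ESp -> ESpp'
        ESpp' <-> Spp + E
        Spp + F <-> FSpp
        FSpp -> FSp'
        FSp' <-> Sp + F
        Sp + F <-> FSp
        FSp -> FS'
        FS' <-> S + F
        """
    )


def _erk() -> ReactionNetwork:
    """ERK dual phosphorylation with mixed processive/distributive
    mechanism: kinase E and phosphatase F act through intermediates C1..C6,
    with the partially phosphorylated forms S01, S10 re-entering."""
    return parse_network(
        """
        S00 + E <-> C1
        C1 -> C2
        C2 -> S11 + E
        C2 <-> S01 + E
        S11 + F <-> C3
        C3 -> C4
        C4 -> S00 + F
        C4 <-> S10 + F
        S01 + F <-> C5
        C5 -> S00 + F
        S10 + E <-> C6
        C6 -> S11 + E
        """
    )


_SHARED_KINASE_TEXT = """
species: S E SE Sp F1 SpF1 P PSp Pp PE F2 PpF2
S + E <-> SE
SE -> Sp + E
Sp + F1 <-> SpF1
SpF1 -> S + F1
P + Sp <-> PSp
PSp -> Pp + Sp
P + E <-> PE
PE -> Pp + E
Pp + F2 <-> PpF2
PpF2 -> P + F2
"""

_SHARED_KINASE_LABELS = [
    "k2", "k3", "k1", "k5", "k6", "k4", "k8", "k9", "k7",
    "k11", "k12", "k10", "k14", "k15", "k13",
]


def _shared_kinase() -> ReactionNetwork:
    """Two-layer cascade with shared kinase E: E phosphorylates S, and both
    E and Sp phosphorylate P; phosphatases F1, F2.  Labels follow the
    (catalytic, binding, unbinding) = (k_{3j-2}, k_{3j-1}, k_{3j})
    convention."""
    return parse_network(_SHARED_KINASE_TEXT, labels=_SHARED_KINASE_LABELS)


def _shared_kinase_reduced() -> ReactionNetwork:
    """The shared-kinase cascade with the five unbinding reactions
    k3, k6, k9, k12, k15 removed."""
    labels = [lab for lab in _SHARED_KINASE_LABELS if lab not in
              ("k3", "k6", "k9", "k12", "k15")]
    text = "\n".join(
        line for line in _SHARED_KINASE_TEXT.splitlines()
        if line.strip()
    )
    text = text.replace("<->", "->")
    return parse_network(text, labels=labels)


def _mapk_two_layer() -> ReactionNetwork:
    """Two-layer MAPK cascade: single phosphorylation cycle (A) whose
    product Ap is the kinase of a 2-site distributive cycle (B); distinct
    phosphatases F1, F2."""
    return parse_network(
        """
        A + E <-> AE
        AE -> Ap + E
        Ap + F1 <-> ApF1
        ApF1 -> A + F1
        B + Ap <-> BAp
        BAp -> Bp + Ap
        Bp + Ap <-> BpAp
        BpAp -> Bpp + Ap
        Bpp + F2 <-> BppF2
        BppF2 -> Bp + F2
        Bp + F2 <-> BpF2
        BpF2 -> B + F2
        """
    )


def _mapk_three_layer() -> ReactionNetwork:
    """Three-layer MAPK cascade (structural fixture only: its full critical
    polynomial is beyond the symbolic determinant budget by design)."""
    return parse_network(
        """
        A + E <-> AE
        AE -> Ap + E
        Ap + F1 <-> ApF1
        ApF1 -> A + F1
        B + Ap <-> BAp
        BAp -> Bp + Ap
        Bp + Ap <-> BpAp
        BpAp -> Bpp + Ap
        Bpp + F2 <-> BppF2
        BppF2 -> Bp + F2
        Bp + F2 <-> BpF2
        BpF2 -> B + F2
        C + Bpp <-> CBpp
        CBpp -> Cp + Bpp
        Cp + Bpp <-> CpBpp
        CpBpp -> Cpp + Bpp
        Cpp + F3 <-> CppF3
        CppF3 -> Cp + F3
        Cp + F3 <-> CpF3
        CpF3 -> C + F3
        """
    )


def _covalent_regulation() -> ReactionNetwork:
    """Reciprocal covalent regulation of a phosphorylation cycle: the
    modifier enzyme E activates the kinase (K -> Kp) and inactivates the
    phosphatase (P -> Pp) by Michaelis-Menten covalent modification; a
    constitutive demodifying activity D reverses both modifications."""
    return parse_network(
        """
        S + Kp <-> SKp
        SKp -> Sp + Kp
        Sp + P <-> SpP
        SpP -> S + P
        K + E <-> KE
        KE -> Kp + E
        P + E <-> PE
        PE -> Pp + E
        Kp + D -> K + D
        Pp + D -> P + D
        """
    )


_ALLOSTERIC_LABELS = ["k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10"]


def _allosteric_regulation() -> ReactionNetwork:
    """Phosphorylation cycle with reciprocal allosteric regulation: ligand L
    activates the kinase (KL is catalytically active) and sequesters the
    phosphatase (PL is inactive).  Species order S, Sp, K, P, KL, PL, SKL,
    SpP, L matches the reference stoichiometric matrix."""
    return parse_network(
        """
        species: S Sp K P KL PL SKL SpP L
        S + KL <-> SKL
        SKL -> Sp + KL
        Sp + P <-> SpP
        SpP -> S + P
        K + L <-> KL
        P + L <-> PL
        """,
        labels=_ALLOSTERIC_LABELS,
    )


def _allosteric_reduced() -> ReactionNetwork:
    """The allosteric-regulation network with the unbinding reactions k2,
    k5 removed; 9 species, 8 reactions."""
    return parse_network(
        """
        species: S Sp K P KL PL SKL SpP L
        S + KL -> SKL
        SKL -> Sp + KL
        Sp + P -> SpP
        SpP -> S + P
        K + L <-> KL
        P + L <-> PL
        """,
        labels=["k1", "k3", "k4", "k6", "k7", "k8", "k9", "k10"],
    )


_BUILDERS = {
    "running_example": _running_example,
    "cell_cycle": _cell_cycle,
    "hybrid_histidine_kinase": _hybrid_histidine_kinase,
    "phospho_cycle": _phospho_cycle,
    "phospho_diff_phosphatases": _phospho_diff_phosphatases,
    "weakly_irrev_dephos": _weakly_irrev_dephos,
    "fully_weakly_irrev": _fully_weakly_irrev,
    "erk": _erk,
    "shared_kinase": _shared_kinase,
    "shared_kinase_reduced": _shared_kinase_reduced,
    "mapk_two_layer": _mapk_two_layer,
    "mapk_three_layer": _mapk_three_layer,
    "covalent_regulation": _covalent_regulation,
    "allosteric_regulation": _allosteric_regulation,
    "allosteric_reduced": _allosteric_reduced,
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def build(name: str, m: Optional[int] = None) -> ReactionNetwork:
    """Build a benchmark network by name.

    ``m`` is required for the parametric families ``phospho_cycle`` and
    ``phospho_diff_phosphatases`` and rejected otherwise.
    """
    if name not in _BUILDERS:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    builder = _BUILDERS[name]
    if name in ("phospho_cycle", "phospho_diff_phosphatases"):
        if m is None:
            raise ValueError(f"fixture {name!r} needs the site count m")
        return builder(m)
    if m is not None:
        raise ValueError(f"fixture {name!r} takes no parameter m")
    return builder()
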
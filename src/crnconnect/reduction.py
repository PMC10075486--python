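"""Reverse-reaction removal for intermediate species.

When a species ``X`` occurs in exactly three reactions

    A  <->  X  ->  B        (binding, unbinding, conversion)

with ``X`` the sole product of the binding step (coefficient 1), the sole
reactant of the conversion step, and absent from every other complex, the
unbinding (reverse) reaction may be removed: connectivity conclusions for the
multistationarity region of the reduced network lift to the original one.
Each removed reverse reaction deletes one extreme ray of the flux cone, so
the critical polynomial loses a λ variable — often the difference between an
infeasible and an easy symbolic determinant.

The pattern match is syntactic on stoichiometry and deliberately
conservative: intermediates of selected patterns must not occur in each
other's complexes; ambiguous species are skipped, which only forfeits
reduction opportunities, never soundness.
"""

from __future__ import annotations

from .network import ReactionNetwork

__all__ = ["removable_reverse_reactions", "reduce_network"]


def _unit(vec: tuple[int, ...]) -> int:
    """Index i if vec = e_i, else -1."""
    idx = -1
    for i, v in enumerate(vec):
        if v == 0:
            continue
        if v != 1 or idx >= 0:
            return -1
        idx = i
    return idx


def removable_reverse_reactions(net: ReactionNetwork) -> list[int]:
    """Indices of reverse (unbinding) reactions that may be removed.

    A reaction R qualifies when it is the exact reverse of a reaction P whose
    product is a single species X with coefficient 1, and X participates in
    exactly three reactions: P, R, and one reaction consuming X alone.
    Patterns are selected greedily with disjoint intermediates.
    """
    n = net.n
    occurs: list[list[int]] = [[] for _ in range(n)]
    for j, (reactant, product, _) in enumerate(net.reactions):
        for i in range(n):
            if reactant[i] > 0 or product[i] > 0:
                occurs[i].append(j)

    candidates = []  # (x, idx_P, idx_R, idx_Q)
    for x in range(n):
        if len(occurs[x]) != 3:
            continue
        js = occurs[x]
        idx_p = idx_r = idx_q = None
        for j in js:
            reactant, product, _ = net.reactions[j]
            if reactant[x] == 0 and _unit(product) == x:
                idx_p = j if idx_p is None else -1
        if idx_p is None or idx_p == -1:
            continue
        p_react, p_prod, _ = net.reactions[idx_p]
        for j in js:
            if j == idx_p:
                continue
            reactant, product, _ = net.reactions[j]
            if _unit(reactant) != x or product[x] != 0:
                idx_q = idx_r = None
                break
            if reactant == p_prod and product == p_react:
                idx_r = j
            else:
                idx_q = j
        if idx_r is None or idx_q is None:
            continue
        candidates.append((x, idx_p, idx_r, idx_q))

    # disjointness: no selected intermediate inside another pattern's complexes
    selected: list[tuple[int, int, int, int]] = []
    chosen_species: set[int] = set()
    for cand in candidates:
        x, idx_p, idx_r, idx_q = cand
        touched = set()
        for j in (idx_p, idx_r, idx_q):
            reactant, product, _ = net.reactions[j]
            for i in range(n):
                if i != x and (reactant[i] or product[i]):
                    touched.add(i)
        own_prior = any(
            x in t for t in (_touched(net, c) for c in selected)
        )
        if touched & chosen_species or own_prior:
            continue
        selected.append(cand)
        chosen_species.add(x)
    return sorted(idx_r for _, _, idx_r, _ in selected)


def _touched(net: ReactionNetwork, cand: tuple[int, int, int, int]) -> set[int]:
    x, idx_p, idx_r, idx_q = cand
    out: set[int] = set()
    for j in (idx_p, idx_r, idx_q):
        reactant, product, _ = net.reactions[j]
        for i in range(net.n):
            if i != x and (reactant[i] or product[i]):
                out.add(i)
    return out


def reduce_network(net: ReactionNetwork, indices) -> ReactionNetwork:
    """Remove the given reverse reactions, keeping species and labels.

    ``indices`` must come from :func:`removable_reverse_reactions`.
    """
    allowed = set(removable_reverse_reactions(net))
    drop = set(indices)
    if not drop <= allowed:
        bad = sorted(drop - allowed)
        raise ValueError(f"reactions {bad} are not removable reverse reactions")
    reactions = tuple(
        rx for j, rx in enumerate(net.reactions) if j not in drop
    )
    return ReactionNetwork(species=net.species, reactions=reactions)
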
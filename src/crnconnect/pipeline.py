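"""End-to-end connectivity check for the multistationarity region.

The procedure: (1) verify the network is conservative and that minimal
siphons exclude relevant boundary steady states; (2) compute the flux-cone
rays and the critical polynomial of the convex parametrization; (3) decide
whether the signed support admits a strict separating hyperplane; (4) if
step 2 or 3 fails, retry on the reverse-reaction reduction, whose positive
verdict lifts to the original network.

Outcomes are verdicts, never exceptions: PATH_CONNECTED (certified),
EMPTY_REGION (the critical polynomial is never negative, so no parameters
enable multistationarity and the region is trivially connected),
PRECONDITION_FAILED (step 1 inconclusive), INCONCLUSIVE (no certificate).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

from .critpoly import (
    TermBudgetExceeded,
    critical_polynomial,
    signed_support,
)
from .fluxcone import extreme_rays, is_consistent
from .hyperplane import Hyperplane, find_strict_separating_hyperplane
from .network import ReactionNetwork, is_conservative, stoichiometry
from .reduction import reduce_network, removable_reverse_reactions
from .siphons import DEFAULT_BOUND, excludes_boundary_steady_states

__all__ = [
    "ConnectivityReport",
    "check_connectivity",
    "format_report",
    "report_to_json",
]

PATH_CONNECTED = "PATH_CONNECTED"
INCONCLUSIVE = "INCONCLUSIVE"
EMPTY_REGION = "EMPTY_REGION"
PRECONDITION_FAILED = "PRECONDITION_FAILED"


@dataclass(frozen=True)
class ConnectivityReport:
    n: int
    r: int
    ell: Optional[int]
    conservative: bool
    no_boundary_steady_states: bool
    consistent: Optional[bool]
    sigma_plus_count: Optional[int]
    sigma_minus_count: Optional[int]
    hyperplane: Optional[Hyperplane]
    reduced_used: bool
    removed_labels: tuple[str, ...]
    reduced_sigma_plus_count: Optional[int] = None
    reduced_sigma_minus_count: Optional[int] = None
    verdict: str = INCONCLUSIVE
    detail: str = ""


@dataclass
class _StepResult:
    outcome: str  # hyperplane | no_hyperplane | empty_sigma | precondition | inconsistent | budget
    ell: Optional[int] = None
    plus: Optional[int] = None
    minus: Optional[int] = None
    hyperplane: Optional[Hyperplane] = None
    detail: str = ""


def _run_steps(
    net: ReactionNetwork, term_budget: Optional[int], siphon_bound: int
) -> _StepResult:
    sd = stoichiometry(net)
    conservative, _ = is_conservative(sd)
    if not conservative:
        return _StepResult(outcome="precondition", detail="network is not conservative")
    # an inconsistent network has no positive steady states at all, so the
    # multistationarity region is empty regardless of boundary behaviour
    fc = extreme_rays(sd.N)
    if not is_consistent(fc):
        return _StepResult(
            outcome="inconsistent",
            ell=fc.ell,
            detail="the network is not consistent: no positive steady states exist",
        )
    if not excludes_boundary_steady_states(net, sd, bound=siphon_bound):
        return _StepResult(
            outcome="precondition",
            detail="siphon criterion cannot exclude relevant boundary steady states",
        )
    try:
        cp = critical_polynomial(sd, fc, term_budget=term_budget)
    except TermBudgetExceeded as exc:
        return _StepResult(outcome="budget", ell=fc.ell, detail=str(exc))
    ss = signed_support(cp)
    plus, minus = len(ss.positive), len(ss.negative)
    if minus == 0:
        return _StepResult(outcome="empty_sigma", ell=fc.ell, plus=plus, minus=0)
    hp = find_strict_separating_hyperplane(ss)
    if hp is None:
        return _StepResult(outcome="no_hyperplane", ell=fc.ell, plus=plus, minus=minus)
    return _StepResult(
        outcome="hyperplane", ell=fc.ell, plus=plus, minus=minus, hyperplane=hp
    )


def check_connectivity(
    net: ReactionNetwork,
    reduce: str = "auto",
    term_budget: Optional[int] = 4_000_000,
    siphon_bound: int = DEFAULT_BOUND,
) -> ConnectivityReport:
    """Run the full connectivity check on a network.

    ``reduce``: ``"auto"`` (original first, reduction as fallback),
    ``"never"``, or ``"first"`` (reduce before the first attempt).
    """
    if reduce not in ("auto", "never", "first"):
        raise ValueError(f"unknown reduce policy {reduce!r}")
    removable = removable_reverse_reactions(net)
    removed_labels: tuple[str, ...] = ()

    def base_report(**kw) -> ConnectivityReport:
        fields = dict(
            n=net.n,
            r=net.r,
            ell=None,
            conservative=True,
            no_boundary_steady_states=True,
            consistent=None,
            sigma_plus_count=None,
            sigma_minus_count=None,
            hyperplane=None,
            reduced_used=False,
            removed_labels=removed_labels,
        )
        fields.update(kw)
        return ConnectivityReport(**fields)

    target = net
    reduced_first = reduce == "first" and removable
    if reduced_first:
        removed_labels = tuple(net.reactions[j][2] for j in removable)
        target = reduce_network(net, removable)

    res = _run_steps(target, term_budget, siphon_bound)

    if res.outcome == "precondition":
        return base_report(
            conservative="not conservative" not in res.detail,
            no_boundary_steady_states="siphon" not in res.detail,
            reduced_used=bool(reduced_first),
            verdict=PRECONDITION_FAILED,
            detail=res.detail,
        )
    if res.outcome == "inconsistent":
        return base_report(
            consistent=False,
            ell=res.ell,
            reduced_used=bool(reduced_first),
            verdict=EMPTY_REGION,
            detail=res.detail,
        )
    if res.outcome == "empty_sigma" and not reduced_first:
        return base_report(
            consistent=True,
            ell=res.ell,
            sigma_plus_count=res.plus,
            sigma_minus_count=0,
            verdict=EMPTY_REGION,
            detail="the critical polynomial has no negative coefficients; "
            "no parameters enable multistationarity",
        )
    if res.outcome == "hyperplane":
        if reduced_first:
            return base_report(
                consistent=True,
                ell=res.ell,
                reduced_sigma_plus_count=res.plus,
                reduced_sigma_minus_count=res.minus,
                hyperplane=res.hyperplane,
                reduced_used=True,
                verdict=PATH_CONNECTED,
                detail="certified on the reduced network; lifts to the original",
            )
        return base_report(
            consistent=True,
            ell=res.ell,
            sigma_plus_count=res.plus,
            sigma_minus_count=res.minus,
            hyperplane=res.hyperplane,
            verdict=PATH_CONNECTED,
        )

    # no hyperplane / term budget on the first attempt
    first = res
    if reduce == "auto" and removable and not reduced_first:
        removed_labels = tuple(net.reactions[j][2] for j in removable)
        reduced = reduce_network(net, removable)
        res2 = _run_steps(reduced, term_budget, siphon_bound)
        if res2.outcome == "hyperplane":
            return base_report(
                consistent=True,
                ell=first.ell,
                sigma_plus_count=first.plus,
                sigma_minus_count=first.minus,
                reduced_sigma_plus_count=res2.plus,
                reduced_sigma_minus_count=res2.minus,
                hyperplane=res2.hyperplane,
                reduced_used=True,
                verdict=PATH_CONNECTED,
                detail="certified on the reduced network; lifts to the original",
            )
        return base_report(
            consistent=True,
            ell=first.ell,
            sigma_plus_count=first.plus,
            sigma_minus_count=first.minus,
            reduced_sigma_plus_count=res2.plus,
            reduced_sigma_minus_count=res2.minus,
            verdict=INCONCLUSIVE,
            detail=_inconclusive_detail(first, res2),
        )
    if reduced_first:
        return base_report(
            consistent=True,
            ell=res.ell,
            reduced_sigma_plus_count=res.plus,
            reduced_sigma_minus_count=res.minus,
            reduced_used=True,
            verdict=INCONCLUSIVE,
            detail=_inconclusive_detail(None, res),
        )
    return base_report(
        consistent=True,
        ell=first.ell,
        sigma_plus_count=first.plus,
        sigma_minus_count=first.minus,
        verdict=INCONCLUSIVE,
        detail=_inconclusive_detail(first, None),
    )


def _inconclusive_detail(
    first: Optional[_StepResult], second: Optional[_StepResult]
) -> str:
    parts = []
    for tag, res in (("original", first), ("reduced", second)):
        if res is None:
            continue
        if res.outcome == "budget":
            parts.append(f"{tag} network: {res.detail}")
        elif res.outcome == "no_hyperplane":
            parts.append(f"{tag} network: no strict separating hyperplane")
        elif res.outcome == "empty_sigma":
            parts.append(f"{tag} network: critical polynomial never negative")
        else:
            parts.append(f"{tag} network: {res.outcome}")
    return "; ".join(parts)


def format_report(report: ConnectivityReport) -> str:
    """Human-readable report, one finding per line."""
    lines = [f"n = {report.n}", f"r = {report.r}"]
    if report.verdict == PRECONDITION_FAILED:
        if not report.conservative:
            lines.append("The reaction network could not be shown conservative.")
        else:
            lines.append("The reaction network is conservative.")
            lines.append(
                "Relevant boundary steady states could not be excluded."
            )
        lines.append("The algorithm is inconclusive.")
        return "\n".join(lines)
    lines.append("The reaction network is conservative.")
    lines.append("There are no relevant boundary steady states.")
    if report.consistent is False:
        lines.append("The network is not consistent: no positive steady states.")
        lines.append("The parameter region of multistationarity is empty.")
        return "\n".join(lines)
    if report.ell is not None:
        lines.append(f"l = {report.ell}")
    if report.reduced_used and report.removed_labels:
        lines.append(
            "Reduced network used (removed reactions: "
            + ", ".join(report.removed_labels)
            + ")."
        )
        plus, minus = report.reduced_sigma_plus_count, report.reduced_sigma_minus_count
    else:
        plus, minus = report.sigma_plus_count, report.sigma_minus_count
    if plus is not None:
        lines.append(f"Number of positive coefficients: {plus}")
        lines.append(f"Number of negative coefficients: {minus}")
    if report.verdict == EMPTY_REGION:
        lines.append("The critical polynomial attains no negative values.")
        lines.append("No parameter pair enables multistationarity.")
    elif report.verdict == PATH_CONNECTED:
        lines.append("The support set has a strict separating hyperplane.")
        lines.append("All the conditions are satisfied.")
        lines.append("We conclude that the parameter region of multistationarity")
        lines.append("is path connected.")
    else:
        lines.append("The support set has no strict separating hyperplane.")
        lines.append("The algorithm is inconclusive.")
    return "\n".join(lines)


def report_to_json(report: ConnectivityReport) -> str:
    data = dataclasses.asdict(report)
    hp = data.pop("hyperplane")
    if hp is not None:
        data["hyperplane"] = {
            "v": [str(c) for c in hp["v"]],
            "a": str(hp["a"]),
        }
    else:
        data["hyperplane"] = None
    data["removed_labels"] = list(data["removed_labels"])
    return json.dumps(data, indent=2)
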
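"""Screen for alternative cofactor-producing reactions.

Given a cofactor metabolite (NADPH in the motivating analysis) the screen
first collects every reaction whose stoichiometry involves the cofactor and
annotates each with two properties:

* *synthesis-capable* — can the reaction, within its feasible flux range
  (FVA), carry flux in the direction that produces the cofactor?
* *essential* — does knocking the reaction out alone abolish growth?

The producer-identification algorithm then closes the synthesis direction of
every independently non-essential synthesis-capable cofactor reaction and
verifies that growth collapses to zero (the screen is only well posed when
the closed set covers all routes to the cofactor).  Re-opening a designated
reference reaction (the transhydrogenase) alone must restore optimal growth;
every other member that independently restores growth when re-opened alone
is reported as a candidate alternative producer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .fba_engine import (
    GROWTH_TOL,
    FBAError,
    Medium,
    apply_medium,
    knockout,
    run_fva,
    solve_fba,
)
from .model_core import MetabolicModel, Reaction

#: flux below which an FVA extreme does not count as synthesis capability
SYNTH_FLUX_TOL = 1e-6


class ScreenError(RuntimeError):
    """The screen's preconditions do not hold."""


@dataclass
class CofactorReaction:
    """One reaction touching the cofactor.

    ``coefficient`` is the cofactor's stoichiometric coefficient (positive =
    produced in the forward direction).  ``can_carry_synthesis_flux`` and
    ``essential`` are evaluated under the screen's medium.
    """

    reaction_id: str
    coefficient: float
    can_carry_synthesis_flux: bool
    essential: bool
    is_pseudo: bool = False  # biomass/demand/exchange sink, never a producer


@dataclass
class ScreenResult:
    """Outcome of the alternative-producer screen."""

    cofactor_id: str
    reference_reaction_id: str
    total_cofactor_reactions: int
    nonessential_synthesis_capable: list[str] = field(default_factory=list)
    baseline_growth_after_mass_knockout: float = 0.0
    reference_restores: bool = False
    reference_growth_rate: float = 0.0
    candidates: dict[str, float] = field(default_factory=dict)


def _close_synthesis_direction(rxn: Reaction, coefficient: float) -> None:
    """Bound a reaction to its cofactor-consumption side.

    Forward flux produces the cofactor when ``coefficient`` > 0, so the upper
    bound drops to 0; reverse production (coefficient < 0) zeroes the lower
    bound.  Consumption-direction flux remains allowed.
    """
    if coefficient > 0:
        rxn.upper_bound = min(rxn.upper_bound, 0.0)
        if rxn.lower_bound > rxn.upper_bound:
            rxn.lower_bound = rxn.upper_bound
    else:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
        if rxn.upper_bound < rxn.lower_bound:
            rxn.upper_bound = rxn.lower_bound


def find_cofactor_reactions(
    model: MetabolicModel,
    cofactor_id: str,
    medium: Medium | None = None,
    count_mode: str = "either-sign",
) -> list[CofactorReaction]:
    """All reactions involving the cofactor, with capability annotations.

    ``count_mode`` selects which stoichiometric signs qualify:
    ``either-sign`` (default) takes any nonzero coefficient,
    ``consumption-only`` restricts to reactions that consume the cofactor in
    their forward direction — the two readings of "cofactor-requiring
    reaction" when reversible reactions blur producer and consumer.
    Synthesis capability is read off the feasibility flux range (FVA with no
    objective constraint): the reaction can produce the cofactor iff
    coefficient * flux > 0 is attainable.  Essentiality is a one-at-a-time
    knockout under the same medium.
    """
    if count_mode not in ("either-sign", "consumption-only"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    model.metabolite(cofactor_id)  # KeyError if absent
    work = apply_medium(model, medium) if medium is not None else model.copy()
    touching = [
        (r, r.stoichiometry[cofactor_id])
        for r in work.reactions
        if abs(r.stoichiometry.get(cofactor_id, 0.0)) > 0.0
    ]
    if count_mode == "consumption-only":
        touching = [(r, coef) for r, coef in touching if coef < 0]
    if not touching:
        return []

    ranges = {fr.reaction_id: fr for fr in run_fva(work, fraction_of_optimum=0.0)}
    out = []
    for r, coef in touching:
        fr = ranges[r.id]
        if coef > 0:
            capable = fr.max_flux > SYNTH_FLUX_TOL
        else:
            capable = fr.min_flux < -SYNTH_FLUX_TOL
        ko = solve_fba(knockout(work, reaction_ids=[r.id]))
        essential = not (ko.optimal and ko.objective_value > GROWTH_TOL)
        pseudo = r.category in ("demand", "exchange") or r.id == work.objective_id
        out.append(
            CofactorReaction(
                reaction_id=r.id,
                coefficient=coef,
                can_carry_synthesis_flux=capable,
                essential=essential,
                is_pseudo=pseudo,
            )
        )
    return out


def screen_alternative_producers(
    model: MetabolicModel,
    cofactor_id: str,
    reference_reaction_id: str,
    medium: Medium | None = None,
    full_deletion: bool = False,
    count_mode: str = "either-sign",
) -> ScreenResult:
    """Identify reactions that can independently supply the cofactor.

    Closes the synthesis direction of every non-essential synthesis-capable
    cofactor reaction (or deletes them outright with ``full_deletion``),
    checks the baseline growth is ~0, then re-opens each member alone —
    first the reference, then every other — and records all single
    restorations with growth above ``GROWTH_TOL``.  Biomass/demand/exchange
    pseudo-reactions are sinks, not producers, and are excluded from the
    knockout and candidate sets.
    """
    work = apply_medium(model, medium) if medium is not None else model.copy()
    annotated = find_cofactor_reactions(work, cofactor_id, count_mode=count_mode)
    by_id = {a.reaction_id: a for a in annotated}
    if reference_reaction_id not in by_id:
        raise ScreenError(
            f"reference {reference_reaction_id!r} does not involve {cofactor_id!r}"
        )
    if not by_id[reference_reaction_id].can_carry_synthesis_flux:
        raise ScreenError(
            f"reference {reference_reaction_id!r} cannot carry flux in the "
            f"{cofactor_id!r} synthesis direction"
        )

    members = [
        a.reaction_id
        for a in annotated
        if a.can_carry_synthesis_flux and not a.essential and not a.is_pseudo
    ]
    if reference_reaction_id not in members:
        members.append(reference_reaction_id)
    members = sorted(members)

    closed = work.copy()
    original_bounds = {}
    for rid in members:
        rxn = closed.reaction(rid)
        original_bounds[rid] = (rxn.lower_bound, rxn.upper_bound)
        if full_deletion:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        else:
            _close_synthesis_direction(rxn, by_id[rid].coefficient)

    base = solve_fba(closed)
    baseline = base.objective_value if base.optimal else 0.0
    if base.optimal and baseline > GROWTH_TOL:
        leaky = sorted(
            rid
            for rid, v in base.fluxes.items()
            if abs(v) > SYNTH_FLUX_TOL
            and abs(closed.reaction(rid).stoichiometry.get(cofactor_id, 0.0)) > 0
        )
        raise ScreenError(
            f"mass knockout leaves growth {baseline:.4g} > 0; cofactor flux "
            f"still flows through {leaky} — closed set incomplete"
        )

    def _restore_alone(rid: str) -> float:
        probe = closed.copy()
        rxn = probe.reaction(rid)
        rxn.lower_bound, rxn.upper_bound = original_bounds[rid]
        sol = solve_fba(probe)
        return sol.objective_value if sol.optimal else 0.0

    ref_rate = _restore_alone(reference_reaction_id)
    candidates = {}
    for rid in members:
        if rid == reference_reaction_id:
            continue
        rate = _restore_alone(rid)
        if rate > GROWTH_TOL:
            candidates[rid] = float(rate)

    return ScreenResult(
        cofactor_id=cofactor_id,
        reference_reaction_id=reference_reaction_id,
        total_cofactor_reactions=len(annotated),
        nonessential_synthesis_capable=members,
        baseline_growth_after_mass_knockout=float(max(baseline, 0.0)),
        reference_restores=ref_rate > GROWTH_TOL,
        reference_growth_rate=float(ref_rate),
        candidates=candidates,
    )
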
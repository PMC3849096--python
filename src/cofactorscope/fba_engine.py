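"""Linear-programming core: FBA, FVA, deletions, media, and growth calls.

Flux balance analysis solves

    max  v_biomass
    s.t. S v = 0,   v_min <= v <= v_max

with the HiGHS solver (scipy.optimize.linprog).  Flux variability analysis
re-solves min/max per reaction with the biomass flux constrained to a stated
fraction of its optimum.  Reaction and gene knockouts, medium application
(exchange-bound editing plus the non-growth ATP maintenance flux), and the
growth/no-growth predicate used against phenotype-microarray data are built
on the same LP.

All fluxes are mmol/gDW/h; the biomass flux is 1/h when the objective is a
biomass equation.  An objective value above ``GROWTH_TOL`` (1e-6) counts as
growth: LP solvers return numerical dust, so a strictly-positive test needs a
tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Reaction,
    build_stoich_matrix,
)

#: objective value above which a simulation counts as growth (1/h)
GROWTH_TOL = 1e-6

#: mass-balance tolerance for accepting an LP solution
BALANCE_TOL = 1e-6

#: default non-growth ATP maintenance flux, mmol/gDW/h
DEFAULT_ATPM = 8.39

#: reaction id carrying the ATP maintenance flux
ATPM_ID = "ATPM"


class FBAError(RuntimeError):
    """The LP could not be set up or solved as requested."""


@dataclass
class Medium:
    """Growth-medium specification.

    ``exchange_bounds`` maps exchange-reaction ids to (lower, upper) flux
    bounds in mmol/gDW/h (negative lower bound = uptake allowed).  ``atpm``
    is the non-growth ATP maintenance flux imposed as a lower bound on the
    ATPM reaction when the model has one.
    """

    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    atpm: float = DEFAULT_ATPM

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ValueError(f"medium entry {rid!r}: lower {lb} > upper {ub}")


@dataclass
class FluxSolution:
    """One steady-state flux vector.

    ``status`` is ``optimal``, ``infeasible`` or ``unbounded``;
    ``objective_value`` is the biomass flux; ``fluxes`` maps reaction id to
    flux.  On an optimal solution S.v = 0 holds within ``BALANCE_TOL`` and
    every flux is within its bounds.
    """

    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """FVA result for one reaction at a stated fraction of the optimum."""

    reaction_id: str
    min_flux: float
    max_flux: float
    fraction_of_optimum: float = 1.0


@dataclass
class GrowthCall:
    """Predicted utilisation of one substrate as sole C/N/P/S source."""

    substrate: str
    element_class: str
    predicted_growth: bool
    growth_rate: float
    reason: str = ""


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of the model with the medium imposed.

    Every exchange reaction not listed in the medium is made secretion-only,
    (0, 100); listed exchanges get the stated bounds verbatim.  If the model
    has an ATP maintenance reaction its lower bound is set to ``medium.atpm``.
    The input model is never mutated.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges}
    unknown = set(medium.exchange_bounds) - exchange_ids
    if unknown:
        raise FBAError(f"medium references unknown exchange reactions: {sorted(unknown)}")
    for r in out.reactions:
        if r.id in medium.exchange_bounds:
            r.lower_bound, r.upper_bound = medium.exchange_bounds[r.id]
        elif r.id in exchange_ids:
            r.lower_bound, r.upper_bound = 0.0, DEFAULT_BOUND
        elif r.id == ATPM_ID:
            r.lower_bound = max(r.lower_bound, medium.atpm)
    return out


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def _lp_arrays(model: MetabolicModel):
    sm = build_stoich_matrix(model)
    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(n)
    c[sm.col_index[model.objective_id]] = 1.0
    return sm, c, lb, ub


def _solve_lp(S, c_max, lb, ub):
    """Maximize c.v subject to S v = 0, lb <= v <= ub (HiGHS)."""
    res = linprog(
        -c_max,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res


def solve_fba(model: MetabolicModel) -> FluxSolution:
    """Maximise the biomass objective; return one optimal vertex.

    Degenerate optima return an arbitrary solver vertex — callers needing the
    whole optimal face must use the alternative-optima enumerator.
    """
    model.validate()
    sm, c, lb, ub = _lp_arrays(model)
    res = _solve_lp(sm.coefficients, c, lb, ub)
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=math.nan, fluxes={})
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=math.inf, fluxes={})
    if not res.success:
        raise FBAError(f"LP solver failure: {res.message}")
    fluxes = {rid: float(res.x[j]) for rid, j in sm.col_index.items()}
    return FluxSolution(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


def run_fva(
    model: MetabolicModel, fraction_of_optimum: float = 1.0
) -> list[FluxRange]:
    """Flux variability analysis.

    The biomass flux is fixed at >= fraction * optimum, then every reaction's
    flux is minimised and maximised.  The FBA vertex flux lies within every
    returned range at fraction <= 1.
    """
    if not (0.0 <= fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    sol = solve_fba(model)
    if not sol.optimal:
        raise FBAError(f"FVA requires an FBA optimum; status {sol.status}")
    sm, c, lb, ub = _lp_arrays(model)
    j_obj = sm.col_index[model.objective_id]
    lb = lb.copy()
    # small backoff keeps the constrained problem feasible at fraction 1.0
    lb[j_obj] = max(lb[j_obj], fraction_of_optimum * sol.objective_value - 1e-9)
    S = sm.coefficients
    out = []
    n = len(model.reactions)
    for rid, j in sm.col_index.items():
        direction = np.zeros(n)
        direction[j] = 1.0
        res_min = _solve_lp(S, -direction, lb, ub)
        res_max = _solve_lp(S, direction, lb, ub)
        if not (res_min.success and res_max.success):
            raise FBAError(f"FVA subproblem failed for {rid}")
        out.append(
            FluxRange(
                reaction_id=rid,
                min_flux=float(res_min.fun),  # min = -max(-v) = res.fun of min problem
                max_flux=float(-res_max.fun),
                fraction_of_optimum=fraction_of_optimum,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------


def knockout(
    model: MetabolicModel,
    reaction_ids: Iterable[str] = (),
    gene_ids: Iterable[str] = (),
) -> MetabolicModel:
    """Return a copy with reactions and/or genes deleted.

    Reaction knockouts close the reaction, bounds (0, 0).  Gene knockouts
    evaluate every GPR with the deleted genes inactive: a reaction is closed
    iff its boolean association becomes false (a deleted subunit kills an AND
    complex; an OR isozyme survives while any isozyme remains).
    """
    out = model.copy()
    reaction_ids = list(reaction_ids)
    gene_ids = list(gene_ids)
    known_rxns = set(out.reaction_ids)
    unknown = [rid for rid in reaction_ids if rid not in known_rxns]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    unknown_g = [g for g in gene_ids if g not in set(out.genes)]
    if unknown_g:
        raise KeyError(f"unknown gene ids: {unknown_g}")
    active = {g: g not in set(gene_ids) for g in out.genes}
    for r in out.reactions:
        if r.id in reaction_ids or (gene_ids and not r.gpr.evaluate(active)):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# Substrate growth prediction
# ---------------------------------------------------------------------------

#: uptake rate imposed on a tested carbon source, mmol/gDW/h
CARBON_UPTAKE = -4.0
#: uptake rate imposed on a tested N/P/S source, mmol/gDW/h
NPS_UPTAKE = -1.0


def predict_substrate_growth(
    model: MetabolicModel,
    substrate_exchange_id: str,
    element_class: str,
    default_sources: Mapping[str, str] | None = None,
    medium: Medium | None = None,
) -> GrowthCall:
    """Predict growth with one substrate as the sole source of an element.

    The default source of the tested element class (from ``default_sources``,
    a map element class -> exchange id) is closed, the test substrate's
    exchange is opened at -4 mmol/gDW/h for carbon or -1 mmol/gDW/h for
    N/P/S, FBA is run, and growth is called iff the objective exceeds
    ``GROWTH_TOL``.  Default sources of the *other* element classes stay open
    (e.g. a standing carbon source while nitrogen sources are probed).  A
    substrate whose exchange reaction is absent from the model is called
    no-growth with reason "no transporter/exchange" — the raw material of a
    model-gap (NGG) inconsistency.
    """
    if element_class not in ("C", "N", "P", "S"):
        raise ValueError(f"element_class must be C/N/P/S, got {element_class!r}")
    default_sources = dict(default_sources or {})
    work = apply_medium(model, medium) if medium is not None else model.copy()
    if not work.has_reaction(substrate_exchange_id):
        return GrowthCall(
            substrate=substrate_exchange_id,
            element_class=element_class,
            predicted_growth=False,
            growth_rate=0.0,
            reason="no transporter/exchange",
        )
    default_here = default_sources.get(element_class)
    for r in work.reactions:
        if default_here is not None and r.id == default_here:
            r.lower_bound = 0.0
            r.upper_bound = DEFAULT_BOUND
    test_rxn = work.reaction(substrate_exchange_id)
    uptake = CARBON_UPTAKE if element_class == "C" else NPS_UPTAKE
    test_rxn.lower_bound = uptake
    test_rxn.upper_bound = DEFAULT_BOUND
    sol = solve_fba(work)
    rate = sol.objective_value if sol.optimal else 0.0
    return GrowthCall(
        substrate=substrate_exchange_id,
        element_class=element_class,
        predicted_growth=bool(sol.optimal and rate > GROWTH_TOL),
        growth_rate=float(rate if sol.optimal else 0.0),
    )


# ---------------------------------------------------------------------------
# Solution checking (used by tests and by the alt-optima enumerator)
# ---------------------------------------------------------------------------


def check_solution(model: MetabolicModel, solution: FluxSolution, tol: float = BALANCE_TOL) -> float:
    """Return max |S.v| after asserting bound feasibility; raises on violation."""
    sm = build_stoich_matrix(model)
    v = np.array([solution.fluxes[rid] for rid in model.reaction_ids])
    for r in model.reactions:
        x = solution.fluxes[r.id]
        if x < r.lower_bound - tol or x > r.upper_bound + tol:
            raise AssertionError(
                f"flux {r.id}={x} outside bounds ({r.lower_bound}, {r.upper_bound})"
            )
    imbalance = float(np.abs(sm.coefficients @ v).max()) if v.size else 0.0
    if imbalance > tol:
        raise AssertionError(f"mass balance violated: max |S.v| = {imbalance}")
    return imbalance
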
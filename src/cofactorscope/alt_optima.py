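"""Alternative-optima enumeration and cofactor-demand estimation.

An FBA optimum is rarely unique: the optimum is attained on a face of the
flux polytope, and many distinct flux distributions share the same biomass
rate.  This module enumerates alternative optima as *distinct support
patterns* (sets of reactions carrying non-negligible flux) via a mixed
integer linear program: the objective is fixed at its optimum, every
reaction direction gets a binary activity indicator linked to its flux, and
integer "no-good" cuts exclude every previously seen support pattern until
the requested number of patterns is found or the face is exhausted.

The cofactor-demand estimator runs this enumeration with all alternative
producers of the cofactor closed, so every optimal solution must route
cofactor production through a single reference reaction (the
transhydrogenase, in the motivating analysis); the mean flux through that
reference across the alternative optima estimates the cofactor demand, with
its standard error quantifying solution-space spread.

Because an optimal face is a continuum, it usually holds fewer *distinct
support patterns* than the conventional fixed solution count (n = 1000).
When the face is exhausted early the solution list is padded, by default, to
the requested n with seeded random convex combinations of the patterns
already found — convexity keeps every padded point optimal and feasible —
so mean/SEM summaries over a fixed n remain well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba_engine import BALANCE_TOL, FBAError, FluxSolution, solve_fba
from .model_core import MetabolicModel, build_stoich_matrix

# The activity threshold must sit well above the MIP solver's integer
# feasibility tolerance (HiGHS default 1e-6, not adjustable through scipy):
# with the two equal, the solver may declare a binary active while leaving
# its flux at zero, silently breaking the support-pattern semantics.
#: |flux| above which a reaction counts as active in a support pattern
ACTIVITY_EPS = 1e-4

# The slack when fixing the objective must sit well below ACTIVITY_EPS
# (plus the solver's own feasibility tolerance): otherwise a reaction that
# *wastes* objective can be switched on at exactly the activity epsilon,
# manufacturing support patterns that do not exist on the true optimal face.
#: objective slack when fixing the biomass flux at its optimum
OPTIMUM_TOL = 1e-9

#: per-cut MILP time guard, seconds
MILP_TIME_LIMIT = 10.0


@dataclass
class AltOptimaSet:
    """Enumerated alternative optima.

    ``support_patterns`` are pairwise-distinct sets of active reaction ids;
    ``solutions`` holds one flux vector per pattern, plus padded convex
    combinations when fewer patterns exist than were requested.
    ``exhausted`` is True when the optimal face held fewer distinct patterns
    than requested; ``status`` is ``ok`` or ``time_limit`` (partial result).
    """

    objective_value: float
    solutions: list[FluxSolution] = field(default_factory=list)
    support_patterns: list[frozenset[str]] = field(default_factory=list)
    exhausted: bool = False
    status: str = "ok"


@dataclass
class DemandEstimate:
    """Mean and SEM of a reference reaction's flux across alternative optima."""

    reference_reaction_id: str
    mean_flux: float
    sem: float
    n_solutions: int


def _support(fluxes: dict[str, float], eps: float = ACTIVITY_EPS) -> frozenset[str]:
    return frozenset(rid for rid, v in fluxes.items() if abs(v) > eps)


def enumerate_alternative_optima(
    model: MetabolicModel,
    k: int,
    seed: int = 0,
    pad: bool = True,
    time_limit: float = MILP_TIME_LIMIT,
) -> AltOptimaSet:
    """Enumerate up to ``k`` distinct support patterns at the FBA optimum.

    The first pattern is the plain FBA vertex's support; subsequent patterns
    come from MILPs with integer cuts excluding everything already found.
    With ``pad`` (default), an early-exhausted face is padded to ``k``
    solutions by seeded convex combinations of the found solutions.
    Deterministic given the seed and solver.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    base = solve_fba(model)
    if not base.optimal:
        raise FBAError(f"no FBA optimum to enumerate around (status {base.status})")
    opt = base.objective_value

    sm = build_stoich_matrix(model)
    S = sparse.csr_matrix(sm.coefficients)
    m, n = S.shape
    rids = model.reaction_ids
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    big_f = np.maximum(ub, 0.0)  # forward big-M per reaction
    big_b = np.maximum(-lb, 0.0)

    solutions = [base]
    patterns = [_support(base.fluxes)]
    status = "ok"
    exhausted = False

    while len(patterns) < k:
        res = _solve_pattern_milp(
            S, lb, ub, big_f, big_b, rids, sm.col_index[model.objective_id],
            opt, patterns, time_limit,
        )
        if res is None:
            exhausted = True
            break
        if res == "time_limit":
            status = "time_limit"
            break
        fluxes, pattern = res
        if pattern in patterns:  # solver returned a known pattern: stop defensively
            exhausted = True
            break
        patterns.append(pattern)
        solutions.append(
            FluxSolution(status="optimal", objective_value=opt, fluxes=fluxes)
        )

    if pad and len(solutions) < k:
        rng = np.random.default_rng(seed)
        vertices = np.array(
            [[s.fluxes[rid] for rid in rids] for s in solutions]
        )
        for _ in range(k - len(solutions)):
            weights = rng.dirichlet(np.ones(len(vertices)))
            v = weights @ vertices
            solutions.append(
                FluxSolution(
                    status="optimal",
                    objective_value=opt,
                    fluxes=dict(zip(rids, map(float, v))),
                )
            )
    return AltOptimaSet(
        objective_value=opt,
        solutions=solutions,
        support_patterns=patterns,
        exhausted=exhausted,
        status=status,
    )


def _solve_pattern_milp(S, lb, ub, big_f, big_b, rids, j_obj, opt, patterns, time_limit):
    """One integer-cut MILP; returns (fluxes, pattern), None (infeasible) or
    'time_limit'."""
    m, n = S.shape
    # variables: vf (n), vb (n), yf (n), yb (n)
    nvar = 4 * n
    lo = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0), np.zeros(2 * n)])
    hi = np.concatenate([big_f, big_b, np.ones(2 * n)])
    # directions that cannot carry flux keep their binaries at zero
    hi[2 * n : 3 * n][big_f <= 0] = 0.0
    hi[3 * n : 4 * n][big_b <= 0] = 0.0
    integrality = np.concatenate([np.zeros(2 * n), np.ones(2 * n)])

    eye = sparse.identity(n, format="csr")
    zero_mn = sparse.csr_matrix((m, n))
    constraints = []

    # mass balance S (vf - vb) = 0
    constraints.append(
        LinearConstraint(sparse.hstack([S, -S, zero_mn, zero_mn]), 0.0, 0.0)
    )
    # objective fixed at optimum: v_obj >= opt - tol
    c_obj = np.zeros(nvar)
    c_obj[j_obj] = 1.0
    c_obj[n + j_obj] = -1.0
    constraints.append(LinearConstraint(c_obj[None, :], opt - OPTIMUM_TOL, np.inf))
    # big-M linking: vf <= big_f * yf  and  vf >= eps * yf (same for backward)
    zero_nn = sparse.csr_matrix((n, n))
    constraints.append(
        LinearConstraint(
            sparse.hstack([eye, zero_nn, -sparse.diags(big_f), zero_nn]), -np.inf, 0.0
        )
    )
    constraints.append(
        LinearConstraint(
            sparse.hstack([eye, zero_nn, -ACTIVITY_EPS * eye, zero_nn]), 0.0, np.inf
        )
    )
    constraints.append(
        LinearConstraint(
            sparse.hstack([zero_nn, eye, zero_nn, -sparse.diags(big_b)]), -np.inf, 0.0
        )
    )
    constraints.append(
        LinearConstraint(
            sparse.hstack([zero_nn, eye, zero_nn, -ACTIVITY_EPS * eye]), 0.0, np.inf
        )
    )
    # one direction at a time: yf + yb <= 1
    constraints.append(
        LinearConstraint(sparse.hstack([zero_nn, zero_nn, eye, eye]), -np.inf, 1.0)
    )
    # integer cuts: for pattern P,  sum_{j in P} (1 - yf_j - yb_j)
    #                             + sum_{j not in P} (yf_j + yb_j) >= 1
    idx = {rid: j for j, rid in enumerate(rids)}
    for pattern in patterns:
        row = np.zeros(nvar)
        in_p = np.zeros(n, dtype=bool)
        for rid in pattern:
            in_p[idx[rid]] = True
        row[2 * n : 3 * n] = np.where(in_p, -1.0, 1.0)
        row[3 * n : 4 * n] = np.where(in_p, -1.0, 1.0)
        constraints.append(
            LinearConstraint(row[None, :], 1.0 - float(in_p.sum()), np.inf)
        )

    # prefer sparse supports: minimise the number of active directions
    objective = np.concatenate([np.zeros(2 * n), np.ones(2 * n)])
    res = milp(
        objective,
        constraints=constraints,
        bounds=Bounds(lo, hi),
        integrality=integrality,
        options={"time_limit": time_limit, "mip_rel_gap": 0.0},
    )
    if res.status == 2:  # infeasible: the face is exhausted
        return None
    if res.x is None:
        return "time_limit"
    vf = res.x[:n]
    vb = res.x[n : 2 * n]
    v = vf - vb
    fluxes = {rid: float(v[j]) for j, rid in enumerate(rids)}
    # support from the binaries: a flux sitting exactly at the activity
    # epsilon is active by construction but would fail a strict |v| > eps test
    y = res.x[2 * n : 3 * n] + res.x[3 * n : 4 * n]
    pattern = frozenset(rid for j, rid in enumerate(rids) if y[j] > 0.5)
    return fluxes, pattern


def estimate_cofactor_demand(
    model: MetabolicModel,
    reference_reaction_id: str,
    k: int = 1000,
    seed: int = 0,
) -> DemandEstimate:
    """Estimate cofactor demand as the mean reference-reaction flux across
    ``k`` alternative optima.

    The caller must already have closed all other producers of the cofactor,
    so the reference reaction is the sole source and its flux reads out the
    whole-network demand.  SEM is the sample standard error over the
    enumerated (and padded) solutions; it is 0 when the flux is invariant on
    the optimal face.
    """
    rxn = model.reaction(reference_reaction_id)  # KeyError if absent
    if rxn.lower_bound == 0.0 and rxn.upper_bound == 0.0:
        raise FBAError(
            f"reference reaction {reference_reaction_id!r} is closed; "
            "cannot estimate demand through it"
        )
    alt = enumerate_alternative_optima(model, k=k, seed=seed, pad=True)
    values = np.array([s.fluxes[reference_reaction_id] for s in alt.solutions])
    if values.size == 0:
        raise FBAError("no alternative optima found")
    mean = float(values.mean())
    if values.size > 1 and float(values.std(ddof=1)) > BALANCE_TOL:
        sem = float(values.std(ddof=1) / math.sqrt(values.size))
    else:
        sem = 0.0
    return DemandEstimate(
        reference_reaction_id=reference_reaction_id,
        mean_flux=mean,
        sem=sem,
        n_solutions=int(values.size),
    )
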
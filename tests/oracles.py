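"""Brute-force oracles, independent of the production LP/MILP path.

Everything here works by exhaustive enumeration of basic solutions
(vertices) of the flux polytope {S v = b, lb <= v <= ub}: a vertex fixes
n - rank(S) variables at a bound and solves the remaining square system.
Feasible for the toy networks (<= ~12 reactions) these oracles are meant
for; never used by the package itself.
"""

from __future__ import annotations

import itertools

import numpy as np

VERTEX_TOL = 1e-7


def enumerate_vertices(S, b, lb, ub, tol=VERTEX_TOL):
    """All feasible basic solutions (vertices) of {S v = b, lb <= v <= ub}."""
    S = np.asarray(S, dtype=float)
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    vertices = []
    seen = set()
    for fixed in itertools.combinations(range(n), k):
        basic = [j for j in range(n) if j not in fixed]
        S_b = S[:, basic]
        if basic and np.linalg.matrix_rank(S_b) < len(basic):
            continue  # basis not unique; other fixings cover these points
        for signs in itertools.product((0, 1), repeat=k):
            v = np.empty(n)
            for j, s in zip(fixed, signs):
                v[j] = ub[j] if s else lb[j]
            rhs = b - S[:, list(fixed)] @ v[list(fixed)] if k else b
            if basic:
                sol, *_ = np.linalg.lstsq(S_b, rhs, rcond=None)
                v[basic] = sol
            if np.max(np.abs(S @ v - b), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            key = tuple(np.round(v, 7))
            if key not in seen:
                seen.add(key)
                vertices.append(np.clip(v, lb, ub))
    return vertices


def solve_lp_by_vertices(S, lb, ub, c):
    """max c.v over {S v = 0, lb <= v <= ub}; returns (optimum, argmax vertex)
    or (None, None) when infeasible.  Valid because the polytope is bounded."""
    S = np.asarray(S, dtype=float)
    verts = enumerate_vertices(S, np.zeros(S.shape[0]), lb, ub)
    if not verts:
        return None, None
    values = [float(np.dot(c, v)) for v in verts]
    best = int(np.argmax(values))
    return values[best], verts[best]


def optimal_face_vertices(S, lb, ub, c, tol=1e-6):
    """Vertices of the optimal face {S v = 0, c.v = opt, bounds}."""
    opt, _ = solve_lp_by_vertices(S, lb, ub, c)
    assert opt is not None, "infeasible polytope has no optimal face"
    S_ext = np.vstack([S, np.asarray(c, dtype=float)])
    b_ext = np.concatenate([np.zeros(S.shape[0]), [opt]])
    return opt, enumerate_vertices(S_ext, b_ext, lb, ub, tol=tol)


def fva_by_vertices(S, lb, ub, c, fraction=1.0):
    """Per-reaction flux min/max with the objective held at fraction * opt.

    At fraction 1 the extreme of a linear function over the optimal face is
    attained at a face vertex; below 1 the constraint c.v >= f*opt makes a
    polytope whose vertices we enumerate by adding a slack variable.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    if fraction >= 1.0:
        _, verts = optimal_face_vertices(S, lb, ub, c)
    else:
        opt, _ = solve_lp_by_vertices(S, lb, ub, c)
        # c.v - s = fraction*opt with slack s >= 0 turns the inequality into
        # an equality the vertex enumerator understands
        S_ext = np.hstack([np.vstack([S, c]), np.zeros((S.shape[0] + 1, 1))])
        S_ext[-1, -1] = -1.0
        b_ext = np.concatenate([np.zeros(S.shape[0]), [fraction * opt]])
        big = float(np.abs(c).sum() * np.max(np.abs([lb, ub])) + 1.0)
        verts = enumerate_vertices(
            S_ext, b_ext, np.append(lb, 0.0), np.append(ub, big)
        )
        verts = [v[:n] for v in verts]
    vmat = np.array(verts)
    return vmat.min(axis=0), vmat.max(axis=0)


def optimal_support_patterns(S, lb, ub, c, reaction_ids, eps=1e-4):
    """Achievable support patterns on the optimal face.

    Computed as unions of optimal-vertex supports over non-empty vertex
    subsets — exact when no flux changes sign across the face's vertices
    (asserted), since then every convex combination's support is the union
    of the combined vertices' supports.
    """
    _, verts = optimal_face_vertices(S, lb, ub, c)
    vmat = np.array(verts)
    signs_ok = ~np.any((vmat.min(axis=0) < -eps) & (vmat.max(axis=0) > eps))
    assert signs_ok, "oracle assumption violated: flux changes sign across face"
    supports = [
        frozenset(rid for j, rid in enumerate(reaction_ids) if abs(v[j]) > eps)
        for v in verts
    ]
    patterns = set()
    for size in range(1, len(supports) + 1):
        for combo in itertools.combinations(supports, size):
            patterns.add(frozenset().union(*combo))
    return patterns


# ---------------------------------------------------------------------------
# Model-level conveniences
# ---------------------------------------------------------------------------


def model_arrays(model):
    from cofactorscope import build_stoich_matrix

    sm = build_stoich_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(model.reactions))
    c[sm.col_index[model.objective_id]] = 1.0
    return sm.coefficients, lb, ub, c


def oracle_fba(model):
    """Objective optimum by vertex enumeration (0 treated as no growth)."""
    S, lb, ub, c = model_arrays(model)
    opt, _ = solve_lp_by_vertices(S, lb, ub, c)
    return opt


def oracle_screen(model, cofactor_id, reference_id, growth_tol=1e-6):
    """Exhaustive single-restoration screen using only the vertex LP oracle."""
    S, lb, ub, c = model_arrays(model)
    rids = model.reaction_ids
    coef = {
        r.id: r.stoichiometry.get(cofactor_id, 0.0)
        for r in model.reactions
        if abs(r.stoichiometry.get(cofactor_id, 0.0)) > 0
    }
    fmin, fmax = fva_by_vertices(S, lb, ub, c, fraction=0.0)
    j_of = {rid: j for j, rid in enumerate(rids)}

    def close(lb_, ub_, rid):
        j = j_of[rid]
        lb2, ub2 = lb_.copy(), ub_.copy()
        if coef[rid] > 0:
            ub2[j] = min(ub2[j], 0.0)
            lb2[j] = min(lb2[j], ub2[j])
        else:
            lb2[j] = max(lb2[j], 0.0)
            ub2[j] = max(ub2[j], lb2[j])
        return lb2, ub2

    members = []
    for rid in sorted(coef):
        j = j_of[rid]
        capable = (coef[rid] > 0 and fmax[j] > growth_tol) or (
            coef[rid] < 0 and fmin[j] < -growth_tol
        )
        rxn = model.reaction(rid)
        pseudo = rxn.category in ("demand", "exchange") or rid == model.objective_id
        if not capable or pseudo:
            continue
        lb_ko, ub_ko = lb.copy(), ub.copy()
        lb_ko[j] = ub_ko[j] = 0.0
        opt_ko, _ = solve_lp_by_vertices(S, lb_ko, ub_ko, c)
        essential = opt_ko is None or opt_ko <= growth_tol
        if not essential:
            members.append(rid)
    if reference_id not in members:
        members.append(reference_id)

    lb_all, ub_all = lb.copy(), ub.copy()
    for rid in members:
        lb_all, ub_all = close(lb_all, ub_all, rid)
    baseline, _ = solve_lp_by_vertices(S, lb_all, ub_all, c)

    restores = {}
    for rid in members:
        j = j_of[rid]
        lb_r, ub_r = lb_all.copy(), ub_all.copy()
        lb_r[j], ub_r[j] = lb[j], ub[j]
        opt_r, _ = solve_lp_by_vertices(S, lb_r, ub_r, c)
        if opt_r is not None and opt_r > growth_tol:
            restores[rid] = opt_r
    candidates = {rid: v for rid, v in restores.items() if rid != reference_id}
    return {
        "members": sorted(members),
        "baseline": 0.0 if baseline is None else baseline,
        "reference_restores": reference_id in restores,
        "reference_rate": restores.get(reference_id, 0.0),
        "candidates": candidates,
    }


def minimal_addition_sets(model, exchange_id, element_class, defaults, catalogue, cap):
    """All minimum-cardinality catalogue subsets whose addition enables
    growth, found by exhaustive search with the vertex LP oracle."""
    from cofactorscope.pm_analysis import _extended_model
    from cofactorscope.fba_engine import CARBON_UPTAKE, NPS_UPTAKE, DEFAULT_BOUND

    best: list[tuple[str, ...]] = []
    for size in range(0, cap + 1):
        for combo in itertools.combinations(sorted(catalogue, key=lambda r: r.id), size):
            ext = _extended_model(model, [], list(combo))
            work = ext.copy()
            default_here = defaults.get(element_class)
            for r in work.reactions:
                if default_here is not None and r.id == default_here:
                    r.lower_bound, r.upper_bound = 0.0, DEFAULT_BOUND
            rxn = work.reaction(exchange_id)
            rxn.lower_bound = CARBON_UPTAKE if element_class == "C" else NPS_UPTAKE
            rxn.upper_bound = DEFAULT_BOUND
            opt = oracle_fba(work)
            if opt is not None and opt > 1e-6:
                best.append(tuple(r.id for r in combo))
        if best:
            return best
    return best
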
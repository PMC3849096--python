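"""E-flux: expression-constrained flux bounds.

E-flux shrinks each reaction's flux bounds in proportion to the measured
expression of its associated genes, so poorly expressed enzymes cannot carry
large fluxes.  Expression values are first normalised to activities in
[0, 1]; each reaction's activity is then read off its GPR tree — the maximum
over OR branches (isozymes: the best-expressed isozyme carries the reaction)
and the minimum over AND branches (complexes: the worst-expressed subunit
limits the enzyme).  GPR-bearing reactions get bounds

    upper = vmax_scale * activity
    lower = -vmax_scale * activity  (reversible)  or 0 (forward-only)

while GPR-free reactions keep (0, 100) or (-100, 100) and exchange/demand
pseudo-reactions are never touched (they have no enzymes).  The constrained
model is then simulated with ordinary FBA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .model_core import DEFAULT_BOUND, GPRExpression, MetabolicModel

logger = logging.getLogger("cofactorscope")


@dataclass
class ExpressionProfile:
    """Normalised gene activities in [0, 1].

    Genes absent from the measurement are *missing*, not zero — a missing
    probe is no evidence of absence.
    """

    activities: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.activities.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"activities outside [0, 1]: {bad}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.activities

    def get(self, gene: str, default: float | None = None) -> float | None:
        return self.activities.get(gene, default)


@dataclass
class EfluxResult:
    """An expression-constrained model plus the per-reaction activity applied
    (1.0 for reactions without a gene association)."""

    model: MetabolicModel
    reaction_activity: dict[str, float] = field(default_factory=dict)


def normalize_expression(
    raw: Mapping[str, float], provenance: str = "", mode: str = "global-max"
) -> ExpressionProfile:
    """Scale raw expression values to activities in [0, 1].

    ``global-max`` (default) divides every value by the dataset-wide maximum,
    so the most-expressed gene gets activity 1.0.  ``per-gene`` is accepted
    for callers that pre-compute per-gene maxima across conditions and pass
    already-comparable values; it applies the same global-max formula to
    whatever was passed, existing as an explicit tag of that convention.
    """
    if mode not in ("global-max", "per-gene"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not raw:
        raise ValueError("empty expression table")
    neg = {g: v for g, v in raw.items() if v < 0}
    if neg:
        raise ValueError(f"negative expression values: {neg}")
    peak = max(raw.values())
    if peak <= 0:
        raise ValueError("all expression values are zero; cannot normalize")
    return ExpressionProfile(
        activities={g: v / peak for g, v in raw.items()}, provenance=provenance
    )


def gpr_activity(gpr: GPRExpression, profile: ExpressionProfile) -> float:
    """Activity of a reaction's gene association under a profile.

    OR -> max of children (isozymes), AND -> min of children (subunits),
    empty -> 1.0 (unconstrained).  A gene missing from the profile
    contributes 1.0 with a warning: an absent measurement must not silently
    close the reaction.
    """
    if gpr.is_empty:
        return 1.0
    if gpr.op == "gene":
        value = profile.get(gpr.gene)
        if value is None:
            logger.warning(
                "gene %s missing from expression profile %s; treated as "
                "unconstraining (activity 1.0)",
                gpr.gene,
                profile.provenance or "<unnamed>",
            )
            return 1.0
        return float(value)
    child_vals = [gpr_activity(c, profile) for c in gpr.children]
    return min(child_vals) if gpr.op == "and" else max(child_vals)


def apply_eflux(
    model: MetabolicModel,
    profile: ExpressionProfile,
    vmax_scale: float = DEFAULT_BOUND,
) -> EfluxResult:
    """Build the expression-constrained model.

    Every new bound interval is a subset of the original: upper bounds are
    ``min(original_upper, vmax_scale * activity)`` and lower bounds
    ``max(original_lower, -vmax_scale * activity)`` (0 stays 0 for
    forward-only reactions).  Exchange and demand reactions are never
    constrained.  A unit profile therefore reduces E-flux to plain FBA.
    """
    model.validate()
    out = model.copy()
    applied: dict[str, float] = {}
    for r in out.reactions:
        if r.category in ("exchange", "demand") or r.gpr.is_empty:
            applied[r.id] = 1.0
            continue
        activity = gpr_activity(r.gpr, profile)
        applied[r.id] = activity
        r.upper_bound = min(r.upper_bound, vmax_scale * activity)
        r.lower_bound = max(r.lower_bound, -vmax_scale * activity)
        if r.lower_bound > r.upper_bound:  # can only arise from pathological inputs
            r.lower_bound = r.upper_bound
    return EfluxResult(model=out, reaction_activity=applied)


def read_expression_tsv(path: str, condition: str | None = None) -> dict[str, float]:
    """Read a gene-expression TSV.

    Two-column files (gene_id, value) need no header; wide files with a
    header row require ``condition`` naming the column to use.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if condition is not None:
        if condition not in df.columns:
            raise KeyError(f"condition column {condition!r} not in {list(df.columns)}")
        return dict(zip(df.iloc[:, 0].astype(str), df[condition].astype(float)))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    # two-column file: tolerate files written with or without a header
    first_col = df.columns[1]
    try:
        float(first_col)
        df = pd.read_csv(path, sep="\t", header=None)
    except (TypeError, ValueError):
        pass
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
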
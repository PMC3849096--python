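"""Phenotype-microarray growth calling and model reconciliation.

Biolog phenotype microarrays (PM) probe growth on 95 substrates plus a
negative-control well (A1) per 96-well plate.  Readings are endpoint OD650
for photosynthetic/anaerobic assays or summary Omnilog units for aerobic
respiration.  Growth calling subtracts the A1 background, floors at zero,
and scores growth only when the corrected reading clears the
condition-specific threshold (0.05 OD650; 5 Omnilog units) in *every*
replicate — single-replicate blips do not count.

Model reconciliation cross-tabulates PM calls against FBA growth
predictions into the four consistency categories

    GG    growth predicted, growth observed
    GNG   growth predicted, no growth observed
    NGG   no growth predicted, growth observed   (model gap)
    NGNG  no growth predicted, none observed

and proposes refinements: NGG gaps are closed by the smallest set of
reactions from a universal catalogue (breadth-first over subset cardinality,
plus an auto-generated exchange/transport pair when the substrate is absent
from the model); GNG conflicts are resolved by removing the substrate's
transport reactions, accepted only when re-comparison introduces no new
inconsistency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .fba_engine import Medium, predict_substrate_growth
from .model_core import MetabolicModel, Metabolite, Reaction

#: OD650 threshold for photosynthetic (and anaerobic OD-based) growth calls
OD_THRESHOLD = 0.05

#: Omnilog-unit threshold for aerobic respiratory calls
OMNILOG_THRESHOLD = 5.0

PLATE_CONDITIONS = ("photosynthetic", "aerobic", "anaerobic")

_WELL_IDS = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))

CONTROL_WELL = "A1"


class PMValidationError(ValueError):
    """A plate file violates the 96-well layout contract."""


@dataclass
class PMWell:
    well: str
    substrate: str
    element_class: str
    reading: float


@dataclass
class PMPlate:
    """One 96-well plate reading (one replicate).

    ``condition`` selects the growth-call threshold; well A1 is the negative
    control whose reading is subtracted from every other well.
    """

    plate_id: str
    condition: str
    replicate: int
    wells: dict[str, PMWell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in PLATE_CONDITIONS:
            raise PMValidationError(
                f"plate {self.plate_id!r}: unknown condition {self.condition!r}"
            )
        missing = [w for w in _WELL_IDS if w not in self.wells]
        if missing:
            raise PMValidationError(
                f"plate {self.plate_id!r} replicate {self.replicate}: "
                f"missing wells {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        if len(self.wells) != 96:
            extra = sorted(set(self.wells) - set(_WELL_IDS))
            raise PMValidationError(
                f"plate {self.plate_id!r}: {len(self.wells)} wells; unexpected {extra}"
            )
        negative = [w.well for w in self.wells.values() if w.reading < 0]
        if negative:
            raise PMValidationError(
                f"plate {self.plate_id!r}: negative readings in wells {negative}"
            )

    @property
    def control_reading(self) -> float:
        return self.wells[CONTROL_WELL].reading

    def threshold(self) -> float:
        return OMNILOG_THRESHOLD if self.condition == "aerobic" else OD_THRESHOLD


@dataclass
class SubstrateCall:
    """Growth call for one substrate under one condition, across replicates."""

    substrate: str
    element_class: str
    condition: str
    corrected_value: float  # minimum corrected reading across replicates
    growth: bool
    n_replicates: int


@dataclass
class ConsistencyReport:
    """Per-element-class 2x2 consistency tallies against model predictions."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    per_substrate: dict[str, str] = field(default_factory=dict)

    def totals(self) -> dict[str, int]:
        out = {"GG": 0, "GNG": 0, "NGG": 0, "NGNG": 0}
        for cls_counts in self.counts.values():
            for key in out:
                out[key] += cls_counts.get(key, 0)
        return out

    @property
    def n_substrates(self) -> int:
        return sum(self.totals().values())

    @property
    def agreement(self) -> float:
        t = self.totals()
        n = sum(t.values())
        return (t["GG"] + t["NGNG"]) / n if n else float("nan")


@dataclass
class RefinementProposal:
    """A proposed model edit resolving one PM inconsistency."""

    substrate: str
    inconsistency: str  # "NGG" or "GNG"
    action: str  # "add-reactions", "remove-transport", "none found (cap k)"
    reaction_ids: list[str] = field(default_factory=list)
    new_inconsistencies: int = 0


# ---------------------------------------------------------------------------
# Plate I/O
# ---------------------------------------------------------------------------

_PM_COLUMNS = [
    "plate_id",
    "condition",
    "well",
    "substrate",
    "element_class",
    "replicate",
    "reading",
]


def load_pm_data(path: str) -> list[PMPlate]:
    """Read plates from CSV with columns plate_id, condition, well, substrate,
    element_class, replicate, reading; one row per well per replicate."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in _PM_COLUMNS if c not in df.columns]
    if missing:
        raise PMValidationError(f"{path}: missing columns {missing}")
    plates = []
    for (plate_id, replicate), grp in df.groupby(["plate_id", "replicate"], sort=True):
        dup = grp["well"][grp["well"].duplicated()].tolist()
        if dup:
            raise PMValidationError(
                f"{path}: plate {plate_id!r} replicate {replicate}: "
                f"duplicate wells {sorted(set(dup))}"
            )
        conditions = grp["condition"].unique()
        if len(conditions) != 1:
            raise PMValidationError(
                f"{path}: plate {plate_id!r} mixes conditions {sorted(conditions)}"
            )
        wells = {
            row.well: PMWell(
                well=row.well,
                substrate=str(row.substrate),
                element_class=str(row.element_class),
                reading=float(row.reading),
            )
            for row in grp.itertuples()
        }
        plates.append(
            PMPlate(
                plate_id=str(plate_id),
                condition=str(conditions[0]),
                replicate=int(replicate),
                wells=wells,
            )
        )
    return plates


def write_pm_data(plates: Sequence[PMPlate], path: str) -> None:
    """Write plates back to the CSV layout accepted by :func:`load_pm_data`."""
    import pandas as pd

    rows = [
        {
            "plate_id": p.plate_id,
            "condition": p.condition,
            "well": w.well,
            "substrate": w.substrate,
            "element_class": w.element_class,
            "replicate": p.replicate,
            "reading": w.reading,
        }
        for p in plates
        for w in (p.wells[wid] for wid in _WELL_IDS)
    ]
    pd.DataFrame(rows, columns=_PM_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Growth calling
# ---------------------------------------------------------------------------


def call_substrates(plates: Sequence[PMPlate]) -> list[SubstrateCall]:
    """Call growth per substrate from background-corrected replicate readings.

    Corrected reading = max(reading - A1 reading, 0).  A substrate is a
    growth substrate iff its corrected reading clears the condition threshold
    in every replicate.  Replicates are grouped by plate_id; all replicates
    of a plate must share the same condition and substrate layout.
    """
    by_plate: dict[str, list[PMPlate]] = {}
    for p in plates:
        by_plate.setdefault(p.plate_id, []).append(p)

    calls: list[SubstrateCall] = []
    for plate_id, reps in sorted(by_plate.items()):
        conditions = {p.condition for p in reps}
        if len(conditions) != 1:
            raise PMValidationError(
                f"plate {plate_id!r}: replicates mix conditions {sorted(conditions)}"
            )
        condition = reps[0].condition
        threshold = reps[0].threshold()
        layout = {w: reps[0].wells[w].substrate for w in _WELL_IDS}
        for p in reps[1:]:
            if {w: p.wells[w].substrate for w in _WELL_IDS} != layout:
                raise PMValidationError(
                    f"plate {plate_id!r}: replicate {p.replicate} has a "
                    "different substrate layout"
                )
        for well_id in _WELL_IDS:
            if well_id == CONTROL_WELL:
                continue
            substrate = layout[well_id]
            corrected = [
                max(p.wells[well_id].reading - p.control_reading, 0.0) for p in reps
            ]
            calls.append(
                SubstrateCall(
                    substrate=substrate,
                    element_class=reps[0].wells[well_id].element_class,
                    condition=condition,
                    corrected_value=min(corrected),
                    growth=all(c >= threshold for c in corrected),
                    n_replicates=len(reps),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Model-vs-PM comparison
# ---------------------------------------------------------------------------


def compare_model_pm(
    model: MetabolicModel,
    medium_defaults: Mapping[str, str],
    calls: Sequence[SubstrateCall],
    substrate_map: Mapping[str, str | None],
    medium: Medium | None = None,
) -> ConsistencyReport:
    """Cross-tabulate FBA growth predictions against PM calls.

    ``medium_defaults`` maps element class to the default-source exchange id
    (closed when that class is probed); ``substrate_map`` maps substrate name
    to its exchange-reaction id, or None/missing when the model lacks the
    compound — such substrates are predicted no-growth, so an observed-growth
    call lands in NGG.
    """
    report = ConsistencyReport()
    for call in calls:
        exchange_id = substrate_map.get(call.substrate)
        if exchange_id is None:
            predicted = False
        else:
            gc = predict_substrate_growth(
                model,
                exchange_id,
                call.element_class,
                default_sources=medium_defaults,
                medium=medium,
            )
            predicted = gc.predicted_growth
        key = ("GG" if call.growth else "GNG") if predicted else (
            "NGG" if call.growth else "NGNG"
        )
        cls_counts = report.counts.setdefault(
            call.element_class, {"GG": 0, "GNG": 0, "NGG": 0, "NGNG": 0}
        )
        cls_counts[key] += 1
        report.per_substrate[call.substrate] = key
    return report


# ---------------------------------------------------------------------------
# Refinement proposals
# ---------------------------------------------------------------------------

#: default cap on the number of reactions added to fix one NGG gap
BFS_CAP = 3


def _auto_uptake_pair(model: MetabolicModel, substrate: str) -> tuple[list[Metabolite], list[Reaction], str]:
    """Exchange + transport pair for a substrate absent from the model."""
    ext_id = f"{substrate}_e"
    cyt_id = f"{substrate}_c"
    mets = []
    for mid, comp in ((ext_id, "e"), (cyt_id, "c")):
        if not any(m.id == mid for m in model.metabolites):
            mets.append(Metabolite(id=mid, name=substrate, compartment=comp))
    rxns = [
        Reaction(
            id=f"EX_{substrate}",
            stoichiometry={ext_id: -1.0},
            lower_bound=-100.0,
            upper_bound=100.0,
            category="exchange",
        ),
        Reaction(
            id=f"T_{substrate}",
            stoichiometry={ext_id: -1.0, cyt_id: 1.0},
            lower_bound=-100.0,
            upper_bound=100.0,
            category="transport",
        ),
    ]
    return mets, [r for r in rxns if not model.has_reaction(r.id)], f"EX_{substrate}"


def _extended_model(
    model: MetabolicModel,
    extra_mets: Sequence[Metabolite],
    extra_rxns: Sequence[Reaction],
) -> MetabolicModel:
    out = model.copy()
    known = set(out.metabolite_ids)
    for m in extra_mets:
        if m.id not in known:
            out.metabolites.append(m)
            known.add(m.id)
    for r in extra_rxns:
        out.reactions.append(replace(r, stoichiometry=dict(r.stoichiometry)))
        for mid in r.stoichiometry:
            if mid not in known:
                comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
                out.metabolites.append(
                    Metabolite(id=mid, compartment=comp if comp in ("c", "e", "p") else "c")
                )
                known.add(mid)
    out.genes = sorted({g for r in out.reactions for g in r.gpr.genes()})
    return out


def propose_refinements(
    model: MetabolicModel,
    medium_defaults: Mapping[str, str],
    calls: Sequence[SubstrateCall],
    substrate_map: Mapping[str, str | None],
    universal_reactions: Sequence[Reaction] = (),
    medium: Medium | None = None,
    cap: int = BFS_CAP,
) -> list[RefinementProposal]:
    """Propose model edits for every NGG and GNG inconsistency.

    NGG: breadth-first search over subsets of the universal catalogue by
    increasing cardinality (ties broken lexicographically on reaction ids),
    after auto-adding an exchange/transport pair when the model lacks the
    substrate; the first subset whose addition yields predicted growth wins.
    GNG: tentatively remove the substrate's transport reactions and re-run
    the full comparison; the removal is proposed only when it introduces no
    new inconsistency on any other substrate.
    """
    report = compare_model_pm(model, medium_defaults, calls, substrate_map, medium)
    calls_by_substrate = {c.substrate: c for c in calls}
    proposals: list[RefinementProposal] = []

    for substrate, category in sorted(report.per_substrate.items()):
        if category == "NGG":
            proposals.append(
                _fix_ngg(
                    model,
                    medium_defaults,
                    calls_by_substrate[substrate],
                    substrate_map,
                    universal_reactions,
                    medium,
                    cap,
                )
            )
        elif category == "GNG":
            proposals.append(
                _fix_gng(
                    model,
                    medium_defaults,
                    calls,
                    substrate_map,
                    medium,
                    substrate,
                    report,
                )
            )
    return proposals


def _fix_ngg(
    model,
    medium_defaults,
    call: SubstrateCall,
    substrate_map,
    universal_reactions,
    medium,
    cap,
) -> RefinementProposal:
    substrate = call.substrate
    exchange_id = substrate_map.get(substrate)
    base_mets: list[Metabolite] = []
    base_rxns: list[Reaction] = []
    if exchange_id is None or not model.has_reaction(exchange_id):
        base_mets, base_rxns, exchange_id = _auto_uptake_pair(model, substrate)

    catalogue = sorted(universal_reactions, key=lambda r: r.id)
    for size in range(0, cap + 1):
        for combo in itertools.combinations(catalogue, size):
            extended = _extended_model(model, base_mets, list(base_rxns) + list(combo))
            gc = predict_substrate_growth(
                extended,
                exchange_id,
                call.element_class,
                default_sources=medium_defaults,
                medium=medium,
            )
            if gc.predicted_growth:
                added = [r.id for r in base_rxns] + [r.id for r in combo]
                return RefinementProposal(
                    substrate=substrate,
                    inconsistency="NGG",
                    action="add-reactions",
                    reaction_ids=added,
                )
    return RefinementProposal(
        substrate=substrate,
        inconsistency="NGG",
        action=f"none found (cap {cap})",
    )


def _fix_gng(
    model,
    medium_defaults,
    calls,
    substrate_map,
    medium,
    substrate,
    baseline_report: ConsistencyReport,
) -> RefinementProposal:
    exchange_id = substrate_map.get(substrate)
    transporters = []
    if exchange_id is not None and model.has_reaction(exchange_id):
        carried = set(model.reaction(exchange_id).stoichiometry)
        transporters = [
            r.id
            for r in model.reactions
            if r.category == "transport" and carried & set(r.stoichiometry)
        ]
    if not transporters:
        return RefinementProposal(
            substrate=substrate,
            inconsistency="GNG",
            action="no transporter found",
        )
    trimmed = model.copy()
    for rid in transporters:
        rxn = trimmed.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    new_report = compare_model_pm(trimmed, medium_defaults, calls, substrate_map, medium)
    regressions = sum(
        1
        for sub, cat in new_report.per_substrate.items()
        if sub != substrate
        and cat in ("GNG", "NGG")
        and baseline_report.per_substrate.get(sub) in ("GG", "NGNG")
    )
    if regressions == 0 and new_report.per_substrate.get(substrate) == "NGNG":
        return RefinementProposal(
            substrate=substrate,
            inconsistency="GNG",
            action="remove-transport",
            reaction_ids=sorted(transporters),
            new_inconsistencies=0,
        )
    return RefinementProposal(
        substrate=substrate,
        inconsistency="GNG",
        action="removal rejected (new inconsistencies)",
        reaction_ids=sorted(transporters),
        new_inconsistencies=regressions,
    )
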
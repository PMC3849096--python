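"""Deterministic generators for toy cofactor networks and test data.

The generators stand in for the real inputs of the analysis — a
genome-scale reconstruction, microarray expression tables and Biolog plate
readings — with small networks whose ground truth is known by construction
and re-verifiable by brute force:

* ``make_toy_model`` builds hand-checkable toy networks around the NADPH
  architecture of interest: substrate uptake feeding an NADH-producing
  catabolic reaction, a transhydrogenase (THD) converting NADH + NADP to
  NAD + NADPH, a planted alternative NADPH producer (ZWF_alt), an NADH
  respiration sink and an NADPH-consuming biomass equation.
* ``make_random_network`` plants a configurable number of alternative NADPH
  producers and decoy reactions in a randomized layered network and verifies
  the planted facts with FBA before returning.
* ``make_pm_plates`` renders a scenario's growth-substrate truth into noisy
  96-well plates with an A1 negative-control baseline.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; the same seed reproduces the same scenario
(and the same SBML bytes) exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eflux import ExpressionProfile
from .fba_engine import GROWTH_TOL, knockout, solve_fba
from .model_core import (
    GPRExpression,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    write_sbml,
)
from .pm_analysis import (
    CONTROL_WELL,
    OD_THRESHOLD,
    OMNILOG_THRESHOLD,
    PMPlate,
    PMWell,
    SubstrateCall,
    write_pm_data,
)

TOY_NAMES = ("TOY1", "TOY1-dup", "TOY1-H")

#: A1 negative-control baseline added to every raw synthetic reading
PLATE_BASELINE = 0.03


@dataclass
class SyntheticTruth:
    """Planted facts about a generated scenario, verified at generation."""

    alternative_producers: set[str]
    growth_substrates: set[str]
    non_growth_substrates: set[str]
    optimal_objective: float
    reference_reaction: str = "THD"
    cofactor: str = "NADPH_c"


@dataclass
class SyntheticScenario:
    """A generated model plus its ground truth and companion data."""

    model: MetabolicModel
    truth: SyntheticTruth
    expression: ExpressionProfile
    seed: int
    plates: list[PMPlate] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Toy models
# ---------------------------------------------------------------------------


def make_toy_model(name: str = "TOY1") -> MetabolicModel:
    """Build one of the named toy networks.

    TOY1 — the base network: EX_S (-4, 100) / T_S uptake of substrate S, a
    catabolic reaction R_CAT (S + 3 NAD -> 2 PRE + 3 NADH), the
    transhydrogenase THD (NADH + NADP -> NAD + NADPH, complex gThA and
    gThB), the planted alternative producer ZWF_alt
    (S + 2 NADP -> PRE + 2 NADPH), an NADH respiration sink, and a biomass
    equation PRE + NADPH -> NADP + BIO with a demand closure on BIO.
    Its FBA optimum is 8.0 (all carbon through R_CAT, NADPH via THD);
    deleting THD drops it to 16/3 via ZWF_alt; deleting both gives 0.

    TOY1-dup — adds R_CAT2, a duplicate of R_CAT under isozyme gene g1b,
    so the optimum becomes degenerate with three support patterns.

    TOY1-H — couples THD to a periplasmic proton gradient
    (2 H[p] consumed, 2 H[c] released) with a proton-pumping closure,
    exercising multi-compartment stoichiometry without changing the optimum.
    """
    if name not in TOY_NAMES:
        raise ValueError(f"unknown toy model {name!r}; choose from {TOY_NAMES}")

    mets = [
        Metabolite(id="S_e", name="substrate", compartment="e"),
        Metabolite(id="S_c", name="substrate", compartment="c"),
        Metabolite(id="PRE_c", name="biomass precursor", compartment="c"),
        Metabolite(id="NAD_c", name="NAD+", compartment="c"),
        Metabolite(id="NADH_c", name="NADH", compartment="c"),
        Metabolite(id="NADP_c", name="NADP+", compartment="c"),
        Metabolite(id="NADPH_c", name="NADPH", compartment="c"),
        Metabolite(id="BIO_c", name="biomass", compartment="c"),
    ]
    thd_stoich = {"NADH_c": -1.0, "NADP_c": -1.0, "NAD_c": 1.0, "NADPH_c": 1.0}
    compartments = {"e": "extracellular", "c": "cytosol"}
    rxns = [
        Reaction(
            id="EX_S",
            name="substrate exchange",
            stoichiometry={"S_e": -1.0},
            lower_bound=-4.0,
            upper_bound=100.0,
            category="exchange",
        ),
        Reaction(
            id="T_S",
            name="substrate transport",
            stoichiometry={"S_e": -1.0, "S_c": 1.0},
            gpr=parse_gpr("gT"),
            category="transport",
        ),
        Reaction(
            id="R_CAT",
            name="catabolism",
            stoichiometry={"S_c": -1.0, "NAD_c": -3.0, "PRE_c": 2.0, "NADH_c": 3.0},
            gpr=parse_gpr("g1"),
        ),
        Reaction(
            id="THD",
            name="transhydrogenase",
            stoichiometry=dict(thd_stoich),
            gpr=parse_gpr("gThA and gThB"),
        ),
        Reaction(
            id="ZWF_alt",
            name="alternative NADPH producer",
            stoichiometry={"S_c": -1.0, "NADP_c": -2.0, "PRE_c": 1.0, "NADPH_c": 2.0},
            gpr=parse_gpr("g2"),
        ),
        Reaction(
            id="RESP",
            name="NADH respiration",
            stoichiometry={"NADH_c": -1.0, "NAD_c": 1.0},
            gpr=parse_gpr("g3"),
        ),
        Reaction(
            id="BIOMASS",
            name="biomass equation",
            stoichiometry={"PRE_c": -1.0, "NADPH_c": -1.0, "NADP_c": 1.0, "BIO_c": 1.0},
        ),
        Reaction(
            id="DM_BIO",
            name="biomass demand",
            stoichiometry={"BIO_c": -1.0},
            category="demand",
        ),
    ]
    if name == "TOY1-dup":
        rxns.insert(
            3,
            Reaction(
                id="R_CAT2",
                name="catabolism isozyme",
                stoichiometry={"S_c": -1.0, "NAD_c": -3.0, "PRE_c": 2.0, "NADH_c": 3.0},
                gpr=parse_gpr("g1b"),
            ),
        )
    if name == "TOY1-H":
        compartments["p"] = "periplasm"
        mets += [
            Metabolite(id="H_c", name="proton", compartment="c"),
            Metabolite(id="H_p", name="proton", compartment="p"),
        ]
        for r in rxns:
            if r.id == "THD":
                r.stoichiometry.update({"H_p": -2.0, "H_c": 2.0})
        rxns.append(
            Reaction(
                id="PMP",
                name="proton pump",
                stoichiometry={"H_c": -2.0, "H_p": 2.0},
                gpr=parse_gpr("g4"),
            )
        )
    model = MetabolicModel(
        id=name.replace("-", "_"),
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS",
        compartments=compartments,
    )
    model.validate()
    return model


def toy_scenario(name: str = "TOY1") -> SyntheticScenario:
    """A TOY1-family scenario with its hand-derivable truth attached."""
    model = make_toy_model(name)
    sol = solve_fba(model)
    truth = SyntheticTruth(
        alternative_producers={"ZWF_alt"},
        growth_substrates={"S"},
        non_growth_substrates=set(),
        optimal_objective=sol.objective_value,
    )
    genes = sorted(model.genes)
    expression = ExpressionProfile(
        activities={g: 1.0 for g in genes}, provenance=f"{name}-unit"
    )
    return SyntheticScenario(model=model, truth=truth, expression=expression, seed=0)


# ---------------------------------------------------------------------------
# Random planted networks
# ---------------------------------------------------------------------------


class GenerationError(RuntimeError):
    """A generated network failed its own self-check after bounded retries."""


def make_random_network(
    seed: int,
    n_substrates: int = 3,
    n_alt_producers: int = 2,
    n_decoys: int = 2,
    max_retries: int = 5,
) -> SyntheticScenario:
    """Generate a layered network with planted alternative NADPH producers.

    Layout: each substrate gets an exchange, and *growth* substrates also a
    transporter and a catabolic reaction emitting NADH (randomised precursor
    yield); NADPH comes from the transhydrogenase or from one of
    ``n_alt_producers`` planted bypass reactions; decoy reactions consume
    NADPH into dead-end sinks so the cofactor-reaction list is larger than
    the producer set.  The first substrate is the medium's carbon source.

    Before returning, the generator verifies with FBA that the model grows,
    that closing THD plus all bypasses abolishes growth, and that each
    planted bypass independently restores it.  Failures retry with a derived
    sub-seed up to ``max_retries`` times, then raise
    :class:`GenerationError`.
    """
    if n_alt_producers < 0:
        raise ValueError("n_alt_producers must be >= 0")
    if n_substrates < 1:
        raise ValueError("n_substrates must be >= 1")
    last_err: Exception | None = None
    for attempt in range(max_retries):
        sub_seed = (seed + 1_000_003 * attempt) % (2**31)
        try:
            return _build_random_network(sub_seed, seed, n_substrates, n_alt_producers, n_decoys)
        except AssertionError as err:  # self-check failure
            last_err = err
    raise GenerationError(f"network generation failed after {max_retries} tries: {last_err}")


def _build_random_network(
    sub_seed: int, seed: int, n_substrates: int, n_alt_producers: int, n_decoys: int
) -> SyntheticScenario:
    rng = np.random.default_rng(sub_seed)
    mets = [
        Metabolite(id="PRE_c", compartment="c"),
        Metabolite(id="NAD_c", compartment="c"),
        Metabolite(id="NADH_c", compartment="c"),
        Metabolite(id="NADP_c", compartment="c"),
        Metabolite(id="NADPH_c", compartment="c"),
        Metabolite(id="BIO_c", compartment="c"),
    ]
    rxns: list[Reaction] = []
    growth_substrates: set[str] = set()
    non_growth: set[str] = set()

    # substrate layer; substrate 0 is always a complete growth route and the
    # medium's carbon source
    for i in range(n_substrates):
        name = f"SUB{i}"
        complete = i == 0 or rng.random() < 0.7
        mets.append(Metabolite(id=f"{name}_e", compartment="e"))
        rxns.append(
            Reaction(
                id=f"EX_{name}",
                stoichiometry={f"{name}_e": -1.0},
                lower_bound=-4.0 if i == 0 else 0.0,
                upper_bound=100.0,
                category="exchange",
            )
        )
        if complete:
            mets.append(Metabolite(id=f"{name}_c", compartment="c"))
            rxns.append(
                Reaction(
                    id=f"T_{name}",
                    stoichiometry={f"{name}_e": -1.0, f"{name}_c": 1.0},
                    gpr=parse_gpr(f"gT{i}"),
                    category="transport",
                )
            )
            yield_pre = float(rng.integers(1, 3))
            rxns.append(
                Reaction(
                    id=f"CAT_{name}",
                    stoichiometry={
                        f"{name}_c": -1.0,
                        "NAD_c": -3.0,
                        "PRE_c": yield_pre,
                        "NADH_c": 3.0,
                    },
                    gpr=parse_gpr(f"gC{i}"),
                )
            )
            growth_substrates.add(name)
        else:
            non_growth.add(name)

    rxns.append(
        Reaction(
            id="THD",
            name="transhydrogenase",
            stoichiometry={"NADH_c": -1.0, "NADP_c": -1.0, "NAD_c": 1.0, "NADPH_c": 1.0},
            gpr=parse_gpr("gThA and gThB"),
        )
    )
    rxns.append(
        Reaction(
            id="RESP",
            stoichiometry={"NADH_c": -1.0, "NAD_c": 1.0},
            gpr=parse_gpr("gR"),
        )
    )

    # planted alternative producers: bypasses from the medium substrate
    planted: set[str] = set()
    for j in range(n_alt_producers):
        rid = f"ALT{j}"
        n_nadph = float(rng.integers(1, 3))
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry={
                    "SUB0_c": -1.0,
                    "NADP_c": -n_nadph,
                    "PRE_c": 1.0,
                    "NADPH_c": n_nadph,
                },
                gpr=parse_gpr(f"gA{j}"),
            )
        )
        planted.add(rid)

    # decoys: NADPH consumers into dead-end sinks (cofactor-coupled but
    # never synthesis-capable)
    for d in range(n_decoys):
        sink = f"W{d}_c"
        mets.append(Metabolite(id=sink, compartment="c"))
        rxns.append(
            Reaction(
                id=f"DEC{d}",
                stoichiometry={"NADPH_c": -1.0, "NADP_c": 1.0, sink: 1.0},
                gpr=parse_gpr(f"gD{d}"),
            )
        )
        rxns.append(
            Reaction(id=f"DM_W{d}", stoichiometry={sink: -1.0}, category="demand")
        )

    rxns.append(
        Reaction(
            id="BIOMASS",
            stoichiometry={"PRE_c": -1.0, "NADPH_c": -1.0, "NADP_c": 1.0, "BIO_c": 1.0},
        )
    )
    rxns.append(Reaction(id="DM_BIO", stoichiometry={"BIO_c": -1.0}, category="demand"))

    model = MetabolicModel(
        id=f"synthnet_{sub_seed}",
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS",
        compartments={"e": "extracellular", "c": "cytosol"},
    )
    model.validate()

    # self-checks: growth; collapse when THD + bypasses close; each bypass
    # restores alone
    wt = solve_fba(model)
    assert wt.optimal and wt.objective_value > GROWTH_TOL, "wild type does not grow"
    all_producers = ["THD", *sorted(planted)]
    dead = solve_fba(knockout(model, reaction_ids=all_producers))
    assert not (dead.optimal and dead.objective_value > GROWTH_TOL), (
        "closing all planted producers does not abolish growth"
    )
    for rid in sorted(planted):
        others = [r for r in all_producers if r != rid]
        restored = solve_fba(knockout(model, reaction_ids=others))
        assert restored.optimal and restored.objective_value > GROWTH_TOL, (
            f"planted bypass {rid} does not restore growth alone"
        )

    genes = sorted(model.genes)
    activities = dict(zip(genes, np.round(rng.uniform(0.3, 1.0, len(genes)), 6)))
    expression = ExpressionProfile(
        activities={g: float(v) for g, v in activities.items()},
        provenance=f"synthetic expression seed={seed}",
    )
    truth = SyntheticTruth(
        alternative_producers=planted,
        growth_substrates=growth_substrates,
        non_growth_substrates=non_growth,
        optimal_objective=wt.objective_value,
    )
    return SyntheticScenario(model=model, truth=truth, expression=expression, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic PM plates
# ---------------------------------------------------------------------------


def make_pm_plates(
    scenario: SyntheticScenario,
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    condition: str = "photosynthetic",
    plate_id: str = "SPM1",
) -> tuple[list[PMPlate], list[SubstrateCall]]:
    """Render a scenario's substrate truth into noisy 96-well plates.

    Growth substrates get corrected readings drawn around 3x the calling
    threshold, non-substrates around 0.2x; Gaussian noise of ``noise_sd`` is
    added per well per replicate, the A1 baseline is added to every raw
    reading, and readings are floored at zero.  Wells beyond the scenario's
    substrates are filled with inert decoy substrates (non-growth truth).
    Returns the plates together with the ground-truth calls.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    threshold = OMNILOG_THRESHOLD if condition == "aerobic" else OD_THRESHOLD

    wells = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]
    substrates = sorted(scenario.truth.growth_substrates) + sorted(
        scenario.truth.non_growth_substrates
    )
    layout: dict[str, tuple[str, bool]] = {}
    for well_id in wells:
        if well_id == CONTROL_WELL:
            continue
        if substrates:
            name = substrates.pop(0)
            layout[well_id] = (name, name in scenario.truth.growth_substrates)
        else:
            layout[well_id] = (f"decoy_{well_id}", False)

    plates = []
    for rep in range(1, n_replicates + 1):
        plate_wells = {
            CONTROL_WELL: PMWell(
                well=CONTROL_WELL,
                substrate="negative control",
                element_class="C",
                reading=PLATE_BASELINE,
            )
        }
        for well_id, (name, grows) in layout.items():
            center = 3.0 * threshold if grows else 0.2 * threshold
            corrected = max(center + rng.normal(0.0, noise_sd), 0.0) if noise_sd else center
            plate_wells[well_id] = PMWell(
                well=well_id,
                substrate=name,
                element_class="C",
                reading=max(corrected + PLATE_BASELINE, 0.0),
            )
        plates.append(
            PMPlate(plate_id=plate_id, condition=condition, replicate=rep, wells=plate_wells)
        )

    truth_calls = [
        SubstrateCall(
            substrate=name,
            element_class="C",
            condition=condition,
            corrected_value=3.0 * threshold if grows else 0.2 * threshold,
            growth=grows,
            n_replicates=n_replicates,
        )
        for name, grows in sorted(layout.values())
    ]
    return plates, truth_calls


# ---------------------------------------------------------------------------
# Scenario bundles
# ---------------------------------------------------------------------------


def write_scenario(scenario: SyntheticScenario, directory: str) -> None:
    """Write a scenario bundle: model.xml, expr.tsv, plates.csv, truth.json."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    write_sbml(scenario.model, str(out / "model.xml"))
    with open(out / "expr.tsv", "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gene in sorted(scenario.expression.activities):
            fh.write(f"{gene}\t{scenario.expression.activities[gene]}\n")
    if scenario.plates:
        write_pm_data(scenario.plates, str(out / "plates.csv"))
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": scenario.seed,
                "alternative_producers": sorted(scenario.truth.alternative_producers),
                "growth_substrates": sorted(scenario.truth.growth_substrates),
                "non_growth_substrates": sorted(scenario.truth.non_growth_substrates),
                "optimal_objective": scenario.truth.optimal_objective,
                "reference_reaction": scenario.truth.reference_reaction,
                "cofactor": scenario.truth.cofactor,
            },
            fh,
            indent=2,
        )
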
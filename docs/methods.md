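# Methods

## Model representation and conventions

A metabolic network is a list of compartment-tagged metabolites, a list of
reactions (stoichiometry map, flux bounds, boolean GPR tree, structural
category) and one biomass objective. All fluxes are mmol/gDW·h; the biomass
flux reads as a specific growth rate (1/h). The stoichiometric matrix *S*
excludes boundary metabolites from its rows. A reaction is *reversible* iff
`lower_bound < 0 < upper_bound`, so the reversible/irreversible split always
partitions the reaction total. Exchange fluxes are positive for secretion,
negative for uptake.

SBML Level 3 + fbc v2 is the canonical dialect (flux-bound parameters,
gene-product associations, an active objective); Level 2 files with
`GENE_ASSOCIATION:` notes and kinetic-law `LOWER_BOUND`/`UPPER_BOUND`
parameters are read as a fallback. When no fbc objective is declared, a
*unique* reaction whose id or name contains "biomass" (case-insensitive) is
taken as the objective; two or more matches are an error rather than a
guess. The writer is deterministic: identical models produce byte-identical
files, which the generators rely on for reproducibility.

Reaction categories are decided structurally on read (exchange: single
non-boundary, extracellular metabolite; transport: spans compartments;
demand: flagged sink, id prefix `DM_` or SBO:0000628), with annotation
overrides carried in SBO terms and a notes tag. A reaction with no
classifiable structure falls back to enzymatic with a logged warning. Note
one deliberate consequence: a proton-translocating transhydrogenase whose
substrates span periplasm and cytosol classifies as transport — membrane
machines are transporters in the structural sense even when their chemistry
is redox.

## FBA, FVA, media and knockouts

FBA is solved with HiGHS through `scipy.optimize.linprog`; an optimal
solution is one vertex of the optimal face, with no uniqueness claim
(callers needing the face use the alternative-optima enumerator). Every
solution asserted in tests satisfies max |S·v| ≤ 1e-6 and bound
feasibility.

Key tunables, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| global bounds | ±100 / (0, 100) mmol/gDW·h | reversible / forward-only reactions |
| ATP maintenance | 8.39 mmol/gDW·h | lower bound on the `ATPM` reaction when present |
| carbon uptake | −4 mmol/gDW·h | tested C source in growth predictions |
| N/P/S uptake | −1 mmol/gDW·h | tested N/P/S source |
| growth tolerance | 1e-6 (1/h) | objective above this counts as growth |
| FVA fraction | 1.0 | objective fixed at its optimum |

The growth tolerance deserves a note: the decision rule is "growth iff the
predicted rate is positive", but LP solvers return numerical dust, so a
strictly-positive test is meaningless; 1e-6 sits orders of magnitude above
solver noise and below any biologically meaningful rate at these flux
scales. FVA constrains the biomass flux with a 1e-9 backoff below
fraction × optimum so the constrained LP stays feasible at fraction 1.

Applying a medium copies the model (never mutates), makes every unlisted
exchange secretion-only (0, 100), copies listed exchange bounds verbatim and
sets the ATPM lower bound. Gene knockouts evaluate each GPR with the deleted
genes false — a deleted subunit kills an AND complex, an OR isozyme set
survives while any member remains — and close exactly the reactions whose
association evaluates false.

## E-flux

Raw expression is normalised by the dataset-wide maximum (activities in
[0, 1], best-expressed gene at 1.0). The exact normalisation used upstream
of published E-flux analyses varies; global-max scaling is the canonical
choice and the `mode` argument exists to mark the convention explicitly
rather than to hide a second algorithm. Reaction activity is computed
recursively on the GPR tree (OR → max, AND → min), so nested isozyme/complex
expressions are handled deterministically. Bounds become
`upper = min(orig_upper, 100·activity)` and
`lower = max(orig_lower, −100·activity)`; every E-flux interval is therefore
a subset of the original, which yields two testable laws: a unit profile
reproduces plain FBA exactly, and pointwise-lower activities can never raise
the optimum. Exchange and demand pseudo-reactions carry no enzymes and are
never constrained. A gene missing from the profile contributes activity 1.0
with a warning — an absent probe is missing evidence, and treating it as
zero would silently close reactions.

## Alternative optima and cofactor demand

The enumerator fixes the objective at its optimum and searches for flux
vectors with new *support patterns* (sets of active reactions). Each
reaction is split into forward/backward parts with a binary per direction,
linked by `eps·y ≤ v_dir ≤ bigM·y` (big-M = 100, the global bound) and
`y_f + y_b ≤ 1`; a no-good cut per known pattern,
`Σ_{j∈P}(1−y_j) + Σ_{j∉P} y_j ≥ 1`, guarantees pairwise-distinct patterns.
The first pattern is the plain FBA vertex's support; each subsequent MILP
minimises the number of active directions (sparse patterns first,
deterministic given the solver). Infeasibility means the face is exhausted.
Each cut's MILP carries a 10 s time guard and a partial result is returned
with `status="time_limit"` rather than hanging.

Two numerical couplings matter and are set deliberately:

* the activity epsilon is **1e-4**, not the solver-noise scale: HiGHS's MIP
  feasibility tolerance (1e-6, not adjustable through scipy) would otherwise
  let a binary switch on while its flux stays at zero, fabricating patterns;
* the objective-fixing slack is **1e-9**, well below the activity epsilon,
  so a reaction that wastes objective cannot be switched on at epsilon flux
  to manufacture a pattern that does not exist on the true optimal face.

An optimal face is a continuum, so it usually holds fewer distinct support
patterns than a conventional fixed solution count (n = 1000). When
enumeration exhausts early, the solution list is padded to n with seeded
random convex combinations (Dirichlet weights) of the solutions found;
convexity keeps every padded point feasible and optimal, so fixed-n
mean/SEM summaries remain well defined. The `exhausted` flag and the
distinct-pattern list always report what was actually found; padding is a
sampling convention, not a claim of additional distinct optima.

Cofactor demand: with every other producer of the cofactor closed by the
caller, all optimal solutions must route production through the reference
reaction (the transhydrogenase in the motivating analysis); the mean and
SEM of its flux across the n solutions estimate demand and its
solution-space spread. SEM is reported as exactly 0 when the flux is
invariant across solutions.

## Producer screen

`find_cofactor_reactions` takes every reaction with a nonzero stoichiometric
coefficient for the cofactor (`count_mode="either-sign"`; a
`"consumption-only"` mode exists because "cofactor-requiring reaction" is
ambiguous for reversible stoichiometries, and the two modes change the
counts on real reconstructions). Synthesis capability is read off the
feasibility flux range (FVA at fraction 0): capability is a property of the
network, not of any particular optimum. Essentiality is a one-at-a-time
knockout under the same medium — the medium is an explicit parameter, never
ambient state.

The screen closes only the *synthesis direction* of each non-essential
synthesis-capable member (a reversible reaction keeps its consumption
direction; `full_deletion=True` closes both, for sensitivity checks),
verifies the baseline growth is ≈ 0 — a positive baseline means the closed
set misses a route and the screen aborts with the leaky reactions named —
then re-opens each member alone. Biomass, demand and exchange
pseudo-reactions are sinks, not producers, and are excluded from both the
knockout set and the candidate set.

## PM calling and reconciliation

Corrected reading = max(raw − A1, 0); negative corrected values are floored
because negative growth is meaningless. Thresholds: 0.05 OD₆₅₀ for
photosynthetic growth; 5 Omnilog units for aerobic respiration; anaerobic
OD-based calls reuse the 0.05 OD threshold since both score an optical
density increase (exposed as module constants). A substrate is called a
growth substrate only when every replicate clears the threshold, which
makes calling monotone in readings and demonstrably cuts false positives
versus single-replicate calling under threshold-scale noise.

Model comparison runs the sole-source growth prediction per called
substrate (closing the default source of that element class, opening the
test substrate at −4 or −1) and fills the GG/GNG/NGG/NGNG table per element
class; substrates absent from the model are predicted no-growth, so an
observed-growth call lands in NGG. Refinement proposals:

* **NGG** — breadth-first search over universal-catalogue subsets by
  increasing cardinality (default cap 3), lexicographic tie-break among
  equal-size sets for deterministic output, with an auto-generated
  exchange/transport pair when the substrate is missing entirely; the first
  subset enabling growth is returned, or `none found (cap k)`.
* **GNG** — tentative removal of the substrate's transporters followed by a
  full re-comparison; accepted only when no previously consistent substrate
  becomes inconsistent.

Candidate gene evidence (sequence-homology support for added reactions) is
out of scope; a per-reaction prior weight column in the catalogue is the
hook for encoding it externally.

## Synthetic data: what it emulates and what it does not

The toy networks reproduce the NADPH architecture that drives the analysis:
substrate uptake, NADH-producing catabolism, an AND-complex
transhydrogenase, a planted alternative producer, NADH respiration and an
NADPH-consuming biomass equation with a demand closure. `TOY1` collapses
the proton coupling of the real transhydrogenase so optima are
hand-checkable (optimum 8.0; 16/3 after deleting THD; 0 after deleting both
producers); `TOY1-H` restores periplasmic protons to exercise
multi-compartment stoichiometry; `TOY1-dup` duplicates the catabolic step
to create a degenerate optimum with exactly three support patterns.

`make_random_network` plants a configurable number of producer bypasses and
NADPH-consuming decoys in a layered network and *verifies* the planted
facts with FBA before returning (growth; collapse when all producers close;
single restoration per bypass), retrying with derived sub-seeds on failure.
Synthetic plates place real and decoy substrates in a 96-well layout with
an A1 baseline of 0.03, growth readings centred at 3× threshold and
non-growth at 0.2×, Gaussian noise per well per replicate. All randomness
flows from explicit seeds through `numpy.random.default_rng`; identical
seeds give byte-identical SBML.

What passing tests therefore show: the solver stack, the screen logic, the
calling rules and the reconciliation search are correct on networks whose
ground truth is known and independently re-derivable by brute force
(exhaustive vertex enumeration of the flux polytope, exhaustive
single-restoration screens, exhaustive subset search — all in the test
tree, sharing no code with the production LP/MILP path, plus cobrapy as an
independent FBA/FVA cross-check). What they do not show: correctness of any
particular genome-scale reconstruction's biology, microarray preprocessing,
kinetic PM curve features (lag, slope), or the manual curation steps of
real model refinement. Genome-scale count checks (model statistics, the
61/29 producer screen, published PM call totals) are wired into the
acceptance tests but require the published external artifacts, which cannot
ship with the package.

## Problem sizes

The shipped verification runs use toy networks of 8–12 reactions (the
brute-force oracles enumerate all basic solutions, which is exact and fast
at that size), 20 seeded random networks for recovery screens, 100 random
profiles for the E-flux laws, up to n = 1000 alternative-optima solutions,
and 96-well plates in 2–3 replicates. These sizes were chosen so every
claim is checked against an exhaustive oracle; all operations accept
genome-scale inputs through the same interfaces.

## Known limitations

* No loopless/thermodynamic constraints; FVA ranges and alternative optima
  may include thermodynamically infeasible cycles if a model contains them.
* Alternative-optima distinctness is defined on support patterns, not
  solver bases; the padded fixed-n sample is a convention (see above).
* The screen tests single restorations only; synergistic producer pairs
  are invisible by design.
* PM ingestion expects endpoint/summary readings; Omnilog kinetic series
  must be summarised upstream.
* E-flux normalisation is global-max; per-gene cross-condition scaling must
  be computed by the caller if wanted (the mode tag marks the convention).
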
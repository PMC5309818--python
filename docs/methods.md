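# Methods

This note documents the models and procedures implemented in `timbr`,
the parameters that matter, the numerical choices, and what the bundled
fixtures do and do not demonstrate.

## Network model

A `MetabolicNetwork` stores metabolites keyed by `id[compartment]`,
reactions with stoichiometry maps, flux bounds in model units
(fmol·cell⁻¹·h⁻¹ for the hepatocyte-scale models this package targets)
and canonical GPR trees.  Reaction kinds are derived, not declared:
*exchange* = boundary reaction touching one metabolite; *transport* =
participants span ≥ 2 compartments; *biochemical* = the rest.  A
reaction that both moves and transforms matter is classified transport —
the classification exists to assign default TIMBR weights, which need a
single kind per reaction.  Stoichiometry is kept exactly as written
(no cancellation of a metabolite appearing on both sides).

GPR rules are canonicalized on construction: nested same-operator nodes
are flattened, duplicate children removed, children sorted by their
serialization, single-child nodes collapsed.  `and` binds tighter than
`or` when parentheses are absent — the conventional reading in
constraint-based modelling.  Canonicalization makes parsing and
serialization mutually inverse and makes rule equality a truth-table
equality for the rule shapes that occur in GENREs.

The irreversible split represents each reversible reaction `[-a, b]` as
a forward column `[0, b]` and a negated reverse column `[0, a]`; a
strictly negative reaction is stored as its reverse column alone, so
every lower bound is non-negative, as the weighted flux-minimization LP
requires.  Net flux `v_fwd − v_rev` maps any irreversible solution back
to a feasible source-network flux.

**Reconstruction statistics.** *Enzymatic* = non-empty GPR, *isozymic* =
rule containing an OR, *enzyme complex* = rule containing an AND, mean
GPR size = mean distinct-gene count over enzymatic reactions.  Nested
rules can make a reaction both isozymic and complex; whether published
model tables used exactly this convention for nested rules is not
certain, so any discrepancy on external files should be reported rather
than reconciled silently.

## I/O

SBML Level 3 + FBC v2 through libSBML: bounds as per-reaction constant
parameters, genes as FBC gene products (original identifier in the
label), GPRs as FBC association trees, subsystem in the reaction notes.
Identifiers are escaped reversibly into valid SIds, so arbitrary
metabolite names round-trip.  The spreadsheet dialect is one reaction
per row (`id, equation, gpr, lb, ub, subsystem`) with `=>` / `<=>`
arrows and `met[compartment]` tokens; load errors are collected and
reported together.  Media tables, plain-text task files, a RAVEN-style
Excel task layout, expression tables and IEM case tables have small
dedicated loaders.

## Orthology consensus and GPR translation

Pairs from the five databases are unioned; `db_score` (1–5) counts the
databases annotating a pair.  Human genes with ten or more rat partners
are excluded *before* ranking (boundary inclusive).  Ranks order each
human gene's partners by database score, then rat-gene confidence —
consumed as a supplied ordinal column, since its derivation depends on
external database snapshots — then rat gene id as a deterministic
tie-break.  The consensus filter keeps `db_score ≥ 2` and `rank ≤ 2` by
default, with ranks computed on the full post-promiscuity table.  If
the published pair counts were not matched exactly, computing ranks
after the db-score cut is the documented alternative ordering.

Translation replaces each human leaf by the OR of its retained rat
orthologues.  An unmapped leaf inside an OR simply drops
(`isozyme_dropped`); inside an AND the complex degrades to its mapped
subunits and is flagged `broken_complex` rather than deleting the
reaction — such cases are exactly the ones resolved manually during
curation, and the report surfaces them for that treatment.  A rule
losing every leaf becomes empty and the reaction is flagged `orphaned`.
Nothing is lost silently and no gene is invented.

## LP engine

All solves go to HiGHS via `scipy.optimize.linprog` with feasibility
and duality tolerances of 1e-9 requested; results are asserted to
1e-6 (absolute, model flux units) — genome-scale LPs span several
orders of magnitude in bounds, so the looser assertion absorbs scaled
round-off.  Only objective values are contractual; flux vectors are one
optimal vertex and may differ under degeneracy.  Infeasible and
unbounded statuses are distinguished and never conflated with solver
failure.  FVA solves two LPs per reaction (the implementation is the
plain formulation; an independent per-reaction two-LP oracle and
cobrapy cross-checks back it in the tests), snapping |flux| < 1e-6 to
zero so blocked reactions report (0, 0).

**Tasks.**  A task closes *all* model exchange reactions and opens
temporary boundary inflows/outflows only for its listed inputs and
outputs (uptake and secretion between the stated bounds).  Byproducts
not listed as outputs therefore may **not** leave the system — the
stricter reading of task semantics; a task that needs byproduct efflux
must list it with bounds `[0, big]`.  `should_fail` inverts feasibility
into the pass/fail verdict, so known incapabilities (e.g. no ATP
rephosphorylation from inorganic ions alone) are first-class tests.

**Media.**  Media objects override bounds only for listed exchange
reactions.  The open-exchange builder gives the named inorganic-ion
exchanges unconstrained uptake, every other exchange uptake of at most
1 arbitrary unit, and unconstrained secretion throughout.  The 12-ion
list is configuration (`timbr.iem.DEFAULT_ION_IDS` names common
inorganic species); quantitative strict/relaxed physiological bounds
are properties of specific curated models and are loaded from tables,
not hard-coded.

## TIMBR

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `q_threshold` | 0.1 | FDR cutoff; changes with q ≥ threshold are zeroed |
| default weight | 1 / 2 | biochemical / transport+exchange cost per flux unit |
| no-data multiplier | ×2 | applied when a reaction has no GPR or no platform gene |
| `production_cap` | 100 fmol·cell⁻¹·h⁻¹ | ceiling on the forced secretion rate |
| `fva_fraction` | 0.9 | fraction of the FVA secretion maximum otherwise forced |

Summarization walks the GPR tree: OR = arithmetic mean (an upregulated
isozyme is diluted by unaffected partners), AND = child with the
largest absolute value.  The AND rule follows the more specific
published statement (largest |log2fc|); ties break toward the positive
value, then the first child.  Genes on the platform but absent from the
model are ignored; model genes absent from the platform give the
reaction *no-data* status (weight doubling) instead of a zero change —
no data and no change are deliberately different things.  Both split
directions of a reversible reaction share one weight: expression
carries no directionality.

The raw score `(d_c − d_t)/(d_c + d_t)` is the committed symmetric
form: it is antisymmetric under condition swap, bounded in (−1, 1)
(which makes cross-metabolite z-scoring meaningful), invariant to
uniform scaling of all weights, and positive exactly when the treatment
network demand is smaller.  z-normalization uses the sample (n−1)
standard deviation; at realistic metabolite counts (hundreds) the
choice is numerically negligible, and tests allow 1e-3 where it could
matter.  Metabolites whose FVA secretion maximum is ≤ 1e-9 are skipped
as unproducible and excluded from normalization.  Compound suitability
requires significant change in ≥ 1% of model∩platform genes (boundary
inclusive).

Cross-species comparison computes Pearson r with a two-sided p-value
per compound (undefined below 3 pairs, reported as such), adjusts
p-values Benjamini–Hochberg across the compound family, and labels by
sign at q < 0.1.  Quantile calls use inclusive boundaries (score ≥ 75th
percentile → elevated, ≤ 25th → reduced); evaluation counts
experimentally changed metabolites as positives and elevated-or-reduced
calls as predicted positives, reporting sensitivity, specificity and
MCC (undefined when its denominator vanishes).

## IEM biomarker prediction

Affected reactions are those whose GPR evaluates false with the causal
genes absent and all others present.  The healthy condition forces each
affected reaction to ≥ 90% of its FBA optimum under open-exchange
media; for reversible reactions the direction with the larger |optimum|
is forced, since a single "maximum possible flux value" does not
address reversibility.  Affected reactions with zero attainable flux
impose no forcing (healthy = unforced).  All affected reactions are
forced simultaneously by default; a per-reaction mode (`simultaneous=
False`) runs each forcing separately and unions the biomarker ranges,
as the published workflow does not state which was used.  The disease
condition sets affected reactions to zero.  Two FVA intervals reduce to
a call by the shift of the interval midpoint sum with tolerance
`τ = 1e-6 · max(1, |max_healthy|)` — a statistic chosen because it
responds to shifts of either bound and is symmetric; the published
workflow does not state its interval reduction.  Infeasible forcing
marks a case unevaluable rather than guessing.

## Fixtures

The toy generator builds `n_pathways` independent chains — uptake
exchange (bound ≈ 10 flux units), transport in, biochemical
conversions, transport out, secretion exchange — joined by a biomass
sink, with GPR profiles (single gene, isozyme pair, complex pair,
nested) cycling over internal reactions and a seeded fraction of
reversible conversions.  Uptake bounds near 10 put fixtures on the
`0.9·v_max` branch of the production bound; variants with larger bounds
exercise the 100-unit cap.  Paired networks share one namespace and
differ by a planted conversion present in one network only, emulating
one-enzyme species differences (the urate→allantoin pattern); the
delta product's transport and exchange exist in both so tasks and
scores are comparable.  Planted expression sets every gene on the
backward closure of a target metabolite to ±effect (q = 0.01) and all
other genes to insignificant Gaussian background — on these acyclic
fixtures the closure is exactly the synthesis pathway.

What fixtures demonstrate: correctness of the algebra, the LP
formulations, the score arithmetic, and end-to-end signal recovery
under a planted ground truth.  What they do not demonstrate: behaviour
under mass-imbalanced or thermodynamically looped networks, realistic
GPR size distributions, correlated expression noise, or the biology of
any curated GENRE — quantitative claims about published models require
the published model files.  Quantities tied to those external files
(growth rates 0.048/0.040 h⁻¹ under strict physiological constraints,
Table-scale reconstruction counts, the 4,768→2,629 orthology
filtering, compound-panel correlations) are implemented as drop-in
reproduction tests against `data/external/` and otherwise fail with an
explanatory message; the doubling-time arithmetic ln 2/µ and the
confusion-matrix arithmetic of the caffeine validation are desk-scale
and always checked.

## Problem sizes

Test and acceptance runs use fixtures of 1–3 pathways (≈ 7–20
reactions), 20-fixture recovery sweeps, 10⁴ random weight pairs and
286-element score vectors; every LP solves in milliseconds, keeping the
full suite in the tens of seconds on one CPU.
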
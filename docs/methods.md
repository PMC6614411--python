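# Methods

This note documents the models and procedures implemented in
`fluxcondition`, the parameters that matter, the choices made where the
design was genuinely open, and what the synthetic study does and does
not establish.

## Constraint-based model and solvers

A metabolic model is a stoichiometric matrix `S` (metabolites ×
reactions), flux bounds `lb ≤ v ≤ ub` in mmol·gDW⁻¹·h⁻¹, GPR boolean
trees, subsystem labels and a biomass objective (h⁻¹). Reversibility is
defined purely by `lb < 0`; a disagreeing SBML `reversible` flag is
logged and ignored, since bounds are what the LP sees. SBML I/O accepts
Level 3 + fbc-v2 (gene products, bound parameters) and the older COBRA
dialect (kinetic-law bound parameters, `GENE_ASSOCIATION` notes);
writing always emits L3+fbc-v2 with subsystems in reaction notes.

All LPs go through SciPy's HiGHS interface with feasibility/optimality
tolerances of 1e-9. HiGHS with fixed options is deterministic for a
fixed problem, but FBA optima are degenerate, and subsystem averages
depend on *which* optimal vertex is reported. The pipeline therefore
uses the minimum-L1-norm optimal flux vector throughout (secondary LP
with the objective pinned at its optimum, `Σ|v|` minimized). This is the
single most consequential reproducibility decision in the package: it
makes two runs of the pipeline byte-identical and is the parsimonious
("enzyme-economical") representative of the optimal set. Downstream,
any `|v| < 1e-6` counts as zero flux (`FLUX_EPS`).

Blocked-reaction detection runs FVA with the objective constraint
released (optimality fraction 0) and flags reactions with
`max(|v_min|, |v_max|) < 1e-6`. Gap filling is a single MILP over all
targets jointly: one flux vector per target (forced to carry flux
through it), shared binary add-indicators on candidate reactions, and a
minimum-cardinality objective with a tiny (1e-6-scale) lexicographic
tie-break on reaction id. The forcing flux is `max(1e-6, min(1e-3,
bound/2))`: HiGHS's MIP feasibility tolerance is 1e-6, so forcing at
exactly 1e-6 would accept a zero-flux "solution". Reactions that stay
blocked with the entire universal database added are reported
unfillable rather than failing the MILP.

## Transcriptome integration

Log2 intensities are un-logged (`2^x`) per sample and averaged over a
condition's replicates **on the linear scale** before GPR mapping, so
that `min`/`max` and the E-flux ratio operate on abundances. When
several probes map to one gene the maximum intensity is taken (upstream
of this package's input format). GPR scoring ignores unmeasured leaves
inside an OR but voids an AND — an unmeasured isozyme cannot lower the
evidence, an unmeasured complex subunit makes the complex unquantifiable.
Reactions without a GPR or without any measured gene are "absent": no
evidence, no penalty (GIMME), no scaling (E-flux).

GIMME's two free parameters are config-exposed with these defaults:
threshold = 25th percentile of the condition's reaction-score
distribution (percentile thresholds survive array-scale shifts;
an absolute threshold is available), and required objective fraction
0.9 (the algorithm's customary setting). E-flux scales only internal
reactions; exchange bounds are untouched so that the growth medium is
identical across conditions and methods — diet enters through the
transcriptome, not through the medium.

## Cross-condition comparison

Conditions are the eight non-control (group, day) cells — group 1 at
days 4/14 and groups 3–5 (−15 %, −30 %, −60 % food) at days 4/14 — plus
one control column pooling group 2's overnight-fasted replicates from
both days. "Active in a majority" means a strict majority of all
condition columns; the consensus set intersects the per-method majority
sets. The subsystem table takes `|v|` first, means within subsystem
second, and subtracts the control column last (this ordering is a
documented choice; the alternative — differencing per reaction before
aggregation — weighs sign flips differently). The E-flux table feeds
this stage by default because E-flux preserves flux magnitudes, which
subsystem averaging needs; GIMME's vectors answer the activity question
and drive the consensus only. Both tables are written, and
`flux_table_method = "gimme"` switches the choice.

Projective decomposition is alternating row/column RMS scaling of
`|X|` (signs reattached to the core afterwards): divide each row by its
RMS, then each column, accumulating the divisors, until every row and
column RMS is within `tol = 1e-9` of 1 (default cap 10 000 iterations;
non-convergence is flagged, not raised — certain zero patterns provably
cannot be balanced, and divergence is detected by a finiteness guard).
Rows/columns indistinguishable from zero at `FLUX_EPS` are removed
first: a condition whose fluxes equal the control exactly yields a zero
column whose RMS cannot be scaled to 1. The normalization is invariant
to positive rescaling of rows or columns of the input — the property
that motivates using it on fluxes whose natural scales differ by orders
of magnitude across subsystems.

"Altered" subsystems — the enrichment query — are judged on the
*unnormalized* control-differenced table (default: any entry with
`|Δmean flux| ≥ 0.5` mmol·gDW⁻¹·h⁻¹). The normalized core serves
clustering and display; after normalization every surviving row has RMS
1 by construction, so it cannot rank alteration.

Clustering is average-linkage on Euclidean row distances with rows
pre-sorted by name, making leaf order independent of input order; the
tree is also emitted as Newick.

## Enrichment and network statistics

Fisher's exact test is two-sided by the point-probability rule, with the
GEM's own genes as the background universe — the query arises from
model subsystems, so the array-wide universe would inflate enrichment.
Odds ratios are displayed with the Haldane +0.5 correction; p-values are
never corrected that way. BH adjustment is the classical step-up.

Interaction edges are kept at combined score strictly greater than 0.7,
deduplicated keeping the maximum score, self-loops dropped. Path lengths
are unweighted (scores filter, they do not weight). Edge betweenness
uses Brandes' fractional counting over tied shortest paths by default;
an integer-counting mode (every tied path counts fully) is provided
because "number of shortest paths through an edge" is ambiguous under
ties. Hubs are nodes ranked by degree, ties broken by id; the default
hub-list length of 8 is a convention, not a statistic.

## The synthetic study

`generate_toy_gem` builds a deterministic 40-reaction, 37-metabolite,
38-gene model over cytosol/mitochondria/extracellular space: lumped
glycolysis/gluconeogenesis, TCA cycle, pentose phosphate pathway, a
C8-like β-oxidation, an NADH-driven oxidative phosphorylation, cofactor
pairs (ATP/ADP, NAD(H), NADP(H)), transports and exchanges, a biomass
reaction drawing G6P, pentose, pyruvate, oxaloacetate, acetyl-CoA, ATP
and NADPH, and one deliberately dead-ended side branch (a PRPP-like
metabolite with no consumer) whose producing reaction is the planted
blocked reaction. Two deliberate design features make diet effects
*selective* rather than global:

* enzymatic internal reactions carry capacity bounds (40; β-oxidation 8)
  comparable to pathway demand, so a 2–4-fold expression drop in a
  pathway genuinely throttles it, while transports and the electron
  transport chain have loose bounds (1000);
* a large constant maintenance ATP demand (25) dominates the energy
  budget, so when glycolysis is suppressed, respiration is sustained by
  induced fat oxidation instead of collapsing with growth — the fasting
  physiology the study design expects.

Growth on 10 glucose + up to 6 fatty acid is `μ = 1.091 h⁻¹`; the toy's
absolute growth rate is arbitrary and only its condition-to-condition
ratios matter.

`generate_expression` draws one baseline log2 intensity per gene from
Uniform(10.8, 12) — a deliberately narrow, high-abundance window so
that relative E-flux capacities `x/max(x)` sit within a factor ~2.5 of
each other and a planted 4-fold suppression crosses the binding
threshold while control bounds stay slack — then adds `log2(multiplier)`
pathway effects per (group, day) and i.i.d. Gaussian noise (sd 0.25
log2 units) per sample, five replicates per cell. Default effects grade
with restriction severity and duration: glycolysis ×0.9…×0.25 (weakest
at −15 % day 4, strongest at −60 % day 14), fatty-acid oxidation
induced ×1.25…×2, pentose phosphate mildly reduced at the severe end.
A multiplier of 0 maps to zero abundance (complete silencing).

`generate_interactions` plants hub genes (hexokinase-, GAPDH- and
pyruvate-kinase-like) with 15 confident partners each and caps every
other gene's above-threshold degree at 6 background edges (+3 possible
hub edges), so planted hubs out-rank all other nodes after 0.7-filtering
by construction, not merely in expectation.

What passing the recovery tests shows: the pipeline's plumbing is
lossless (the constitutive carbon path survives both integration
methods and the consensus intersection), its comparisons point the right
way (the suppressed pathway is the strongest negative flux shift at
severe late restriction), and its network stage finds planted structure.
What it does not show: performance on real arrays — probe-level noise
structure, cross-hybridization, normalization artefacts, many-to-many
orthology and 80+-subsystem models are not emulated; absolute flux
changes in the toy say nothing about rat physiology.

## Problem sizes and runtime

The default test-and-acceptance workload uses the 40-reaction model,
9 condition columns (≈ 40 LP solves with ≤ 86 variables each per
condition), brute-force oracles on ≤ 12-node graphs and ≤ 6-variable
LPs, and 1000 null-enrichment replicates; the full suite runs in well
under a minute of LP time. These sizes were chosen so every oracle is
exhaustive; the library itself has no small-size assumptions and reads
genome-scale SBML directly.

## Known limitations

* GIMME leaves fluxes of unpenalized reactions underdetermined; the
  reported vector is HiGHS's optimal basic solution, deterministic but
  basis-dependent. Consensus counting is robust to this (activity, not
  magnitude); the subsystem stage uses E-flux fluxes.
* E-flux's `x/max(x)` normalization makes all capacities relative to
  the single most-expressed reaction, so one extreme transcript rescales
  the whole model; percentile-referenced variants are not implemented.
* Gap filling assumes the universal database shares the model's
  metabolite namespace; no identifier translation is attempted.
* The two-sided Fisher test flags depletion as readily as enrichment;
  with small universes (toy scale) depleted pathways can be the only
  significant rows.
* Projective decomposition on a single surviving condition column
  yields a ±1 core — correct, but uninformative for display; alteration
  calls therefore never use the core (see above).
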
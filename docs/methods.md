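# Methods

## Reaction grammar and its semantics

A model file is line-oriented: each non-comment, non-directive line is one
reaction. The verb inventory (binds / is dissociated into / phosphorylates /
dephosphorylates / is phosphorylated / is dephosphorylated / transcribes /
is translated into / is degraded / is synthesized) is the minimal set that
covers association, covalent modification, transcription/translation and
turnover — the reaction classes that make up typical growth-factor signaling
models. Species names are case-sensitive identifiers; comments run from `#`
to end of line; a trailing `| name=value, ...` clause overrides the default
values of that line's rate parameters, and unknown override names are
errors rather than silently ignored.

Two deliberate semantic choices:

* **Unary state transitions are reversible first order; catalyzed
  modifications are irreversible Michaelis–Menten.** "S is phosphorylated"
  with no named kinase is a background interconversion (k_f, k_r);
  "E phosphorylates S" is enzyme-limited, v = V·[E]·[S]/(K+[S]), with the
  enzyme concentration explicit rather than folded into V, so that changing
  enzyme abundance (e.g. by a stimulus) changes the rate without refitting.
* **Templates are not consumed.** `TF transcribes M` produces M at a Hill
  rate in [TF] (default n = 2, fit bounds [1, 4]); `M is translated into P`
  produces P at k_f·[M]. Transcription factors and mRNAs act as modifiers,
  exactly like MM enzymes, so their stoichiometric columns stay empty.

Directives attach observables (`@obs`, named nonnegative linear
combinations of species), initial amounts (`@init`), named stimulus
conditions (`@sim_condition`), and per-parameter fit bounds
(`@param_bound`). The canonical renderer emits the same dialect and is
byte-stable under re-parsing, which the round-trip tests rely on.

## Compilation

Species are enumerated in first-appearance order; each reaction j gets its
own parameters named `<slot>_r<j>` (1-based). Default parameter value 1.0
with fit bounds [10⁻³, 10³] — a symmetric log-space box around unity, since
relative (normalized) data carry no natural scale. The stoichiometric
matrix S holds −1 per consumed reactant and +1 per product; the compiled
right-hand side is exactly S·v(x, θ), with v assembled symbolically (sympy)
and lambdified once per model. The rate-law registry is user-extensible;
overwriting a built-in mapping requires an explicit flag.

Conserved moieties are computed as an integer basis of the left null space
of S and serve both as a user-facing diagnostic and as the oracle for the
conservation tests.

## Detailed balance

At thermodynamic equilibrium every reversible reaction is individually
balanced, which forces the product of equilibrium constants around any
closed reaction loop to one (the Wegscheider condition). A loop is any
vector c with S_rev·c = 0, where S_rev is the stoichiometric submatrix of
the reversible mass-action reactions: that null-space definition is the one
under which ∏(k_f/k_r)^c must equal 1, and it is strictly stronger than
cycles of the composition graph. The canonical counterexample is the
binding diamond {A+B⇌AB, AB+C⇌ABC, A+C⇌AC, AC+B⇌ABC}: its composition
graph is acyclic (a deficiency-one network), yet c = (+1,+1,−1,−1) is a
thermodynamic loop. The package therefore reports the composition graph
only for inspection and detects loops via the integer null-space basis.

Per independent loop, the reverse rate constant of the highest-indexed
not-yet-derived reaction is eliminated (deterministic, and automatically
added reactions — which come last — yield their constants first). Derived
constants are recomputed from the loop formula at every parameter
evaluation, so fitted and perturbed models are always thermodynamically
consistent, and the free-parameter count drops by exactly the number of
loops.

A subtlety uncovered while validating: with matched conserved totals, the
*unconstrained* diamond also relaxes to a unique steady state, so "different
initializations give different equilibria" is not the observable violation.
What a loop product ≠ 1 actually produces is a perpetual flux around the
loop at steady state, and disagreement between the overall equilibrium
constants predicted along the two assembly paths (they differ by exactly
the loop product, so the realized concentration ratio can match neither).
The tests assert those signatures, plus initialization-independence and
per-reaction balance for the constrained model.

## Simulation and normalization

Integration uses LSODA (stiff-capable) at rtol 10⁻⁸ / atol 10⁻¹⁰; a
stimulus is an initial-amount override at t = 0, matching
growth-factor-addition experiments. Negative excursions beyond −10⁻⁸ are
treated as solver failures; smaller ones are clipped to zero. Observables
are normalized per observable *across all conditions of a dataset* by the
single group maximum (peak exactly 1): immunoblot-style intensities are
comparable within a blot but not across targets, so each observable gets
its own scale shared by its conditions.

## Estimation

The objective is Σ(normalized simulation − normalized data)² over all
(observable, condition, time) rows, with simulation and data each
normalized by their own per-observable group maximum; an optional `sd`
column turns the residuals into sd-weighted ones (sd scaled by the same
group maximum). Solver failures return a large finite penalty (10¹⁰) so
the search can move away from pathological regions.

Fitting runs independent seeded differential-evolution searches in log₁₀
space, one per requested parameter set (default 10), each a multi-start
sample rather than a posterior draw; the reported trajectory is the
pointwise ensemble mean ± sd of the normalized observables. Identical
model + data + configuration reproduces the ensemble bit for bit.
`polish=False` keeps evaluation counts within the configured budget and
the procedure derivative-free.

## Sensitivity

Coefficients are normalized log-log finite differences,
s = ln(q(f·θᵢ)/q(θ))/ln f with f = 1.01 — the metabolic-control-analysis
convention. Only free parameters are perturbed; derived constants follow
their loop formula so every perturbed model stays consistent.
Reaction-level coefficients scale a whole reaction's rate instead.
Integration tolerances default tighter here (rtol 10⁻¹⁰) because the log
difference amplifies solver noise by 1/ln f ≈ 100.

## KGML import

KEGG pathway XML stores entries (genes, compounds, groups, map links) and
typed relations with subtypes. Because KEGG diagrams do not represent
activated protein states as nodes, import proceeds in two stages: state
expansion adds one active form per activated entry ("p"+name when
phosphorylation is evidenced among incoming subtypes, "a"+name otherwise)
and re-sources that entry's outgoing edges from the active form; conversion
then maps each relation to a line (activation → `phosphorylates`,
inhibition/dephosphorylation → `dephosphorylates` of the active form,
binding/association → `binds`, GErel expression → `transcribes`), adds a
first-order reversion line for every active form lacking an explicit
deactivator, and appends requested degradation lines. Groups become single
complex species (members joined by `_`); compounds and map links generate
no species; "indirect effect" is skipped by default; any other unmapped
subtype is an error — guessing a mechanism would silently corrupt the
model. A deactivating relation whose target was never activated is likewise
an error: there is no active form to remove. Every generated line carries
provenance back to its relation or option, and generated text is re-parsed
before being returned.

## Literature co-occurrence

Corpora are PubTator-shaped tables (document id, entity text, entity type).
Counting is document-level (a gene counts once per document) with
case-folded exact matching; no synonym expansion (alias tables are user
input). Query filtering keeps documents with a mention equal to the query.
The comparison statistic is a pseudocounted rate ratio,
fold = ((c_q+π)/(N_q+2π)) / ((c_b+π)/(N_b+2π)) with π = 0.5 — strictly
positive, exactly 1 under self-comparison, and defined at zero counts.
Ratios are descriptive weights for graph annotation (node size, edge
width), not significance tests.

## Synthetic study conditions

The generators in `textode.fixtures` are pure functions of their arguments
and seed.

* **Toy KGML**: gene entries G1…Gn with relations drawn without replacement
  over ordered pairs; subtype mix 40% activation+phosphorylation, 30%
  activation, 20% binding, 10% inhibition, with inhibition only assigned to
  targets that also receive activation (mirroring kinase/phosphatase
  pairing, and required for a deactivation line to be expressible).
* **Toy corpus**: each document carries a species annotation, mentions the
  query with probability 0.2, and mentions each gene at rate 0.8 (planted
  genes in query-positive documents) versus 0.2 otherwise — a planted rate
  ratio of ≈2.5 against the mixed background.
* **Synthetic time courses**: the model is simulated at known parameters,
  normalized exactly as the objective normalizes, and multiplied by
  unit-mean lognormal noise with the requested coefficient of variation
  (immunoblot intensities are positive and heteroscedastic). The hidden
  truth is returned for recovery benchmarks.
* **Recovery benchmark**: synthesize → phosphorylate (reversible) → degrade
  with true rates (0.5, 1.2, 0.4, 0.8), 50 timepoints over 10 time units,
  5% noise, three conditions — basal (A₀=1), stimulus (A₀=3) and a
  phospho-loaded relaxation experiment (A₀=0, pA₀=2) — observed through
  A, pA and total A+pA. The design is chosen for identifiability: the total
  observable pins the relative scales that per-observable normalization
  removes (without it three of the four rates lie on a one-dimensional
  unidentifiable manifold), and the relaxation condition isolates the
  reverse rate, whose error otherwise fluctuates with the noise realization.
  Under these conditions a 10-start fit recovers all four rates within 25%
  (typically under 10%).

What the synthetic data do *not* emulate: real immunoblot error structure
(band saturation, loading-control artifacts), KEGG's full relation-type
diversity (ECrel stoichiometry, compound intermediates), or biomedical
synonymy in the literature. Passing tests demonstrate the machinery is
self-consistent and numerically correct at desk scale, not that a given
biological model is right.

## Numerical choices and limitations

* Problem sizes: 50-pathway round-trip batches, 50-document-scale corpora,
  ≤3000-evaluation fits with 10 starts — sized so the whole verification
  suite runs in minutes on one CPU.
* Differential evolution uses latin-hypercube initialization, immediate
  updating, tol = 0 (budget-controlled termination), popsize 15.
* Tie-breaks are deterministic everywhere: species by first appearance,
  cycles sorted by reaction-index signature, derived-parameter election by
  highest reaction index.
* No compartments, volumes, events, delays, algebraic rules or SBML; no
  steady-state pre-equilibration (long integration serves); no global
  sensitivity; no LLM API calls (prompt construction and output validation
  only).
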
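# Methods

`mlago` couples a data-driven Michaelis-constant (K_m) predictor to a
constrained global optimizer for kinetic-model calibration. This note
describes the models and procedures, the parameters that matter, what
the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## The estimation problem

A kinetic model is a system of ODEs dx/dt = f(t, x, p) over molecular
concentrations x with kinetic parameters p, among them Michaelis
constants. Fit to a concentration dataset x^exp indexed by experimental
condition i, timepoint j and measured molecule k is scored by the
badness-of-fit,

    BOF(p) = sqrt( mean over available (i,j,k) of
                   ((x_sim_ijk(p) − x_exp_ijk) / x_exp_ijk)^2 ),

a root-mean-square *relative* error, invariant under joint rescaling of
simulation and data. Plausibility of an estimate is scored on log10
scale against a reference vector q* (measured values or machine-learning
predictions):

    RMSE(q, q*) = sqrt( mean_i (q_i − q*_i)^2 ),   q_i = log10 p_i.

Conventional calibration minimizes BOF inside box bounds
p ∈ [10⁻⁵, 10³] mM and is prone to unrealistic, non-unique estimates:
many parameter vectors fit the data equally well (non-identifiability).
The constrained formulation instead minimizes RMSE(q, q^ML) to
predictor-supplied references subject to BOF(p) ≤ AE, with the allowable
error AE = 0.02 by default. The constraint guarantees a good fit; the
objective acts as a regularizer that selects, among all well-fitting
parameter sets, the one closest to biologically plausible values —
restoring uniqueness.

Division by x_exp makes BOF undefined at zero measurements: cells whose
magnitude falls below a floor (default 1e-9 concentration units) are
masked out and the mean runs over the masked-in cell count, which also
supports ragged (non-rectangular) datasets. Concentration units are the
model's own; BOF is scale-free so no conversion is ever applied.

## K_m prediction

### Curation

One record is an (EC number, compound ID, organism ID, K_m/mM) tuple.
Duplicated triples are merged into a single record carrying the
geometric mean of the group's K_m values — equivalently the arithmetic
mean of log10 K_m, the scale on which all modeling happens. Grouping is
by exact string triple; no EC-wildcard or synonym resolution is
attempted (the curated source data have already had mutant enzymes and
non-natural substrates removed). Rows with non-positive or unparseable
K_m are dropped and counted, never silently. The train/test split is a
seeded random partition, 4:1 by default.

### Hierarchical one-hot encoding

An EC number a.b.c.d is encoded as four concatenated one-hot blocks for
its prefixes a, a.b, a.b.c and a.b.c.d, so two enzymes sharing the first
three classification levels share three hot bits; compound and organism
identifiers get one conventional one-hot block each. Blocks are
concatenated in the order EC level 1..4, compound, organism, and a fully
known record has exactly six ones. Two consequences used as test
oracles: encoding is injective on known records, and the Hamming
distance between the EC regions of two codes is 2·(4 − shared prefix
length).

Vocabularies are the categories observed in the training table, sorted
lexicographically — any fixed deterministic order works, and published
worked indices are reproduced by constructing vocabularies with the
corresponding ranks. Categories unseen at prediction time yield an
all-zero block with a logged warning rather than an error: predictions
degrade gracefully toward the model's response to an uninformative
input. User-facing bit positions are 1-based; storage is 0-based numpy.

### Learners and evaluation

Four regressor families are wrapped behind one configuration surface:
k-nearest neighbors, elastic net, random forest (scikit-learn) and
gradient boosting (XGBoost). The target is log10(K_m/mM) and both
evaluation metrics (RMSE, R² about the reference mean) are computed on
that scale. Model selection minimizes mean cross-validation RMSE over a
user-suppliable grid (small default grids ship per algorithm); ties
break by grid enumeration order. Cross-validation rebuilds the encoding
scheme on every training fold so held-out-only categories cannot leak
into the vocabulary; round r of repeated CV shuffles folds with seed
base + r. Predictions are back-transformed to mM and clipped into the
global search bounds [10⁻⁵, 10³] mM.

Permutation importance permutes a feature group's columns jointly (one
row shuffle per group per repeat, default 10 seeded repeats) and
reports the mean RMSE increase over the unpermuted baseline; the default
groups are the six encoding blocks, and a per-feature variant supports
top-k rankings. An all-zero (constant) group has importance exactly 0.

## Simulation

The default integrator is LSODA (stiff-capable, via
`scipy.integrate.odeint`, which has markedly lower per-call overhead
than the generic `solve_ivp` wrapper; other `solve_ivp` methods are
available by name). Default tolerances rtol 1e-6 / atol 1e-9 are
recorded in result manifests. Integration failure — non-convergence or
non-finite states — is reported through a success flag and, inside
optimization loops, mapped to a sentinel BOF of 1e10 so that a global
optimizer can still rank such points (as maximally violating) instead of
crashing.

Quasi-experimental data are produced by simulating a model at reference
parameter values; with zero noise the round trip BOF(p_true) vanishes to
solver tolerance. Optional multiplicative noise is median-1 lognormal
with a given coefficient of variation; for small CV the expected BOF at
the true parameters equals the CV, a Monte-Carlo test oracle.

SBML input is supported for a Level 2/3 core subset: compartments,
species with initial concentrations, global and reaction-local
parameters, and reactions with content-MathML kinetic laws. Events,
rules, function definitions and delays are outside the subset and raise
a structured unsupported-construct error naming the elements. Parameters
are flagged as K_m's by name pattern (`Km*`, `km_*`, `R1.Km`, …) or by a
user-supplied annotation map, which also attaches the (EC, compound,
organism) query triple for each K_m.

## Global optimization

The engine is a real-coded genetic algorithm of the REXstar/JGG family.
Search runs in log10-transformed coordinates, so the default bounds
become the uniform box [−5, 3] — appropriate because K_m spans about
eight orders of magnitude. Per generation, m parents are drawn at random
from the population; children are sampled around the parents' centroid G
as

    child = G + ξ·(G_best − G) + Σ_i u_i (x_i − G),

with u_i ~ N(0, 1/m), G_best the centroid of the better half of the
parents, and ξ ~ U(0, t) the steering step (t = 6 by default). Children
are clipped to the bounds, and the best m children replace the parents
(just-generation-gap replacement). Defaults: population max(50, 10 d),
m = d + 1 parents, 5(d + 1) children; all configurable.

Constraints are handled by stochastic ranking with comparison
probability P_f = 0.45: adjacent individuals are compared by objective
with probability P_f (always, when both are feasible) and by constraint
violation otherwise. A strict feasibility-first (Deb-style) ranking is
available via configuration. Independently of the population ranking,
the engine tracks the best feasible point ever evaluated (and the
minimal-violation point as a fallback), so the reported optimum is
feasible whenever any feasible point was visited, and the trace of best
feasible objective is non-increasing by construction.

Termination is by evaluation budget (default 100,000 objective
evaluations — the cost unit is one model simulation) or stagnation: no
improvement greater than 1e-6 in either the best feasible objective or
the best violation for 300 consecutive generations. The window is
deliberately wide: JGG touches only d + 1 of the ~50+ population members
per generation, and a short window (e.g. 50 generations) halts 1-D
constrained searches an order of magnitude short of the constraint
boundary. Co-searched k_cat/V_max parameters are expressed through an
RMSE mask: they participate in the search and the BOF constraint but are
excluded from the RMSE objective, since reference values are rarely
available for them.

Repeated-trial campaigns run trial t with seed base + t and summarize
dispersion: feasibility rate, mean ± SD of the RMSE to the reference,
and the per-parameter SD of log10 estimates across trials — the
operational measure of estimation uniqueness.

## Synthetic study systems

### Toy pathway

`make_toy_pathway` builds an irreversible Michaelis–Menten chain
S0 → S1 → … → Sn with v_i = Vmax_i·S_{i−1}/(Km_i + S_{i−1}), a constant
inflow into S0 and a first-order sink from Sn. The boundary conditions
give a unique stable steady state (at steady state every reaction
carries the inflow flux — a test oracle), keep stiffness mild and
simulations at ~2 ms, and make flux balance checkable in closed form.
Parameters are drawn log-uniformly: K_m from 0.01–10 mM (the bulk of
measured K_m values), Vmax from 0.1–10 concentration/time. Each reaction
carries a synthetic (EC, compound, organism) annotation so the
prediction-to-estimation pipeline can be exercised end to end.

Default quasi-data use one condition and ten timepoints on t ∈
[0.5, 10]. With **all** species observed noiselessly the chain's K_m's
are fully identifiable and unconstrained fitting already recovers them
uniquely; the non-identifiable regime that motivates the constrained
method is reproduced by observing only the boundary species (S0 and Sn),
which leaves interior K_m's weakly constrained by fit alone. The
dispersion experiments therefore use partial observation.

### Random-effects K_m table

`make_synthetic_km_table` draws log10 K_m = μ + Σ effects + ε, with one
centered normal effect per category at each of the six encoding levels
and residual noise ε ~ N(0, σ_ε²). Defaults: 2,000 entries, category
counts (6, 12, 24, 60) EC levels / 40 compounds / 20 organisms, effect
SDs (0.10, 0.15, 0.20, 0.60, 0.40, 0.10) log10 units, σ_ε = 0.5,
μ = −0.5 — placing the dominant signal on the full EC code and the
compound, a residual spread of half a decade, and most K_m values below
1 mM. Because effects are additive and independent, the best achievable
held-out R² has the closed form Σσ²_effects/(Σσ²_effects + σ_ε²) ≈ 0.71
at the defaults; a fitted random forest must land below this ceiling but
within reach of it, and grouped permutation importance must rank the
planted dominant block first. These are the predictor acceptance
oracles.

What the generator does **not** emulate: real K_m tables have heavily
skewed category frequencies, correlated effects between related
compounds, organism-by-enzyme interactions, and measurement-protocol
heterogeneity. Passing tests demonstrate that the encoding and learners
recover additive hierarchical signal, not that real-data accuracy
matches published benchmarks — reproducing those requires the external
curated table (see README).

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run at desk scale, chosen so
the full pipeline (including ~10⁴-point grid oracles and repeated GA
trials) completes quickly on one CPU: 5,000-entry synthetic tables with
a 100-tree random forest; a 5-reaction chain with 8,000-evaluation GA
budgets and 5 repeated trials; a 1-reaction chain against a 10,000-point
exhaustive grid. Larger budgets only sharpen the reported contrasts.

## Known limitations

- The predictor is only as good as category overlap: fully unseen
  triples collapse to the zero-vector response. No structural,
  sequence, temperature or pH features are used by design.
- The SBML subset excludes events, rules and function definitions;
  models using them must be supplied as native right-hand sides.
- The GA's internal hyperparameters follow common settings for the
  REXstar/JGG family; no claim is made of setting-for-setting parity
  with any particular toolbox implementation. The acceptance surface is
  property-based: convergence against grid oracles, feasibility
  semantics, determinism, and recovery/uniqueness contrasts.
- Stochastic ranking trades constraint-boundary precision for
  exploration; where tight boundary accuracy matters on low-dimensional
  problems, the feasibility-first ranking converges tighter.
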
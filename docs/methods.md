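# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind the package, in the spirit of a model-description chapter:
what is computed, why the defaults are what they are, and what the synthetic
benchmarks do and do not demonstrate.

## Model substrate and conventions

Models are handled as COBRApy `Model` objects (SBML Level 3 + FBC or
COBRA-style JSON, both read and written). Exchange and sink reactions are
written export-positive (`met ->`), so uptake is a negative flux. Sinks
added for measured metabolites are irreversible consumers
(`SK_<met>: met ->`, bounds `[0, 1000]`) and are created idempotently.
Gene–reaction rules aggregate per-gene scores with AND → min (a complex is
limited by its scarcest subunit) and OR → max (isozymes substitute); genes
without data are dropped from their connective, and a rule with no
informative leaf is treated as unknown — such reactions are never pruned on
expression grounds. These are the dominant community conventions; nothing
in the method depends on the aggregation beyond monotonicity.

Steady-state and bound tolerances are 1e-8 and 1e-9 for exact LP/QP
solutions, and 1e-6 for hit-and-run samples, which are only periodically
re-projected onto the steady-state subspace. All three live in
`qm2ta.config.Tolerances`.

## Condition-specific models

Genes with FPKM below 1 in every condition are removal candidates;
additionally, genes below 1 FPKM in a treatment but at or above 1 in the
control are treatment-specific candidates when their differential
expression is significant (FDR-adjusted p < 0.05). Candidates are removed
sequentially in ascending order of their maximum FPKM (ties broken by gene
id), and each removal is kept only if the model still reaches 50% of the
*original* (pre-pruning) biomass optimum and every required metabolite's
sink can carry at least `min_sink_flux = 1e-4`. Sequential greedy removal
with a deterministic order makes pruning reproducible; the guard is
re-checked after every step, so the final model satisfies it by
construction. The reference point for the 50% guard (original vs current
optimum) is a genuinely open choice; the original optimum is used because
it makes the guard monotone as candidates accumulate. A reaction is closed
only when its rule evaluates inactive with the removed genes knocked out,
so isozymes protect shared reactions. Models that produce no biomass at
all are rejected before pruning rather than trivially passing a
fraction-of-zero guard.

## Reference flux

The control state chains four steps:

1. **Expression-weighted flux minimization** — minimize
   `sum_i w_i |v_i|` with `w_i = 1 / (1 + e_i)`, where `e_i` is the
   GPR-aggregated FPKM of reaction `i`; reactions without expression
   evidence receive the median weight. The weight is continuous and
   monotone-decreasing in expression, so poorly supported reactions pay
   more per unit flux; it is deliberately simple and is exposed as a
   replaceable function. Constraints: steady state, bounds, biomass at
   `>= 0.95 x` optimum, and a floor of `min_sink_flux` on the sink of
   every measured metabolite. Absolute values are handled exactly by
   splitting each flux into nonnegative forward/reverse parts (LP, HiGHS).
2. **FVA restriction** — "within 99% of the optimum" for a minimization
   objective is read as `sum w_i |v_i| <= optimum / 0.99`, which keeps the
   optimal face inside the restricted set; per-reaction bounds are then
   tightened to the variability ranges under that budget, and the budget
   constraint itself stays attached to the model used for sampling.
3. **Hit-and-run sampling** — COBRApy's artificial-centering hit-and-run
   sampler, seeded, so runs are bitwise reproducible. Defaults are 1000
   samples at thinning 100; tests and the acceptance script use 120–300
   samples at thinning 10–25, which keeps the chain inside CI timings
   while the sample mean remains well inside the polytope. A fully pinned
   (0-dimensional) polytope is detected and its unique point returned
   directly, since a random walk has nowhere to go.
4. **Averaging** — the componentwise sample mean. The constraints carve a
   convex set, so the mean satisfies every constraint it was sampled
   under, including the biomass floor; stacking the two fractions gives
   the guaranteed bound `biomass >= 0.95 x 0.99 x optimum`.

## The transformation QP

Each significant measure (FDR-adjusted p below the 0.25 gate) pulls its
reactions toward the target `v_ref x FC`, normalized by the expected
excursion `|v_ref (FC - 1)|`; unmeasured reactions are anchored at the
reference, normalized by `|v_ref|`. Both denominators are floored at
`epsilon = 1e-6 x mean|v_ref|` so the objective stays a strictly convex,
separable quadratic even where the reference flux vanishes.

Two decisions deserve a note:

* **Squared denominators in the anchor term.** The anchor term is
  implemented as `((v_ref - v)/max(|v_ref|, eps))^2`, i.e. the
  normalization is squared along with the residual. A first-power
  denominator would make the two objective terms scale differently under a
  common rescaling of fluxes and bounds (and could go negative for
  reversible reactions), defeating the purpose of normalizing by the
  reference; with the squared form the whole objective is dimensionless
  and exactly invariant under `v_ref, lb, ub -> c v_ref, c lb, c ub`,
  which the test suite asserts.
* **Reversible reactions.** Targets preserve the sign of the reference
  flux (`target = v_ref x FC`), i.e. fold changes scale magnitude along
  the realized direction.

Measures with fold change exactly 1 carry no direction (their weight would
also explode the normalization) and are dropped with a warning. Overlapping
measure-to-reaction maps contribute additive terms; no deduplication.

Drug constraints are bound edits: `ub <- fraction x v_ref` for the named
reaction (half the reference flux for a glutaminase inhibitor). Knockdowns
are the same edit anchored at either the reference (transformation screen)
or the adapted flux (MOMA screen), applied on the side of the anchor's
sign; a zero anchor closes the forward direction.

### Solving

The objective is diagonal, so every solve is
`min v' diag(a) v - 2 b'v  s.t.  S v = 0, lb <= v <= ub`. The production
path runs SLSQP from an LP-feasible start, reads the active set off the
iterate, solves that active set's KKT system exactly, and accepts the
polished point only with a verified KKT certificate (stationarity plus
dual-sign feasibility) — convexity then guarantees global optimality. If
the certificate fails the solver falls back to `trust-constr` with the same
polishing. Objective values reported to callers are always recomputed at
the returned point, never read off the solver. The knockdown screens
exploit the fact that a knockdown only moves bounds: the objective is
assembled once and re-solved per gene on edited bound arrays, avoiding
per-gene model copies.

The independent oracle (`qm2ta.synthetic.qp_oracle`) enumerates all 3^n
active-set patterns and keeps the best feasible stationary point; it
shares no code with the production path and is exact on the small models
it accepts (n ≤ 12; the randomized benchmark fixtures use 8 reactions,
where the enumeration is fast). The LP oracle enumerates polytope vertices
batched per basis choice, with an optional half-space for
fraction-of-optimum constraints.

## Scoring

The transformation score sums, per measure, the weighted signed change of
absolute flux over the measure's reactions:
`TS = sum_m W_m sign(log FC_m) sum_{i in R_m} (|v_res_i| - |v_ref_i|)`.
The per-measure inner sum subtracts reference from result reaction-wise
(the only reading that is coherent when a measure maps to several
reactions). `sign` maps 0 to 0, so null knockdown effects propagate to
`S_g = 0` rather than inventing a tie-break. Knockdowns that render the
problem infeasible are flagged and excluded from the ranking rather than
scored as extreme. `TS_base = 0` makes the normalization in `S_g`
undefined and raises, with raw TS differences as the suggested fallback.

## Synthetic benchmarks

`make_toy6` is the canonical 6-reaction two-route network; `make_route_model`
builds n interchangeable enzyme routes between two metabolites — redundancy
is the point, because a target screen is only discriminative when ordinary
knockdowns can be rerouted around. `make_random_model` grows a feasible
backbone chain plus random connections, reversibility and small GPRs, and
is deterministic per seed.

`simulate_adaptation` defines the ground-truth adapted state as the
feasible flux nearest the reference with the perturbed genes' reactions
fixed at `effect_size x v_ref` and all GPR-less reactions (exchanges,
biomass) pinned at their reference value: the simulated adaptation is an
internal redistribution at conserved exchange, which is what makes a
noiseless scenario exactly recoverable (every flux that changes is
attributable to a measured gene). Fold changes are aggregate
|flux|-ratios per gene times multiplicative lognormal noise (sigma on the
log, default 0.1); p-values are drawn, not computed — changed measures get
`p ~ U(1e-4, p_th/2)`, unchanged ones `p ~ U(p_th, 1)` — because the
pipeline consumes (FC, p) pairs exactly as produced by an upstream
differential-expression tool. Default effect size is 2x on one gene among
ten candidates.

What passing benchmarks show: the QP solver is exact against enumeration,
the pipeline recovers noiseless ground truth to machine precision, and the
screen has >= 80% top-1 power at a 2x effect under 10% fold-change noise
on a redundant network. What they do not show: behavior at genome scale
(thousands of reactions; the solver path is dense and deliberately sized
for toys), realistic correlation structure between genes, measures mapping
through complex multi-reaction GPRs, or p-values with realistic
miscalibration. Conclusions about real tumors require the real model and
omics.

## Study metrics

Exchange rates assume exponential growth and constant per-cell flux:
`mu = ln(N_T/N_0)/T`, `J = mu (M_T - M_0)/(N_T - N_0)`, switching to the
constant-population limit `J = (M_T - M_0)/(N_0 T)` when `|mu| T < 1e-9`
to avoid catastrophic cancellation. Units are propagated, not converted.
Tumor volumes use the modified ellipsoid formula `L W^2 pi/6` with
length/width swapped (with a warning) when recorded inverted; TGI is the
baseline-normalized treated/control volume ratio, allowed to go negative.
The enzyme-activity proxy `(product/substrate)/control_ratio` is exposed
as an explicitly underspecified convenience and labeled as such.

## Pipeline and provenance

The `run` pipeline executes build-context → reference-flux → transform
(with drug constraints) → screen-targets and writes TSV artifacts whose
comment headers carry the config hash, model hash and seed; reruns with
identical inputs are byte-identical. Exit codes separate configuration
errors (2), infeasibility (3) and numerical failure (4). A missing pathway
annotation file downgrades the pathway report to a warning rather than
failing the run.
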
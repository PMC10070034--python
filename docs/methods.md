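# Methods

## Model class and scope

`cellforge` targets hybrid single-cell models in which gene expression is
intrinsically stochastic and low-copy (promoter states, mRNA molecules)
while protein biochemistry is high-copy and treated as deterministic ODEs
in concentration units. The two modules communicate on a fixed grid: every
`dt` seconds the gene module advances one step using protein
concentrations frozen at step start, its new mRNA counts are converted to
nM and written into the biochemistry module's boundary species, and the
biochemistry ODEs are integrated to the end of the interval. This is Lie
(first-order) operator splitting; its error is O(dt) and dominates solver
error at the default tolerances.

Protein biochemistry is always deterministic, in both targets; there is no
stochastic simulation of the integrated SBML file.

## Gene-expression kernel

Each gene is a telegraph model: `g_total` independent promoter copies with
activation rate `k_on,eff` and inactivation rate `k_off`, transcription at
`k_tc` per active copy, first-order mRNA decay at `k_deg`. Regulation
multiplies `k_on` by `1 + w·c^h/(K^h + c^h)` per activator and divides by
the same factor per repressor (weight `w` ≥ 0, half-max `K` in nM, Hill
exponent `h` ≥ 1); the functional form is a framework choice declared per
gene in `regulation.tsv`.

For rates frozen within a step, the stochastic kernel samples the exact
per-step marginals of the underlying continuous-time process:

* each allele's terminal state from the exact two-state Markov transition,
  `P(off→on) = (k_on/r)(1 − e^(−r dt))` with `r = k_on + k_off`
  (symmetrically for on→off), which reduces to the first-switch
  probability `1 − e^(−k dt)` whenever the opposing rate is zero;
* transcription as `Poisson(k_tc · g_active,start · τ_eff)` with
  `τ_eff = (1 − e^(−k_deg dt))/k_deg → dt`, the survival-weighted exposure
  that accounts for decay of molecules born within the step;
* degradation as binomial thinning of the step-start count with survival
  probability `e^(−k_deg dt)`.

A simpler scheme (at most one switch per allele, `Poisson(k_tc g dt)`
transcription) matches these marginals only to first order in `dt`; at
`dt = 30 s` with switching rates up to 1e-2/s its accumulated bias in
steady-state promoter occupancy reaches several percent, which an ensemble
of a few hundred cells resolves as a systematic departure from the
mean-field trajectory. The exact-marginal kernel removes that bias by
construction: the expectation of one stochastic step coincides with the
mean-field update exactly at the allele level and up to the within-step
variation of the allele count (an O(dt²) transient effect) for mRNA. The
one remaining approximation is that transcription uses the step-start
allele count rather than the allele path.

The mean-field variant propagates the linear ODE system exactly over each
step (closed form for a 2×2 triangular linear system, with analytic limits
for the degenerate cases `r = 0`, `k_deg = 0`, `k_deg = r`), so mean mode
adds no integration error of its own; `gene_mean_rhs` exposes the raw
derivatives and a test cross-checks the propagator against high-accuracy
numerical integration of it.

## Units

`UnitContext` holds one cell volume `V` (default 1.0e-12 L) and Avogadro's
number; one molecule corresponds to `1e9/(N_A·V)` ≈ 1.66e-3 nM. The same
conversion is applied at the hybrid module boundary and, as an explicit
`nM_per_molecule` parameter, inside the integrated target's kinetic laws,
so the two formulations are numerically identical by construction. The
single volume is used for all conversions even if the compartments table
declares several compartments.

## Compilation targets

Both targets are SBML Level 3 Version 2, built with libsbml and required
to pass libsbml consistency validation with zero errors (unit-consistency
checks excluded: the dialect deliberately mixes nM-valued and
molecule-count-valued species and documents the conversion). Compilation
is deterministic: identical inputs give byte-identical documents.

* biochem-only: one species per table row (initial concentrations in nM),
  one reaction per row with its rate law as the kinetic law and
  reaction-local parameters; species referenced in a rate law but not
  consumed/produced become SBML modifiers; every `is_mrna` species is a
  boundary-condition species.
* integrated: mRNA species become ordinary species in molecule counts
  (`hasOnlySubstanceUnits`), biochemistry kinetic laws see them through
  `mRNA · nM_per_molecule`, and each gene contributes two count species
  (`<gene>__active`, `<gene>__inactive`, conserved sum `g_total`) and four
  reactions (activation with regulation inlined, inactivation,
  transcription, degradation). Gene dynamics are encoded as reactions
  rather than rate rules so stoichiometry is explicit and the allele
  conservation is checkable; this also keeps the document pure-ODE — no
  events, rules or delays anywhere in the dialect.

## Engines and numerics

Both engines integrate with scipy's LSODA (stiff/non-stiff automatic
switching) at `rtol = 1e-6`, `atol = 1e-12`. Reference operating point:
72 h horizon (259 200 s) at a 30 s interval, i.e. 8640 communication
intervals and 8641 recorded rows. The recording grid equals the
communication grid.

The hybrid loop asks the solver for the interval endpoint only and hands
exactly `n_species` values to the next step (`extract_terminal_state`,
instrumented by `HandoffRecord`), independent of the solver's internal
step density — the structural, hardware-free expression of the
communication cost. The integrated engine runs one solver session over the
whole horizon with output sampled on the same grid (`n_solver_inits == 1`
vs `duration/dt` for the hybrid loop). Within each hybrid step the gene
module advances first and the ODEs then see the step-end mRNA; regulator
concentrations are step-start values. The communication order within a
step (gene update before ODE integration) is one defensible reading of
the modular cycle and is fixed here for reproducibility.

Values in `(−atol, 0)` after an ODE interval are clamped to zero; anything
more negative, or non-finite, aborts with the failure time. `(model,
config, seed)` fully determines every recorded number; ensemble cell `i`
uses `seed + i`.

## Verification

Per-quantity AUC is the trapezoidal integral on the shared grid. The
relative difference uses denominator `max(|auc_a|, |auc_b|)` (symmetric);
quantities with both areas below `atol · duration` are compared absolutely
against that floor, since species pinned at zero have no meaningful
relative scale. The default pass tolerance is 1e-3, sized to the O(dt)
splitting error at `dt = 30 s` (measured discrepancies on the toy panel
are below 1e-4); it is configurable.

## Toy models

`make_toy` generates the model class at reduced scale: telegraph genes
(2 alleles each, rates sampled log-uniformly from `k_on, k_off ∈
[1e-4, 1e-2]/s`, `k_tc ∈ [0.01, 0.2]/s`, `k_deg ∈ [1e-4, 1e-3]/s`), one
protein per gene driven by its mRNA, a linear signaling cascade whose
influx saturates in protein 0, and optionally one feedback term (the
terminal signal species activates gene 0) closing a loop across the
module boundary. Models are initialized at the mean-field steady state
with a 5-fold stimulus bolus on the first signal species — the
starved-then-treated pattern — so dynamics are a cascade relaxation rather
than a global start-up transient. Ranges keep 72 h dynamics non-trivial
but non-stiff at the default tolerances.

What the toys do not emulate: realistic network scale (hundreds of genes,
thousands of species), mass-conserving bimolecular signaling topologies,
translation/protein-synthesis stochasticity, cell division, and realistic
parameter correlations. Passing the equivalence and ensemble tests on
these fixtures demonstrates the correctness of the compilation and
stepping machinery, not biological fidelity of any particular model.

`make_constitutive_benchmark` is the closed-form oracle: a single
always-active gene (`k_on = k_off = 0`, both alleles active, `k_tc =
0.1/s`, `k_deg = 5e-4/s`), for which `m(t) = m0 e^(−k_deg t) + (k_tc
g/k_deg)(1 − e^(−k_deg t))` and the stationary mRNA law is Poisson(400).

## Verification problem sizes

The shipped tests and the acceptance script use: the full 8640-interval
grid for the grid-count and closed-form checks (one species, so both
engines complete in seconds); a 2 h horizon for the 5-model equivalence
panel (2–10 genes); a 1 h horizon and 200 cells for the ensemble-mean
coverage check; and 10 000 samples per marginal for goodness-of-fit at
α = 0.001. These sizes were chosen so the whole verification battery runs
on a laptop-class single core in well under a minute per item while
keeping every statistical band tight enough to detect the biases the
design guards against.

## Known limitations

* No SBML import of arbitrary third-party models: `load_sbml` accepts only
  this framework's dialect (pure reaction networks).
* Regulation acts on `k_on` only; no regulation of `k_off`, `k_tc` or
  `k_deg`.
* The stochastic mode has no path-resolved transcription within a step
  (allele count frozen at step start in the transcription draw).
* Adaptive or per-module communication intervals are out of scope; the
  recording grid is the communication grid.
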
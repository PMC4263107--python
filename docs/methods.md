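# Methods

## Scope and model

`emuflux` performs steady-state 13C metabolic flux analysis (13C-MFA): given
a reaction-table metabolic model with carbon atom transitions, measured GC-MS
mass isotopomer distributions (MIDs) of derivatized fragments, and measured
extracellular rates (effluxes), it estimates the intracellular flux vector u
and its uncertainty.

The flux space is parameterized by free fluxes θ.  With S the stoichiometric
matrix over the balanced metabolites (one column per non-negative flux;
bi-directional reactions contribute a forward and a reverse column;
mapping-only reactions contribute none), p = n − rank(S) fluxes are chosen
free and the rest follow linearly: u(θ) = Zθ with S·Z = 0.  Feasibility means
θ within its bounds and u(θ) ≥ 0 elementwise.  Measured effluxes are
themselves free fluxes box-constrained to their 95% measurement band
(value ± 1.96σ).  Free fluxes are chosen by honouring a user-preferred list
and completing it via QR column pivoting so the dependent block stays
well-conditioned; the reference software assigned free fluxes automatically,
but its rule is unpublished, so the pivoting completion is this package's own
choice.

## Labeling simulation

Labeling states are simulated with the elementary metabolite unit (EMU)
formalism.  Backward tracing from the measured fragments' carbon backbones
yields the minimal closure of EMUs; each unknown EMU's mass distribution
vector (MDV) satisfies a flux-weighted linear balance whose inputs are
tracer EMUs, smaller EMUs, and convolutions of smaller EMUs (condensation
reactions).  Blocks are the strongly-connected components of the same-size
dependency graph, solved densely (LU) in cascade order — sizes ascend, and
within a size the component order is topological.  Components with more than
one EMU (or a self-dependency) are genuine simultaneous systems; the count of
those is reported as `n_matrix_systems`.  Symmetric molecules (succinate,
meso-diaminopimelate) scramble via explicit equal-weight alternative atom
maps in the model table, not via engine special-casing.  CO2 is a balanced
1-carbon species with explicit production/consumption maps and an
environment-exchange pair, so tracer carbon lost by decarboxylation can
re-enter by carboxylation.

Tracers are positional-isotopomer mixtures: labeled positions carry the
isotopic purity (default 99%), all other positions the natural 13C background
(default 1.07%), independently across positions.

A full positional-isotopomer model (2^c unknowns per c-carbon species, solved
by damped fixed-point iteration) serves as an independent oracle; EMU and
isotopomer paths agree to < 1e−8 on every network small enough to enumerate
(≤ 20 carbons).  For larger networks the isotopomer model is only counted,
never solved.

## Measurement model

Simulated backbone MDVs are convolved with the natural mass-shift
distribution of the fragment's non-backbone atoms (H, N, O, Si, S and
derivatization carbons, from its elemental formula), truncated to the first
n+1 masses and, by default, renormalized — matching how uncorrected GC-MS
MIDs of TBDMS/TMS-derivatized fragments are reported.  A detection filter
drops masses whose noise-free abundance is below 4 mol%, so the retained
measurement set depends on the tracer.  Noise is added as independent
N(0, σ) on the retained entries (default σ_MID = 0.4 mol%, efflux σ per
measurement); noisy MIDs are not renormalized (a switch enables it for
sensitivity studies), and negative corrupted abundances are floored at zero
and flagged.  Replicate sets are summarized by the per-entry mean and the
unbiased (L−1) standard deviation.

## Estimation

The objective is the variance-weighted sum of squared residuals over all
retained MIDs and measured effluxes; Ξ(θ) = Σ r² (twice the half-SSR) is the
χ²-tested statistic.  Minimization uses SLSQP under the box bounds and the
linear constraints Zθ ≥ 0, with termination tolerance TT (default 1e−4,
1e−6 supported) on the objective.  Multi-start estimation repeats the local
search from points rejection-sampled uniformly from the feasible box
(default 100 trials; tests and examples use 10–20, which suffices at desk
scale); trials whose Ξ exceeds the minimum by at most TT are counted as
having reached it.  A parallel-labeling-experiment (PLE) problem concatenates
the residual blocks of several experiments sharing θ; residual ordering is
canonical, so Ξ is invariant to measurement and experiment order.

## Statistics

* Goodness of fit: two-sided χ² band χ²_{α/2}(W−p) < Ξ < χ²_{1−α/2}(W−p),
  strict at the edges; α = 0.05 and 0.32 both supported.  An objective far
  below the band is reported as an overfit signal.
* Residual normality: Kolmogorov–Smirnov against N(0,1) combined with
  per-residual reference-line flags (two-sided ±1.96 — the residuals are
  signed, so the two-sided 95% line is used).  The verdict rejects when test
  and high-value plot anomaly agree, when the spread is degenerate
  (near-zero residuals, the uncorrupted-data case), or when ≥ 3 residuals
  exceed |r| > 4 — individually overwhelming evidence the blunt KS statistic
  barely registers.
* Identifiability: numerical null space of the residual Jacobian at the
  optimum; an empty basis means locally identifiable.
* Linearized statistics: H = JᵀJ (Gauss–Newton Hessian of the half-SSR),
  Σ_θ = H⁻¹, Σ_u = ZΣ_θZᵀ.  The contribution matrix is
  CM_ij = (ZH⁻¹Jᵀ)²_ij normalized per row — measurement j's share of flux
  i's linearized variance; rows sum to one identically.  The exact published
  formula is not printed; this propagation-of-variance construction matches
  its stated meaning.
* Monte Carlo confidence intervals: each trial corrupts the measured data
  with N(0, σ) and refits using a multi-runs-per-trial strategy — first run
  warm-started at θ̂, up to N_AS = 3 restarts from random feasible points
  when a run fails or exceeds the trial incumbent by more than ε = 1e−4,
  each run capped at K_NR = 50 iterations.  (N_AS/K_NR/ε semantics are this
  package's reconstruction; the reference defaults are kept.)  Bounds per
  flux: "discarding" (MC-1) drops ⌊L(1−γ)/2⌋ order statistics from each
  tail; "mean-varianced" (MC-2) is mean ± z_{(1+γ)/2}·sd.  Convergence is
  monitored per bound over a sliding window of M = 40 trials: relative
  spread δ = 100·(max−min)/|mean| (rigorous ≤ 1%, relaxed ≤ 10%) with an
  absolute fallback Δ = max−min ≤ 2 for near-zero bounds; runs go to
  L_MAX = 500 by default, optionally stopping early when all bounds
  converge.  MC-1 is robust to stray non-global refits; MC-2 is not — the
  package exposes both precisely to make that contrast visible.
* Profile-likelihood ("non-linear search") intervals walk one flux away from
  its estimate, re-optimizing the rest under an equality constraint, until
  Ξ rises by χ²_γ(1), then bisect.  The method is EXPERIMENTAL: premature
  inner-optimizer termination can yield a 68% interval not nested in the 95%
  one; `check_nesting` detects this and such intervals must be treated as
  unreliable, never silently returned.
* Normalized flux precision: η_γ(u_i) = 1 − CI_γ(u_i)/(u_i + β·max V_eff),
  clamped to [0,1], β = 0.1; Σ_η sums η over all n fluxes.

## Experimental design

D = det Σ_θ = det[JᵀJ]⁻¹ at a user-supplied flux point (the reference point
in simulations); its 2p-th root reads as an average confidence-interval
length.  General design minimizes the 2p-th-root D ratio against a reference
tracer over a mixture simplex of up to three candidate isotopomers (grid scan,
default 2% steps, plus coordinate-descent refinement from the best cell);
partial design minimizes √([H⁻¹]_ii) of one targeted free flux, flagging flat
surfaces.  The detection filter is re-applied per candidate tracer before the
Hessian is built.  No iterative redesign loop is provided.

## The C. glutamicum fixture

`emuflux.cgl` reconstructs a central-carbon model of an l-lysine-producing
C. glutamicum strain on glucose: EMP and PP pathways (three bidirectional
non-oxidative reactions plus bidirectional glucose-6-phosphate isomerase),
TCA cycle with lumped PEP/PYR and OAA/MAL pools and single irreversible
carboxylation/decarboxylation reactions between them, explicit CO2 with
environment exchange, trehalose/lactate/glycine/α-ketoglutarate/lysine
secretion, two glycine routes (serine hydroxymethyltransferase and threonine
aldolase, the latter releasing acetaldehyde which is exported), explicit
biosynthesis of the measured amino acids and those whose synthesis produces
or consumes CO2 (Val, Ile, Leu, Phe, Tyr, Trp, Lys via diaminopimelate, Arg)
plus Met, His, Pro, alanine/aspartate/glutamate as label-mapping-only
reactions, and one lumped biomass equation.  This yields 54 reactions, 36
balanced metabolites, S of dimension 36×51 and rank 36, and 15 free fluxes
in three classes: 7 measured effluxes (glucose uptake, biomass, five secreted
products), 5 reverse fluxes, 3 irreversible branch-point fluxes.  The EMU
decomposition targeted at the ten measured fragments (Ala-260, Val-288,
Thr-404, Asp-418, Glu-432, Ser-390, Phe-336, Tyr-466, Tre-361, Gly-246;
standard TBDMS/TMS compositions recorded per fragment) draws on 15 input
EMUs (14 glucose sub-units plus extracellular CO2) and, under this package's
minimal-closure definition, contains 162 unknown EMUs (502 scalar MID
unknowns) solved through 18 coupled matrix systems; the corresponding full
isotopomer model would hold 8,408 scalar unknowns.  These interior counts
are properties of the exact atom-map file, which is not published; a
reconstruction can pin the stoichiometric structure exactly but not the
EMU-interior sizes, and the structural test suite states the reconstruction's
own values so that any model edit that moves them fails loudly.

The reference flux vector (`THETA_REF`) is a repo-chosen feasible point —
glucose uptake normalized to 100, lysine efflux 15, a high oxidative-PP split
(60) characteristic of lysine producers, modest TCA and exchange fluxes —
standing in for the original study's unpublished true fluxes.  Consequently
every quantitative fixture test targets structure and self-consistency
(round-trip parameter recovery, χ² calibration, CI behavior), not published
flux values or Σ_η magnitudes.

## What the synthetic data do and do not emulate

The generator reproduces the published protocol: forward simulation at the
reference fluxes, natural-abundance expansion, truncation/normalization, the
4 mol% detection filter applied to noise-free values, then Gaussian
corruption of MIDs (0.4 mol%) and effluxes (their measured σ), independently
per labeling experiment of a PLE.  It does not emulate chromatographic
integration error structure (correlated within a fragment), drift between
runs, tracer impurity patterns beyond position-independent purity, or
metabolic non-stationarity.  Passing tests therefore demonstrate correctness
of the inference machinery under the stated error model, not robustness to
real-instrument artifacts.

## Numerical choices and desk-scale sizes

Dense LU for EMU blocks (largest coupled system ≈ 13 EMUs); central
differences (relative step 1e−6) for the residual Jacobian; rejection
sampling capped at 10,000 attempts; SLSQP feasibility violations tolerated
to 1e−6 with tiny negative dependents clipped to zero during simulation
only.  The test-suite and examples run the estimation at reduced sizes — 20
multi-start trials for recovery, 200 goodness-of-fit replicates, 300–500
Monte Carlo trials on the toy networks — chosen so the full suite completes
in minutes while keeping every statistical check's sampling error well below
its assertion tolerance.

## Known limitations

Only MS MIDs are supported (no tandem-MS or NMR observables).  The
profile-likelihood interval search keeps the known failure mode of its
published counterpart (flag-and-warn, not fixed).  The design module
evaluates local (linearized) precision only; no global design criteria.  The
fixture's atom maps follow standard central-metabolism transitions and the
printed free-flux classes, but the original study's exact model file could
differ in interior detail, as the EMU-count discussion above records.
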
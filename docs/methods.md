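# Methods

`dielflux` simulates photoautotroph growth across day/night cycles by
coupling a continuous representation of a diel transcriptome to a
constraint-based metabolic model. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
test fixtures do and do not establish.

## Continuous transcriptome

Diel RNA-seq gives discrete samples (typically 2-h resolution over 24 h).
Each gene's series is fitted by least squares against eight candidate
expression families, all defined on the wrapped diel frame t mod 24:

| family | form | free params |
|---|---|---|
| constant | c | 1 |
| one-term cosine | c + A cos(2π(t−φ)/24) | 3 |
| two-term cosine | c + A₁cos(2π(t−φ₁)/24) + A₂cos(4π(t−φ₂)/24) | 5 |
| hat | c + A·1[t ∈ [t_on, t_off)] (wrap-around allowed) | 4 |
| fixed decay | c + A e^(−t/τ₀), τ₀ = 4 h | 2 |
| variable decay | c + A e^(−t/τ) | 3 |
| Kronecker delta | c + A·1[t ∈ [t₀, t₀+Δ)] , Δ = one sampling interval | 3 |
| cosine multiplicative | (c + A cos(2π(t−φ)/24))·e^(gt) | 4 |

These exact functional forms are this package's declared choices for the
named shapes; alternates can be swapped in through the family registry
without touching the pipeline. The fixed-decay time constant (4 h) and
the Kronecker spike width (2 h) are configuration, not biology.

Selection uses the small-sample corrected Akaike information criterion
AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), with a +∞ sentinel when
n ≤ k+1 and an RSS floor of 1e-12·n so interpolating fits stay finite
(ties then break toward fewer parameters, then a fixed family order).
Akaike weights w_i = exp(−Δ_i/2)/Σ_r exp(−Δ_r/2) always sum to one and
are shift-invariant in AICc.

Fitting is exact where possible: families that are linear in their
coefficients once a single nonlinear parameter is fixed (the cosines via
a sin/cos basis; the decays given τ; the multiplicative cosine given g)
are solved by linear least squares, profiling the nonlinear parameter
over a deterministic ladder plus the requested random restarts with a
bounded local polish. The two discontinuous families are fitted by exact
enumeration of breakpoints over the sampling grid with closed-form
conditional means. Restarts therefore only matter for the profiled
parameters, and more restarts can never worsen the result. All restart
randomness derives from a per-(gene, family) stream keyed by CRC32, so
batch order and parallel execution cannot change any fit.

The winning family's curve, clamped at zero and evaluated modulo 24, is
the queryable expression function a(t).

## Similarity and clustering

Two comparisons are provided. The *score* method concatenates, per gene,
weight × parameters for every family in a fixed 25-slot layout and
compares vectors u, v by S = cos θ · min(1 − ln d / ln d_max, 1), where d
is the Euclidean distance and d_max the dataset maximum. Natural log is
used; if a dataset's d_max ≤ 1 (where the log mapping loses
monotonicity) all distances are rescaled by e/d_max and a warning is
logged. d = 0 maps to distance value 1. The *integral* method samples
the two best-fit curves on a 0.1-h grid, min-max normalizes each, and
returns the mean absolute difference — a shape-only measure, invariant
to positive affine transforms.

A flat curve has no shape: its min-max normalization is undefined, and
any measurement noise is amplified to full scale. Flat curves are mapped
to a constant 0.5 with a logged flag. A related caveat: for a truly flat
transcript under multiplicative noise, single-interval spike fits can
win the AICc comparison with probability independent of the noise scale
(the RSS ratio is scale-invariant), so flat genes are the least reliable
members of any shape clustering.

Clustering feeds the rows of the square dissimilarity matrix (1 − S for
score; integral values as-is) to Ward-criterion agglomeration. Passing
the square matrix rows as observations — rather than condensed
distances — is a deliberate dialect, chosen to match the behavior of the
standard hierarchy routine when handed a square matrix; it is documented
here because the two conventions differ. Heatmaps are assembled one
truncated-dendrogram leaf at a time (memory bounded by one block) with a
stacked per-gene family-weight sidebar.

## Transcript-derived flux bounds

Each gene's flux fraction is v_a(t) = a(t)/max_t a(t) (grid-scanned at
0.05 h; an all-zero curve gets fraction 0 with a flag). GPR Boolean
rules combine fractions with AND = min (enzyme complexes) and OR = sum
(isozyme capacities add); OR sums are not capped inside the tree. A
reaction's bounds at time t are upper = u_max·min(1, v_rule(t)), lower =
−upper if reversible else 0. Reactions without a GPR keep their model
defaults, and genes that appear in GPRs but not in the transcriptome are
treated as unconstrained (fraction 1, logged) — penalizing unmeasured
genes would fabricate constraints. The ceiling u_max is calibrated so
the transcript-bounded light-uptake reaction peaks exactly at the
environment's light availability. Bounds are evaluated lazily at
arbitrary times, so the simulation timestep is freely adjustable; they
are 24-periodic by construction.

## Decoupled biomass and PI control

The single biomass equation is split into 10 pools — carotenoid,
chlorophyll a, chlorophyll b, protein, lipid, lipid droplet,
carbohydrate, nucleotide, redox, starch. Component k's synthesis
pseudo-reaction consumes its share of the biomass metabolites rescaled
by 1/w_k (w_k = the component's grams per gram dry weight, from
metabolite formula weights), so one flux unit makes exactly 1 g of
component per gDW·h and the mass update needs no further stoichiometric
conversion. Summing synthesis stoichiometries times mass fractions
reproduces the original biomass demands exactly (regression-tested).
Degradation pseudo-reactions return the catabolizable share of a
component's metabolites to the network; metabolites with no consuming
reaction are dumped (mass leaves the cell and is tracked). Redox and
nucleotide pools are producible-only by default. TAG species measured in
lipidomics partition into the lipid-droplet pool; all other lipids stay
in the general pool, which carries the nitrogen-containing species and
therefore responds to nitrogen limitation.

Each component has a dual PI controller against a diel mass-fraction
setpoint (piecewise-linear, 24-periodic table):
I ← clamp(I + (sp−x)dt, ±windup), e_prod = Kp(sp−x) + Ki·I, e_cons =
−e_prod. Defaults Kp = 1 h⁻¹, Ki = 0.1 h⁻², windup ±10× setpoint; these
abstract regulation rather than measure it and are fully configurable.
Positive production errors normalize into objective weights over the
currently producible components (uniform fallback when all errors ≤ 0,
so growth never stalls at setpoint). Positive consumption errors order
the catabolism priority (ties: starch first, then a fixed order); in an
emergency — maintenance ATP unmet — the remaining components are
appended in descending-error order.

## The diel marching loop

Forward Euler with dt = 0.1 h (6 min) by default. Per step: (1) rebound
all GPR reactions from the curves; (2) update controllers from current
mass fractions; (3) secure NGAM — maintenance ATP, enforced as a lower
bound — from the medium if possible, otherwise opening store degradation
one component at a time in priority order (death is declared, and the
trajectory truncated with status, only when NGAM is infeasible with
every store open); (4) produce: maximize the error-weighted sum of
synthesis fluxes, then expand the production window by fixing achieved
fluxes as floors and re-maximizing total synthesis of the desired set
until the gain falls below 1e-6 relative (at most 4 rounds; components
whose floors bind are the limiting ones — this floor-and-remaximize
detection replaces per-component re-optimization, reaching the same
fixed point at about one LP per round); a final pass minimizes
degradation at the achieved production, with a small synthesis penalty
pinning the vertex deterministically; (5) advance masses by
Δm_k = (v_syn,k − v_deg,k)·M·dt.

Two pacing rules matter. Degradation of an open store is capped at its
maintenance-required rate plus its positive consumption error, so the PI
controller — not raw availability — paces catabolism; without this, the
nighttime production step would convert an entire store into other
components within a few steps and then starve. And production
feasibility per (time, energy source) is precomputed on an hourly grid
(medium source: environment exchanges open; component source: energy
exchanges closed, nutrients open, that component's degradation open);
the simulator unions the sources active at each step.

The mass ledger closes identically at every step:
Δtotal = production − consumption − dumped, where consumption is the
catabolizable share of degraded mass and dumping the rest; the suite
asserts closure to 1e-9 g on all scenario bundles. Total mass is exactly
the sum of the 10 pools (no structural remainder). LP solutions come
from GLPK through a persistent model with incremental bound and
objective edits; trajectories are deterministic for fixed inputs.

## Knockout scanning

A knockout zeroes one gene's curve everywhere; GPR semantics do the rest
(an AND containing the gene goes to zero, an OR loses one summand). Each
knockout re-runs the full scenario against a wild-type baseline;
underperformers have final-mass ratio ≤ 0.75 (a growth defect of 25% or
more), overperformers ≥ 1.10, both boundary-inclusive and configurable.
Per-gene runs are pure functions of (model, curves, scenario), so the
scan is a plain parallel map, independent of worker count and gene
order. No constraint ties biomass composition ratios across components,
so a knockout can rank as an overperformer while unable to make an
expensive minor component — replicated deliberately, not "fixed", and
worth remembering when reading overperformer lists.

## The toy fixture

A ~45-reaction, 28-gene synthetic photoautotroph: photon capture charges
ATP/NADPH, a carbon-fixation lump makes a generic sugar unit, an
oxidative pentose-phosphate lump supplies dark NADPH, and the ten pools
have GPR-governed synthesis routes. Starch is the only respirable store
(night-peaking catabolic genes behind an OR rule); the structural
carbohydrate pool is deliberately non-respirable so that a cell unable
to build starch by day starves in the dark — the starchless-mutant
phenotype. A designated gene sits in an AND rule over starch synthesis
to make that lesion a single knockout. Biomass fractions (protein 0.45,
starch 0.20, carbohydrate 0.12, lipid 0.10, TAG 0.04, chlorophylls
0.045, carotenoid 0.01, nucleotide 0.03, redox 0.005) are plausible
round numbers summing to 1 g/gDW; all reactions balance C and N by
construction. Default environment: 12:12 light at 30 mmol
photons·gDW⁻¹·h⁻¹, NGAM 2.5 mmol ATP·gDW⁻¹·h⁻¹, replete CO₂ and
nitrogen; acetate scenarios add 2 mmol·gDW⁻¹·h⁻¹ uptake. Phenotype
scenarios run 48 h (two cycles) so a mutant that inherits a wild-type
starch endowment at t = 0 still reaches its steady diel behavior. The
one-doubling calibration bisects light availability until the 24-h
wild-type run ends at normalized mass 2.0 (±0.5% bracket tolerance).

What the fixture shows: the control loops, E-Flux bounds, ledger
bookkeeping and qualitative genotype→phenotype logic behave as designed.
What it does not show: quantitative fidelity to any real organism —
yields, gains and expression phases are stylized, and passing tests on
the toy say nothing about a genome-scale model's numerical predictions.

## Problem sizes and tolerances used in the test suite

Family-recovery checks fit 100 synthetic genes at 5% multiplicative
noise with 12 restarts (the full default remains 100 restarts);
clustering purity uses 60 genes in three planted archetypes, the shaped
ones at 1% noise and the flat one noise-free (see the flat-curve caveat
above); simulations use dt = 0.1 h with a dt = 0.05 refinement check
(<1% final-mass difference); GPR evaluation is verified against an
independent brute-force evaluator on 1000 random trees. Solver-facing
comparisons use 1e-6 tolerances; ledger identities 1e-9; analytic
identities 1e-12.

## Known limitations

Forward Euler is first-order; very large dt can overshoot stores (masses
are clamped at zero with the overshoot charged to the ledger, and an
overshoot beyond 1e-6 g raises). Producibility is looked up on an hourly
grid, so sub-hour producibility transitions are quantized. LP degeneracy
means flux *distributions* are one optimal vertex among many — totals
and masses are stable, individual transport fluxes are not. No
photorespiration, photoinhibition, pH or temperature effects; regulation
beyond the PI abstraction is out of scope.
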
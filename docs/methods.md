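# Methods

This note documents the models, numerical procedures and design choices
behind `orbitempo`, in enough detail to reproduce or criticise them.

## Orbits, tempo, and orbital equivalence

A gene regulatory network is an autonomous ODE system `dx/dt = f(x)` over
named species.  Two systems are *orbitally equivalent* when their rate
vectors differ by a strictly positive scalar field `μ(x, t)`: they trace
identical curves in phase space at different local speeds.  The package
represents this by `apply_scalar_prefactor`, which wraps a model's rate
function; `apply_vector_prefactor` applies a per-species (Hadamard) factor,
which preserves orbits only where its components agree on species that are
actually moving.

The tempo of a process relative to its base rates is the harmonic mean of
μ along the orbit, `⟨μ⟩ = L / ∮ dl/μ`, computed by discretising the orbit
into segments and evaluating μ at segment midpoints.  This converges
second-order in the resolution; the constant and two-level identities are
exact by construction of the quadrature.  The *allochrony deviation* — how
far a tempo field is from one global speed change — is the arc-length RMS
deviation of μ from its arc-length mean, normalised by that mean.  (The
norm is a choice; RMS was picked for its closed forms and smoothness.)

## Orbit extraction

Models are integrated with stiff-capable adaptive solvers (LSODA by
default, BDF for the 12-variable repressilator), rtol 1e-8 / atol 1e-10
for single-system comparisons and rtol 1e-7 / atol 1e-9 inside the large
sweeps.  Trajectories keep the solver's dense output; events (threshold
crossings, Poincaré sections) are refined on it with a root bracketing
step.

Limit cycles are extracted by integrating 28 estimated periods, discarding
the first 12 (both configurable; the period bootstrap comes from
mean-level crossings of a pilot run or a caller-supplied guess), taking
one cycle between successive upward crossings of a Poincaré section (first
protein-like species through its post-transient mean), and resampling it
to arc-length-uniform points (default 500; 200 in sweeps).  The period is
the mean inter-crossing interval; a coefficient of variation above 5%
raises a warning.  Oscillations whose amplitude is below 1e-3 of the
species' magnitude are classified non-oscillatory — solver noise around a
stable fixed point otherwise masquerades as a fast oscillation.

Orbits are normalized per species by the maximum along the orbit
(`mode="own"`) or along a reference orbit (`mode="reference"`).  Distances
between two independently extracted cycles are floored by the stagger of
their arc-length grids; `align_cycle_start` re-cuts a closed orbit at the
point nearest a reference's start (projection onto polyline segments) to
remove this artefact when needed.

## Orbital distance

The discrete Fréchet distance is computed by dynamic programming over the
pairwise distance matrix (numba-accelerated, with a pure-Python fallback);
for closed curves the distance is minimised over all cyclic re-indexings
of one curve in both traversal directions, pruning shifts whose forced
start pairing already exceeds the incumbent.  A witness coupling is
returned by backtracking.  Correctness is gated on an exhaustive-recursion
oracle over all monotone couplings (exact agreement on random ≤8-point
polylines) and on metric properties checked by property-based tests.  DTW
(classic accumulated cost) and symmetric Hausdorff are provided as an
aggregate alternative and a lower-bound cross-check; the acceptance
analyses use Fréchet only.

## Prefactor heterogeneity

For models declaring a decomposition `f = μ ⊙ g`, `prefactor_components`
returns the μ_i together with weights `w_i = |v_i| / Σ|v_j|` from the
system's velocity components — heterogeneity only matters for species that
shape the orbit at that state.  `D_σ(x)` is the square root of the
weighted variance of the μ_i about their weighted mean (the unweighted
mean is available as an option), and the orbital heterogeneity distance is
its maximum along the orbit; points with zero velocity are excluded.

When a perturbed model is analysed **relative to a reference** sharing its
base rates, μ is the component-wise ratio `μ_pert / μ_ref` and the weights
come from the reference velocity.  Sweep records report this relative
D_σ in its scale-free form (divided by the weighted mean, a coefficient of
variation): a perturbation that slows all genes uniformly is pure tempo
and scores zero, mirroring the choice of the coefficient of variation for
the r-statistics.  The absolute (scale-equivariant) form remains the
default of `weighted_heterogeneity`.

## Built-in models

**Bistable switch** — two mutually repressing genes with Hill kinetics
(default α=4, K=1, n=2, δ=1), bistable with two saddle-separated
attractors.

**Ventral neural tube** — Pax6, Olig2, Nkx2-2 and Irx3 with multiplicative
Hill cross-repression; Olig2 and Nkx2-2 additionally require Shh input
(half-activation 0.3 and 0.5, Hill 2, so Nkx2-2 needs stronger signal).
Levels are expressed relative to each gene's production/degradation scale.
The shipped parameter set is a calibrated default chosen to reproduce the
qualitative biology: from the Pax6/Irx3-high progenitor state under high
Shh it runs the cascade progenitor → transient Olig2 → stable Nkx2-2
(V3 identity); with Shh = 0 the progenitor state persists; and scaling the
four degradation rates alone loses the V3 fate slightly above a twofold
increase (shipped value ≈ 1.96, grid-bracketed), stalling in an Olig2-high
motor-neuron profile because Nkx2-2's reduced steady level can no longer
shut Olig2 down.  Fates are labelled by the maximal terminal species
(ties within 5% are ambiguous, except a Pax6/Irx3 tie, which is the
progenitor state).  Only this qualitative structure — not the exact
threshold — should be read as biology; the ceiling's location depends on
the calibration.

**Repressilator, full (12 variables).**  Per gene *i* (cyclic, the dimer
of gene *i* silences the promoter of gene *i+1*): transcription `α_i π_i`,
mRNA decay `δ_i m_i`, translation `σ_i m_i`, monomer decay `γ_i p_i`,
reversible dimerisation (`k⁺_i p_i²` forward, consuming two monomers per
dimer, `k⁻_i d_i` backward) and reversible promoter binding of the
upstream dimer (`κ⁺ d π`, `κ⁻ (1−π)`), with promoter copy concentration 1.
The default set is symmetric: δ=2.5, γ=1, α=σ=50 (protein scale
p0 = σα/(δγ) = 1000), with dimer and promoter kinetics 200–500× faster
than degradation.

**Reduced (6 variables).**  Treating the distribution of protein between
monomer, free dimer and bound dimer as fast relative to the total protein
pool, and non-dimensionalising mRNA by α/δ and protein by p0, gives

    dm_i/dt = δ_i [ 1/(1 + s_{i−1} p_{i−1}²) − m_i ]
    dp_i/dt = μ_i(p_i) · γ_i (m_i − p_i)

    μ_i(p) = 1 / (1 + 4 r_i p + 4 η_i s_i p/(1 + s_i p²)²)

with composed constants `r_i = (k⁺_i/k⁻_i)·p0_i` (dimer-flux strength —
the inverse sensitivity of the total protein pool to the monomer level),
`s_i = (κ⁺_{i+1}/κ⁻_{i+1})(k⁺_i/k⁻_i)p0_i²` (repression strength) and
`η_i = promoter copies / p0_i` (promoter sequestration, negligible at
p0 = 1000).  `r_i` appears **only** in the prefactor; `s_i` shapes the
base rates.  The derivation is gated numerically: with the default full
parameterisation, the 12- and 6-variable limit cycles agree to a
normalized Fréchet distance of ~7e-4 and 0.06% in period.

**mRNA-QSSA (3 variables).**  Slaving mRNA as well,
`dp_i/dt = μ_i(p_i) γ_i [1/(1 + s_{i−1} p_{i−1}²) − p_i]` — every
intermediate mechanism is the prefactor on a Hill-type base rate.  This
tier does not sustain oscillations on its own (the dimer-mediated
repression has maximal logarithmic gain 2, below the three-stage ring
threshold), so its validity is checked on transient orbits in a regime
with mRNA turnover 100× faster than the effective protein timescale
(agreement ~0.016).  It serves as the analytic representation on which
prefactors, D_σ and mean prefactors are evaluated.

**Reference oscillator.**  The sweep/design reference is the reduced model
with r = (22, 25, 28.5) (strong dimer flux with mild asymmetry),
s = 1e5, η = 1e-3, δ = 2.5, γ = 1; period ≈ 222.  Strong dimer flux
places the system where `4 r p ≫ 1` over most of the orbit, so uniform
r-folds act nearly as scalar prefactors — the regime in which tempo is
genuinely r-controlled.

## Experiments

**Degradation scan.**  25 log-spaced folds in [0.25, 5]; strategies
`degradation_only` (β → μβ) and `production_and_degradation` (a scalar
prefactor).  Time factors are event-time ratios at Nkx2-2 crossing 50% of
the reference terminal level; orbit distances are on max-normalized
300-point open paths.  Joint rescaling gives time factor 1/μ to
~1e-13 and distance ~1e-4 at every fold; degradation-only distances grow
monotonically with |log μ| and the fate flips above the ceiling.

**Perturbation sweep.**  Independent log-uniform folds in [0.2, 5] per
r_i (linear-uniform available), seeded; 200 systems at desk scale (the
statistical conclusions are unchanged from n = 60 upward; larger n is a
flag away).  For each system the analytic predictors are computed first —
relative D_σ and mean prefactor fold along the reference orbit projected
to protein coordinates — then the system is integrated (28 predicted
periods, the prediction coming from the mean prefactor), classified, and
measured.  Orbital distances are Fréchet on reference-normalized,
protein-projected 200-point closed orbits.  Protein projection is
deliberate: a uniform r-fold preserves the protein-space orbit but shifts
the mRNA–protein phase-lag structure, so joint-space distances conflate
tempo mechanism with orbit function; protein coordinates are also the
space where μ_i and D_σ are defined and where gene-expression comparisons
are made.

Perturbed systems start from a state **on the reference cycle** rather
than near the fixed point: a parameter perturbation of a running programme
inherits the running state.  This matters because a few percent of sampled
systems are bistable, with a small near-Hopf cycle around the fixed point
coexisting with the large relaxation cycle; the fixed-point start would
select the small cycle, whose period reflects the Hopf frequency rather
than orbit tempo.

**Tempo design.**  Each design multiplies all r_i by a target fold,
changing their mean at exactly fixed coefficient of variation.  Because
the period is affine in a uniform fold (T(c) = T₀ + c·T₁, the T₀ term
coming from the `1` in μ⁻¹ = 1 + 4rp + …), the period span across designs
is strictly smaller than the fold span; the default folds (1, 2, 4, 8, 16)
span 16× in mean r and deliver ≈15× in period, with every orbit within
0.025 of the reference (preservation threshold 0.05, configurable and
reported with every claim).  The mean-prefactor prediction matches each
achieved period fold to ≈2%.

## What the synthetic conditions do and do not show

All inputs are generated by the built-in models; there is no external
data.  The neural-tube parameterisation is calibrated to qualitative
behaviour, so quantitative outputs tied to it (the ≈2.0 ceiling, time
factors at specific folds) demonstrate the *mechanism*, not measured
biology.  The repressilator conclusions hold in the strong-dimer-flux,
fast-intermediate regime by construction; outside it (weak dimerisation,
slow promoters) the prefactor picture degrades and the reductions fail —
the QSSA tests quantify exactly how much.  Deterministic ODEs mean no
molecular noise, no delays and no cell-to-cell variability; the sweep's
correlations describe this idealised ensemble, not experimental scatter.

## Numerical choices and degenerate inputs

Tolerances as above; non-negativity enforced by clipping at tolerance
level (undershoots beyond 10·atol raise).  Orbit resampling requires ≥8
points and a positive length; consecutive duplicate points are dropped;
all-zero species survive normalization unscaled and are flagged.  Closed
cycles must close to 1e-6 of their length.  Ties in event detection break
toward the earliest time.  Fréchet on empty or dimension-mismatched inputs
raises; zero-velocity states yield NaN heterogeneity and are excluded from
orbital maxima.  Every experiment is a pure function of (parameters, seed,
config); records round-trip CSV at full float precision with a metadata
sidecar (schema version, parameter hash, seed, tool version).

## Known limitations

Stochastic, delayed and spatially coupled dynamics are out of scope, as is
inference of landscapes from experimental data.  The closed-curve Fréchet
search is O(n³) worst case (mitigated by pruning; n = 200–500 in
practice).  `detect_fate` presumes comparable dynamic ranges across
species.  Continuation-based cycle tracking is not implemented, so systems
whose cycle is lost under perturbation are reported non-oscillatory rather
than followed through the bifurcation.
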
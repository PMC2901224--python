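# Methods

This note documents the model implemented by `mscsim`, the numerical choices
behind it, the design decisions taken where the underlying model description
is open, and the limitations a user should keep in mind when reading
simulation output.

## Noise-driven differentiation dynamics

Each cell carries a continuous differentiation state α ∈ [0, 1]
(0 = full stem-cell competency, 1 = completely differentiated).  At Poisson
times with randomization rate R the cell redraws its state from a Gaussian
centred on the current state,

    α′ ~ N(α, σ(α)),   truncated and renormalized on [0, 1],

with a state-dependent amplitude

    σ(α) = σ₀ · (1 − f(pO₂) · α),   f(p) = pⁿ / (kⁿ + pⁿ).

Cells accumulate in low-noise states, so the shape of σ(α) — set by the
environment — decides where the population settles.  Oxygen enters only
through the Hill response `f`; tension is normalized by 20% O₂ (ambient
culture air), so 20% maps to p = 1.0 and 5% to p = 0.25, placing 5% below
the half-saturation constant k = 0.3 and 20% far above it.  At high oxygen
(f ≈ 0.998) differentiated states become nearly frozen (σ(1) ≈ 3.6·10⁻⁴)
and differentiation is quasi-deterministic; at low oxygen (f ≈ 0.29) the
landscape stays shallow and cells keep exchanging between stem
(α < α_s = 0.15) and differentiated (α > α_d = 1 − α_s = 0.85) regions.

Design choices at this layer, each fixed once and exposed in configuration:

* **Noise profile.**  The linear-in-α form above is the simplest profile
  consistent with a fluctuation strength σ₀ in stem states, an amplitude
  decreasing in α, and stronger quieting at higher oxygen.  It is the
  single most consequential modeling choice in the package and is
  implemented as one function (`noise_amplitude`) used by every layer, so a
  different profile can be swapped in at exactly one place.  Residuals
  attributable to this reconstruction are listed under *Limitations*.
* **Randomization rate.**  R = 2.5·10⁻⁴ s⁻¹ (≈ 21.6 events/day).  This
  places single-cell transition times on the day scale, consistent with
  every population-level observable the package computes.
* **Boundary handling.**  The transition kernel is truncated to [0, 1] and
  renormalized (not reflected), keeping it a proper conditional density;
  sampling uses the inverse-CDF of the truncated normal.
* **Proliferation gate.**  Only cells in the open progenitor band
  α_s < α < α_d grow and divide; the boundary values themselves are
  non-proliferative (a measure-zero convention fixed for determinism).
* **Inheritance.**  Daughters inherit the mother's α unchanged at division.

Default parameters (intracellular regulation): σ₀ = 0.15, R = 2.5·10⁻⁴ s⁻¹,
n = 5, k = 0.3, α_s = 0.15.

## Master-equation layer

The α-axis is discretized on M uniform bins (M = 201 by default; a
resolution error is raised below M = 50).  Row i of the per-event transition
matrix P is the truncated Gaussian centred at the bin midpoint integrated
over each bin — differences of Gaussian CDFs, renormalized over [0, 1].  CDF
differences rather than midpoint densities keep rows stochastic even where
σ(α) is far below the bin width (near α = 1 at 20% O₂); such rows are
self-mass dominated by construction, which is the correct discrete limit of
a nearly frozen state.

* **Stationary distribution** (confluent, non-proliferating culture): left
  Perron eigenvector of P, with the fixed-point residual checked to 10⁻¹⁰.
* **Low-density equilibrium** (freely proliferating culture): normalized
  dominant eigenvector of the growth-augmented generator
  G = R(Pᵀ − I) + r·diag(1{α_s < α < α_d}), i.e. Markov randomization plus
  an exponential source at the doubling rate r = 1.9/day on the progenitor
  band.  r = 0 reduces exactly to the stationary distribution.
* **Transition times**: target bins are made absorbing, the expected event
  count to absorption solves (I − Q)n = 1, and ϑ = n/R converts events to
  time.  Headline numbers are unweighted means of ϑ(α) over the initial
  band (α < α_s or α > α_d).  If the linear solve is singular or its
  residual exceeds 10⁻⁶ — the absorbed fraction converges too slowly to
  resolve, as happens for the stem-ward passage when noise is nearly frozen
  — the result is flagged *not computable* instead of reporting a number.
* **Absorbed fractions** over time use uniformization: the absorbing
  skeleton is iterated and mixed over the Poisson(R·t) event count, which
  matches the continuous-time process exactly and preserves monotonicity.

Proliferation is deliberately absent from the plain chain: it describes the
population average of single-cell dynamics.  The growth-augmented
equilibrium is this package's reconstruction of the freely-growing limit.

## Individual cell-based model

Cells are elastic adhesive spheres living on a flat substrate, tracked by
in-plane centre positions (monolayer culture; full 3D is out of scope).
Sphere overlap is computed from the in-plane centre distance.

**Contacts.**  The normal force of the modified Hertz contact at overlap δ is

    F(δ) = (4/3) E* √R_eff δ^{3/2} − ε π R_eff,

Hertz repulsion minus adhesion proportional to the contact area
A(δ) = π R_eff δ, with 1/R_eff = 1/R_i + 1/R_j and
1/E* = (1 − ν_i²)/E_i + (1 − ν_j²)/E_j.  The substrate is a rigid plane
(R_eff = R_i, cell-side elasticity only).  The adhesive equilibrium overlap
has the closed form δ_eq = (3πε√R_eff / 4E*)^{2/3} ≈ 0.9 μm for two default
cells.  Every cell keeps a constant substrate contact at its adhesive
equilibrium; it contributes friction and a constant repulsive load but no
in-plane force.

**Motion.**  Inertia is negligible at cellular Reynolds numbers, so each
step solves the coupled overdamped system

    (γ_cs A_is + Σ_j γ_cc A_ij) dx_i − Σ_j γ_cc A_ij dx_j
        = (Σ_j F_ij n_ij + F_i^stoch) dt

exactly (sparse LU, shared by both coordinates; a diagonal approximation is
not used).  The stochastic force has per-component standard deviation
γ_cs A_is √(2 D_cell/dt), so an isolated cell reproduces the cellular
diffusion coefficient D_cell exactly in the dilute limit (MSD = 4 D t in
two dimensions).

**Growth and division.**  The interphase is a chain of K = 10 exponential
stages of mean τ/K each (τ = 1/r), one volume increment V₀/K per stage, so
the unconstrained growth time is Erlang(K, K/τ): mean τ, CV = 1/√K ≈ 0.32,
approximating a Γ-distributed growth time.  Stage clocks carry remainders
across steps, so the distribution is exact for any step size.  At volume
2V₀ the mother divides instantaneously into two daughters of volume V₀
placed symmetrically at separation R₀ along a uniformly random in-plane
axis; the overlap relaxes mechanically over the following ~15–30 minutes.
Cell volumes never leave [V₀, 2V₀].

**Contact inhibition.**  A cell arrests growth (reversibly) while the sum of
repulsive deformation-force magnitudes over its cell-cell contacts exceeds
F_max = 10⁻⁹ N.  The always-present substrate contact is excluded from this
sum by default: it alone contributes ε_cs π R₀ ≈ 0.94·10⁻⁹ N ≈ F_max, so
including it would arrest every cell at first contact and no colony could
grow; with the cell-cell-only gate, cells with three or more adhesive
contacts arrest — colony interiors stop growing while rims keep expanding,
which is the intended contact-inhibition phenomenology.  The substrate term
can be switched back on (`arrest_includes_substrate`).  A second, optional
pressure gate (mean contact pressure > F_q = 10 N/m², permanent quiescence)
is off by default; with default parameters it would mark every touching
cell quiescent, and which gate produced the published contact-inhibition
behaviour is ambiguous.  `total_deformation_force` itself reports the full
sum including the substrate.

**Time stepping.**  Default mechanics step dt = 30 s; the protocol pipelines
use dt = 120 s, which resolves post-division relaxation (~10 steps per
relaxation time) at a quarter of the cost.  α-events are Poisson-thinned
onto the mechanics clock (R·dt ≈ 0.03 events/step).  Any per-step
displacement above R₀/2 aborts the run with an instability diagnostic.
Runs are bit-reproducible given the seed: a single generator drives all
stochastic draws in a fixed order.

## Protocols and the synthetic mother population

`generate_mother_population` samples α from a model equilibrium (low-density
or stationary), seeds cells sparsely, and assigns proliferative cells a
uniformly random growth stage with the matching volume (an unsynchronized
culture at the moment of sorting).  This generator *is* the study
population: it emulates an ideal low-density culture in internal
equilibrium.  It does not emulate FACS noise (sorting is exact in α),
marker-to-α calibration, cell death, aggregation in 3D, or spatial oxygen
gradients — conclusions from these simulations carry over to real cultures
only insofar as those features are negligible.

**Transition times.**  A cohort of independent α-walkers (default 10⁵) is
initialized uniformly on [0, 1]; each carries its own exponential event
clock; first arrivals in each region are recorded, censored at the time
budget.  Walker means per initial-α bin agree with the master-equation
ϑ(α) within Monte-Carlo error (tested at 3 standard errors per bin).

**Regeneration.**  Founders are sampled from the low-density equilibrium
restricted to the sort region (exact sorting of an arbitrarily large
mother), each seeding an isolated clone — clones are placed 2 mm apart, so
"secondary cultures of separated cells" is realized within a single
simulation.  The pooled 20-bin α-histogram is recorded every 0.1 day.  The
regeneration time is the first recorded time at which the total-variation
distance to the low-density equilibrium falls below a tolerance.  The
tolerance is a *single global calibration*: the low-oxygen condition
regenerates in about one day, so the tolerance is read off the pooled 5%
series at day 1 and then held fixed for every other condition.  At full
scale (hundreds of founders) this reads ≈ 0.10; at the scaled 50-founder
analysis the finite-sample TV floor of small pooled histograms (≈ 0.11 at
~100 cells) raises it to ≈ 0.19.  Series that never cross the tolerance
within the observation window report the window end as a lower bound
(censoring, stated explicitly by the API).  Quiescent founders are those
whose clone never divided.

**Stem-pool composition.**  Every founder (default 400; the acceptance
analysis uses 200) expands as an isolated clone for 5 days; cells ending in
the stem region (0 < α < α_s) are attributed to their clone founder's α at
time zero, on 10 uniform founder bins.  Total cell count is capped at 10⁴
with a warning; divisions are suppressed beyond the cap.

**Problem sizes.**  The bundled acceptance analysis runs the regeneration
protocol at 50 founders per sort and the stem-pool protocol at 200
founders, each over 3 replicate seeds, with dt = 120 s and M = 201 master-
equation bins — sizes chosen so the full analysis completes in minutes on a
single core while keeping the Monte-Carlo error of each headline number
within its quoted tolerance band.

## Numerical details

* Dense eigenproblems (M ≤ a few hundred) use LAPACK via `numpy.linalg.eig`;
  the stationary solve verifies |w − 1| < 10⁻⁸ and a fixed-point residual
  < 10⁻¹⁰, raising a diagnostic error otherwise.
* Truncated-normal sampling uses inverse-CDF with `ndtr`/`ndtri`; σ = 0 is
  the degenerate kernel (state returned unchanged).
* The friction system is assembled sparse (≈ 7 non-zeros per row) and
  factorized once per step; x and y displacements share the factorization.
* Neighbour search uses a k-d tree rebuilt each step with query radius
  2·max(R_i); pairs are filtered to positive overlap.
* Internal units are SI (m, s, N, Pa); days and percentages appear only at
  the I/O boundary.

## Limitations

* The linear noise profile is a reconstruction.  Its known residuals, all
  computed by the package's own analysis: the confluent differentiated
  fraction at 20% O₂ reads ≈ 100% (reference value ≈ 90%); the low-density
  fraction reads ≈ 17% (reference ≈ 25%); the stem-pool stem-founder share
  reads ≈ 7% at 5% O₂ (reference ≈ 11%).  All shifts point the same way —
  the reconstructed profile quiets high-α states slightly too strongly —
  and would be absorbed by a profile with a softer high-α plateau, at the
  cost of an extra shape parameter with nothing to pin it.
* The stem-pool share at 20% O₂ is estimated from small pools (~200 cells
  per seed); its 3-seed average carries a standard error of about one
  percentage point on a ~4% value.
* No cell death, no lineage-specification state, no oxygen consumption or
  gradients (pO₂ is a global scalar), no mechano-feedback of substrate
  elasticity on the noise amplitude, no 3D aggregation.
* Which of the two published contact-inhibition thresholds (force sum vs
  pressure) produced the published behaviour is ambiguous; both are
  implemented, the force-sum gate is active by default (see above).
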
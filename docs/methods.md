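# Methods

This note documents the models, numerical choices and limitations behind
`chexflux`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Exchange networks

A network is a set of named kinetic states connected by first-order rate
constants; bimolecular binding steps enter as pseudo-first-order
constants at fixed free-ligand concentration (`k_UB = k_on·[L]`), which
is appropriate for equilibrium samples with the binder in modest excess.
The rate matrix uses the convention `dp/dt = K p` with `K[j,i] = k_ij`
and conserving columns.

All models in scope are equilibrium models, so **detailed balance is an
error, not a warning**: populations (given or derived from the null
space of `K`) must satisfy `p_i·k_ij = p_j·k_ji` on every connected pair
to a relative 1e-6. Two parameterizations guarantee this by
construction:

* *rates*: free one-way rates on a tree topology; populations follow
  from the stationary distribution.
* *kex_pop*: free per-edge exchange rates `k_ex = k_fwd + k_rev` plus
  populations; one-way rates are `k_ij = k_ex·p_j/(p_i+p_j)`. This is
  the natural frame for CEST fits (where `k_ex` per edge is the
  well-determined quantity) and remains consistent on cyclic topologies
  such as the four-state N/U/B1/B2 network.

Populations are fractions summing to 1 internally; percentages appear
only in reporting helpers. An explicit helper converts the measured
ratios N:U (from the first zz plane) and U:B (= k_BU/k_UB) into
three-state percentages.

The IF pathway's transient encounter complex (an N-like bound
intermediate) is never resolved by these experiments; following standard
practice the three-state N→NK→UK leg is collapsed into a single
observable N→B step, and no NK-resolved model is provided.

## Bloch-McConnell propagation

Each state contributes a (Mx, My, Mz) block with offset precession
`Ω_i = 2π·ν₀(MHz)·(δ_i − δ_rf)` rad/s, x-phase B₁ nutation
`ω₁ = 2π·B₁`, and relaxation −R₂/−R₂/−R₁ on the diagonal; chemical
exchange couples corresponding components across states. Propagation is
a dense scaling-and-squaring matrix exponential (≤ 6 states, ≤ 18
dimensions; eigendecomposition appears only in test oracles). An
adaptive-ODE comparison on randomized 2–4-state systems bounds the
propagation error at ≤ 1e-8 max-abs.

Deliberate modelling choices:

* **Homogeneous equation (no +R₁M₀ recovery term).** The observable is
  referenced to a T_EX = 0 plane, so a far off-resonance profile decays
  as `exp(−R₁·T_EX)` rather than returning to 1, and fits must model
  that decay — there is no baseline re-normalization.
* **Single ideal B₁ along x.** B₁ inhomogeneity and calibration error
  are not modelled; minor-dip widths are mildly sensitive to this.
* **Perfect heteronuclear decoupling** during the exchange period:
  scalar couplings are omitted.
* **Shared relaxation per probe.** One apparent R₁ (and R₂) per
  resonance is the default, matching how R₁ is measured (single
  exponential fit of an inversion-comparison experiment); per-state
  overrides are available, e.g. for a bound state in a slow-tumbling
  complex.
* **zz-exchange** evolves longitudinal order only: the propagator is
  `expm((K − diag(R₁))·t)`, initial conditions are the equilibrium
  populations, diagonal peaks decay from `p_o` and cross peaks build
  from zero. Reading populations off the first (25 ms) plane is exposed
  as an explicit helper so its small-mixing-time bias can be quantified
  (≈ a few percent for the default truth scenario).

Default spectrometer frequency is 800 MHz (the field at which such
relaxation data are typically collected); ppm↔rad/s conversion uses
`2π·ν₀(MHz)·Δδ(ppm)`.

## Fitting

The objective is weighted least squares with per-point experimental
sigmas; reduced χ² surfaces are only meaningful with weighted residuals.
Optimization is lmfit's trust-region least-squares driver with a
Latin-hypercube multi-start (default 10 starts, log-spaced over positive
bounds because rates span decades; the first start is always the user's
initial values; ties broken by start order, so results are deterministic
given a seed). Convergence tolerances are 1e-10 on the relative χ²
change. Populations enter through a softmax of log-weights with one
weight fixed, so the simplex constraint can never be violated and
poorly-determined populations cannot pin at a boundary.

Identifiability is diagnosed with 1D reduced-χ² profiles: the target
parameter is fixed at each grid value and all others re-optimized from
the best fit. A surface whose total variation is below 0.2 in reduced χ²
is flagged *shallow* — the typical signature of populations in
CEST-only fits, where exchange rates carry the information.

Uncertainties come from a point-level bootstrap: points are resampled
with replacement independently within each profile, preserving each
profile's point count, and every replicate is refit starting from the
original best fit (single start — fast, and stable within the original
basin). The same point-level scheme is applied to zz datasets, treating
the whole dataset as one profile. Replicates whose fit fails are dropped
and counted; more than 20% failures aborts. The conventional production
replicate count is 1000; tests and examples use 60–200 for speed.

## Flux partitioning

Pathway fluxes are reported in population-fraction·s⁻¹ (total protein
concentration normalizes out of pathway comparisons; multiply by the
total concentration for molar flux):

* CS direct: `F(U→UK) = k_UB·p_U`;
* CS via N: `F(N→U→UK) = min(k_NU·p_N, k_UB·p_U)` — the rate-limiting
  step bounds a multi-step pathway, and when N↔U interconversion is very
  slow this pathway is negligible next to the direct one;
* IF: `F(N→NK→UK) = k_NB·p_N` with the unresolved intermediate folded
  into the single N→B step.

`Θ = F_CS/F_IF`; the CEST route multiplies the exchange-rate ratio by
the population factor Ξ. Rates known only as bounds propagate their
flags: an upper-bound `k_NB` makes Θ a lower bound, and the report
carries explicit "upper"/"lower" markers rather than silently mixing
exact and bounded numbers.

When a cross-peak is never observed, the largest exchange rate
consistent with that absence is found by bisection (relative tolerance
1e-4): the forward rate is scanned, the reverse rate follows from
detailed balance, the two-state zz cross-peak is simulated over the
actual mixing-time grid with the measured R₁ values, and the bound is
the largest rate whose maximal cross-peak stays at or below the noise
floor. Intensities are scaled so that one population unit corresponds to
`diag_intensity_scale` at t = 0; zero noise returns 0 and a noise floor
unreachable at any rate returns +inf with the unbounded sentinel.

## Synthetic data

Generators add i.i.d. Gaussian noise on intensity (ratios) — the
appropriate model for thermal NMR noise and the assumption behind χ²
fitting — over the standard acquisition schedules: 40 CEST offsets
evenly spanning 1.0 to −0.2 ppm (the Ile methyl ¹H region), B₁ =
20.3 Hz, T_EX = 150 ms, 800 MHz; and 13 zz mixing times from 25 to
800 ms. Everything is bit-reproducible given the scenario seed. The
default noise SD is 1% of the reference intensity, chosen so bootstrap
errors are comparable in relative size to typical reported rate
uncertainties; recovery studies at 2% noise are used where a more
conservative envelope is wanted.

Two truth scenarios ship with the package:

* **R17_zz** — two-state U⇌B binding of a marginally stable
  three-helix-bundle client: k_UB = 0.8 s⁻¹ (pseudo-first-order at
  500 μM free chaperone, i.e. k_on = 1600 M⁻¹s⁻¹), k_BU = 2.7 s⁻¹,
  shared methyl ¹H R₁ = 2.0 s⁻¹.
* **SH3_cest4** — four-state N/U/B1/B2 network for a slow-folding SH3
  client with two bound conformations: populations (0.44, 0.44, 0.08,
  0.04) with p_N = p_U so Ξ = 1 exactly at truth; per-edge exchange
  rates (k_ex,NU = 1.0, k_ex,UB1 = 3.0, k_ex,NB1 = 0.75, k_ex,UB2 =
  4.2, k_ex,NB2 = 0.2 s⁻¹) giving per-arm flux ratios Θ₁ = 4 and
  Θ₂ = 21; shifts 0.55/0.70/0.20/0.35 ppm, R₁ = 1.5 s⁻¹, R₂ = 25 s⁻¹.
  All rates sit in the slow-exchange regime the experiments address.

NOE contamination — the main artifact of ¹H CEST — is emulated as
symmetric longitudinal cross-relaxation to a non-exchanging pseudo-spin
at the partner's shift, coupled to the target state's Mz channel only.
This reproduces the phenomenology (a spurious minor dip at the partner
shift whose depth grows with T_EX, absorbable by a naive exchange fit
with biased rates) without simulating full dipolar spin dynamics.

What passing tests on synthetic data do **not** show about real data:
lineshape/peak-fitting errors upstream of the intensity tables,
correlated or non-Gaussian noise, B₁ miscalibration, partial
decoupling, scalar-coupling evolution, and sub-ensemble averaging within
the N and U states are all outside the generator, so recovery results
here bound only the statistical (not systematic) error of the pipeline.

## Problem sizes and regime choices

The parameter-recovery studies use the schedules above at their native
sizes (52-point zz datasets over 100 noise realizations; 4×40-point CEST
datasets over 20 realizations with a 60-replicate Ξ bootstrap), which
the package completes in about a minute.

For the fast/slow interconversion regime demonstration the N and U
reporter shifts are taken nearly degenerate (0.55/0.56 ppm). Rationale:
at k_ex,NU = 1000 s⁻¹ the N and U resonances of a real reporter with a
distinct shift difference are themselves exchange-averaged toward
coalescence, and residual differential direct-saturation on the major
dip flanks (of order saturation-rate/k_ex, a few 1e-3) is a lineshape
effect, not the mechanistic observable. With near-degenerate reporter
shifts the comparison isolates the feature of interest — the
bound-state minor dip, present in both N and U profiles under fast
interconversion and in the U profile alone under slow interconversion —
and the profiles agree to RMS < 1e-3 in the fast regime.

## Known limitations

* Networks beyond ~6 states are untested and the dense propagator will
  slow down; non-equilibrium (time-varying population) kinetics are out
  of scope by design.
* The optimizer is local with multi-start; pathological multimodal
  objectives may need more starts or tighter bounds.
* Covariance-based standard errors from the optimizer are reported but
  secondary; the bootstrap is the intended uncertainty estimate.
* Raw spectrum processing, lineshape fitting, CPMG/R1ρ dispersion and
  spin-state-selective CEST variants are not implemented; the pipeline
  starts from extracted peak intensities.
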
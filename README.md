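# chexflux

Quantifying whether a chaperone (or any binder) selects a pre-existing
ligand conformation (**conformational selection, CS**) or remodels the
ligand after binding (**induced fit, IF**) from solution-NMR chemical
exchange data.

`chexflux` is aimed at NMR spectroscopists and kineticists working on
slowly interconverting protein states — e.g. a marginally stable client
protein whose native (*N*) and unfolded (*U*) conformers are both
populated at equilibrium and whose unfolded form is captured by an Hsp70
chaperone into a bound state (*UK*). It provides, as a tested library
plus a small CLI:

* **Bloch–McConnell simulation** of the two observables that resolve
  such networks: ¹H **CEST** intensity-ratio profiles (weak B₁
  saturation stepped across the spectrum during a fixed exchange period)
  and **zz-exchange** diagonal/cross-peak build-up and decay curves;
* **global weighted least-squares fitting** of those observables to
  multi-state exchange models, with 1D reduced-χ² surfaces for
  identifiability and point-level **bootstrap** uncertainties;
* **flux partitioning** of the fitted kinetics into CS and IF pathway
  fluxes, including upper bounds for pathways whose cross-peaks never
  rise above the noise;
* a **synthetic-data module** that generates CEST/zz datasets with known
  truth, the standard acquisition schedules, Gaussian noise, and
  optional NOE-contamination dips, so the entire pipeline is testable
  without experimental spectra.

## The model

Exchange among *n* states with first-order rates `k_ij` (bimolecular
binding steps folded in as pseudo-first-order constants, `k_UB =
k_on·[L]`) is propagated through the Bloch–McConnell equations: each
state carries a magnetization vector (Mx, My, Mz) subject to offset
precession Ω, B₁ nutation ω₁, relaxation (R₁, R₂) and exchange, and the
profile/curve is a matrix exponential of the resulting 3n×3n (CEST) or
n×n (zz, longitudinal-only) evolution matrix.

The mechanistic readout is the flux ratio

    Θ = F_CS / F_IF = (k_UB / k_NB) · (p_U / p_N)

for one-way rates (zz route). CEST fits determine per-edge exchange
rates `k_ex = k_fwd + k_rev` instead; detailed balance then gives

    Θ = (k_ex,UB / k_ex,NB) · Ξ,   Ξ = p_U(p_N + p_B) / [p_N(p_U + p_B)]

so that for near-equal native and unfolded populations (Ξ ≈ 1) Θ is
simply the ratio of exchange rates. When the IF-pathway rate is only an
upper bound (no visible *N*–*B* cross-peak), Θ is reported as a lower
bound.

## Worked example

Simulate a noisy two-state (U ⇌ B) zz-exchange experiment at the
standard schedule (13 mixing times, 25–800 ms; truth k_UB = 0.8 s⁻¹,
k_BU = 2.7 s⁻¹), refit it, bootstrap the uncertainties and partition the
flux:

```python
from chexflux import (
    generate_zz_dataset, r17_zz_scenario, fit_model,
    ParameterSpec, NetworkSpec, bootstrap, flux_report,
)

data = generate_zz_dataset(r17_zz_scenario(noise_sd=0.01, seed=7))

spec = NetworkSpec(states=("U", "B"), edges=(("U", "B"),),
                   parameterization="rates", ligand_conc=500e-6)
params = (
    ParameterSpec("k_U_B", 0.3, 0.01, 50.0),
    ParameterSpec("k_B_U", 1.0, 0.01, 50.0),
    ParameterSpec("r1_Met26", 2.0, vary=False),
)
fit = fit_model([data], spec, params, n_starts=5, seed=0)
print(f"k_UB = {fit.params['k_U_B']:.3f} /s   k_BU = {fit.params['k_B_U']:.3f} /s   "
      f"reduced chi2 = {fit.redchi:.2f}")

boot = bootstrap([data], spec, params, n_replicates=200, seed=1,
                 start_from=fit.params)
print(f"bootstrap: k_UB = {boot.mean['k_U_B']:.3f} +/- {boot.sd['k_U_B']:.3f} /s, "
      f"k_BU = {boot.mean['k_B_U']:.3f} +/- {boot.sd['k_B_U']:.3f} /s")

report = flux_report(
    rates={"k_UB": fit.params["k_U_B"], "k_NB": 0.004, "k_NU": 0.005},
    populations={"N": 0.58, "U": 0.33, "B": 0.09},
    ligand_conc=500e-6,
    bounds={"k_NB": "upper", "k_NU": "upper"},
)
print(report.summary())
```

Output (this seed):

```
k_UB = 0.734 /s   k_BU = 2.471 /s   reduced chi2 = 0.86
bootstrap: k_UB = 0.734 +/- 0.035 /s, k_BU = 2.470 +/- 0.133 /s
Flux report
-----------
  U->UK                        0.2424 fraction/s
  N->U->UK (upper bound)       0.0029 fraction/s
  N->NK->UK (upper bound)      0.00232 fraction/s
  Theta (F_CS/F_IF, zz) > 104.5
  k_on = 1469 M^-1 s^-1
```

Reading the numbers: the direct CS pathway (U→UK, 0.24 population
fractions per second) dominates both competing pathways by two orders of
magnitude, Θ > 100 says at least 99% of the binding flux goes through
conformational selection, and dividing the pseudo-first-order on-rate by
the 500 μM free-chaperone concentration gives the bimolecular
k_on ≈ 1.5 × 10³ M⁻¹s⁻¹. (The fitted rates scatter around the truth
within their bootstrap errors for any given noise realization.)

The same steps are available from the shell:

```bash
chexflux simulate  --config config.yaml --out sim/
chexflux fit       --config config.yaml --out fit/  sim/*.tsv
chexflux profile   --config config.yaml --out prof/ --param k_U_B --grid 0.4:1.2:17 sim/*.tsv
chexflux bootstrap --config config.yaml --out boot/ --n 1000 sim/*.tsv
chexflux flux      --config config.yaml --out flux/
```

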
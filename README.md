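# coldamyl

Biophysical analysis toolkit for cold-active GH13 amylases — the kind of
psychrophilic enzymes isolated from cold, alkaline environments that stay
catalytically active far below the temperature at which their structure
melts. The package reimplements, as tested library code with a CLI, the
quantitative analyses used to characterize such enzymes:

* **Activity assays** — conversion of reducing-end (MBTH) absorbance
  readings to velocities, condition profiles (temperature, pH, NaCl,
  CaCl₂), and the two-site Ca²⁺ activation/inhibition model

  v([Ca]) = (V_apo·K_1 + V_1·[Ca] + V_2·[Ca]²/K_2) / (K_1 + [Ca] + [Ca]²/K_2),

  the bell-shaped dependence in which a first, activating Ca²⁺ site
  (dissociation constant K_1) raises the velocity and a weaker second site
  (K_2) suppresses it.
* **Thermal unfolding** — a global three-state N ⇌ I ⇌ D fit of CD melt
  matrices (shared t_m1, t_m2, ΔH_1, ΔH_2 across 210–230 nm wavelengths,
  per-wavelength linear state baselines) and a two-state fit of DSF
  350/330 nm fluorescence-ratio curves, both with Boltzmann weights
  exp(±ΔH(1 − t/t_m)/(R·t)); plus a reversibility (hysteresis) score for
  heat/cool scan pairs.
* **SAXS** — Guinier regression, a regularized indirect Fourier transform
  giving p(r), D_max, R_g and I(0), absolute-scale molecular weight
  M = I(0)·N_A/(c·Δρ_m²), Debye-equation theoretical curves of atomic/bead
  models with Gaussian form factors, two-fold (P2) symmetric dimer
  construction and optimization, and non-negative monomer/dimer mixture
  fits on absolute scale.
* **SEC** — log₁₀(MW) vs elution-volume calibration and Gaussian (or
  exponentially-modified-Gaussian) peak deconvolution with area fractions.
* **MD flexibility** — Kabsch superposition, RMSD, replicate-combined
  per-residue RMSF, radius of gyration, Shrake–Rupley SASA, hydrogen-bond
  and salt-bridge counts, sequence-aligned psychrophile-vs-homolog
  flexibility classification at a ±0.5 Å RMSF threshold with domain
  attribution, and backbone PCA (essential dynamics).
* **Synthetic data** — seeded generators for every input class, each
  returning its ground truth, so the full pipeline is testable without any
  external data.

## Worked example

Fit the Ca²⁺ response of a synthetic enzyme measured on the assay grid
(0–20 mM CaCl₂) with 2 units of added noise:

```python
from coldamyl.activity import CaResponseParams, fit_ca_model
from coldamyl.synth import NoiseSpec, gen_ca_response

truth = CaResponseParams(vmax_apo=10.0, vmax_l1=100.0, vmax_l2=20.0,
                         kl1=0.5, kl2=8.0)
prof, _ = gen_ca_response(truth, noise=NoiseSpec(scale=2.0, seed=7))
fit = fit_ca_model(prof.condition_values, prof.velocities, seed=7)
print(f"vmax_apo = {fit.vmax_apo:.2f}  vmax_l1 = {fit.vmax_l1:.2f}  "
      f"vmax_l2 = {fit.vmax_l2:.2f}")
print(f"kl1 = {fit.kl1:.3f} mM  kl2 = {fit.kl2:.2f} mM  "
      f"(reduced chi2 = {fit.chi2:.2f})")
```

prints

```
vmax_apo = 10.15  vmax_l1 = 96.69  vmax_l2 = 25.22
kl1 = 0.509 mM  kl2 = 7.98 mM  (reduced chi2 = 0.61)
```

i.e. the activating site's dissociation constant (0.5 mM) is recovered to
2% under noise, while the saturated velocities — which the 0–20 mM grid
only brackets — carry larger uncertainty, exactly the behaviour one sees
fitting real bell-shaped Ca²⁺ profiles. The same round trip for a DSF melt
generated at t_m = 61.97 °C returns `tm = 61.99 C`.

From the shell, the equivalent is:

```bash
coldamyl synth generate ca --out demo/
coldamyl activity fit-ca --input demo/ca_profile.csv --out demo/params.json
coldamyl run --seed 1 --outdir demo_run/    # full synthesize-fit-report pipeline
```

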
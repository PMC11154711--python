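# foldscape

Quantitative analysis of protein stability and amyloid aggregation, built
around the biophysical toolkit used to characterize an aggregation-prone
~31 kDa deubiquitinase and its stabilizing point mutants:

- **FCS sizing** — fit autocorrelation curves G(τ) with the 3D-diffusion
  model for a Gaussian confocal volume,
  G(τ) = ⟨N⟩⁻¹ (1 + τ/τ_D)⁻¹ (1 + (r/l)² τ/τ_D)⁻¹ᐟ², calibrate the
  observation volume against rhodamine-6G (r = √(4 D_ref τ_D)), and convert
  diffusion times to hydrodynamic radii via D = r²/4τ_D and
  R_h = kT/6πηD. Polydisperse samples use the Gaussian Distribution Model
  (GDM): per-component amplitudes a_i(τ_Di) = A_i exp[−((ln τ_Di − ln τ_p)/b)²]
  summed over a log-spaced diffusion-time grid, yielding amplitude-weighted
  R_h distributions.
- **Two-state unfolding thermodynamics** — mean-residue ellipticity
  [θ] = θ·100·M/(c·l·n), fraction-unfolded conversion, linear extrapolation
  method ΔG_D(C) = ΔG_D(H₂O) + m·C (midpoint [den]₅₀% = −ΔG/m), the
  two-state *scaled* van't Hoff DSC model
  C_p,exc = s·ΔH²/(RT²)·K/(1+K)², refolding efficiency, and
  entropy–enthalpy compensation regression.
- **ThT aggregation kinetics** — four-parameter logistic fits
  F(t) = F₀ + A/(1+e^{−k(t−t₅₀)}), lag time t₅₀ − 2/k
  (tangent-at-inflection), aggregation index (pellet/supernatant), and
  seeded-vs-unseeded comparisons.
- **Trajectory post-processing** — Kabsch superposition, RMSD/RMSF,
  Cartesian-covariance PCA of Cα coordinates, porcupine displacement
  fields, and free-energy landscapes by Boltzmann inversion,
  G = −kT ln(P/P_max), over (PC1, PC2) histograms.

A first-class synthetic-data module generates every input modality with
known ground truth (correlation decays, sigmoidal unfolding transitions,
van't Hoff endotherms, logistic ThT traces, Gaussian-mode multi-basin Cα
trajectories), so each fitting stage is validated by parameter recovery —
no instrument data required.

## Worked example

Calibrate from a reference-dye curve, then size a monomer:

```python
import numpy as np
from foldscape import fcs
from foldscape.synthetic import NoiseSpec, SpeciesSpec, gen_fcs_curve

lags = np.logspace(-6.5, 0, 250)
ref = gen_fcs_curve([SpeciesSpec(35e-6, 1.0)], 5.0, 5.0, lags,
                    NoiseSpec(model="none", sigma=0.0))
cal = fcs.calibrate(ref, d_ref=4.14e-10, aspect_ratio=5.0)

tau = fcs.rh_to_tau_d(1.95e-9, cal)          # 1.95 nm particle
curve = gen_fcs_curve([SpeciesSpec(tau, 1.0)], 10.0, 5.0, lags,
                      NoiseSpec(sigma=0.01, seed=1))
fit = fcs.fit_single_3d(curve, aspect_ratio=5.0)
d = fcs.diffusion_coefficient(fit.tau_d, cal)
print(f"r = {cal.lateral_radius*1e9:.1f} nm, "
      f"Rh = {fcs.stokes_einstein_rh(d)*1e9:.2f} nm")
```

prints

```
r = 240.7 nm, Rh = 1.94 nm
```

the calibrated lateral radius of the confocal volume (within 3% of the
instrument's printed 235 nm) and the recovered hydrodynamic radius of the
1.95 nm particle. The same chain runs from the shell:

```sh
foldscape simulate --kind dsc --seed 3 --out .
foldscape fit-dsc dsc.tsv
# Tm = 56.20 C, dH = 119.7 kcal/mol, dG(25 C) = 11.34 kcal/mol
```

## Analysis scripts

The `analysis/` directory holds the narrative drivers, each writing a table
under `results/`:

| script | what it computes |
| --- | --- |
| `01_chemical_unfolding.py` | ΔG_D(H₂O) for wild type (3.02 kcal/mol) and the stabilized variant (6.98), ΔΔG = 3.96; midpoint recovery over 50 noisy replicates |
| `02_dsc_thermal_stability.py` | Tm recovery (56.2 °C) and entropy–enthalpy compensation across a six-variant panel (r² > 0.999) |
| `03_fcs_sizing.py` | calibration, monomer R_h (1.95 nm), dual-GDM oligomer sizing (14.02 nm ≈ 7 monomer units) |
| `04_tht_kinetics.py` | t₅₀ ordering of an aggregation panel, flat-trace detection, 2 h seeding lag shift |
| `05_md_landscape.py` | two-basin vs single-basin free-energy landscapes, 0.85 kT basin gap, porcupine field |

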
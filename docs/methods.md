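# Methods

This note records the models implemented, the numerical choices behind the
fits, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying experimental conventions were
open.

## FCS models and sizing chain

The single-component autocorrelation for free 3D diffusion through a
Gaussian observation volume is

    G(τ) = (1/⟨N⟩) (1 + τ/τ_D)^−1 (1 + (r/l)² τ/τ_D)^−1/2

with mean occupancy ⟨N⟩, diffusion time τ_D, lateral radius r, and axial
half-length l. The aspect ratio l/r defaults to 5, a typical confocal
geometry; it is fixed during sample fits (calibrated once from the
reference dye) because refitting it trades off against τ_D and ⟨N⟩.

Calibration uses a reference dye of known diffusion coefficient
(rhodamine-6G, D = 4.14×10⁻⁶ cm²/s in water): r = √(4·D_ref·τ_D,ref) holds
exactly in the returned calibration, and V_eff = π^{3/2} r² l is recorded
as metadata. The printed instrument values (τ_D ≈ 35 μs, r = 235 nm,
V_eff = 0.56 fl) are mutually consistent only at the few-percent level —
35 μs implies 240.7 nm, and 0.56 fl implies l/r ≈ 7.75 rather than 5 — so
the package treats r as *derived* from the identity and regards the printed
values as rounded reports. Sizing follows D = r²/(4τ_D) and the
Stokes–Einstein relation R_h = kT/(6πηD) with defaults T = 298.15 K and
η = 0.89×10⁻³ Pa·s (water at 25 °C); both are overridable per call.

### Gaussian Distribution Model

Polydisperse samples are modelled as one or two components whose
amplitudes follow a Gaussian in ln τ_D with peak τ_p and width b. Each
component is evaluated on 60 log-spaced grid points spanning ±3 ln-widths
around τ_p with the Gaussian weights renormalized to sum to the component
amplitude; a width at or below 0.01 collapses to a single grid point, which
makes the b → 0 limit reproduce the single-component model to machine
precision. Fits are bounded weighted least squares (scipy
`least_squares`) with a 3-point multi-start in the slow component's peak
position; dual fits whose peaks land within 0.5 ln-units are flagged
degenerate.

**Shared width.** By default the dual fit ties the ln-width b between the
two components. With realistic noise the minority slow component's width is
essentially unidentifiable on its own: the optimizer trades b against τ_p
(a collapsed, shifted delta fits equally well), which biases the recovered
slow-component size upward by ~8%. The majority component pins the shared
width and suppresses this degeneracy; `shared_width=False` restores fully
independent components.

**Radius distributions.** Every grid diffusion time converts through the
calibration and Stokes–Einstein to R_h, and a component's "average R_h" is
the amplitude-weighted arithmetic mean over its grid. Because the grid is
symmetric in ln τ, that mean exceeds the point conversion of τ_p by the
lognormal factor exp(b²/4) — +2.3% at b = 0.3 — which is an estimator
convention, not a fit error; it is recorded in the distribution object.
Oligomer size in monomer units is the plain radius ratio R_h/R_h,monomer
(linear stacking), the only convention consistent with the reported
14.02/1.95 ≈ 7 and 8.94/1.95 ≈ 4.6 equivalences.

## Two-state unfolding thermodynamics

Chemical denaturation follows the linear extrapolation method:
ΔG_D(C) = ΔG_D(H₂O) + m·C with m stored negative as reported, so the
midpoint obeys [den]₅₀% = −ΔG_D(H₂O)/m and the fraction unfolded is
f_U = K/(1+K), K = exp(−ΔG/RT), with R = 1.987×10⁻³ kcal/(mol·K).
Signal-space fits estimate linear native and unfolded baselines *jointly*
with (ΔG, m) — baseline treatment is otherwise a hidden degree of freedom —
while fraction-space fits fix the baselines at 0 and 1 and require the
transition to be covered on both sides (min f_U < 0.2, max > 0.8).
Fraction-unfolded conversion clips to [−0.05, 1.05] before winsorizing to
[0, 1], tolerating baseline noise without biasing the transition region.

Mean-residue ellipticity uses [θ] = θ·100·M/(c·l·n) with θ in degrees, c in
mg/ml and l in cm, matching the reported convention. Unit audit: with the
more common convention (θ in mdeg, c in g/L) the same expression differs by
a constant factor; since refolding efficiency and fraction unfolded are
*ratios* of MRE values, the factor cancels everywhere it matters.

DSC endotherms use the two-state van't Hoff excess heat capacity

    Cp_exc(T) = s · ΔH²/(RT²) · K/(1+K)²,  K = exp[−(ΔH/R)(1/T − 1/Tm)]

with a free scale factor s (our reading of the vendor's "two-state
(scaled)" model) and a linear baseline. Derived quantities: ΔS_m = ΔH/Tm
and ΔG(T_ref) = ΔH(1 − T_ref/Tm) with ΔCp = 0 by default (T_ref defaults
to 298.15 K; a Gibbs–Helmholtz ΔCp term is available in `dg_thermal` but
off by default, since the extraction convention behind reported ΔG values
is undocumented). Initialization reads Tm from the peak position and ΔH
from the peak height via Cp_max = ΔH²/(4RTm²).

Entropy–enthalpy compensation is ordinary least squares of ΔH on ΔS across
variants; the slope has units of kelvin (the compensation temperature).

## ThT kinetics

Traces are fitted with a four-parameter logistic — the generic "sigmoidal
fit" of plate-reader software — chosen because the lag time has the closed
form of the tangent-at-inflection convention, lag = t₅₀ − 2/k, the standard
amyloid-kinetics definition (no lag estimator accompanies the reported
values, so the ≈2 h seeding shift is treated as a generator-level condition
rather than a fitting target). Traces whose rise is below 5× the baseline noise
are reported as "no detectable aggregation" instead of being force-fitted;
traces that end before reaching 98% of the fitted plateau carry a
`plateau_censored` flag. Replicates are fitted independently and
summarized as mean ± sd, preserving between-replicate variance.

## Trajectory analysis

Superposition is the Kabsch algorithm with the proper-rotation correction
(det = +1). PCA and RMSF share one alignment protocol — two passes of
superposition onto an iteratively refined mean — so the trace identity
Σ RMSF² = Σ eigenvalues holds to 1e−6 relative. The covariance is over
Cartesian Cα coordinates without mass weighting (uniform Cα masses);
eigenvectors follow the sign convention that the largest-magnitude element
is positive. Free-energy landscapes histogram (PC1, PC2) on a 50×50 grid by
default and apply G = −kT ln(P/P_max); empty bins are *masked*, not imputed
(−kT ln 0 is undefined and any finite imputation distorts barrier heights),
and the occupied-bin minimum is exactly 0 by construction. Energies are in
kT by default (0.5925 kcal/mol at 298.15 K via the `units` switch).
Porcupine fields are the per-atom difference between structures
reconstructed at the maximum and minimum observed projections of one
component.

## Synthetic data: what it does and does not emulate

Each generator evaluates the same closed-form model its fitting counterpart
assumes, plus multiplicative Gaussian noise (relative σ, default 0.01 —
FCS and plate-reader noise scales with signal; the instrument noise
magnitude is not reported, so 1% is a package choice). Identical seeds give
bit-identical output. FCS curves carry their known per-point error
σ·G(τ) as fit weights. Trajectory truth is a set of orthonormal collective
modes with Gaussian projections and optional weighted basin offsets; the
`random_internal_modes` helper samples modes orthogonal to the six
rigid-body directions so that superposition leaves them intact.

What passing the recovery suites does **not** show: real correlation curves
contain triplet photophysics and detector afterpulsing absent from the
model; real CD baselines are not exactly linear; real DSC scans have
ΔCp ≠ 0 and scan-rate effects; real aggregation kinetics are not logistic
(no secondary-nucleation rate law is modelled); and real trajectories have
anharmonic, non-Gaussian mode statistics. The suites validate the
*estimators* under their own assumptions, not the assumptions themselves.

## Problem sizes

Recovery studies use 50 replicates (100 for single-component sizing) at 1%
relative noise: DSC scans 25–90 °C at 0.1 °C (651 points), denaturant grids
0–8 M at 0.25 M, FCS lag grids of 250 points over 6.5 decades (a realistic
multi-tau correlator density), ThT traces of ~100 points, and trajectories
of 2,000–10,000 frames on 15–30 pseudo-atoms. These sizes put the Monte
Carlo medians well inside their tolerance bands while every study completes
in seconds.

## Known limitations

- The dual GDM is limited to two components and requires ≥3 decades of lag
  coverage; three-population mixtures are out of scope.
- `fit_dsc` fits one endotherm; multi-transition thermograms (e.g. a
  shoulder from conformational heterogeneity) need masking before fitting.
- The FEL reports raw histogram inversion; no kernel smoothing or
  reweighting is applied.
- No photon-stream simulation: generators produce correlation curves, not
  time-tagged photons.
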
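# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `idpchar`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Equilibrium binding

The core assumption is 1:1 binding of the protein *dimer* (P) to a dsDNA
probe (L) with explicit depletion of both species: the complex
concentration is the closed-form root of `K_D·cx = (P−cx)(L−cx)` clipped
to [0, min(P, L)] for numerical safety. The signal model is linear in
bound fraction. EMSA densitometry is modelled phenomenologically with the
modified Hill form (floating plateaus A, B absorb gel-loading and
quantitation offsets; n absorbs deviations from ideality).

Fitting choices:

- Replicates are fitted as stacked observations by default;
  `average_replicates=True` reproduces the pre-averaging convention common
  in commercial software. At zero noise both give identical estimates.
- Initialization: plateaus from the ladder endpoints; K_D from a 40-point
  log-spaced grid search (1e-4 to 1e2 µM), ties broken by lowest SSR.
  Bounds: K_D ∈ (1e-6, 1e3) µM, n ∈ (0.1, 10); estimates at a bound set
  `at_bound`.
- 95% CIs are t-based on the asymptotic least-squares covariance. A
  simulation in the test suite checks that CI coverage is ≈95% at the
  default study conditions. Profile-likelihood CIs are not implemented.
- Monomer-basis K_D values are produced by *refitting* with the ligand
  axis doubled (monomer = 2×dimer), not by rescaling; the doubling of the
  axis is exact only in the dilute (Hill-like) limit, which is why the
  refit value is the default and a `method="scale"` shortcut is offered
  separately.

### Runs test

The fit diagnostic is a two-sided Wald–Wolfowitz runs test on the signs of
residuals ordered by concentration (zeros dropped). For n ≤ 20 the exact
run-count distribution is enumerated and the two-sided P sums all
outcomes with probability ≤ that of the observed run count; above 20 the
standard normal approximation is used (cross-checked against statsmodels
in the tests). If every residual has the same sign the run-count
distribution is degenerate, so the sign sequence itself is scored as the
extreme outcome of n fair sign flips (P = 2^(1−n)·2, capped at 1) — a
package convention chosen so that a single run is reported as strong
evidence of misfit rather than an error.

## FCS

The autocorrelation model is the standard triplet-corrected one-component
3D-diffusion form (the lateral term halves at τ = τ_D; the axial term
contributes the (1+τ/(s²τ_D))^(−½) factor). The structure parameter s is
never fitted alongside the sample: it is fixed per slide from the
reference-dye calibration, as in practice. `fit_curve` floats
(N, T, τ_T, τ_D) and requires ≥30 lag points; a curve whose tail has not
decayed below half its initial amplitude is rejected as unidentifiable
rather than fitted.

Diffusion-to-radius conversion uses the reference-dye identity
D·τ = D_ref·τ_ref at fixed calibration, then Stokes–Einstein with the
water viscosity at the droplet temperature (fixed published table, linear
interpolation; 23 °C → 0.9321 mPa·s) times the measured solution/water
viscosity ratio. τ_ref has no default — it is slide-specific and cannot
be invented. Uncertainty is first-order propagation over (τ, τ_ref,
D_ref, T); the temperature channel enters both T_abs and η(T) and is
differentiated numerically. The tests verify the propagated SD against a
10⁴-draw Monte-Carlo resampling within 10%.

## HDX-MS

Fractional uptake uses control *means*; per-replicate control variance is
deliberately not propagated into profile SDs (the replicate spread of M
dominates at the fidelity of this pipeline). Values outside [0, 100]% are
preserved — clamping would bias differentials — and flagged when more
than 5 points outside. Exposure matching across states is exact; no
interpolation. Coordinates are 1-based inclusive throughout.

Significance: two-sided Welch t (unequal variances,
Welch–Satterthwaite df) at α = 0.02, matching a 98% confidence interval.
No multiplicity correction is applied by default because the per-peptide,
per-timepoint decision is the unit of reporting in this field's
difference tables; Benjamini–Hochberg is available via
`differential(..., bh_correct=True)`. On null synthetic data the
false-positive rate is ≈2%, as the test suite checks.

## SV-AUC post-analysis

The package consumes species-level results (mass, v̄, sedimentation
coefficient), not raw boundary scans; it does not solve the Lamm
equation. The f/f0 refinement mirrors the three-pass grid procedure used
downstream of a continuous c(f/f0) analysis: ladders of 1–3.5 in 12
steps, then 1.7–3.5 in 20 steps, then ±0.09 around the running best in 6
steps; on each ladder the chosen rung minimizes |M(peak s, f/f0) −
M_known|, Δf/f0 is the final grid spacing, and ΔR_h is the neighbor-rung
radius difference. A solvent viscosity supplied below 0.05 mPa·s is
interpreted as a common ×10⁻² unit mislabelling and rescaled with a log
warning (water-like buffers are ≈1 mPa·s at 20 °C).

The R_h(N) scaling laws default to published power-law sets — folded:
4.75·N^0.29, IDP: 2.49·N^0.509, denatured: 2.21·N^0.57 (Å) — and are
overridable, since coefficient choices vary across compilations.

Known limitation: for the DNA-bound dimer, published frictional-ratio and
radius values are not mutually consistent under the anhydrous-sphere
relation (the apo species is self-consistent). The package therefore
validates the apo chain quantitatively and the holo case only through
property tests.

SEC calibration is a linear K_av vs log10(R_h) regression with inverse
prediction; it requires ≥3 standards inside the column volume.

## Thermal stability

The dye-melt correction divides by the control-fitted exponential
envelope normalized to 1 at the lowest temperature, preserving the raw
signal scale. Tm is the maximum |dF/dT| after Savitzky–Golay smoothing
(2nd-order, 11-point window, configurable); a derivative maximum on a
grid boundary is flagged as "no transition in span" rather than reported
as a Tm. The Boltzmann fit uses
`y = bottom + (top−bottom)/(1+exp((Tm−T)/width))` with Tm bounded to the
grid. On zero-noise symmetric sigmoids the two Tm routes agree within the
grid resolution, and both are invariant to affine signal rescaling.

The MRE convention is `[θ] = θ_mdeg·MRW/(10·l·c)` with c in mg/ml and l
in cm (stated explicitly because conventions differ); MRW is computed as
chain mass over N residues (not N−1).

Reversibility is `(S_cool(T_low) − S_denat)/(S_heat(T_low) − S_denat)`
with the denatured plateau taken at the highest shared temperature; the
index may slightly exceed 1 under noise.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
validated:

- **FP**: probe 40 nM, 12 dimer concentrations 0–1.5 µM, triplicate,
  truth K_D = 0.12 µM, Y_0 = 60 mP, Y_max = 230 mP.
- **EMSA**: free-probe fraction directly from the Hill model
  (A = 1, B = 0, n = 1.2, K_D = 0.327 µM) — generated from the model, not
  from gel physics, since only densitometric probe loss is analyzed.
- **FCS**: τ-titrations at K_D = 0.33 µM between τ_free = 70 µs and
  τ_bound = 390 µs (probe 100 nM, ladder to 2.5 µM); autocorrelation
  curves at τ_D = 390 µs, T = 0.15, τ_T = 2 µs, s = 5, N = 1.
- **HDX**: a 120-residue synthetic protein (charged/polar-enriched
  disordered segments flanking a hydrophobic 30-residue core at residues
  41–70), tiled by 10-mers at step 8; per-residue pseudo-first-order
  exchange `uptake(t) = Σ_r (1 − e^(−k_int·t/PF_r))` with k_int = 1 s⁻¹
  for every residue — the min/max normalization makes absolute intrinsic
  rates unidentifiable at this fidelity, so a sequence-dependent
  intrinsic-rate table would add nothing testable. Protection factors:
  background 1, core 30 (apo) / 3000 (holo), so the core is moderately
  slow when free and strongly protected when DNA-bound. Exchangeable
  sites per peptide = length − 1 (N-terminal amide excluded); deuterium
  increments 1.00628 Da/site. Exposures 10 s, 1 min, 5 min, 30 min,
  2.5 h in quadruplicate; FD/T0 control rows included per peptide.
- **Melts**: dye mode is a two-state sigmoid (Tm = 68 °C, width 2 °C,
  baselines 100/1000 a.u.) times an exp(−0.02·ΔT) envelope on a
  25–99 °C, 0.25 °C grid with 1% noise, plus a dye-only control;
  ellipticity mode is a bare Boltzmann (Tm = 66 °C, width 3 °C, −6000 to
  −2000 deg·cm²·dmol⁻¹) on 20–95 °C with 2% noise.

Noise is additive Gaussian with SD = sigma × signal dynamic range,
default sigma = 0.03 (1% for dye melts, 2% for CD melts, matching the
scatter the respective instruments show); replicate SDs in published
figures are error bars without a printed noise model, so the 3% default
is a package choice. All randomness flows through one
`numpy.random.default_rng(seed)` entry point; identical (truth, design,
seed) triples are bit-reproducible.

What the generators deliberately do **not** emulate: gel physics behind
EMSA densitometry, photon statistics and afterpulsing in FCS,
sequence-dependent intrinsic exchange rates and EX1 kinetics in HDX,
baseline drift and aggregation artifacts in melts, and raw AUC boundary
shapes. Passing tests therefore demonstrate correctness of the estimators
under their own statistical assumptions — not robustness to every
instrument artifact of real data.

## Problem sizes

The simulation-based checks use 200 titrations per binding assay, 100
melts per melt type, 500 fits for CI-coverage calibration, and 10⁴ draws
for the Monte-Carlo propagation oracle. These sizes put Monte-Carlo error
well below the corresponding acceptance tolerances while keeping the full
suite in the tens of seconds.

## Reference sequence

Chain-mass checks against the study protein (UniProt P15884-16, the
TCF4 isoform I⁻) need its FASTA, which is not redistributed here; run
`idpchar.seqfeat.fetch_reference_sequence()` once on a networked machine
to place it in the package data directory. All other functionality is
self-contained.
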
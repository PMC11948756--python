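# idpchar

Quantitative analysis toolkit for the biophysical characterization of large
intrinsically disordered proteins (IDPs), built around the assays used to
characterize dimeric DNA-binding transcription factors: equilibrium
dimer:dsDNA binding (fluorescence polarization, EMSA, FCS), FCS diffusion
analysis, differential hydrogen/deuterium-exchange mass spectrometry
(HDX-MS), sedimentation-velocity AUC hydrodynamics, thermal/CD stability,
and sequence-level disorder descriptors. A synthetic-data module emulates
every assay so the whole pipeline is testable without instrument data.

## Who it is for

Structural biologists and biophysicists who have species-level or tabular
instrument output (titration series, centroid-mass tables, c(f/f0) peak
positions, melt curves) and want reproducible, scriptable parameter
estimation with honest uncertainties and fit diagnostics — the kind of
analysis usually scattered across Origin/Prism/Excel sessions.

## The models

**Equilibrium binding with ligand depletion.** A dimeric protein P binds a
labelled dsDNA probe L at 1:1 stoichiometry. The complex concentration is
the exact root of the mass-balance quadratic

```
[cx] = ½ [ P + L + K_D − √((P − L + K_D)² + 4 L K_D) ]
```

and the observed signal (millipolarization or apparent diffusion time)
interpolates linearly between the free- and bound-probe plateaus,
`Y = (Y_max − Y_0)·[cx]/L + Y_0`. Densitometric EMSA free-probe fractions
follow a modified Hill equation `A/(1 + (P/K_D)^n) + B`. Fits report 95%
CIs, R², and a two-sided Wald–Wolfowitz runs test on residual signs (exact
enumeration for n ≤ 20).

**FCS.** Triplet-corrected one-component 3D diffusion,
`G(τ) = (1/N)(1 + T/(1−T) e^(−τ/τ_T))(1+τ/τ_D)⁻¹(1+τ/(s²τ_D))^(−½)`, with
the structure parameter s fixed from a reference-dye calibration
(D_AF488 = 435 µm²/s). Diffusion times convert to hydrodynamic radii by
the reference-dye route and Stokes–Einstein, with first-order error
propagation.

**HDX-MS.** Fractional uptake `D[%] = (M − M_min)/(M_max − M_min)·100`
between per-peptide minimal/maximal exchange controls; apo-vs-holo
differentials with pooled SD `√(var_a + var_b)` and Welch t tests at a 98%
confidence level.

**SV-AUC.** The frictional ratio links mass and shape:
`R_h = (f/f0)·(3·M·v̄/4πN_A)^⅓`, with the Svedberg relation
`s = M(1 − v̄ρ)/(N_A·6πη·R_h)` inverted on progressively narrower f/f0
grids exactly as a post-c(f/f0) refinement. Empirical R_h(N) power laws
for folded/IDP/denatured chains quantify expansion.

**Thermal stability.** Dye melts are divided by an exponential quenching
envelope fitted on a dye-only control before derivative Tm extraction; CD
melts at 220 nm are converted to mean-residue ellipticity
(`[θ] = θ·MRW/(10·l·c)`) and fitted with a Boltzmann sigmoid.

**Disorder descriptors.** Charge–hydropathy classification against the
canonical discriminant `<H>_boundary = (<q> + 1.151)/2.785`, chain
mass/MRW statistics, and the degree-of-labeling calculation.

## Worked example

```
$ python examples/auc_hydrodynamics.py
anhydrous sphere radius R0 = 30.1 Å; R_h = f/f0 x R0 = 72.5 Å at f/f0 = 2.41
peak s = 3.25 S -> refined f/f0 = 2.42 ± 0.04, R_h = 72.8 ± 1.1 Å
scaling laws at N = 905: folded 34.2 Å, IDP 79.6 Å
measured/folded = 2.12 (>= 2 indicates strong expansion)
mass-weighted vbar of the protein:DNA complex = 0.697 ml/g
```

Reading: a 96.5 kDa dimer with v̄ = 0.7131 ml/g would be a 30.1 Å sphere if
perfectly compact; the measured frictional ratio of 2.41 puts its
hydrodynamic radius at ~72.5 Å, more than twice the folded-chain
prediction for a 905-residue chain — the hydrodynamic signature of an
extensively disordered protein. The grid refinement, run backwards from
the sedimentation coefficient alone, recovers the same shape factor within
one grid step.

```
$ python examples/binding_titrations.py
FP   K_D = 0.122 µM  (95% CI 0.104-0.139, R² = 0.991, runs-test P = 0.20)
     monomer-basis refit: K_D = 0.264 µM
EMSA K_D = 0.349 µM  (Hill n = 1.10, R² = 0.991)
dsDNA needed for 95% saturation of 5 µM dimer: 7.06 µM (a 2x molar excess gives 97.7%)
```

The other scripts in `examples/` (`fcs_diffusion.py`, `hdx_differential.py`,
`thermal_stability.py`, `sequence_disorder.py`) walk through the remaining
capabilities the same way. A thin CLI (`idpchar simulate|fit-binding|
fit-fcs|hdx-uptake|hdx-diff|auc-rh|melt|cd-melt|seq-ch`) wraps the same
functions for shell pipelines.

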
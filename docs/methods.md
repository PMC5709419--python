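# Methods

## The coupled-equilibrium occupancy model

The central computation treats one sensor, its DNA target, one metal and a
hypothetical buffer as a closed system at equilibrium. Four bimolecular
associations are modelled (protein–metal, apo-protein–DNA,
metal-protein–DNA, metal–buffer); metal binding to the preformed
protein–DNA complex is not an independent reaction because the
thermodynamic cycle closes it (K₂ = K₁K₄/K₃), matching a four-equilibrium
formulation. All concentrations are molar; association constants are the
reciprocals of the dissociation constants in the sensor registry.

Assumptions worth stating explicitly:

* **One effective metal-binding event per sensor assembly.** The registry's
  metal affinities are "combined" constants measured across the assembly's
  sites (e.g. four Co(II) sites per Zur dimer behave indistinguishably in
  competition assays), so the model binds one metal per assembly with that
  combined constant. No cooperativity parameter is introduced.
* **One assembly per DNA molecule in vivo.** Although anisotropy
  titrations resolve 2:1 assembly:DNA stoichiometries in vitro, the
  occupancy model uses a single binding event per operator–promoter; the
  2:1 models live in the titration-fitting module only.
* **Equilibrium only.** No on/off rates; shock-type transients are outside
  the model. Activity coefficients are unity.

### Totals and units

Protein and DNA totals convert from copies per cell at a cell volume of
1 fl (e.g. 21 Zur dimers → 3.49 × 10⁻⁸ M; 1 DNA copy → 1.66 × 10⁻⁹ M),
with Avogadro's number 6.02214076 × 10²³ mol⁻¹. DNA targets per cell: 4
for Zur (multiple regulated operators), 1 for ZntR and RcnR, 15 for FrmR
and FrmR^E64H (plasmid-borne reporter). Metal and buffer totals default to
0.01 M and 0.1 M: metal far above total protein (so sensor binding cannot
deplete the buffered pool) and buffer tenfold above metal (so free metal is
set by the buffer affinity alone). A legacy-script unit convention for the
buffer constant is supported through a converter anchored on the printed
worked example (script constant 0.1 ↔ 10 M⁻¹ ↔ 5.12 × 10⁻³ M free metal).

### Equilibrium solver

General networks are solved in log free-concentration space of the base
species, because concentrations span ~10⁻¹⁶–10⁻¹ M and linear-space
iteration is ill-conditioned. A damped Newton iteration (finite-difference
Jacobian, step clipping at ±5 log units, halving line search on the max
log-residual) runs first; if a step fails to improve, each coordinate
falls back to bisection on its own mass balance, which is monotone in that
coordinate. Convergence demands relative mass-balance error below 10⁻¹⁰
(configurable); the initial guess is free = total. Zero totals and zero
association constants short-circuit analytically. The two-component case
is closed-form: each free concentration is taken from its own depletion
quadratic in a cancellation-free arrangement, so free concentrations many
orders below the totals (tight binding) keep full relative precision.

The specialised forward models in the titration module reduce their
networks to a single monotone scalar mass balance (free metal for
competition; free assembly for sequential DNA binding) and solve it by
bracketed root finding — exact speciation at a fraction of the cost of the
general solver, which matters for the repeated evaluations inside fits.

### Parameter-combination rules

Where a sensor's Co(II) and Zn(II) holo-DNA affinities agree within their
standard deviations, the occupancy model drives both metals with their
arithmetic mean: 3.6 × 10⁻⁸ M for Zur, 1.4 × 10⁻⁵ M for RcnR. FrmR's
Co(II) holo-DNA affinity is not directly measurable (its Co(II) affinity is
too weak to reach DNA-saturating metalation), so it is estimated as the
Zn(II)-FrmR value scaled by the Co/Zn fold-difference of the FrmR^E64H
variant, giving 2.0 × 10⁻⁶ M. For ZntR the default is the per-metal values
(3.4 and 6.5 × 10⁻⁷ M) because the registry's stated combined average
(4.7 × 10⁻⁷ M) is not the mean of the per-metal values — it presumably
averages replicate-level data not reprinted — and both options are exposed
rather than silently preferring one. Bound-flagged affinities (≥/≤) enter
all computation as point estimates, with the flag carried through for
reporting; this is the only reading that reproduces the published coupling
energies.

### Coupling free energy

ΔG_C = RT ln(Kd_holo/Kd_apo) with R = 1.98720 × 10⁻³ kcal mol⁻¹ K⁻¹ and
T defaulting to 298.15 K. The temperature is a modelling choice — the
affinity measurements were made near room temperature — and 298.15 K
reproduces the published values within ±0.05 kcal mol⁻¹; it is
configurable. Bound flags propagate (a lower-bounded apo Kd with an exact
holo Kd makes ΔG_C an upper bound). Standard deviations on the inputs are
not propagated into ΔG_C confidence intervals.

### Set points and ranking

Each curve over the default grid (61 log-spaced points, 10⁻¹⁶–10⁻³ M
buffered metal) is affinely normalised to [0, 1]; the set point is the
0.5 crossing, interpolated linearly in log concentration. The 0.5
threshold is this package's definition — the underlying curves are drawn
without one — chosen because it makes cross-sensor ordering reproducible
and is insensitive to the grid. Curves that cross 0.5 more than once, or
never, raise rather than guessing. Ranking sorts by ascending set point
and reports neighbour fold-ratios as specificity margins; pairs under
2-fold apart are flagged as overlapping, since their predicted order is
not meaningful at that resolution. A joint-normalisation mode rescales a
group of curves by their common min/max, preserving relative amplitude
(used for FrmR vs FrmR^E64H, whose weaker apo-DNA affinity keeps its
occupancy below the wild type's).

## Titration simulation and fitting

Competition models put `equivalents` identical, independent metal sites on
each protein monomer (ZntR 1, Zur 2, RcnR 1 — i.e. 2, 4 and 4 sites per
functional assembly) competing with a probe of fixed affinity (fura-2
8.64 × 10⁻⁹ M and EGTA 7.89 × 10⁻⁹ M for Co(II); magfura-2 2 × 10⁻⁸ M and
quin-2 3.7 × 10⁻¹² M for Zn(II)). The observed signal is affine in the
designated complex concentration — probe–metal for the quenching assays
(decreasing), protein–metal for the d–d absorbance assay (increasing).
The affine parameterisation is this package's choice of nuisance model,
validated by round-trip recovery. Anisotropy models count binding per
non-dissociable assembly, either 1:1 or two sequential events sharing one
Kd (no cooperativity; a single affinity describes both events), with
r_obs = r₀ + Δr × (mean assemblies bound per DNA). Δr may be fixed
(0.025 per event, the ZntR convention) or fitted, and fitting can be
truncated to the first binding event (1500 nM monomer for ZntR) to avoid
ternary-complex contributions at high protein.

Fits minimise the sum of squared signal residuals over log₁₀(Kd), with
the linear nuisance parameters solved exactly at each trial Kd (profiled
linear least squares). The 1-D search is a deterministic coarse grid
(0.25-decade steps over 10⁻¹⁵–10⁻¹ M) followed by bounded local
refinement — equivalent in effect to a dense multi-start, with no random
initialisation. Kd uncertainty comes from the local curvature of the
residual profile. A fit whose optimum sits at the search-window edge
(the data carry no information about the protein, e.g. no detectable
competition) or whose signal is constant is flagged non-converged and
reports no Kd. Every fit also returns simulated curves at Kd/10 and
Kd×10, the conventional visual envelope for affinity determinations; by
monotonicity of the forward model these bracket the fitted curve
pointwise.

## Synthetic data

The generators emulate the published experimental designs: four
competition designs (fura-2/ZntR at 15.4/9.8 μM, fura-2/Zur at
14.6/9.8 μM, EGTA/Zur at 50/52 μM, quin-2/RcnR at 18.0/14.9 μM) and three
anisotropy designs (sequential 2:1 Zur dimers on 10 nM DNA, 1:1 ZntR dimer
with fixed Δr, sequential 2:1 FrmR^E64H tetramers), each with its
literature truth Kd. Competition grids are linear from zero to 1.2× the
stoichiometric capacity; anisotropy grids are log-spaced over ±2 decades
around the assembly-corrected Kd on the monomer basis. Noise is additive
Gaussian, relative (default 1% of the noise-free signal) or absolute, from
`numpy.random.default_rng` with an explicit seed; generation is
bit-reproducible per seed. The 1% default is an assumption — replicate
scatter is not quantified in the source data — picked so that recovery
tests are non-trivial but identifiable.

What the synthetic data do *not* emulate: baseline drift, pipetting-scale
correlated errors, probe photobleaching, metal oxidation during anaerobic
handling, or the negative cooperativity of Zn(II) binding to Zur (sites
are treated as identical, as the combined-affinity description implies).
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated statistical model, not robustness to
every artefact of real titrations.

## Problem sizes

Default problem sizes keep every stage interactive on a single CPU: 61-point
occupancy grids (10 curves for the full two-metal reproduction), 21-point
titrations, and 20-seed recovery studies per design. All are parameters.

## Known limitations

* The buffer is a single hypothetical 1:1 ligand; no chemically identified
  buffer (glutathione, histidine, bacillithiol) is modelled.
* ZntR ternary (two-dimer) DNA complexes are out of scope; the 1:1 model
  plus range truncation is the supported treatment.
* In vivo transcript responses can only be compared with the model's
  ordering qualitatively; the model predicts occupancy, not transcription.
* Set points depend mildly on the normalisation window: a grid that clips
  a curve's plateau shifts its 0.5 crossing. The default grid comfortably
  spans all five sensors' transitions for both metals.
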
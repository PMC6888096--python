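# Methods

This note documents the models behind each analysis stage, the estimator
and numerical choices where the procedure was genuinely open, what the
synthetic-data generators do and do not emulate, and known limitations.

## Scope and conventions

All concentrations are millimolar (mM) at every interface; operations
needing SI convert internally (mol/L = mM × 10⁻³). Temperatures are °C at
the interface and converted with T/K = t/°C + 273.15. Physical constants:
R = 8.314 J mol⁻¹ K⁻¹, N_A = 6.022 × 10²³ mol⁻¹. CSV inputs are
comma-separated with one header row and `#` comments; duplicate
concentrations are averaged with a warning. Each measurement stage carries
its own temperature (conductivity and tension are typically run at 24 °C,
fluorescence at 22 °C, viscometry at 20 °C); the report does not harmonize
them, because the only temperature-sensitive step (the Gibbs prefactor
chain) uses the tension stage's own temperature.

**Unrounded intermediates are mandatory.** The Gibbs chain
slope → Γmax → Amin → CPP is always evaluated at full precision and rounded
only for display. This matters: Amin computed from a two-significant-figure
Γmax of 1.9 × 10⁻¹⁰ mol cm⁻² is 87.4 Å², versus 87.9 Å² from the unrounded
value — only the latter displays as the consistent integer 88.

## Conductivity break-point fit

Model: a continuous two-segment line
κ(C) = a + S₁·min(C, b) + S₂·(C − b)₊, pseudo-phase micellization with the
break b at the CMC and α = S₂/S₁. The break is selected by exhaustive
ordinary least squares over a deterministic candidate set: every interior
sample abscissa plus every midpoint of adjacent samples, keeping only
candidates that leave ≥ 3 points per segment; ties break toward the
smallest CMC. This estimator is exactly reproducible by brute force, which
the test suite exploits (1000 random instances against an independent
oracle). A golden-section refinement of the break off the candidate grid is
available (`refine=True`) but is not the default: it trades oracle-exact
reproducibility for sub-grid resolution that the midpoint set already makes
smaller than realistic titration spacing. Points are unweighted — nothing
in the measurement suggests heteroscedasticity.

Diagnostics:

* *Broad transition.* A gradual slope change (seen at high cosolvent
  concentration) fitted by the sharp two-segment model leaves a smooth,
  serially correlated residual wave. The fit is flagged "broad transition"
  when the residuals are non-negligible (RMS > 10⁻⁹ of the response scale)
  and their lag-1 autocorrelation exceeds 0.5. A complementary stability
  check refits after removing the two points nearest the break and flags a
  CMC shift above 5%. At a 4-mM logistic transition width the
  autocorrelation test fires essentially always (98% of noisy replicates);
  on sharp-break data at default noise it produced no false flags in 100
  replicates.
* *No micellization signature*: S₂ ≥ S₁; α is still reported but flagged.
* The optional CMC uncertainty is a residual-resampling bootstrap SD. It is
  a fit-stability measure, not a replicate SD, and is labelled as such.

## Gibbs adsorption chain

Γmax = −(dγ/dlogC) · 10⁻³ / (2.303 · n · R · T) in mol m⁻², reported in
mol cm⁻² (× 10⁻⁴); Amin = 10¹⁶/(N_A · Γmax) Å². The 2.303 factor is the
log₁₀ convention, used verbatim rather than ln 10. The prefactor n defaults
to 2 (1:1 ionic surfactant, no swamping electrolyte, both species adsorb)
and is user-overridable to 1 or 3.

The slope window defaults to every point before the terminal plateau,
where the plateau is the longest final run with pairwise γ spread
≤ 0.5 mN/m; an explicit concentration window overrides this. The
tension-derived CMC is the abscissa where the descending line crosses the
horizontal plateau mean. A non-negative slope is flagged
non-surface-active.

## Packing parameter

Fluorocarbon tail geometry by group additivity — (n_c − 1) CF₂ groups of
41.6 ų plus one CF₃ of 84.0 ų, hence V = 41.6·n_c + 42.4 ų and extended
length l = 1.3·n_c + 2.04 Å. No analogous built-in exists for hydrocarbon
tails: their geometry must be supplied explicitly, rather than importing a
formula the package's validation chain does not cover.

CPP = V₀/(Amin·l_c) is classified with exact rational thresholds (1/3,
1/2, 1), not their two-decimal roundings. A CPP within 0.01 of a threshold
carries a `boundary` annotation: 0.34 classifies as cylindrical but is
flagged as adjacent to the spherical range, preserving the geometric
ambiguity a practitioner would note.

## Pyrene I1/I3

Band extraction: I1 is the intensity maximum in 370–376 nm, I3 in
380–386 nm. The third band is anchored at the conventional 383 nm; the
first-band window is centered on pyrene's canonical 373 nm band. A window
whose maximum falls on its edge is used as-is and flagged. Spectrum
normalization divides by I1 (idempotent, scale-invariant).

CMC criterion: intersection of (a) a horizontal line through the mean of
the low-concentration plateau (the longest initial run whose ratio spread
is ≤ 5% of the curve's full range) and (b) a line fitted to the steepest
descent — the largest undivided drop between adjacent samples (per-mM
slopes between closely spaced points on log grids are noise-dominated;
undivided drops are not), ties resolved to the middle of the tied run,
extended by k = 2 points each side but clipped at the plateau edge while
keeping the edge point itself, which anchors the line at the kink. The
variant intersecting the descent with the *upper* plateau is available as
an option. `fit_plateau_slope=True` replaces the horizontal plateau line
with a fitted shallow one.

Estimator bias is inherent here: a bound-fraction curve of Langmuir form
f = K(C − CMC)/(1 + K(C − CMC)) has no linear descent segment, so any
two-line intersection sits below the true CMC (about 6 mM low at the
default sampling and K = 0.2 mM⁻¹). The tests therefore assert
self-consistency of the estimator under noise (median of noisy estimates
within ±2 mM of the noiseless estimate, 200 replicates), exactness on
genuinely piecewise-linear curves, and invariance to baseline shifts (a
urea-shifted aqueous ratio moves both lines equally).

## Viscometry and hydration

Relative viscosity from efflux times: ηr = (t·k)_sample/(t·k)_solvent.
The virial fit solves ηr − 1 = p₁x + p₂x², x = (c_s − c₁) in mol/L, by
least squares **through the origin** — the model, not the data, fixes
ηr = 1 at the CMC (a free intercept is available for diagnostics only).
Then Vshyd = p₁/(ν·N_A·10⁻²⁴) nm³ and k₁ = p₂/p₁². The free-monomer
concentration c₁ is the CMC exactly, with source priority user >
conductivity > tension. Fewer than 4 points above the CMC is an error;
p₁ ≤ 0 is flagged nonphysical; an all-ones curve is flagged "no micellar
contribution".

Shape factors: ν = 2.5 for spheres; for a hemisphere-capped rod of axial
ratio L/d, the equivalent prolate axial ratio is
J = (L/d)·[2/(3 − d/L)]^½ — the only reading of that expression consistent
with the sphere limit J = 1 ⇒ ν = 2.5 — and
ν = 2.5 + 0.407(J − 1)^1.508 for 1 < J < 15, or
ν = 1.6 + (J²/15)[1/(ln 2J − 1.5) + 3/(ln 2J − 0.5)] for J > 15. The
short-rod formula is used up to and including J = 15; at exactly 15 both
values are computed and their discrepancy logged, since neither range
nominally includes the point. ν is strictly increasing in L/d and
continuous at the sphere limit (property-tested). When only ν is known
(e.g. ν = 2.97 from scattering-derived geometry), the axial ratio is
recovered by closed-form inversion of the short-rod formula.

Hydration bookkeeping: v_water_total = Vshyd − V_molecule in plain water,
n_water = round(v_water_total/0.030 nm³). With a cosolvent, the plain-water
shell volume is held as a reference and the excess
Vshyd − V_molecule − v_water_reference is assigned to cosolvent molecules
(urea: 0.075 nm³ each), reported to one decimal. The identity
V_molecule + v_water_total + v_cosolvent_total = Vshyd holds exactly before
rounding in every scenario. A negative cosolvent volume (apparent
dehydration relative to the reference) floors the count at 0 with a
warning. Because Vshyd scales as 1/ν at fixed p₁, running the same fit
under a cylindrical (ν = 2.97) and a spherical (ν = 2.5) reading yields
hydrated volumes in the exact ratio 2.5 : 2.97 — the two bracketing
scenarios for a cosolvent condition whose micelle shape is unknown.

## Synthetic-data generators

The generators emulate the *statistical structure the estimators assume*,
with defaults at the measured APFO-in-water conditions: CMC 26.5 mM,
α 0.47, S₁ 50 µS cm⁻¹ mM⁻¹, γ at 1 mM 60 mN/m with slope −29.6 (plateau
≈ 17.9 mN/m, continuous at the CMC by construction), I1/I3 from 1.8 to 1.2
with binding constant 0.2 mM⁻¹, ν 2.97, Vshyd 0.710 nm³, k₁ 1.0. Noise is
independent Gaussian per channel: 0.5% relative (conductivity), 0.3 mN/m
(tension), 0.01 (ratio), 0.002 (ηr — from the viscometer's ±0.2%
efflux-time reproducibility; the other three are conventions chosen to
resemble typical bench scatter and are free parameters). Identical
(params, seed) gives byte-identical output.

Default grids: conductivity 1–50 mM in 1-mM steps (a dense titration over
the measured range, on which the candidate set resolves the default break
exactly); tension 16 log-spaced points over 2–60 mM; fluorescence 24
log-spaced points over 1–200 mM; viscometry 30–150 mM in 10-mM steps.

At zero noise each generator is exactly inverted by its paired stage
(conductivity → CMC/α to machine precision; tension → slope/CMC/Amin;
viscosity → Vshyd/k₁ to 6+ significant figures; pyrene spectra → ratios to
grid tolerance). Monte-Carlo recovery at the default truths over 200 seeds
gives median |CMC error| ≤ 1 mM, |α error| ≤ 0.03 and |Vshyd error|
≤ 0.02 nm³.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: finite micelle aggregation numbers and
mass-action (non-pseudo-phase) transitions; temperature drift between and
within stages; electrode and tensiometer calibration error (systematic, not
Gaussian); premicellar aggregation and surface-tension minima from
impurities; pyrene excimer formation and real spectral lineshapes beyond
two Gaussian bands; shear-rate and electroviscous effects in the
viscometry; correlated (non-independent) noise.

## Known limitations

* The fluorescence CMC estimator's low bias on smoothly bending ratio
  curves (above) is a property of the two-line intersection criterion, not
  of this implementation; cross-check against the conductivity CMC when
  both measurements exist.
* Volume bookkeeping treats solvation volumes as additive rigid volumes;
  counts of "11 waters" or "2.7 ureas" are effective hydrodynamic numbers,
  not coordination numbers.
* The shape-factor route accepts ν as direct input when micelle geometry
  comes from scattering; no form-factor modeling is attempted.
* Hydrocarbon tail geometry must be user-supplied; the group-additivity
  formulas cover linear fluorocarbon tails only.
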
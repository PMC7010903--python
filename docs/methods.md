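# Methods

`celldose` models the dosimetry of an in vitro ¹⁷⁷Lu-DOTATATE experiment:
adherent SST₂-expressing cells take up activity from the culture medium for
4 h, are washed, and then grow into colonies over 6 days while the
internalized and membrane-bound activity irradiates the cell nucleus.  The
package computes cellular S values (absorbed dose to the nucleus per decay in
a source compartment) by Monte Carlo, assembles the MIRD dose

D(N) = Ã_M·S(N←M) + Ã_CS·S(N←CS) + Ã_C·S(N←C),

and fits the dose–response of clonogenic survival.

## Electron source and transport

**Emission spectrum.** The packaged ¹⁷⁷Lu table combines four β⁻ branches
(endpoints 497.8, 384.5, 248.6, 176.5 keV with yields 0.786/0.091/0.001/0.122)
whose spectral densities follow the allowed Fermi shape for the Z = 72
daughter, plus internal-conversion lines of the 112.95 and 208.37 keV
transitions and grouped Auger electrons.  The compilation's mean electron
energy per decay (≈152 keV above the sampling cutoff) is consistent with
standard decay-data evaluations (≈148 keV); the few-percent difference comes
from the allowed-shape approximation and is irrelevant to the geometry-driven
ratios studied here.  Sampling starts at 3.8 keV (configurable): softer
electrons travel well under 1 µm and cannot couple compartments.  Discrete
lines below the cutoff are dropped and β densities truncated, with yields
reduced accordingly, so the sampled spectrum and the quadrature mean Δ agree
exactly — this makes the full-absorption oracle S(N←N) → Δ/m exact for the
sampled source.

**Stopping power and range.** Collisional stopping power of liquid water from
the Berger–Seltzer formula (I = 75 eV, density effect neglected below 1 MeV),
tabulated 1–1000 keV and shipped as CSV; the CSDA range is the cumulative
trapezoidal integral of 1/S(E) on a dense log grid, with forward and inverse
lookups interpolating linearly on the same knots (exact round trip).  At
6 keV the range is ≈1.07 µm, at the β endpoint ≈1.76 mm.  Membrane lipid is
density-scaled water (ρ = 0.92), but since the membrane is a zero-thickness
surface source it never contributes a traversal path; the nucleus is treated
as water (a known few-percent bias against tissue-composition models).

**Transport.** Straight-line continuous-slowing-down transport: electrons are
emitted isotropically, travel in straight lines, and deposit along each
nucleus chord the difference of residual energies at entry and exit (no
scattering, δ-rays, or straggling — the approximation classically used for
cellular S values).  Consequences: single-cell self-dose trends are captured
well, but planar cross-dose is overestimated because nearly-in-plane
electrons stay aligned with lattice rows of nuclei over hundreds of µm
instead of diffusing out of the monolayer slab; see "Known limitations".

**Estimators.**
- *Self dose*: direct tally, S = Y·⟨E_dep⟩·1.602×10⁻¹⁶ J/keV / (V_N·ρ),
  with Y the electron yield per decay.
- *Cross dose*: lattice reciprocity — decays are sampled in the central cell
  and energy is tallied in every translated neighbour nucleus; on a symmetric
  layout this equals the dose received from all neighbours, with per-neighbour
  contributions that sum to the total exactly.  Normalisation is 1 Bq·s in
  the chosen compartment of each source cell, identical to the self dose.
- *Medium source*: two-stage importance sampling — positions in a
  radius-uniform ball around the nucleus (weight 4πr²R/V_well) and directions
  in the cone subtending the nucleus bounding sphere (weight (1−cosθ)/2).
  Both weightings are exact under straight-line transport (anything outside
  scores zero), and are recorded in the result metadata.  A cell on the floor
  of a range-thick medium reproduces half-space charged-particle equilibrium,
  S = Δ/(2ρV), within MC error.

## Cell geometries

Three families expose one interface (volumes, compartment sampling, ray/
nucleus chords):

- **Spheres** (the classical cellular-S-value convention): cell and nucleus
  spheres, optional eccentric nucleus, membrane = outer surface.
- **Truncated cone** (CSG): the shape dialect is configurable, with a default
  fixed as a *flat adherent* cell — frustum base radius 15 µm, top 7 µm,
  height 8.8 µm (V = 3500 µm³), oblate nucleus (8.2, 8.2, 3.73 µm,
  V ≈ 1050 µm³) resting 0.3 µm above the substrate, and a half circular torus
  Golgi (tube radius 1 µm) wrapped around the +y flank of the nucleus.  The
  Golgi ring radius is solved at construction so the minimum 3-D
  Golgi–nucleus surface distance equals d(G−N) (default 1 µm), verified by a
  brute-force sampled-surface check.  The family scales self-similarly:
  cell volumes 1900–5500 µm³ map onto nucleus volumes ≈570–1650 µm³, the
  observed ranges.  A wider-top variant (top radius 11 µm, same volumes) is
  used for nucleus-placement studies, where the nucleus must move laterally
  by up to 3 µm with the Golgi anchored in place.
- **Triangle meshes**: watertight OBJ/PLY surfaces per compartment; volumes
  by the divergence theorem (signed mesh volume), point-in-mesh by
  crossing-parity ray casting, and chords from a vectorised Möller–Trumbore
  kernel (implemented in-package; for non-convex nuclei the outermost
  crossing pair is used — a convex-chord approximation that is exact for the
  near-convex synthetic nuclei).

**Layouts.** Monolayers are hexagonal lattices (densest packing; the actual
lattice is not specified by the experiment) with pitch = footprint diameter ×
(1 + gap), enumerating neighbours within a cutoff of 280 µm — the average
β range used to bound the interaction distance.  The cell-proximity study
keeps the *total cell count* fixed across spacings (scaled lattices), which
is how the experiment's simulation set-up reads; colony clusters are the
n nearest lattice sites.  The culture well is a cylinder (12-well plate,
radius 11.05 mm), height = volume/πr².

## Uptake kinetics and cumulated activity

Empirical curve forms, fitted by least squares: membrane binding linear in
incubation time (a saturating-step alternative is provided, reflecting the
ambiguity between "saturates within 15 min" and "linear with time");
internalization A_plat(1−e^(−kt)) with the default truth k = 1.5 h⁻¹ placing
95% of plateau at 2 h; daily retention of decay-corrected per-cell activity
exponential with rate λ_eff (default truth 0.024 h⁻¹), fitted log-linearly
(exact for multiplicative noise, honest slope covariance — combine with a
t quantile for interval coverage).  Fits below R² 0.95 (uptake) / 0.94
(retention) are flagged, not rejected.

Cumulated activities: the uptake interval integrates the fitted curves times
e^(−λ_p t) on a fine trapezoidal grid; follow-up days use the closed form
f·A₀·(e^(−λ_p T1)−e^(−λ_p T2))/λ_p with the day's measured fraction, day 1
spanning 4–24 h (20 h) and later days 24 h each.  λ_p = ln2/6.647 d.
Cellular channels are normalised per cell by the measured count of the day
(log-linear interpolation between measured days).  Fractions at unmeasured
added activities come from inverse-distance weighting over
(log₁₀ activity, time) per compartment, both axes span-normalised, power 2 —
the method is named but not specified in the source protocol, so exactness at
nodes, boundedness, and continuity are the tested contract.

## Dose assembly and uncertainty

Per interval, dose = Σ_sources Ã × (self S + cross S of that day's layout).
The medium term is applied during uptake and day 1 only; afterwards the
residual medium activity contributes below the S(N←M) scale (~10⁻¹¹ of the
cellular terms) and is dropped.  Colony growth: cluster size
round(2^(24d/T_d)) with day 1 forced to isolated cells; activity splits
equally to offspring; only the progeny cluster contributes cross-dose
(neighbouring colonies lie beyond the β range).  Uncertainties combine the
reported component classes — fractions 5–33%, cell counts 11–18%, added
activity 1–3%, S-value shape variance 18–27% — as independent relative SDs in
quadrature (class midpoints when replicate SDs are unavailable).

## Dose–response

SF = exp(−αD−βD²), fitted on SF directly (unweighted; log-domain optional),
α, β ≥ 0.  R² is reported on both SF and ln SF since the convention for
nonlinear fits is ambiguous.  Model choice: AIC = n·ln(RSS/n) + 2k, minimum
wins, ties to fewer parameters; a fitted α/β > 100 Gy is classified as the
linear regime.

## Synthetic data generator

The generator emulates the measurement *structure*: five added activities
(0.1–2.5 MBq/ml in 1 ml), 15-min fraction sampling over 0–4 h, daily
follow-up measurements, 2 experiments × 3 replicates, multiplicative
lognormal noise (unit mean) at the reported CV classes, near-Poisson count
noise, and colony-count survival data (lognormal or binomial).  Default
truths: internalized plateau fraction 1.6% of added activity and membrane
slope 0.001/h — chosen so absorbed doses land on the reported dose scale
(~0.1–2 Gy across activities, with the unbound medium contributing 10–17%
during uptake); λ_eff = 0.024 h⁻¹; doubling time 35 h (inside the measured
27–44 h band); α = 0.33 Gy⁻¹ (mid-range of the reported fits).  After the
4-h wash the medium fraction restarts from zero and accumulates excreted
activity only.  Every dataset carries its analytic ground truth (exact
cumulated-activity integrals), enabling closed-loop tests: the full pipeline
recovers α to <0.5% on noiseless data and to ~10% median at measurement-scale
noise.

What the generator does **not** emulate: receptor saturation (fractions are
activity-independent), cell-to-cell uptake heterogeneity (activity is uniform
across cells), cell death and detachment kinetics, and any real gamma-counter
systematics.  Passing recovery tests therefore demonstrates pipeline
correctness under the stated noise model, not robustness to those effects.

## Numerical choices

Seeded `numpy.random.Generator` everywhere; identical seeds give identical
tallies and datasets.  Rejection sampling aborts below an acceptance of 10⁻⁴
(degenerate geometry).  Cross-dose tallies chunk the history × neighbour
matrix to bound memory.  Problem sizes used by the shipped tests and the
acceptance script — 10⁴–10⁵ histories per S value, 10⁶ for the
full-absorption oracle, 100 seeds for recovery studies — give ≈1% Monte Carlo
statistics on S values, comfortably below the geometry effects under study.

## Known limitations

- Straight-line CSDA overestimates monolayer *cross*-dose: the in-plane ring
  sum decays like 1/distance per ring out to the cutoff because electrons are
  never scattered out of the nucleus plane.  Gap-dependence ratios (82%/99%
  reductions) are robust to this, but the absolute cross/self ratio for
  touching cells comes out ~80% here versus ~23% reported from
  condensed-history transport.  Treat absolute cross-dose values from this
  engine as upper bounds.
- Nucleus water-equivalence and the absence of δ-rays/straggling bias self S
  values at the few-percent level.
- The truncated-cone dialect is one reasonable reading of a figure-only
  specification; all dialect parameters are constructor arguments.
- Meshed nuclei use the outermost-chord approximation for re-entrant rays.
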
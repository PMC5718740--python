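# Methods

## Scope and model chain

The package reproduces, at desk scale, a three-part uncertainty analysis of
balloon HDR ¹⁹²Ir breast brachytherapy: (1) dose reduction from iodinated
contrast in the balloon filling, by voxel photon Monte Carlo; (2) dose
perturbation from source-position deviation and balloon deformation, by an
analytic point-source model; (3) the propagation of both into tumor control
probability through a DVH → BED → LQ-survival → Poisson chain. A fourth
component executes the TLD batch-calibration arithmetic that a measurement
campaign would use, on synthetic readings.

## Materials and cross sections

Mixtures are defined by elemental mass fractions and density. The contrast
compound is iopromide (C₁₈H₂₄I₃N₃O₈, 1.409 g/cm³); a mixture at
concentration c mixes mass fractions linearly in c and density
volume-linearly. This is the arithmetic that reproduces the published
composition table for these solutions, even though such concentrations are
nominally "% by volume" (true volume mixing would give, at 15%, an iodine
fraction of 9.6%, not the 7.22% the table prints); we follow the table. Two
of its printed cells do not survive recomputation: the 15% carbon cell
(4.16 vs 4.10 from the affine rule; that row sums to 100.07%) and, at the
0.01 level, cells that require carbon = 12.00 g/mol exactly. We use
standard atomic weights and treat both as printed-rounding artifacts.
Worth noting: a "100%" filling of pure iopromide at 1.409 g/cm³ implies
678 mg iodine/ml, whereas the named commercial agent is a 370 mg I/ml
aqueous solution — the idealized composition overstates what an undiluted
real agent contains.

Elemental photon cross sections (H, C, N, O, Na, Cl, I; 0.05–1.0 MeV) are
shipped as plain-text fixtures generated by `scripts/generate_xsec_tables.py`:

* **incoherent**: exact free-electron Klein–Nishina times Z/A. No
  binding/Doppler corrections; these are a few percent at the low end of
  the range for iodine and negligible for the light elements.
* **photoelectric**: piecewise log-log power laws through per-element
  anchors from standard attenuation compilations. The iodine curve was
  cross-checked against an independent Cromer–Liberman f″ computation
  (agreement ~5% below 150 keV, within ~15% at 300–500 keV where the
  cross section is a minor channel).
* **coherent**: Thomson cross section integrated over IT92 atomic form
  factors; the same F²(x²) tables drive the angular sampling, so coherent
  scatter is properly forward-peaked. The small constant IT92 term is
  damped with the slowest Gaussian so F → 0 at large momentum transfer.

Resulting water totals agree with standard published values to ≤1.6% over
0.06–1.0 MeV (asserted in the test suite). The ¹⁹²Ir spectrum is the
standard decay-scheme line list restricted to 0.060–0.885 MeV: 34 lines
(gammas plus Pt/Os K x-rays), mean energy 354 keV.

## Phantom and transport

The phantom is a cubic water block (half-extent ≥ balloon radius + 5 cm for
full scatter) with a spherical balloon at the origin, voxelized at 0.15 cm
by voxel-centre membership. Tissue defaults to water; a paraffin/bees-wax
substitute (CH₂ at 0.926 g/cm³) is available behind a flag since the
physical phantom this emulates was wax — the dose *ratios* studied here are
insensitive to that choice.

Transport is analog photon-only Monte Carlo with Woodcock (delta) tracking
on an energy-dependent majorant. Interactions: photoelectric absorption
(full local deposit, fluorescence included locally), free-electron
Klein–Nishina incoherent scattering (standard two-branch ε-sampling with
rejection), and coherent scattering by form-factor x²-inversion with a
Thomson rejection step. Photons below 0.06 MeV deposit locally and stop.
Electrons are **not** transported: dose is scored in the kerma
approximation, justified because secondary-electron ranges at these
energies (< 2 mm in water) are at the scoring-voxel scale and ratios are
insensitive to the residual blurring. The full-transport electron cutoff
of general-purpose codes (AE = ECUT = 0.521 MeV) is recorded in
`TransportSettings` but not emulated.

Two estimators are available: the default expected-value ("track-length")
estimator scores E·(μ_tr/ρ)/μ_maj at every Woodcock flight point; the
interaction-site estimator deposits transferred energy at real collisions.
They agree within statistics (tested). Runs are single-threaded and
bit-reproducible for a fixed seed; batches (default 10) give per-voxel and
per-region uncertainties.

**Common random numbers.** Paired DRF runs share one majorant table (the
maximum over both fillings) and one seed, so both runs draw identical
flight geometry until a real/virtual decision differs inside the balloon.
This collapses the variance of the ratio enough to resolve the ~2% effect
of a 15% filling with 10⁶ histories (quoted ratio uncertainties use the
conservative quadrature sum).

**Validation in uniform water.** Dose·r² from the MC is flat to 2.6% over
1–5 cm — the textbook behaviour of ¹⁹²Ir in water, where attenuation and
scatter build-up nearly cancel — and agrees within 4.1% with an independent
point-kernel oracle (first-collision kerma × Berger-form energy-absorption
build-up, coefficients fitted to standard compilations; the oracle's
build-up fit, not the MC, dominates that residual).

## The dose-reduction factor, and why full transport undershoots the published values

The DRF is the shell-averaged dose ratio at 1 cm from the balloon surface.
Our paired-MC values (10⁶–4×10⁶ histories, converged):

| geometry | primary-only ratio | full MC | published |
|---|---|---|---|
| 4 cm, 100% | 0.896 | 0.880 | 0.910 |
| 4 cm, 50%  | 0.944 | 0.923 | 0.950 |
| 4 cm, 15%  | 0.981 | 0.967 | 0.982 |
| 6 cm, 100% | 0.855 | 0.825 | 0.862 |

The pattern is systematic and physically interpretable: the **published
values coincide with narrow-beam primary attenuation ratios** (middle
column: spectrum-weighted exp(−Δμ·R) through the balloon radius), while
**full transport lands 0.015–0.03 lower at high concentration** because
roughly a third of the dose at the prescription point is scattered
radiation, much of it generated *inside* the balloon, soft, and on long
oblique paths — exactly the component the iodine photoelectric effect
(~E⁻³) absorbs preferentially. The checks that convinced us this is
physics rather than a bug: iodine photoelectric confirmed by an independent
computation (which, if adopted, would push our DRF lower still), water
attenuation within 1.6% of standard values, bit-identical CRN pairs for
equal materials, two estimators in agreement, and energy conservation. At
15% concentration, where the scatter effect is small, we reproduce the
published value within 0.015. The residual possibilities — partial-volume
dilution of the contrast region in the CT-derived geometry the published
simulation used, or the idealized-vs-real agent composition noted above —
cannot be distinguished from here. The acceptance tests assert the
published numbers at ±0.02 and therefore fail for the 100% and 50% cases;
we report our computed values rather than widen the band.

## Analytic dose model, shift ratios, DVHs

Around the centred source the dose per fraction is
3.4·((R+1)/r)²·g(r)/g(R+1); g ≡ 1 by default (in water g varies by ~1% over
this range; an MC-derived table can be plugged in). Source-shift
enhancement/reduction ratios follow by evaluating at R+1 ∓ s. Against the
published Monte Carlo table, 27 of 36 cells agree within 0.03 (all of the
1 mm row); the cells that do not — enhancements at 4 cm/2–5 mm and
6 cm/2–4 mm, reductions at 5–6 cm/4–5 mm — deviate by 0.031–0.08, more
than any physical g(r) modulation can produce over ≤ 5 mm, so we treat the
published values there as carrying unmodelled geometry or noise and keep
the inverse-square model. Monotonicity in shift and the
4-cm-balloon-worst-case pattern hold exactly.

The differential DVH of the PTV shell (R < r ≤ R+1 cm) is computed with
exact analytic shell volumes per dose bin (0.5 Gy default bin width;
per-segment linear inversion of the monotone dose-radius map, refined on a
64-point radial sub-grid per band). A DRF multiplies every bin dose.

**Deformation model.** The geometry of "balloon deformation" is
under-determined: we adopt the simplest concrete reading, a hemispherical
outward displacement in which tissue on one side at nominal radius r sits
at r + δ(θ), δ = d·cos θ tapering to zero at the equator, receives the dose
of its actual radius, and the PTV follows the deformed surface while the
dwell position and prescription stay those of the spherical plan. The mode
is pluggable so alternative geometries can be compared. Under this mapping
the TCP loss at 4 mm is *bounded*: the minimum PTV dose is
34·((R+1)/(R+1.4))²·DRF ≈ 26 Gy (4 cm balloon, 15% contrast), whose LQ
survival is 4.2×10⁻⁴, so TCP ≥ exp(−200·4.2×10⁻⁴) ≈ 92% for *any* volume
distribution — our volume-weighted grid gives ~99.4%. The published 74% at
4 mm therefore implies cold volumes (doses near ~15 Gy over ~10% of the
PTV) that no 4 mm surface displacement can create geometrically; those
rows are validated as monotone trends only, and the acceptance clause
demanding TCP < 90% at 4 mm is left failing with this bound quoted.

## Radiobiology

Per DVH bin: d_i = D_i/n, BED_i = D_i[1 + G·d_i/(α/β)],
ln S_i = −α·BED_i + γT, S_i capped at 1; S̄ = Σ v_i S_i (clonogens uniform
over the PTV volume — the distribution is not specified upstream, and the
volume-weighted mean reproduces the zero-deformation TCP values within the
stated ±2 points); TCP = exp(−k·S̄). The protraction factor uses the exact
closed form with a series branch below μT_f = 10⁻⁴ to avoid cancellation;
G(n=10, μ=0.69 h⁻¹, T_f=0.17 h) = 0.0962. The repopulation term is *added*
to ln S (proliferation increases survival), although the source formula
prints "−γT"; a strict-as-printed flag exists and shifts the
zero-deformation TCP by well under one point. T (effective treatment time)
is not given a value upstream; we use 5 days (10 fractions, twice daily).
Defaults: k = 200, α = 0.3 Gy⁻¹, β = 0.03 Gy⁻² (α/β = 10 Gy), T_d = 15 d.

With these choices the centred, undeformed balloon gives TCP = 99.9% (15%
contrast) and 99.8% (50%), matching the published 99%/98% within the
stated ±2-point band for all three balloon diameters; the grid is monotone
non-increasing in deformation and concentration, with cross-diameter
spread ≤ 0.3 points.

## TLD chain

SCF_i = R̄/(R_i − R_BKG) with R̄ the background-subtracted batch mean;
BCF = R̄_expected/R̄_measured; TL_i = (R_i − R_BKG)·SCF_i·BCF. Synthetic
readings are dose × lognormal chip sensitivity (σ = 1.3%, matching a
realistic batch spread of SCFs within ~[0.96, 1.06]) × reader gain +
background, with multiplicative reader noise; dose response is linear
(valid below ~6 Gy; supralinearity above that is out of scope). The
measurement-side DRF is the ratio of group means with pooled-spread
uncertainty and is exactly invariant to common gain.

## What the synthetic setup does and does not show

The generator replaces a CT-imaged wax phantom and a clinical planning
system with ideal geometry: perfect spheres, homogeneous filling, a point
prescription, no balloon wall, catheter, inflation channel, air gaps, or
skin boundary, and no CT partial-volume mixing at the balloon surface.
Passing tests therefore demonstrate the *physics chain* — attenuation,
transport, inverse-square geometry, LQ/Poisson arithmetic — not agreement
with any individual patient geometry; the DRF and deformation
discrepancies discussed above are exactly where the idealization and the
published experiment part ways.

## Numerical choices

Cross-section interpolation is log-log (48-point grids); transport tables
are linear on 256-point log-energy grids; the Woodcock majorant is
inflated by 10⁻⁹ so acceptance ratios stay ≤ 1. Shell profiles average
voxels within half a voxel of the target radius. DVH volume fractions are
renormalized to sum to exactly 1; TCP refinement invariance and the
single-bin closed form hold to 10⁻¹². Default problem sizes — 10⁶ histories
for test-suite MC runs, 4×10⁶ for the acceptance script, 256 polar bands
and 0.5 Gy bins for DVHs — keep the full suite under a few minutes on one
CPU while holding DRF statistical uncertainty near half a percent.
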
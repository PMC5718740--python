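# mammodose

Dose-perturbation and tumor-control analysis for balloon (MammoSite-type)
HDR ¹⁹²Ir breast brachytherapy.

In balloon brachytherapy for early-stage breast cancer, a 4–6 cm balloon is
placed in the lumpectomy cavity, filled with a saline/iodinated-contrast
mixture for CT visibility, and an HDR ¹⁹²Ir source dwells at its centre to
deliver 3.4 Gy × 10 fractions prescribed at 1 cm from the balloon surface.
Three uncertainties perturb the delivered dose: the iodine in the filling
attenuates the therapeutic photons, the source can sit off-centre, and the
balloon can deform. This package quantifies each effect and folds them into
a tumor control probability (TCP), for medical physicists studying
treatment-quality margins and for anyone who wants a compact, tested,
desk-scale photon Monte Carlo with a radiobiology chain on top.

## What it computes

**Dose reduction factor (DRF)** — the ratio of dose with contrast filling to
dose with saline filling at the same point,

    DRF = D(E, d, x, C) / D(E, d, x, 0)

evaluated at x = 1 cm from the surface of a balloon of diameter d filled at
concentration C, from paired common-random-number photon Monte Carlo runs
(Woodcock tracking, Klein–Nishina incoherent scattering, form-factor
coherent scattering, kerma scoring on a 0.15 cm voxel grid, 34-line ¹⁹²Ir
spectrum).

**Source-shift ratios** — dose enhancement/reduction at the prescription
radius for a source displaced s mm: ((R+10)/(R+10∓s))² with R the balloon
radius in mm, optionally modulated by a radial dose function g(r).

**TCP** — from a differential DVH of the PTV (the 1 cm tissue shell around
the balloon): per dose bin D_i with fraction size d_i = D_i/n,

    BED_i = D_i [1 + G d_i/(α/β)]
    ln S_i = −α BED_i + γT
    TCP    = exp(−k Σ v_i S_i)

with the protraction factor G = (2/(nμT_f))[1 − (1/(μT_f))(1 − e^(−μT_f))]
and defaults k = 200, α = 0.3 Gy⁻¹, β = 0.03 Gy⁻², T_d = 15 d (γ = ln2/T_d),
T_½ = 1 h (μ = 0.69 h⁻¹), T_f = 0.17 h, n = 10, d = 3.4 Gy.

**TLD calibration arithmetic** — SCF/BCF/readout processing of
thermoluminescent dosimeter batches and the measurement-side DRF, runnable
on synthetic readings.

## Worked example

```python
from mammodose import materials as M, phantom as P, mc_transport as mc
from mammodose import analytic_dose as A, dvh_radiobio as RB

water, spectrum = M.water(), M.ir192_spectrum()
fill = M.contrast_mixture(100)          # pure iopromide, 48.1% iodine, 1.409 g/cc

cfg = mc.McConfig(n_histories=1_000_000, seed=42)
maj = [water, fill]                     # shared majorant -> common random numbers
bal_c, bal_s = P.BalloonGeometry(4.0, fill), P.BalloonGeometry(4.0, water)
g_c = mc.run_mc(P.build_phantom(bal_c, water, 7.0), mc.SourceModel(), spectrum,
                config=cfg, majorant_materials=maj)
g_s = mc.run_mc(P.build_phantom(bal_s, water, 7.0), mc.SourceModel(), spectrum,
                config=cfg, majorant_materials=maj)
res = mc.drf(mc.radial_profile(g_c, bal_c, [1.0]),
             mc.radial_profile(g_s, bal_s, [1.0]), 1.0)
print(f"DRF = {res.value:.4f} +- {res.rel_uncertainty:.4f}")

dvh = A.analytic_dvh(P.BalloonGeometry(4.0, water), drf=0.982)   # 15% contrast
print(f"TCP = {100 * RB.tcp_from_dvh(dvh).tcp:.2f}%")
```

prints (a few seconds on one CPU):

```
DRF = 0.8756 +- 0.0078
TCP = 99.87%
```

The DRF says an undiluted-contrast filling costs ~12% of the dose at the
prescription point — which is why concentrations of 15% or less (DRF ≈ 0.97,
≈ 2–3% dose loss) are recommended in practice. The TCP says that at 15%
concentration, with the source centred and the balloon spherical, tumor
control is essentially unimpaired.

The numbered scripts under `analysis/` run the full study — mixture table,
water-phantom validation, the 3 × 3 DRF grid, shift ratios with a TG-40
±15% tolerance report, the deformation × concentration × diameter TCP grid,
and the TLD chain — writing CSV tables to `results/`.

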
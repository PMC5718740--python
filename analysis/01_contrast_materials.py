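"""Contrast-solution compositions and their photon attenuation.

Builds the saline/iopromide mixture table (15/50/100% plus pure compound),
tabulates linear attenuation coefficients over the Ir-192 energy range, and
reports the narrow-beam primary attenuation a 2 cm contrast path adds over
water -- the first-order driver of the dose reduction at the prescription
point.

Writes results/contrast_materials.csv and results/attenuation_vs_energy.csv.
"""
import pathlib

import numpy as np
import pandas as pd

from mammodose import materials as M

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    rows = []
    for pct in (0, 15, 50, 100):
        m = M.contrast_mixture(pct)
        row = {"concentration_pct": pct, "density_g_cm3": round(m.density, 4)}
        row.update({el: round(100 * f, 2) for el, f in sorted(m.mass_fractions.items())})
        rows.append(row)
    comp = pd.DataFrame(rows).fillna(0.0)
    comp.to_csv(RESULTS / "contrast_materials.csv", index=False)
    print("Mixture compositions (% by weight):")
    print(comp.to_string(index=False))

    spectrum = M.ir192_spectrum()
    energies = np.linspace(0.06, 0.885, 100)
    att = pd.DataFrame({"energy_MeV": energies})
    for pct in (0, 15, 50, 100):
        att[f"mu_{pct}pct_per_cm"] = M.linear_mu(M.contrast_mixture(pct), energies)
    att.to_csv(RESULTS / "attenuation_vs_energy.csv", index=False)

    print(f"\nIr-192 spectrum: {spectrum.energies.size} lines, "
          f"mean energy {spectrum.mean_energy*1000:.0f} keV")
    print("\nPrimary transmission of a 2 cm balloon path relative to saline")
    print("(spectrum-weighted, narrow beam):")
    w = M.water()
    mu_w = M.linear_mu(w, spectrum.energies)
    p = spectrum.probabilities
    for pct in (15, 50, 100):
        mu_c = M.linear_mu(M.contrast_mixture(pct), spectrum.energies)
        ratio = np.sum(p * np.exp(-2 * mu_c)) / np.sum(p * np.exp(-2 * mu_w))
        print(f"  {pct:>3}% contrast: {ratio:.3f}")
    print("\nThe iodine content dominates below ~0.3 MeV (photoelectric ~E^-3);")
    print("above that the extra electron density of the denser filling takes over.")


if __name__ == "__main__":
    main()
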
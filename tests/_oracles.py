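"""Independent oracles used only by the test suite.

The point-kernel oracle predicts the uniform-water dose profile of the
Ir-192 line spectrum from first-collision kerma times a Berger-form
buildup factor, B(mu r) = 1 + a * mu*r * exp(b * mu*r), with (a, b)
interpolated from approximate fits to standard point-isotropic
energy-absorption buildup compilations for water.  It shares only the
cross-section fixtures with the transport code -- no transport logic.
"""
import numpy as np

from mammodose import materials as M

# energy MeV -> Berger (a, b) for water, point isotropic source
_BERGER = np.array(
    [
        # E       a      b
        [0.08, 2.00, 0.35],
        [0.15, 1.75, 0.28],
        [0.30, 1.55, 0.18],
        [0.50, 1.25, 0.145],
        [0.662, 1.12, 0.16],
        [1.00, 0.89, 0.19],
    ]
)


def berger_ab(e_mev):
    loge = np.log(np.asarray(e_mev, dtype=float))
    a = np.interp(loge, np.log(_BERGER[:, 0]), _BERGER[:, 1])
    b = np.interp(loge, np.log(_BERGER[:, 0]), _BERGER[:, 2])
    return a, b


def point_kernel_water_dose(r_cm, spectrum=None):
    """Water collision kerma vs r for a point source (arbitrary units)."""
    if spectrum is None:
        spectrum = M.ir192_spectrum()
    w = M.water()
    e = spectrum.energies
    p = spectrum.probabilities
    mu = M.linear_mu(w, e)
    mu_tr = M.mu_tr_over_rho(w, e)
    a, b = berger_ab(e)
    r = np.atleast_1d(np.asarray(r_cm, dtype=float))
    out = np.empty_like(r)
    for i, ri in enumerate(r):
        mur = mu * ri
        buildup = 1.0 + a * mur * np.exp(b * mur)
        out[i] = np.sum(p * e * mu_tr * np.exp(-mur) * buildup) / (4 * np.pi * ri**2)
    return out


def brute_force_mu_over_rho(material, e_mev, channel="total"):
    """Mixture rule evaluated element by element, straight from the tables."""
    total = 0.0
    for el, wfrac in material.mass_fractions.items():
        data = M.load_element(el)
        total += wfrac * data.mu_rho(e_mev, channel)
    return total
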
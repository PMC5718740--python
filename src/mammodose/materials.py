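"""Materials, mixtures, and photon attenuation data.

This module provides the material model for balloon-brachytherapy dose
calculations: elemental mass attenuation coefficients (per interaction
channel) on a 0.05-1.0 MeV grid, the iopromide contrast compound
(C18H24I3N3O8), the volume-percent contrast/water mixture rule used to fill
the balloon, and the Ir-192 photon line spectrum.

Mixture arithmetic follows the convention of the source-modelling literature
for contrast solutions: mass fractions mix linearly in the stated
concentration, density mixes volume-linearly.  Elemental data are shipped as
plain-text fixtures under ``mammodose/data/xsec`` (see
``scripts/generate_xsec_tables.py`` for their provenance).
"""
from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "ATOMIC_WEIGHTS",
    "ElementData",
    "Material",
    "PhotonSpectrum",
    "compound_mass_fractions",
    "contrast_mixture",
    "water",
    "saline",
    "wax",
    "mu_over_rho",
    "linear_mu",
    "mu_tr_over_rho",
    "compton_transfer_fraction",
    "ir192_spectrum",
    "material_to_text",
    "material_from_text",
    "spectrum_to_text",
    "spectrum_from_text",
]

ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Cl": 35.45,
    "I": 126.904,
}

IOPROMIDE_FORMULA: dict[str, int] = {"C": 18, "H": 24, "I": 3, "N": 3, "O": 8}
IOPROMIDE_DENSITY = 1.409  # g/cm^3
WATER_DENSITY = 1.000  # g/cm^3 (Table-style mixture arithmetic)

_CHANNELS = ("photoelectric", "incoherent", "coherent")


@dataclass(frozen=True)
class ElementData:
    """Per-element mass attenuation coefficients on an energy grid.

    All coefficients are in cm^2/g; the grid covers 0.05-1.0 MeV which
    brackets the 0.060-0.885 MeV Ir-192 spectrum.
    """

    symbol: str
    atomic_weight: float
    energies: np.ndarray
    photoelectric: np.ndarray
    incoherent: np.ndarray
    coherent: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.incoherent + self.coherent

    def mu_rho(self, energy_mev, channel: str = "total"):
        """Log-log interpolated mass attenuation coefficient (cm^2/g)."""
        e = np.asarray(energy_mev, dtype=float)
        _check_range(e, self.energies)
        table = self.total if channel == "total" else getattr(self, channel)
        # coherent/photoelectric can be ~0 for H; guard the log
        safe = np.maximum(table, 1e-300)
        out = np.exp(np.interp(np.log(e), np.log(self.energies), np.log(safe)))
        out = np.where(out <= 1e-280, 0.0, out)
        return float(out) if np.isscalar(energy_mev) else out


def _check_range(e: np.ndarray, grid: np.ndarray) -> None:
    if np.any(e < grid[0] - 1e-12) or np.any(e > grid[-1] + 1e-12):
        raise ValueError(
            f"energy outside tabulated range [{grid[0]:.3f}, {grid[-1]:.3f}] MeV"
        )


def _read_data_text(name: str) -> str:
    return resources.files("mammodose.data").joinpath(name).read_text()


@functools.lru_cache(maxsize=None)
def load_element(symbol: str) -> ElementData:
    text = _read_data_text(f"xsec/{symbol}.csv")
    rows = np.loadtxt(
        io.StringIO(text), delimiter=",", skiprows=2
    )
    return ElementData(
        symbol=symbol,
        atomic_weight=ATOMIC_WEIGHTS[symbol],
        energies=rows[:, 0],
        photoelectric=rows[:, 1],
        incoherent=rows[:, 2],
        coherent=rows[:, 3],
    )


@functools.lru_cache(maxsize=None)
def load_form_factor(symbol: str) -> tuple[np.ndarray, np.ndarray]:
    """Squared atomic form factor F^2 vs x^2 (x = sin(theta/2)/lambda, 1/A),
    used for coherent-scatter angular sampling."""
    rows = np.loadtxt(
        io.StringIO(_read_data_text(f"xsec/{symbol}_ff.csv")),
        delimiter=",",
        skiprows=2,
    )
    return rows[:, 0], rows[:, 1]


@functools.lru_cache(maxsize=None)
def _transfer_table() -> tuple[np.ndarray, np.ndarray]:
    rows = np.loadtxt(
        io.StringIO(_read_data_text("xsec/compton_transfer.csv")),
        delimiter=",",
        skiprows=2,
    )
    return rows[:, 0], rows[:, 1]


def compton_transfer_fraction(energy_mev):
    """Mean fraction of photon energy transferred to the Compton electron."""
    grid, frac = _transfer_table()
    e = np.asarray(energy_mev, dtype=float)
    _check_range(e, grid)
    out = np.interp(np.log(e), np.log(grid), frac)
    return float(out) if np.isscalar(energy_mev) else out


@dataclass(frozen=True)
class Material:
    """A named medium: elemental mass fractions plus mass density (g/cm^3)."""

    name: str
    mass_fractions: Mapping[str, float]
    density: float

    def __post_init__(self):
        object.__setattr__(self, "mass_fractions", dict(self.mass_fractions))
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.mass_fractions:
            total = sum(self.mass_fractions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"mass fractions sum to {total}, not 1")
            unknown = set(self.mass_fractions) - set(ATOMIC_WEIGHTS)
            if unknown:
                raise ValueError(f"no cross-section data for element(s) {unknown}")
        elif self.density > 0:
            raise ValueError("non-vacuum material needs mass fractions")


def water() -> Material:
    w_h = 2 * ATOMIC_WEIGHTS["H"] / (2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"])
    return Material("water", {"H": w_h, "O": 1.0 - w_h}, WATER_DENSITY)


def saline(nacl_fraction: float = 0.009) -> Material:
    """Physiological saline.  Dosimetrically treated as water; the optional
    NaCl admixture (0.9% by mass) is available for sensitivity checks."""
    if nacl_fraction == 0.0:
        return Material("saline", water().mass_fractions, WATER_DENSITY)
    w = water().mass_fractions
    a_na, a_cl = ATOMIC_WEIGHTS["Na"], ATOMIC_WEIGHTS["Cl"]
    f_na = nacl_fraction * a_na / (a_na + a_cl)
    f_cl = nacl_fraction * a_cl / (a_na + a_cl)
    rest = 1.0 - nacl_fraction
    return Material(
        "saline",
        {"H": w["H"] * rest, "O": w["O"] * rest, "Na": f_na, "Cl": f_cl},
        1.005,
    )


def wax(density: float = 0.926) -> Material:
    """Paraffin/bees-wax tissue substitute modelled as CH2."""
    a_c, a_h = ATOMIC_WEIGHTS["C"], ATOMIC_WEIGHTS["H"]
    w_c = a_c / (a_c + 2 * a_h)
    return Material("wax", {"C": w_c, "H": 1.0 - w_c}, density)


def compound_mass_fractions() -> Material:
    """Pure iopromide contrast compound (C18H24I3N3O8, 1.409 g/cm^3)."""
    masses = {el: n * ATOMIC_WEIGHTS[el] for el, n in IOPROMIDE_FORMULA.items()}
    mw = sum(masses.values())
    return Material(
        "iopromide", {el: m / mw for el, m in masses.items()}, IOPROMIDE_DENSITY
    )


def contrast_mixture(concentration_pct: float) -> Material:
    """Contrast/water mixture at the given volume-percent concentration.

    Mass fractions mix linearly in the concentration, density mixes
    volume-linearly; this is the arithmetic that reproduces the published
    contrast-solution composition table.
    """
    if not 0.0 <= concentration_pct <= 100.0:
        raise ValueError("concentration must be in [0, 100] %")
    c = concentration_pct / 100.0
    comp = compound_mass_fractions()
    w = water()
    fractions: dict[str, float] = {}
    for el in set(comp.mass_fractions) | set(w.mass_fractions):
        fractions[el] = c * comp.mass_fractions.get(el, 0.0) + (1.0 - c) * (
            w.mass_fractions.get(el, 0.0)
        )
    density = c * comp.density + (1.0 - c) * w.density
    return Material(f"contrast_{concentration_pct:g}pct", fractions, density)


def mu_over_rho(material: Material, energy_mev, channel: str = "total"):
    """Mass attenuation coefficient of a mixture, Sum_i w_i (mu/rho)_i."""
    if channel not in _CHANNELS + ("total",):
        raise ValueError(f"unknown channel {channel!r}")
    e = np.asarray(energy_mev, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for el, w in material.mass_fractions.items():
        out = out + w * load_element(el).mu_rho(e, channel)
    return float(out) if np.isscalar(energy_mev) else out


def linear_mu(material: Material, energy_mev, channel: str = "total"):
    """Linear attenuation coefficient (1/cm)."""
    if material.density == 0.0:
        e = np.asarray(energy_mev, dtype=float)
        return 0.0 if np.isscalar(energy_mev) else np.zeros_like(e)
    return mu_over_rho(material, energy_mev, channel) * material.density


def mu_tr_over_rho(material: Material, energy_mev):
    """Mass energy-transfer coefficient (cm^2/g) under the kerma model:
    photoelectric events deposit the full photon energy locally, incoherent
    events the Klein-Nishina mean electron energy, coherent events nothing."""
    tau = mu_over_rho(material, energy_mev, "photoelectric")
    incoh = mu_over_rho(material, energy_mev, "incoherent")
    return tau + incoh * compton_transfer_fraction(energy_mev)


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon line spectrum (energies in MeV, weights normalizable)."""

    energies: np.ndarray
    relative_intensities: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.relative_intensities, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("energies and intensities must be equal-length 1-D")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("intensities must be >= 0 and normalizable")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "relative_intensities", w)

    @property
    def probabilities(self) -> np.ndarray:
        w = self.relative_intensities
        return w / w.sum()

    @property
    def mean_energy(self) -> float:
        return float(np.dot(self.probabilities, self.energies))


@functools.lru_cache(maxsize=None)
def ir192_spectrum() -> PhotonSpectrum:
    """The shipped Ir-192 line spectrum: 34 bins on [0.060, 0.885] MeV."""
    rows = np.loadtxt(
        io.StringIO(_read_data_text("ir192_spectrum.csv")), delimiter=",", skiprows=6
    )
    return PhotonSpectrum(rows[:, 0], rows[:, 1])


# -- plain-text serialization -------------------------------------------------

def material_to_text(material: Material) -> str:
    lines = [f"material {material.name}", f"density {material.density!r}"]
    for el in sorted(material.mass_fractions):
        lines.append(f"{el} {material.mass_fractions[el]!r}")
    return "\n".join(lines) + "\n"


def material_from_text(text: str) -> Material:
    name = None
    density = None
    fractions: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split(maxsplit=1)
        if key == "material":
            name = value
        elif key == "density":
            density = float(value)
        else:
            fractions[key] = float(value)
    if name is None or density is None:
        raise ValueError("missing material name or density")
    return Material(name, fractions, density)


def spectrum_to_text(spectrum: PhotonSpectrum) -> str:
    lines = ["energy_MeV intensity"]
    for e, w in zip(spectrum.energies, spectrum.relative_intensities):
        lines.append(f"{float(e)!r} {float(w)!r}")
    return "\n".join(lines) + "\n"


def spectrum_from_text(text: str) -> PhotonSpectrum:
    es, ws = [], []
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        e, w = line.split()
        es.append(float(e))
        ws.append(float(w))
    return PhotonSpectrum(np.array(es), np.array(ws))
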
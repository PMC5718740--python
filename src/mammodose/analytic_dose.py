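"""Analytic point-source dose model, source-shift ratios, and analytic DVHs.

The balloon treatment prescribes 3.4 Gy per fraction at 1 cm from the
balloon surface.  Around a point source the dose falls essentially as the
inverse square of the distance; in water the radial dose function g(r)
(attenuation vs scatter build-up) is nearly flat over 1-7 cm, so g == 1 is
the default and a tabulated g(r) (e.g. from a Monte Carlo water run) can be
plugged in.

The differential DVH over the 1 cm PTV shell is computed with exact
analytic shell volumes.  Balloon deformation (hemispherical outward,
cosine-tapered at the equator) displaces tissue radially: tissue nominally
at radius r on the deformed side sits at r + delta(theta) and receives the
dose of its actual radius, while the dwell position and the prescription
remain those of the nominal spherical plan.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import BalloonGeometry, PTV_THICKNESS_CM

__all__ = [
    "PointSourceModel",
    "DVH",
    "point_dose",
    "shift_ratios",
    "analytic_dvh",
    "dvh_to_csv",
    "dvh_from_csv",
]

PRESCRIPTION_GY_PER_FRACTION = 3.4
DEFAULT_N_FRACTIONS = 10
DEFAULT_BIN_WIDTH_GY = 0.5


@dataclass(frozen=True)
class PointSourceModel:
    """Point-source dose model: normalization at the prescription distance
    times inverse square, optionally modulated by a tabulated g(r)."""

    normalization_gy: float = PRESCRIPTION_GY_PER_FRACTION
    radial_r_cm: np.ndarray | None = None
    radial_g: np.ndarray | None = None

    def __post_init__(self):
        if self.normalization_gy <= 0:
            raise ValueError("normalization must be > 0")
        if (self.radial_r_cm is None) != (self.radial_g is None):
            raise ValueError("provide both radial_r_cm and radial_g, or neither")
        if self.radial_g is not None and np.any(np.asarray(self.radial_g) <= 0):
            raise ValueError("g(r) must be > 0")

    def g(self, r_cm):
        if self.radial_g is None:
            return np.ones_like(np.asarray(r_cm, dtype=float))
        return np.interp(np.asarray(r_cm, dtype=float), self.radial_r_cm, self.radial_g)


@dataclass
class DVH:
    """Differential dose-volume histogram: bin dose (Gy, total) and the
    volume fraction of the structure in each bin."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose_gy, dtype=float)
        v = np.asarray(self.volume_fraction, dtype=float)
        if d.shape != v.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("dose and volume arrays must be equal-length 1-D")
        if np.any(v < -1e-15):
            raise ValueError("volume fractions must be >= 0")
        order = np.argsort(d)
        object.__setattr__(self, "dose_gy", d[order])
        object.__setattr__(self, "volume_fraction", np.maximum(v[order], 0.0))

    @property
    def total_volume(self) -> float:
        return float(self.volume_fraction.sum())

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, volume fraction receiving >= dose); monotone non-increasing."""
        v_above = self.total_volume - np.concatenate(
            [[0.0], np.cumsum(self.volume_fraction)[:-1]]
        )
        return self.dose_gy, v_above

    def scaled(self, factor: float) -> "DVH":
        return DVH(self.dose_gy * factor, self.volume_fraction.copy())


def point_dose(
    r_cm,
    model: PointSourceModel = PointSourceModel(),
    balloon: BalloonGeometry | None = None,
    balloon_radius_cm: float | None = None,
):
    """Dose per fraction (Gy) at radius r from the source.

    Normalized to ``model.normalization_gy`` at the prescription radius
    R + 1 cm, where R is the balloon radius.
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be > 0")
    if balloon_radius_cm is None:
        if balloon is None:
            raise ValueError("need a balloon (or its radius)")
        balloon_radius_cm = balloon.radius_cm
    r_presc = balloon_radius_cm + PTV_THICKNESS_CM
    out = model.normalization_gy * (r_presc / r) ** 2 * model.g(r) / model.g(r_presc)
    return float(out) if np.isscalar(r_cm) else out


def shift_ratios(
    balloon_diameter_cm: float,
    shift_mm: float,
    model: PointSourceModel = PointSourceModel(),
) -> tuple[float, float]:
    """Dose enhancement and reduction ratios for a source shifted by s mm.

    At the prescription distance R+1 cm from the balloon centre, a shift s
    moves the source closer to one side (dose enhancement, distance
    R+1cm - s) and farther from the opposite side (dose reduction,
    distance R+1cm + s).
    """
    if shift_mm < 0:
        raise ValueError("shift must be >= 0")
    r_presc = balloon_diameter_cm / 2.0 + PTV_THICKNESS_CM
    s = shift_mm / 10.0
    if r_presc - s <= 0:
        raise ValueError("shift places the source beyond the prescription point")
    radius = balloon_diameter_cm / 2.0
    d0 = point_dose(r_presc, model, balloon_radius_cm=radius)
    enh = point_dose(r_presc - s, model, balloon_radius_cm=radius) / d0
    red = point_dose(r_presc + s, model, balloon_radius_cm=radius) / d0
    return float(enh), float(red)


def _band_histogram(edges, r_in, r_out, dose_of_r, n_sub=64):
    """Exact shell volumes per dose bin for a radial band (r_in, r_out] with
    monotone-decreasing dose(r); returns per-bin volumes (abs units r^3)."""
    vols = np.zeros(edges.size - 1)
    # dose is monotone decreasing in r: invert on a fine radial partition
    r_fine = np.linspace(r_in, r_out, n_sub + 1)
    d_fine = dose_of_r(r_fine)
    for i in range(n_sub):
        d_hi, d_lo = d_fine[i], d_fine[i + 1]
        v_seg = r_fine[i + 1] ** 3 - r_fine[i] ** 3
        if d_hi <= d_lo + 1e-15:  # flat segment
            j = np.clip(np.searchsorted(edges, 0.5 * (d_hi + d_lo)) - 1, 0, vols.size - 1)
            vols[j] += v_seg
            continue
        # split the segment at bin edges crossing (d_lo, d_hi)
        cross = edges[(edges > d_lo) & (edges < d_hi)]
        cuts = np.concatenate([[d_lo], cross, [d_hi]])
        # radius at each dose cut by local inversion (linear in this segment;
        # higher dose corresponds to smaller radius)
        r_cuts = np.interp(cuts, [d_lo, d_hi], [r_fine[i + 1], r_fine[i]])
        for a, b, dm in zip(r_cuts[:-1], r_cuts[1:], 0.5 * (cuts[:-1] + cuts[1:])):
            j = np.clip(np.searchsorted(edges, dm) - 1, 0, vols.size - 1)
            vols[j] += abs(b**3 - a**3)
    return vols


def analytic_dvh(
    balloon: BalloonGeometry,
    model: PointSourceModel = PointSourceModel(),
    drf: float = 1.0,
    n_fractions: int = DEFAULT_N_FRACTIONS,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    n_polar: int = 256,
) -> DVH:
    """Differential DVH of the PTV shell under the analytic dose model.

    Total dose at radius r is ``n_fractions * point_dose(r) * drf``.  For a
    deformed balloon the displaced hemisphere's tissue at nominal radius r
    sits at r + delta(theta) (delta = deformation tapered by cos theta) and
    receives the dose of its actual radius; the PTV follows the deformed
    surface while the prescription stays that of the nominal spherical plan.
    Volume fractions sum to exactly 1.
    """
    if not 0.0 < drf <= 1.0:
        raise ValueError("drf must be in (0, 1]")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    if balloon.radius_cm <= 0:
        raise ValueError("empty PTV: balloon has zero radius")
    R = balloon.radius_cm

    def total_dose(r):
        return n_fractions * drf * point_dose(r, model, balloon_radius_cm=R)

    d_max = total_dose(R)  # at the nominal balloon surface
    d_min = total_dose(R + PTV_THICKNESS_CM + balloon.deformation_mm / 10.0)
    lo = np.floor(d_min / bin_width_gy) * bin_width_gy
    hi = np.ceil(d_max / bin_width_gy + 1e-9) * bin_width_gy
    edges = np.arange(lo, hi + bin_width_gy / 2.0, bin_width_gy)
    vols = np.zeros(edges.size - 1)

    if balloon.deformation_mode == "none" or balloon.deformation_mm == 0:
        vols += _band_histogram(edges, R, R + PTV_THICKNESS_CM, total_dose)
    else:
        # polar bands: delta = d * max(cos theta, 0) on the displaced side
        mu_edges = np.linspace(-1.0, 1.0, n_polar + 1)
        d_cm = balloon.deformation_mm / 10.0
        for lo_mu, hi_mu in zip(mu_edges[:-1], mu_edges[1:]):
            frac = (hi_mu - lo_mu) / 2.0  # solid-angle fraction of the band
            delta = d_cm * max(0.0, 0.5 * (lo_mu + hi_mu))
            vols += frac * _band_histogram(
                edges, R + delta, R + delta + PTV_THICKNESS_CM, total_dose
            )

    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = vols > 0
    return DVH(centers[keep], vols[keep] / vols.sum())


def dvh_to_csv(dvh: DVH, path: str) -> None:
    """Write the differential DVH plus its cumulative view as CSV."""
    _, cum = dvh.cumulative()
    with open(path, "w") as fh:
        fh.write("dose_Gy,volume_fraction,cumulative_volume_fraction\n")
        for d, v, c in zip(dvh.dose_gy, dvh.volume_fraction, cum):
            fh.write(f"{float(d)!r},{float(v)!r},{float(c)!r}\n")


def dvh_from_csv(path: str) -> DVH:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return DVH(rows[:, 0], rows[:, 1])
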
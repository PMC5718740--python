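"""Simplified voxel photon Monte Carlo for Ir-192 balloon dosimetry.

Analog photon transport through a :class:`~mammodose.phantom.VoxelPhantom`
with Woodcock (delta) tracking, free-electron Klein-Nishina incoherent
scattering, local photoelectric absorption and (optional) coherent
scattering.  Electrons are not transported: dose is scored in the kerma
approximation, which is adequate here because secondary-electron ranges at
Ir-192 energies (< 2 mm in water) are below the 1.5 mm scoring voxel scale.

Two estimators are provided:

``track_length``
    expected-value scoring at every Woodcock flight point,
    ``E * (mu_tr/rho) / mu_majorant`` per point (collision-density form of
    the track-length kerma estimator); the default, much lower variance.
``interaction_site``
    energy transferred deposited at real interaction sites only.

Runs are reproducible bit-for-bit for a fixed seed (single-threaded,
seeded batches).  Paired runs for dose-reduction factors share one
majorant table and one seed so that common random numbers collapse the
variance of the ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .materials import (
    ATOMIC_WEIGHTS,
    Material,
    PhotonSpectrum,
    linear_mu,
    load_form_factor,
    mu_over_rho,
    mu_tr_over_rho,
)
from .phantom import BalloonGeometry, VoxelPhantom

__all__ = [
    "TransportSettings",
    "McConfig",
    "SourceModel",
    "DoseGrid",
    "DoseProfile",
    "run_mc",
    "radial_profile",
    "drf",
    "DrfResult",
    "uncertainty_at",
]

_MEC2 = 0.51099895
_N_EGRID = 256
_HC_MEV_A = 0.012398420  # h*c in MeV*Angstrom, for momentum-transfer units


@dataclass(frozen=True)
class TransportSettings:
    """Physics switches.  ``electron_transport`` documents the full-transport
    setting of general-purpose codes (AE=ECUT=0.521 MeV); it is not
    implemented here -- the kerma approximation stands in for it."""

    photon_cutoff_mev: float = 0.06
    electron_transport: bool = False
    coherent_scatter: bool = True

    def __post_init__(self):
        if self.photon_cutoff_mev <= 0:
            raise ValueError("photon cutoff must be > 0")
        if self.electron_transport:
            raise NotImplementedError(
                "electron transport is out of scope; dose is scored in the "
                "kerma approximation"
            )


@dataclass(frozen=True)
class McConfig:
    n_histories: int = 1_000_000
    seed: int = 0
    estimator: str = "track_length"
    batches: int = 10

    def __post_init__(self):
        if self.n_histories < 1:
            raise ValueError("need at least one history")
        if self.estimator not in ("track_length", "interaction_site"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.batches < 1:
            raise ValueError("need at least one batch")


@dataclass(frozen=True)
class SourceModel:
    """Uniformly, isotropically radiating parallelepiped source capsule."""

    extent_mm: tuple[float, float, float] = (0.9, 0.9, 4.5)
    position_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError("source extent components must be > 0")

    @classmethod
    def from_balloon(cls, balloon: BalloonGeometry, extent_mm=(0.9, 0.9, 4.5)):
        return cls(extent_mm=tuple(extent_mm), position_cm=tuple(balloon.source_position_cm))


@dataclass
class DoseGrid:
    """Per-voxel dose (MeV/g per source photon) with batch statistics."""

    dose: np.ndarray
    rel_uncertainty: np.ndarray
    batch_dose: np.ndarray  # (batches, nx, ny, nz), float32
    voxel_size_cm: float
    origin_cm: tuple[float, float, float]

    @property
    def n_batches(self) -> int:
        return self.batch_dose.shape[0]


@dataclass
class DoseProfile:
    """Dose vs distance from the balloon surface."""

    distance_from_surface_cm: np.ndarray
    dose: np.ndarray
    rel_uncertainty: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distance_from_surface_cm, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be increasing")
        if np.any(~np.isfinite(self.dose)) or np.any(np.asarray(self.dose) < 0):
            raise ValueError("dose must be finite and >= 0")


@dataclass(frozen=True)
class DrfResult:
    value: float
    rel_uncertainty: float


def _material_tables(
    materials: list[Material],
    settings: TransportSettings,
    majorant_materials: list[Material] | None = None,
):
    """Tabulate linear channel coefficients on a log energy grid."""
    egrid = np.geomspace(0.05, 1.0, _N_EGRID)
    n_m = len(materials)
    mu_tot = np.empty((n_m, _N_EGRID))
    cum_pe = np.empty((n_m, _N_EGRID))
    cum_pi = np.empty((n_m, _N_EGRID))
    mutr_rho = np.empty((n_m, _N_EGRID))
    rho = np.array([m.density for m in materials])
    for i, mat in enumerate(materials):
        if mat.density == 0.0:
            mu_tot[i] = 0.0
            cum_pe[i] = 1.0
            cum_pi[i] = 1.0
            mutr_rho[i] = 0.0
            continue
        pe = linear_mu(mat, egrid, "photoelectric")
        inc = linear_mu(mat, egrid, "incoherent")
        coh = linear_mu(mat, egrid, "coherent") if settings.coherent_scatter else 0.0 * egrid
        tot = pe + inc + coh
        mu_tot[i] = tot
        cum_pe[i] = pe / tot
        cum_pi[i] = (pe + inc) / tot
        mutr_rho[i] = mu_tr_over_rho(mat, egrid)
    maj_set = list(materials) + list(majorant_materials or [])
    mu_maj = np.zeros(_N_EGRID)
    for mat in maj_set:
        if mat.density > 0:
            pe = linear_mu(mat, egrid, "photoelectric")
            inc = linear_mu(mat, egrid, "incoherent")
            coh = linear_mu(mat, egrid, "coherent") if settings.coherent_scatter else 0.0 * egrid
            mu_maj = np.maximum(mu_maj, pe + inc + coh)
    mu_maj *= 1.0 + 1e-9  # keep acceptance ratio strictly <= 1

    # per-material cumulative squared form factor over x^2, for coherent
    # angular sampling (EGS-style: sample x^2 from F^2, reject on Thomson)
    ff_x2, _ = load_form_factor("O")
    ff_cum = np.zeros((n_m, ff_x2.size))
    for i, mat in enumerate(materials):
        if not mat.mass_fractions:
            continue
        f2_mix = np.zeros_like(ff_x2)
        for el, w in mat.mass_fractions.items():
            x2_el, f2_el = load_form_factor(el)
            f2_mix += (w / ATOMIC_WEIGHTS[el]) * np.interp(ff_x2, x2_el, f2_el)
        ff_cum[i, 1:] = np.cumsum(
            0.5 * (f2_mix[1:] + f2_mix[:-1]) * np.diff(ff_x2)
        )
    return egrid, mu_tot, cum_pe, cum_pi, mutr_rho, rho, mu_maj, ff_x2, ff_cum


@njit(cache=True)
def _interp_m(arr, m, fe, nE):
    j = int(fe)
    if j < 0:
        return arr[m, 0]
    if j >= nE - 1:
        return arr[m, nE - 1]
    f = fe - j
    return arr[m, j] * (1.0 - f) + arr[m, j + 1] * f


@njit(cache=True)
def _interp_1(arr, fe, nE):
    j = int(fe)
    if j < 0:
        return arr[0]
    if j >= nE - 1:
        return arr[nE - 1]
    f = fe - j
    return arr[j] * (1.0 - f) + arr[j + 1] * f


@njit(cache=True)
def _run_batch(
    seed,
    n_hist,
    mat_idx,
    ox,
    oy,
    oz,
    vox,
    loge0,
    dloge,
    mu_tot,
    cum_pe,
    cum_pi,
    mutr_rho,
    rho,
    mu_maj,
    spec_e,
    spec_cdf,
    src_lo,
    src_size,
    ff_x2,
    ff_cum,
    cutoff,
    coherent_on,
    track_length,
    deposit,
):
    """Transport one batch; accumulate energy/(g/cm^3) scores in ``deposit``
    (divide by voxel volume afterwards to obtain MeV/g)."""
    np.random.seed(seed)
    nx, ny, nz = mat_idx.shape
    nE = mu_maj.shape[0]
    n_lines = spec_e.shape[0]
    for _ in range(n_hist):
        # sample line energy
        u = np.random.random()
        il = 0
        while il < n_lines - 1 and spec_cdf[il] < u:
            il += 1
        e = spec_e[il]
        # emission point uniform in the source parallelepiped
        x = src_lo[0] + np.random.random() * src_size[0]
        y = src_lo[1] + np.random.random() * src_size[1]
        z = src_lo[2] + np.random.random() * src_size[2]
        # isotropic direction
        wd = 2.0 * np.random.random() - 1.0
        phi = 2.0 * np.pi * np.random.random()
        s = np.sqrt(max(0.0, 1.0 - wd * wd))
        ud = s * np.cos(phi)
        vd = s * np.sin(phi)
        fe = (np.log(e) - loge0) / dloge
        mm = _interp_1(mu_maj, fe, nE)
        while True:
            step = -np.log(np.random.random()) / mm
            x += ud * step
            y += vd * step
            z += wd * step
            ix = int((x - ox) / vox)
            iy = int((y - oy) / vox)
            iz = int((z - oz) / vox)
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                break  # escaped
            m = mat_idx[ix, iy, iz]
            if track_length:
                deposit[ix, iy, iz] += e * _interp_m(mutr_rho, m, fe, nE) / mm
            mt = _interp_m(mu_tot, m, fe, nE)
            if np.random.random() * mm > mt:
                continue  # virtual collision
            q = np.random.random()
            p_pe = _interp_m(cum_pe, m, fe, nE)
            p_pi = _interp_m(cum_pi, m, fe, nE)
            if q < p_pe:
                # photoelectric: local absorption (fluorescence local too)
                if not track_length:
                    deposit[ix, iy, iz] += e / rho[m]
                break
            elif q < p_pi:
                # incoherent: Klein-Nishina sampling of E'/E
                k = e / _MEC2
                eps_min = 1.0 / (1.0 + 2.0 * k)
                a1 = -np.log(eps_min)
                a2 = 0.5 * (1.0 - eps_min * eps_min)
                while True:
                    if np.random.random() * (a1 + a2) < a1:
                        eps = eps_min * np.exp(a1 * np.random.random())
                    else:
                        eps = np.sqrt(
                            eps_min * eps_min
                            + (1.0 - eps_min * eps_min) * np.random.random()
                        )
                    t = (1.0 - eps) / (k * eps)
                    sin2 = t * (2.0 - t)
                    if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
                        break
                mu_s = 1.0 - t
                if not track_length:
                    deposit[ix, iy, iz] += e * (1.0 - eps) / rho[m]
                e = e * eps
                # rotate direction
                sint = np.sqrt(max(0.0, 1.0 - mu_s * mu_s))
                sphi = 2.0 * np.pi * np.random.random()
                cp = np.cos(sphi)
                sp = np.sin(sphi)
                denom = np.sqrt(max(1e-20, 1.0 - wd * wd))
                if denom < 1e-6:
                    ud = sint * cp
                    vd = sint * sp
                    wd = mu_s * (1.0 if wd > 0 else -1.0)
                else:
                    un = ud * mu_s + sint * (ud * wd * cp - vd * sp) / denom
                    vn = vd * mu_s + sint * (vd * wd * cp + ud * sp) / denom
                    wn = wd * mu_s - sint * denom * cp
                    norm = np.sqrt(un * un + vn * vn + wn * wn)
                    ud, vd, wd = un / norm, vn / norm, wn / norm
                if e < cutoff:
                    deposit[ix, iy, iz] += e / rho[m]
                    break
                fe = (np.log(e) - loge0) / dloge
                mm = _interp_1(mu_maj, fe, nE)
            else:
                # coherent: direction change only; angle from the material's
                # squared form factor (strongly forward at these energies)
                if not coherent_on:
                    continue
                xm2 = (e / _HC_MEV_A) ** 2  # x^2 at 180 degrees, 1/A^2
                nX = ff_x2.shape[0]
                jm = np.searchsorted(ff_x2, xm2)
                if jm >= nX:
                    cum_max = ff_cum[m, nX - 1]
                elif jm == 0:
                    cum_max = 0.0
                else:
                    f = (xm2 - ff_x2[jm - 1]) / (ff_x2[jm] - ff_x2[jm - 1])
                    cum_max = ff_cum[m, jm - 1] + f * (
                        ff_cum[m, jm] - ff_cum[m, jm - 1]
                    )
                while True:
                    target = np.random.random() * cum_max
                    jj = np.searchsorted(ff_cum[m], target)
                    if jj <= 0:
                        x2s = ff_x2[0]
                    elif jj >= nX:
                        x2s = min(ff_x2[nX - 1], xm2)
                    else:
                        df = ff_cum[m, jj] - ff_cum[m, jj - 1]
                        f = (target - ff_cum[m, jj - 1]) / df if df > 0 else 0.0
                        x2s = ff_x2[jj - 1] + f * (ff_x2[jj] - ff_x2[jj - 1])
                    mu_s = 1.0 - 2.0 * min(x2s / xm2, 1.0)
                    if np.random.random() <= 0.5 * (1.0 + mu_s * mu_s):
                        break
                sint = np.sqrt(max(0.0, 1.0 - mu_s * mu_s))
                sphi = 2.0 * np.pi * np.random.random()
                cp = np.cos(sphi)
                sp = np.sin(sphi)
                denom = np.sqrt(max(1e-20, 1.0 - wd * wd))
                if denom < 1e-6:
                    ud = sint * cp
                    vd = sint * sp
                    wd = mu_s * (1.0 if wd > 0 else -1.0)
                else:
                    un = ud * mu_s + sint * (ud * wd * cp - vd * sp) / denom
                    vn = vd * mu_s + sint * (vd * wd * cp + ud * sp) / denom
                    wn = wd * mu_s - sint * denom * cp
                    norm = np.sqrt(un * un + vn * vn + wn * wn)
                    ud, vd, wd = un / norm, vn / norm, wn / norm


def run_mc(
    phantom: VoxelPhantom,
    source: SourceModel,
    spectrum: PhotonSpectrum,
    settings: TransportSettings = TransportSettings(),
    config: McConfig = McConfig(),
    majorant_materials: list[Material] | None = None,
) -> DoseGrid:
    """Transport ``config.n_histories`` photons and score dose.

    ``majorant_materials`` lets paired (common-random-number) runs share a
    Woodcock majorant so that identical seeds follow identical flight
    geometry in both runs.
    """
    if settings.photon_cutoff_mev >= spectrum.energies.max():
        raise ValueError("photon cutoff above the spectrum maximum")
    egrid, mu_tot, cum_pe, cum_pi, mutr_rho, rho, mu_maj, ff_x2, ff_cum = _material_tables(
        phantom.material_table, settings, majorant_materials
    )
    loge0 = np.log(egrid[0])
    dloge = np.log(egrid[1]) - np.log(egrid[0])
    probs = spectrum.probabilities
    spec_cdf = np.cumsum(probs)
    spec_cdf[-1] = 1.0
    src_half = np.asarray(source.extent_mm) / 20.0  # mm -> half-extent in cm
    src_lo = np.asarray(source.position_cm) - src_half
    src_size = 2.0 * src_half

    n_b = config.batches
    per_batch = [config.n_histories // n_b] * n_b
    per_batch[0] += config.n_histories - sum(per_batch)
    track_length = config.estimator == "track_length"
    vol = phantom.voxel_size_cm**3

    batch_dose = np.empty((n_b,) + phantom.shape, dtype=np.float32)
    for b, n_h in enumerate(per_batch):
        deposit = np.zeros(phantom.shape, dtype=np.float64)
        _run_batch(
            (config.seed + 7919 * b) % 2**31,
            n_h,
            phantom.material_index,
            phantom.origin_cm[0],
            phantom.origin_cm[1],
            phantom.origin_cm[2],
            phantom.voxel_size_cm,
            loge0,
            dloge,
            mu_tot,
            cum_pe,
            cum_pi,
            mutr_rho,
            rho,
            mu_maj,
            spectrum.energies,
            spec_cdf,
            src_lo,
            src_size,
            ff_x2,
            ff_cum,
            settings.photon_cutoff_mev,
            settings.coherent_scatter,
            track_length,
            deposit,
        )
        batch_dose[b] = (deposit / (vol * n_h)).astype(np.float32)

    dose = batch_dose.mean(axis=0, dtype=np.float64)
    if n_b > 1:
        sem = batch_dose.std(axis=0, ddof=1, dtype=np.float64) / np.sqrt(n_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(dose > 0, sem / dose, 0.0)
    else:
        rel = np.zeros_like(dose)
    return DoseGrid(
        dose=dose,
        rel_uncertainty=rel,
        batch_dose=batch_dose,
        voxel_size_cm=phantom.voxel_size_cm,
        origin_cm=phantom.origin_cm,
    )


def _radius_grid(grid: DoseGrid, center) -> np.ndarray:
    o = np.asarray(grid.origin_cm)
    axes = [
        o[d] + (np.arange(grid.dose.shape[d]) + 0.5) * grid.voxel_size_cm
        for d in range(3)
    ]
    c = np.asarray(center)
    return np.sqrt(
        (axes[0][:, None, None] - c[0]) ** 2
        + (axes[1][None, :, None] - c[1]) ** 2
        + (axes[2][None, None, :] - c[2]) ** 2
    )


def _shell_mask(grid: DoseGrid, balloon: BalloonGeometry, x: float) -> np.ndarray:
    r = _radius_grid(grid, balloon.center_cm)
    target = balloon.radius_cm + x
    return np.abs(r - target) <= grid.voxel_size_cm / 2.0


def radial_profile(
    grid: DoseGrid,
    balloon: BalloonGeometry,
    distances_cm,
    mode: str = "shell",
) -> DoseProfile:
    """Average dose at given distances from the nominal balloon surface.

    ``shell`` averages over full spherical shells one voxel thick (best
    statistics); ``axis`` averages only voxels near the +x axis,
    perpendicular to the source long axis, mimicking a detector column.
    """
    if mode not in ("shell", "axis"):
        raise ValueError(f"unknown profile mode {mode!r}")
    distances = np.asarray(distances_cm, dtype=float)
    r = _radius_grid(grid, balloon.center_cm)
    half_span = (np.asarray(grid.dose.shape) * grid.voxel_size_cm / 2.0).min()
    doses = np.empty_like(distances)
    uncs = np.empty_like(distances)
    for i, x in enumerate(distances):
        target = balloon.radius_cm + x
        if target >= half_span:
            raise ValueError(f"distance {x} cm outside the scored grid")
        mask = np.abs(r - target) <= grid.voxel_size_cm / 2.0
        if mode == "axis":
            o = np.asarray(grid.origin_cm)
            axes = [
                o[d] + (np.arange(grid.dose.shape[d]) + 0.5) * grid.voxel_size_cm
                for d in range(3)
            ]
            lateral = np.sqrt(
                (axes[1][None, :, None] - balloon.center_cm[1]) ** 2
                + (axes[2][None, None, :] - balloon.center_cm[2]) ** 2
            )
            near_axis = (lateral <= grid.voxel_size_cm) & (
                axes[0][:, None, None] > balloon.center_cm[0]
            )
            mask = mask & near_axis
        doses[i] = grid.dose[mask].mean()
        shell_means = grid.batch_dose[:, mask].mean(axis=1)
        if grid.n_batches > 1 and doses[i] > 0:
            uncs[i] = (
                shell_means.std(ddof=1) / np.sqrt(grid.n_batches) / doses[i]
            )
        else:
            uncs[i] = 0.0
    return DoseProfile(distances, doses, uncs)


def drf(
    contrast_profile: DoseProfile,
    saline_profile: DoseProfile,
    x_cm: float,
    paired: bool = True,
) -> DrfResult:
    """Dose reduction factor: contrast dose over saline dose at distance x.

    With ``paired=True`` the two runs are assumed to use common random
    numbers and the quoted uncertainty is the quadrature sum, which is then
    conservative (the true paired variance is smaller).
    """
    dc = contrast_profile.distance_from_surface_cm
    ds = saline_profile.distance_from_surface_cm
    if dc.shape != ds.shape or not np.allclose(dc, ds):
        raise ValueError("profiles are on different distance grids")
    idx = int(np.argmin(np.abs(dc - x_cm)))
    if abs(dc[idx] - x_cm) > 1e-9:
        raise ValueError(f"distance {x_cm} cm not on the profile grid")
    denom = saline_profile.dose[idx]
    if denom <= 0:
        raise ZeroDivisionError("saline dose is zero at the requested distance")
    value = contrast_profile.dose[idx] / denom
    unc = float(
        np.hypot(contrast_profile.rel_uncertainty[idx], saline_profile.rel_uncertainty[idx])
    )
    return DrfResult(float(value), unc)


def uncertainty_at(grid: DoseGrid, region: np.ndarray) -> float:
    """Fractional batch standard error of the mean dose in ``region``."""
    if grid.n_batches < 2:
        raise ValueError("need >= 2 batches for an uncertainty estimate")
    means = grid.batch_dose[:, region].mean(axis=1)
    mean = means.mean()
    if mean <= 0:
        return float("nan")
    return float(means.std(ddof=1) / np.sqrt(grid.n_batches) / mean)
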
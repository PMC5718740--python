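"""TLD calibration arithmetic and the measurement-side dose reduction factor.

Thermoluminescent dosimeter (TLD-100) readings are processed with the
standard batch-calibration chain: background subtraction, per-chip
sensitivity correction factors (SCF), a batch correction factor (BCF) for
reader drift between sessions, and finally the corrected readout
``TL_i = (R_i - R_bkg) * SCF_i * BCF``.  A synthetic-reading generator
emulates a realistic chip batch (lognormal per-chip sensitivity, sigma
~1.3%, plus reader noise) so the whole chain is executable without
hardware; dose response is treated as linear (valid below about 6 Gy).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TldReading",
    "CalibrationSet",
    "sensitivity_factors",
    "batch_correction",
    "corrected_readout",
    "measured_drf",
    "synthetic_readings",
    "readings_to_csv",
    "readings_from_csv",
]


@dataclass(frozen=True)
class TldReading:
    chip_id: str
    gross: float
    is_background: bool = False

    def __post_init__(self):
        if self.gross < 0:
            raise ValueError("gross reading must be >= 0")


@dataclass(frozen=True)
class CalibrationSet:
    readings: tuple[TldReading, ...]
    scf: dict[str, float]
    bcf: float = 1.0

    def __post_init__(self):
        if self.bcf <= 0:
            raise ValueError("BCF must be > 0")
        missing = [
            r.chip_id
            for r in self.readings
            if not r.is_background and r.chip_id not in self.scf
        ]
        if missing:
            raise ValueError(f"no SCF for chip(s) {missing}")


def _background(readings) -> float:
    bkg = [r.gross for r in readings if r.is_background]
    return float(np.mean(bkg)) if bkg else 0.0


def sensitivity_factors(readings: list[TldReading]) -> dict[str, float]:
    """Per-chip sensitivity correction factors SCF_i = Rbar / (R_i - R_bkg),
    with Rbar the background-subtracted batch mean of the exposed chips."""
    exposed = [r for r in readings if not r.is_background]
    if not exposed:
        raise ValueError("need at least one exposed chip")
    bkg = _background(readings)
    net = np.array([r.gross - bkg for r in exposed])
    if np.any(net <= 0):
        bad = [r.chip_id for r, n in zip(exposed, net) if n <= 0]
        raise ZeroDivisionError(f"chip reading(s) at or below background: {bad}")
    rbar = net.mean()
    return {r.chip_id: float(rbar / n) for r, n in zip(exposed, net)}


def batch_correction(expected_mean: float, measured_mean: float) -> float:
    """Batch correction factor BCF = Rbar_expected / Rbar_measured."""
    if measured_mean <= 0:
        raise ZeroDivisionError("measured mean must be > 0")
    return expected_mean / measured_mean


def corrected_readout(
    reading: TldReading, bkg: float, scf: float, bcf: float
) -> float:
    """Corrected thermoluminescent readout (R_i - R_bkg) * SCF_i * BCF."""
    net = reading.gross - bkg
    if net < 0:
        raise ValueError("reading below background")
    return net * scf * bcf


def measured_drf(contrast_readouts, saline_readouts) -> tuple[float, float]:
    """Dose reduction factor from corrected TLD readouts at one distance.

    Returns (ratio of means, fractional uncertainty from the pooled spread
    of the two samples).  Invariant to any common reader-gain factor.
    """
    c = np.asarray(contrast_readouts, dtype=float)
    s = np.asarray(saline_readouts, dtype=float)
    if c.size == 0 or s.size == 0:
        raise ValueError("need readouts in both groups")
    if s.mean() <= 0:
        raise ZeroDivisionError("saline mean readout is zero")
    value = c.mean() / s.mean()
    rel_c = c.std(ddof=1) / np.sqrt(c.size) / c.mean() if c.size > 1 else 0.0
    rel_s = s.std(ddof=1) / np.sqrt(s.size) / s.mean() if s.size > 1 else 0.0
    return float(value), float(value * np.hypot(rel_c, rel_s))


def synthetic_readings(
    true_doses_gy,
    rng: np.random.Generator,
    sensitivity_sigma: float = 0.013,
    reader_gain: float = 100.0,
    background_mean: float = 1.0,
    noise_sigma: float = 0.01,
    n_background: int = 3,
) -> list[TldReading]:
    """Generate a synthetic TLD batch: gross = true dose x lognormal chip
    sensitivity x gain + background, plus multiplicative reader noise.

    The 1.3% default sensitivity spread reproduces a realistic batch (SCFs
    within roughly [0.96, 1.06], mean ~1.0).
    """
    doses = np.asarray(true_doses_gy, dtype=float)
    sens = rng.lognormal(mean=0.0, sigma=sensitivity_sigma, size=doses.size)
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=doses.size)
    gross = doses * sens * noise * reader_gain + background_mean
    out = [
        TldReading(f"chip{i:03d}", float(g)) for i, g in enumerate(gross)
    ]
    for j in range(n_background):
        out.append(
            TldReading(
                f"bkg{j:03d}",
                float(background_mean * rng.lognormal(0.0, noise_sigma)),
                is_background=True,
            )
        )
    return out


def readings_to_csv(readings: list[TldReading], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chip_id,gross,is_background\n")
        for r in readings:
            fh.write(f"{r.chip_id},{r.gross!r},{int(r.is_background)}\n")


def readings_from_csv(path: str) -> list[TldReading]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chip, gross, is_bkg = line.strip().split(",")
            out.append(TldReading(chip, float(gross), bool(int(is_bkg))))
    return out
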
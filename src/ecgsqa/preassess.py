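"""Rule-based signal-quality pre-assessment.

Two cheap screens run before any feature extraction:

* **lead-off** — an electrode that has detached produces a constant
  voltage; a segment whose samples sit in flat runs for more than 80 %
  of its duration is rejected outright;
* **pure noise** — the diagnostic content of an ECG lives below 40 Hz,
  so the fraction of spectral power in 0-40 Hz (MPSQI) acts as a purity
  index; below 30 % the segment is treated as noise, not ECG.

Both thresholds are configurable; the defaults are the operating points
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from .io import EcgRecord, EcgSegment

FLAT_THRESHOLD = 0.8
MPSQI_THRESHOLD = 0.30
ECG_BAND_HZ = 40.0
#: flat-run amplitude tolerance, as a fraction of the segment's range
FLAT_EPS_REL = 1e-4


class Verdict(str, Enum):
    PASS = "PASS"
    REJECT_LEAD_OFF = "REJECT_LEAD_OFF"
    REJECT_PURE_NOISE = "REJECT_PURE_NOISE"


@dataclass
class PreassessResult:
    verdict: Verdict
    flat_fraction: float
    mpsqi: float | None = None


def _samples_fs(seg) -> tuple[np.ndarray, float]:
    if isinstance(seg, (EcgSegment, EcgRecord)):
        return np.asarray(seg.samples, dtype=float), float(seg.fs)
    raise TypeError("expected EcgSegment or EcgRecord")


def detect_lead_off(
    seg, flat_threshold: float = FLAT_THRESHOLD, eps: float | None = None
) -> tuple[bool, float]:
    """Flag a segment whose trace is constant for more than ``flat_threshold``.

    A sample belongs to a flat run when its difference to a neighbour is
    within ``eps``; ``eps`` defaults to ``FLAT_EPS_REL`` times the
    amplitude range (an all-constant trace has range 0 and counts whole).
    Returns ``(is_lead_off, flat_fraction)``.
    """
    x, _ = _samples_fs(seg)
    if x.size < 2:
        raise ValueError("segment too short for lead-off detection")
    rng = float(x.max() - x.min())
    if eps is None:
        eps = FLAT_EPS_REL * rng if rng > 0 else 0.0
    flat_step = np.abs(np.diff(x)) <= eps
    # a sample is "in a flat run" if either adjacent step is flat
    in_run = np.zeros(x.size, dtype=bool)
    in_run[:-1] |= flat_step
    in_run[1:] |= flat_step
    frac = float(in_run.mean())
    return frac > flat_threshold, frac


def mpsqi(seg, band_hz: float = ECG_BAND_HZ) -> float:
    """Fraction of spectral power below ``band_hz`` (0-40 Hz by default).

    Welch PSD with 2-s Hann windows at 50 % overlap; band energies are
    trapezoid-integrated, with the bin straddling the band edge split
    linearly. Values are in [0, 1]; clean ECG sits near 1, broadband
    noise near ``band_hz / nyquist``.
    """
    x, fs = _samples_fs(seg)
    if fs <= 2 * band_hz:
        raise ValueError(f"fs must exceed {2 * band_hz} Hz")
    if x.size < 256:
        raise ValueError("need at least 256 samples for a stable PSD")
    nperseg = min(int(2 * fs), x.size)
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    total = np.trapezoid(p, f)
    if total <= 0:
        return 0.0
    band = _band_power(f, p, 0.0, band_hz)
    return float(np.clip(band / total, 0.0, 1.0))


def _band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of the PSD over [lo, hi], splitting edge bins linearly."""
    hi = min(hi, f[-1])
    grid = np.union1d(f, [lo, hi])
    grid = grid[(grid >= lo) & (grid <= hi)]
    pg = np.interp(grid, f, p)
    return float(np.trapezoid(pg, grid))


def pnsqi(seg, threshold: float = MPSQI_THRESHOLD) -> bool:
    """True (pure noise) when the 0-40 Hz power fraction falls below ``threshold``."""
    return mpsqi(seg) < threshold


def preassess(
    seg,
    flat_threshold: float = FLAT_THRESHOLD,
    mpsqi_threshold: float = MPSQI_THRESHOLD,
) -> PreassessResult:
    """Run the two screens in order: lead-off first, then spectral purity.

    A segment that is both flat and noisy reports lead-off — the
    verdict ordering is fixed so results are deterministic.
    """
    is_flat, frac = detect_lead_off(seg, flat_threshold)
    if is_flat:
        return PreassessResult(Verdict.REJECT_LEAD_OFF, frac)
    m = mpsqi(seg)
    if m < mpsqi_threshold:
        return PreassessResult(Verdict.REJECT_PURE_NOISE, frac, m)
    return PreassessResult(Verdict.PASS, frac, m)
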
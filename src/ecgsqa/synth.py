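"""Synthetic ECG, noise models, SNR-exact mixing and labeled datasets.

The generator stands in for real single-lead wearable recordings: a
quasi-periodic clean ECG built from Gaussian bumps on a beat phase
(P, Q, R, S, T waves), and four noise classes that emulate the character
of ambulatory ECG contaminants:

* ``bw``  — baseline wander: random-phase sinusoids below 0.5 Hz plus a
  slow random walk (respiration / electrode drift);
* ``ma``  — muscle artifact: white noise high-passed above 15 Hz (EMG);
* ``em``  — electrode motion: intermittent bursts (~30 % duty cycle) of
  low-frequency transients riding on broadband noise;
* ``gbw`` — baseline wander with an equal-power white Gaussian component.

Three quality grades are synthesized by mixing noise into clean ECG at a
controlled signal-to-noise ratio: grade B at +10 dB (QRS still visible),
grade C at -10 dB (unusable). Grade A is the clean signal. All
generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import EcgRecord, EcgSegment, minmax_normalize

SNR_B_DB = 10.0
SNR_C_DB = -10.0
SNR_CAP_DB = 120.0

#: Gaussian-bump beat morphology: (phase center in radians, width, amplitude)
#: loosely following the dynamical ECG model convention (R peak at phase 0).
_BEAT_WAVES = (
    (-np.pi / 3, 0.25, 0.12),   # P
    (-np.pi / 12, 0.10, -0.20),  # Q
    (0.0, 0.10, 1.20),           # R
    (np.pi / 12, 0.10, -0.30),   # S
    (np.pi / 1.8, 0.40, 0.35),   # T
)

NOISE_KINDS = ("bw", "ma", "em", "gbw", "white")


class Label(str, Enum):
    A = "A"
    B = "B"
    C = "C"


@dataclass(frozen=True)
class NoiseSpec:
    kind: str
    snr_db: float
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; use one of {NOISE_KINDS}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass
class ScoreCard:
    """Five annotator scores on the {0, .25, .5, .75, 1} grid and their mean."""

    scores: tuple[float, float, float, float, float]

    _GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        if len(self.scores) != 5 or any(s not in self._GRID for s in self.scores):
            raise ValueError("need exactly five scores from {0, 0.25, 0.5, 0.75, 1}")

    @property
    def mean_score(self) -> float:
        return sum(self.scores) / 5.0


@dataclass
class LabeledSegment:
    segment: EcgSegment
    label: Label
    provenance: str                    # clean | augmented_B | augmented_C | pure_noise | flat
    noise: NoiseSpec | None = None


def synth_ecg(
    duration_s: float = 10.0,
    fs: float = 250.0,
    heart_rate_bpm: float = 60.0,
    hr_variability: float = 0.03,
    seed: int = 0,
    noise_floor: float = 0.01,
) -> EcgRecord:
    """Clean quasi-periodic ECG with P-QRS-T morphology.

    Beats are Gaussian bumps on an accumulated phase whose rate wobbles
    by ``hr_variability`` (fractional RR std) around the target heart
    rate; a faint respiratory baseline (0.25 Hz) and a ``noise_floor``
    white component (fraction of R amplitude) keep the trace realistic.
    Spectral energy is concentrated well below 40 Hz.
    """
    if not 30 <= heart_rate_bpm <= 200:
        raise ValueError("heart_rate_bpm must be in [30, 200]")
    if duration_s < 1:
        raise ValueError("duration must be at least 1 s")
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs

    # instantaneous beat rate with smooth RR variability
    base_hz = heart_rate_bpm / 60.0
    n_beats = int(np.ceil(duration_s * base_hz)) + 3
    rr = (1.0 / base_hz) * (1 + hr_variability * rng.standard_normal(n_beats))
    rr = np.clip(rr, 0.3, 2.0)
    beat_times = np.concatenate([[0.0], np.cumsum(rr)])

    # phase within the current beat, in (-pi, pi] with R at 0
    idx = np.searchsorted(beat_times, t, side="right") - 1
    frac = (t - beat_times[idx]) / rr[np.clip(idx, 0, n_beats - 1)]
    phase = 2 * np.pi * frac - np.pi  # beat starts at -pi

    x = np.zeros(n)
    for center, width, amp in _BEAT_WAVES:
        x += amp * np.exp(-0.5 * ((phase - center) / width) ** 2)
    x += 0.05 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    x += noise_floor * 1.2 * rng.standard_normal(n)
    return EcgRecord(x, fs, record_id=f"synth-ecg-{seed}")


def synth_noise(spec: NoiseSpec, duration_s: float = 10.0, fs: float = 250.0) -> EcgRecord:
    """One realization of a noise class, normalized to unit mean power."""
    rng = np.random.default_rng(spec.seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    kind = spec.kind

    if kind in ("bw", "gbw"):
        x = _baseline_wander(rng, t)
        if kind == "gbw":
            g = rng.standard_normal(n)
            x = x / _rms(x) + g / _rms(g)  # equal-power Gaussian add-on
    elif kind == "ma":
        x = _highpass(rng.standard_normal(n), fs, cutoff_hz=15.0)
    elif kind == "em":
        x = _electrode_motion(rng, t, fs)
    elif kind == "white":
        x = rng.standard_normal(n)
    else:  # pragma: no cover - guarded by NoiseSpec
        raise ValueError(kind)

    x = x - x.mean()
    x = x / _rms(x)
    return EcgRecord(x, fs, record_id=f"synth-{kind}-{spec.seed}")


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _baseline_wander(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Random-phase sinusoids below 0.5 Hz plus an integrated random walk."""
    x = np.zeros_like(t)
    for f in (0.05, 0.12, 0.21, 0.33, 0.45):
        x += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    walk = np.cumsum(rng.standard_normal(t.size))
    walk -= np.linspace(walk[0], walk[-1], t.size)  # detrend, keep it slow
    x += 0.3 * walk / (np.abs(walk).max() + 1e-12)
    return x


def _highpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    from scipy import signal as sps

    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _electrode_motion(rng: np.random.Generator, t: np.ndarray, fs: float) -> np.ndarray:
    """Bursty low-frequency transients (duty cycle ~30 %) over weak broadband noise."""
    n = t.size
    x = 0.2 * rng.standard_normal(n)
    duration = t[-1] + 1.0 / fs
    n_bursts = max(1, round(0.3 * duration / 0.5))  # ~0.5-s bursts covering ~30 %
    for _ in range(n_bursts):
        start = rng.uniform(0, max(duration - 0.5, 0.01))
        width = rng.uniform(0.2, 0.6)
        center = start + width / 2
        env = np.exp(-0.5 * ((t - center) / (width / 3)) ** 2)
        f = rng.uniform(0.5, 3.0)
        x += 3.0 * env * np.sin(2 * np.pi * f * (t - start) + rng.uniform(0, 2 * np.pi))
    return x


def add_noise(clean: EcgRecord, noise: EcgRecord, snr_db: float) -> EcgRecord:
    """Mix ``clean + g * noise`` with the gain solving the SNR equation exactly.

    Powers are mean-removed; requested SNR above ``SNR_CAP_DB`` returns
    the clean signal (gain underflows to numerically nothing).
    """
    if clean.samples.size != noise.samples.size or clean.fs != noise.fs:
        raise ValueError("clean and noise must share length and fs")
    s = clean.samples - clean.samples.mean()
    v = noise.samples - noise.samples.mean()
    p_s, p_v = np.mean(s**2), np.mean(v**2)
    if p_s <= 0 or p_v <= 0:
        raise ValueError("zero-power input")
    snr_db = min(snr_db, SNR_CAP_DB)
    g = np.sqrt(p_s / (p_v * 10 ** (snr_db / 10.0)))
    out = clean.samples + g * noise.samples
    return EcgRecord(out, clean.fs, record_id=f"{clean.record_id}+{noise.record_id}")


def measured_snr_db(clean: EcgRecord, mixture: EcgRecord) -> float:
    """SNR of ``mixture`` against the known clean component, in dB."""
    s = clean.samples - clean.samples.mean()
    r = (mixture.samples - clean.samples)
    r = r - r.mean()
    return float(10 * np.log10(np.mean(s**2) / np.mean(r**2)))


def score_to_label(card: ScoreCard) -> Label:
    """Map the five-annotator mean score to a quality grade.

    A for mean >= 0.75, C for mean <= 0.25, B between — the boundaries
    belong to the adjacent extreme grades.
    """
    m = card.mean_score
    if m >= 0.75:
        return Label.A
    if m <= 0.25:
        return Label.C
    return Label.B


def _to_segment(rec: EcgRecord, parent: str) -> EcgSegment:
    vals, degen = minmax_normalize(rec.samples)
    return EcgSegment(vals, rec.fs, parent_id=parent, degenerate=degen)


def build_dataset(
    n_per_class: int,
    fs: float = 250.0,
    seed: int = 0,
    duration_s: float = 10.0,
    snr_b_db: float = SNR_B_DB,
    snr_c_db: float = SNR_C_DB,
    recipe: str = "balanced",
    reject_fraction_c: float = 0.0,
) -> list[LabeledSegment]:
    """Assemble a three-grade labeled dataset of 10-s segments.

    * A — clean synthetic ECG;
    * B — clean ECG plus one of {bw, em, ma, gbw} at ``snr_b_db``;
    * C — the same noise classes at ``snr_c_db``, with an optional
      ``reject_fraction_c`` of flat and pure-white segments mixed in
      (the pre-assessment rejects, which real class-C data contains).

    ``recipe='table2'`` draws class-C noise only from the augmentation
    kinds used to expand the unbalanced source data, weighting bw-family
    noise higher; 'balanced' cycles uniformly. Fully reproducible from
    ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if recipe not in ("balanced", "table2"):
        raise ValueError("recipe must be 'balanced' or 'table2'")
    rng = np.random.default_rng(seed)
    kinds = ("bw", "em", "ma", "gbw")
    out: list[LabeledSegment] = []

    def _clean(k: int) -> EcgRecord:
        return synth_ecg(
            duration_s,
            fs,
            heart_rate_bpm=float(rng.uniform(50, 110)),
            hr_variability=0.03,
            seed=int(rng.integers(2**31)),
        )

    for k in range(n_per_class):
        out.append(LabeledSegment(_to_segment(_clean(k), f"A{k}"), Label.A, "clean"))

    for k in range(n_per_class):
        kind = kinds[k % 4] if recipe == "balanced" else str(
            rng.choice(kinds, p=(0.4, 0.2, 0.2, 0.2))
        )
        spec = NoiseSpec(kind, snr_b_db, int(rng.integers(2**31)))
        mixed = add_noise(_clean(k), synth_noise(spec, duration_s, fs), snr_b_db)
        out.append(
            LabeledSegment(_to_segment(mixed, f"B{k}"), Label.B, "augmented_B", spec)
        )

    n_reject = int(round(reject_fraction_c * n_per_class))
    for k in range(n_per_class):
        if k < n_reject:
            if k % 2 == 0:
                flat = EcgRecord(np.zeros(round(duration_s * fs)) + 0.5, fs, f"C{k}")
                seg = EcgSegment(flat.samples, fs, parent_id=f"C{k}", degenerate=True)
                out.append(LabeledSegment(seg, Label.C, "flat"))
            else:
                spec = NoiseSpec("white", snr_c_db, int(rng.integers(2**31)))
                noise = synth_noise(spec, duration_s, fs)
                out.append(
                    LabeledSegment(_to_segment(noise, f"C{k}"), Label.C, "pure_noise", spec)
                )
            continue
        kind = kinds[k % 4] if recipe == "balanced" else str(
            rng.choice(kinds, p=(0.4, 0.2, 0.2, 0.2))
        )
        spec = NoiseSpec(kind, snr_c_db, int(rng.integers(2**31)))
        mixed = add_noise(_clean(k), synth_noise(spec, duration_s, fs), snr_c_db)
        out.append(
            LabeledSegment(_to_segment(mixed, f"C{k}"), Label.C, "augmented_C", spec)
        )
    return out
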
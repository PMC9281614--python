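"""Record containers, resampling, normalization and fixed-length segmentation.

Single-lead ECG records enter the pipeline either from WFDB header/signal
pairs (formats 16 and 212) or from single-column delimited text. All
downstream stages operate at a working rate of 250 Hz on 10-s segments
whose amplitudes are min-max mapped to [0, 1].
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

WORKING_FS = 250.0
DEFAULT_WINDOW_S = 10.0


class UpsamplingError(ValueError):
    """Raised when a resample request would increase the sampling rate."""


@dataclass
class EcgRecord:
    """A single-lead ECG trace: amplitude samples at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    record_id: str = ""
    lead: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EcgSegment:
    """A fixed-length window cut from a record, normalized to [0, 1].

    ``degenerate`` marks constant windows that cannot be min-max scaled;
    they bypass normalization and are routed to the lead-off check.
    """

    samples: np.ndarray
    fs: float
    parent_id: str = ""
    offset_s: float = 0.0
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def resample(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Downsample a record to ``target_fs`` with anti-aliased polyphase filtering.

    The identity case (already at the target rate) returns the record
    unchanged. Upsampling is refused: the pipeline only ever reduces to
    the 250 Hz working rate.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if record.fs < target_fs:
        raise UpsamplingError(
            f"record at {record.fs} Hz cannot be raised to {target_fs} Hz; "
            "only downsampling is supported"
        )
    if record.fs == target_fs:
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(record.samples, up, down, window=("kaiser", 5.0))
    return EcgRecord(out, target_fs, record.record_id, record.lead)


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Affinely map ``x`` onto [0, 1]; returns ``(values, degenerate)``.

    A constant input cannot be scaled — it is returned untouched with the
    degenerate flag set so the caller can route it to lead-off detection.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to normalize")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return x.copy(), True
    return (x - lo) / (hi - lo), False


def segment(
    record: EcgRecord,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_WINDOW_S,
    normalize: bool = True,
) -> list[EcgSegment]:
    """Cut fixed-length windows; a trailing partial window is discarded.

    Window starts advance by ``hop_s``; with hop == window the segments
    tile the record without overlap.
    """
    if not window_s > 0:
        raise ValueError("window_s must be positive")
    if not 0 < hop_s <= window_s:
        raise ValueError("hop_s must satisfy 0 < hop <= window")
    n = record.samples.size
    win = round(window_s * record.fs)
    hop = round(hop_s * record.fs)
    if n < win:
        warnings.warn(
            f"record {record.record_id!r} shorter than one window; no segments",
            stacklevel=2,
        )
        return []
    out = []
    n_seg = (n - win) // hop + 1
    for k in range(n_seg):
        start = k * hop
        raw = record.samples[start : start + win]
        if normalize:
            vals, degen = minmax_normalize(raw)
        else:
            vals, degen = raw.copy(), False
        out.append(
            EcgSegment(
                vals,
                record.fs,
                parent_id=record.record_id,
                offset_s=start / record.fs,
                degenerate=degen,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_text_record(path: str | Path, fs: float | None = None) -> EcgRecord:
    """Read a single-column text record; ``# fs: <Hz>`` header line sets the rate."""
    path = Path(path)
    header_fs = None
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("fs"):
                header_fs = float(body.split(":", 1)[1])
            continue
        values.append(float(line))
    fs = fs if fs is not None else header_fs
    if fs is None:
        raise ValueError(f"{path}: no sampling rate in header and none supplied")
    return EcgRecord(np.asarray(values), fs, record_id=path.stem)


def write_text_record(record: EcgRecord, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# fs: {record.fs}"]
    lines += [f"{v:.9g}" for v in record.samples]
    path.write_text("\n".join(lines) + "\n")


def read_wfdb_record(header_path: str | Path) -> EcgRecord:
    """Read the first signal of a WFDB record (.hea + .dat, format 16 or 212).

    Minimal single-segment reader: parses record line (name, n_sig, fs,
    n_samples) and per-signal lines (file, format, gain, baseline); ADC
    units are converted to physical via (adc - baseline) / gain.
    """
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if n_sig < 1:
        raise ValueError(f"{header_path}: no signals declared")
    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fname, fmt = f[0], f[1].split("x")[0]
        gain, baseline = 200.0, 0
        if len(f) > 2:
            gspec = f[2]
            if "/" in gspec:
                gspec = gspec.split("/")[0]
            if "(" in gspec:
                gain = float(gspec[: gspec.index("(")])
                baseline = int(gspec[gspec.index("(") + 1 : gspec.index(")")])
            else:
                gain = float(gspec)
        if gain == 0:
            gain = 200.0
        desc = f[-1] if len(f) > 8 else None
        sig_specs.append((fname, int(fmt), gain, baseline, desc))
    fname, fmt, gain, baseline, desc = sig_specs[0]
    dat = (header_path.parent / fname).read_bytes()
    if fmt == 16:
        n_total = len(dat) // 2
        adc = np.asarray(struct.unpack(f"<{n_total}h", dat[: 2 * n_total]), dtype=float)
        adc = adc.reshape(-1, n_sig)[:, 0]
    elif fmt == 212:
        adc = _unpack_212(dat).reshape(-1, n_sig)[:, 0].astype(float)
    else:
        raise ValueError(f"unsupported WFDB format {fmt}; only 16 and 212")
    if n_samp:
        adc = adc[:n_samp]
    return EcgRecord((adc - baseline) / gain, fs, record_id=record_name, lead=desc)


def _unpack_212(dat: bytes) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    usable = len(dat) - len(dat) % 3
    b = np.frombuffer(dat[:usable], dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * b.shape[0], dtype=np.int32)
    out[0::2], out[1::2] = first, second
    out[out > 2047] -= 4096
    return out


def read_record(path: str | Path, fs: float | None = None) -> EcgRecord:
    """Dispatch on extension: .hea → WFDB, anything else → delimited text."""
    path = Path(path)
    if path.suffix == ".hea":
        return read_wfdb_record(path)
    return read_text_record(path, fs=fs)


def write_segments(
    segments: list[EcgSegment], out_dir: str | Path, labels: list[str] | None = None
) -> Path:
    """Write segments as one text file each plus a JSON manifest sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"fs": segments[0].fs if segments else WORKING_FS, "segments": []}
    for k, seg in enumerate(segments):
        name = f"seg{k:05d}.txt"
        np.savetxt(out_dir / name, seg.samples, fmt="%.9g")
        entry = {
            "file": name,
            "parent_id": seg.parent_id,
            "offset_s": seg.offset_s,
            "degenerate": seg.degenerate,
        }
        if labels is not None:
            entry["label"] = labels[k]
        manifest["segments"].append(entry)
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1))
    return man_path


def read_segments(manifest_path: str | Path) -> tuple[list[EcgSegment], list[str | None]]:
    """Load segments written by :func:`write_segments`; returns (segments, labels)."""
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    segs, labels = [], []
    for entry in man["segments"]:
        samples = np.loadtxt(manifest_path.parent / entry["file"])
        segs.append(
            EcgSegment(
                samples,
                man["fs"],
                parent_id=entry.get("parent_id", ""),
                offset_s=entry.get("offset_s", 0.0),
                degenerate=entry.get("degenerate", False),
            )
        )
        labels.append(entry.get("label"))
    return segs, labels
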
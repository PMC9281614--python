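"""Per-class evaluation metrics and streaming quality assessment.

The metric suite is the standard per-class sensitivity / precision / F1
family over the three quality grades, plus their macro average (mF1)
and overall accuracy (mACC):

    Se_k  = TN_k / N_k        (row-normalized diagonal)
    +P_k  = TN_k / T_k        (column-normalized diagonal)
    F1_k  = 2 TN_k / (N_k + T_k)
    mF1   = (F1_A + F1_B + F1_C) / 3
    mACC  = (TN_A + TN_B + TN_C) / N

where TN_k is the correctly-predicted count of class k, N_k the actual
count and T_k the predicted count. Reports carry raw floats; printed
values are rounded half-up to two decimals, matching clinical reporting
convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .io import EcgRecord, EcgSegment, minmax_normalize, resample
from .preassess import Verdict, preassess
from .synth import Label

_LABELS = (Label.A, Label.B, Label.C)


class UndefinedMetricError(ValueError):
    """A class with zero actual or predicted count has no defined metric."""


@dataclass
class ConfusionMatrix3:
    """3x3 counts; rows = actual grade, columns = predicted grade (A, B, C)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(actual, predicted) -> ConfusionMatrix3:
    """Tally actual-vs-predicted grades into a 3x3 matrix."""
    a = [Label(x) for x in actual]
    p = [Label(x) for x in predicted]
    if len(a) != len(p) or not a:
        raise ValueError("actual and predicted must be equal-length and non-empty")
    lut = {lab: k for k, lab in enumerate(_LABELS)}
    counts = np.zeros((3, 3), dtype=int)
    for ai, pi in zip(a, p):
        counts[lut[ai], lut[pi]] += 1
    return ConfusionMatrix3(counts)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Per-class Se / +P / F1 plus mF1 and mACC, all as percentages."""

    se: dict
    precision: dict
    f1: dict
    mf1: float
    macc: float
    cm: ConfusionMatrix3 | None = None

    def rounded(self) -> dict:
        """Two-decimal half-up view of every metric, for printed reports."""
        return {
            "Se": {k.value: _round2(v) for k, v in self.se.items()},
            "+P": {k.value: _round2(v) for k, v in self.precision.items()},
            "F1": {k.value: _round2(v) for k, v in self.f1.items()},
            "mF1": _round2(self.mf1),
            "mACC": _round2(self.macc),
        }

    def table(self) -> str:
        r = self.rounded()
        lines = [f"{'class':>6} {'Se%':>8} {'+P%':>8} {'F1%':>8}"]
        for k in "ABC":
            lines.append(f"{k:>6} {r['Se'][k]:>8.2f} {r['+P'][k]:>8.2f} {r['F1'][k]:>8.2f}")
        lines.append(f"mF1 = {r['mF1']:.2f}%   mACC = {r['mACC']:.2f}%")
        return "\n".join(lines)


def metrics(cm: ConfusionMatrix3, strict: bool = True) -> MetricsReport:
    """Compute the full metric suite from a confusion matrix.

    With ``strict`` (default) a zero actual or predicted count raises
    :class:`UndefinedMetricError` naming the class; with ``strict=False``
    the affected per-class entries are reported as 0 (mACC is always
    defined), which cross-validation uses for degenerate folds.
    """
    c = cm.counts.astype(float)
    n_actual = c.sum(axis=1)
    n_pred = c.sum(axis=0)
    se, pp, f1 = {}, {}, {}
    for k, lab in enumerate(_LABELS):
        if strict and (n_actual[k] == 0 or n_pred[k] == 0):
            which = "actual" if n_actual[k] == 0 else "predicted"
            raise UndefinedMetricError(f"class {lab.value} has zero {which} count")
        se[lab] = 100.0 * c[k, k] / n_actual[k] if n_actual[k] else 0.0
        pp[lab] = 100.0 * c[k, k] / n_pred[k] if n_pred[k] else 0.0
        denom = n_actual[k] + n_pred[k]
        f1[lab] = 200.0 * c[k, k] / denom if denom else 0.0
    mf1 = sum(f1.values()) / 3.0
    macc = 100.0 * np.trace(c) / c.sum()
    return MetricsReport(se, pp, f1, mf1, float(macc), cm)


def mean_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of metric values across folds (no confusion matrix)."""
    if not reports:
        raise ValueError("no reports to average")
    mean = lambda vals: float(np.mean(vals))
    return MetricsReport(
        se={lab: mean([r.se[lab] for r in reports]) for lab in _LABELS},
        precision={lab: mean([r.precision[lab] for r in reports]) for lab in _LABELS},
        f1={lab: mean([r.f1[lab] for r in reports]) for lab in _LABELS},
        mf1=mean([r.mf1 for r in reports]),
        macc=mean([r.macc for r in reports]),
    )


@dataclass
class QualityTimeline:
    """Per-frame grades of a long record under sliding-window assessment."""

    frame_start_s: np.ndarray
    labels: list[str]
    hop_s: float = 1.0

    def __post_init__(self) -> None:
        self.frame_start_s = np.asarray(self.frame_start_s, dtype=float)
        if len(self.labels) != self.frame_start_s.size:
            raise ValueError("labels and frame starts differ in length")
        if self.frame_start_s.size > 1:
            hops = np.diff(self.frame_start_s)
            if (hops <= 0).any() or not np.allclose(hops, hops[0]):
                raise ValueError("frame starts must increase by a constant hop")

    def __len__(self) -> int:
        return len(self.labels)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_s", "label"])
            for t, lab in zip(self.frame_start_s, self.labels):
                w.writerow([f"{t:g}", lab])


def assess_stream(
    record: EcgRecord,
    model,
    bank,
    config=None,
    frame_s: float = 10.0,
    hop_s: float = 1.0,
    flat_threshold: float = 0.8,
    mpsqi_threshold: float = 0.30,
) -> QualityTimeline:
    """Grade a long record frame by frame (default 10-s frame, 1-s hop).

    Each frame runs the full pipeline: resample to the working rate,
    min-max normalize, pre-assess, and — only if it passes — scatter and
    classify. Rejected frames carry their rejection verdict as the
    label. The label is assigned to the frame's start time.
    """
    import warnings

    from .classifier import predict
    from .scattering import scattering_transform

    config = config or bank.config
    if record.fs != config.fs:
        record = resample(record, config.fs)
    n = record.samples.size
    win = round(frame_s * record.fs)
    hop = round(hop_s * record.fs)
    if n < win:
        warnings.warn("record shorter than one frame; empty timeline", stacklevel=2)
        return QualityTimeline(np.empty(0), [], hop_s)

    starts, labels = [], []
    for k in range((n - win) // hop + 1):
        s0 = k * hop
        raw = record.samples[s0 : s0 + win]
        vals, degen = minmax_normalize(raw)
        seg = EcgSegment(vals, record.fs, parent_id=record.record_id,
                         offset_s=s0 / record.fs, degenerate=degen)
        starts.append(s0 / record.fs)
        if degen:
            labels.append(Verdict.REJECT_LEAD_OFF.value)
            continue
        res = preassess(seg, flat_threshold, mpsqi_threshold)
        if res.verdict is not Verdict.PASS:
            labels.append(res.verdict.value)
            continue
        feats = scattering_transform(seg, bank, config)
        labels.append(predict(model, feats.values[None])[0][0].value)
    return QualityTimeline(np.asarray(starts), labels, hop_s)
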
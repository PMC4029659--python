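"""Evaluation indices: accuracy, sensitivity, positive predictivity, and
the 95% feature-validity rule.

* ``Ac = (Na - Ne)/Na x 100`` — fraction of correctly handled items;
* ``Se = TP/(TP+FN) x 100`` and ``+P = TP/(TP+FP) x 100`` — beat-class
  local performance (``None`` when a class has no positives, matching the
  blank cells convention for absent classes);
* feature validation counts an extracted interval as erroneous when it
  deviates from the expert value beyond a tolerance (default 10 ms), and
  flags a record invalid when its interval accuracy falls below 95%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .records import BeatClass, BeatFeatures

__all__ = [
    "accuracy",
    "sensitivity",
    "positive_predictivity",
    "FeatureValidation",
    "validate_features",
    "ClassCounts",
    "beat_confusion",
    "classification_report",
]

FEATURE_FIELDS: tuple[str, ...] = ("pq_interval", "qrs_duration", "t_duration")


def accuracy(n_total: int, n_errors: int) -> float:
    """(Na - Ne)/Na x 100."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= n_errors <= n_total:
        raise ValueError("error count must lie in [0, total]")
    return (n_total - n_errors) / n_total * 100.0


def sensitivity(tp: int, fn: int) -> Optional[float]:
    """Se = TP/(TP+FN) x 100; None when the class has no actual positives."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        return None
    return tp / (tp + fn) * 100.0


def positive_predictivity(tp: int, fp: int) -> Optional[float]:
    """+P = TP/(TP+FP) x 100; None when nothing was predicted positive."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return tp / (tp + fp) * 100.0


@dataclass
class FeatureValidation:
    n_intervals: int
    n_errors: int
    ac: float
    valid: bool


def validate_features(extracted: Sequence[BeatFeatures],
                      expert: Sequence[BeatFeatures],
                      tolerance_ms: float = 10.0,
                      fields: Sequence[str] = FEATURE_FIELDS,
                      validity_threshold: float = 95.0) -> FeatureValidation:
    """Interval-level accuracy of extracted features against expert values.

    Features are aligned by ``beat_index``.  Per aligned beat and interval
    type: agreement within ``tolerance_ms`` counts as correct, a mismatch
    in presence (one side missing) counts as an error, and intervals
    absent on both sides (e.g. the P-Q of a ventricular ectopic) are not
    counted.  The record is invalid when Ac drops below the threshold.
    """
    by_index = {f.beat_index: f for f in expert}
    n = 0
    errors = 0
    overlap = 0
    for f in extracted:
        ref = by_index.get(f.beat_index)
        if ref is None:
            continue
        overlap += 1
        for name in fields:
            got, want = getattr(f, name), getattr(ref, name)
            if got is None and want is None:
                continue
            n += 1
            if got is None or want is None or abs(got - want) > tolerance_ms:
                errors += 1
    if overlap == 0:
        raise ValueError("no overlapping beat indices between extracted and expert features")
    ac = accuracy(n, errors) if n else 100.0
    return FeatureValidation(n_intervals=n, n_errors=errors, ac=ac,
                             valid=ac >= validity_threshold)


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n_actual(self) -> int:
        return self.tp + self.fn


def beat_confusion(true_beats: Sequence[tuple[int, BeatClass]],
                   pred_beats: Sequence[tuple[int, BeatClass]],
                   tolerance_samples: int) -> dict[BeatClass, ClassCounts]:
    """Beat-by-beat confusion counts from (sample time, class) pairs.

    True and predicted beats are matched greedily in time order within the
    tolerance; a matched pair with differing classes contributes FN to the
    true class and FP to the predicted class, unmatched true beats are FN,
    unmatched predictions FP.
    """
    counts = {c: ClassCounts() for c in BeatClass}
    ti = pi = 0
    truths = sorted(true_beats)
    preds = sorted(pred_beats)
    while ti < len(truths) and pi < len(preds):
        tt, tc = truths[ti]
        pt, pc = preds[pi]
        if abs(tt - pt) <= tolerance_samples:
            if tc == pc:
                counts[tc].tp += 1
            else:
                counts[tc].fn += 1
                counts[pc].fp += 1
            ti += 1
            pi += 1
        elif tt < pt:
            counts[tc].fn += 1
            ti += 1
        else:
            counts[pc].fp += 1
            pi += 1
    for tt, tc in truths[ti:]:
        counts[tc].fn += 1
    for pt, pc in preds[pi:]:
        counts[pc].fp += 1
    return counts


def classification_report(confusion: dict[BeatClass, ClassCounts]) -> dict:
    """Per-class Se/+P plus overall beat accuracy, JSON-serializable."""
    total = sum(c.tp + c.fn for c in confusion.values())
    errors = sum(c.fn for c in confusion.values())
    report: dict = {
        "n_beats": total,
        "accuracy": accuracy(total, errors) if total else None,
        "classes": {},
    }
    for cls, c in confusion.items():
        report["classes"][cls.value] = {
            "n": c.n_actual,
            "tp": c.tp, "fp": c.fp, "fn": c.fn,
            "se": sensitivity(c.tp, c.fn),
            "pp": positive_predictivity(c.tp, c.fp),
        }
    return report
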
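"""Core domain containers shared across the pipeline.

An :class:`EcgRecord` is a uniformly sampled single-lead voltage series in
millivolts.  Ground truth (when the record comes from the synthetic
generator, or from an annotated database) travels with the record as a
:class:`GroundTruth` object: per-beat wave-boundary intervals, beat classes
and, optionally, a dense per-sample state-label array.

Sample indexing is 0-based and all intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

#: The six hidden waveform states of one cardiac cycle, in cyclic order:
#: leading isoelectric segment, P wave, PQ (isoelectric) segment, QRS
#: complex, ST (isoelectric) segment, T wave.
WAVE_STATES: tuple[str, ...] = ("ISO1", "P", "PQ", "QRS", "ST", "T")


class BeatClass(str, Enum):
    """Beat-level rhythm classes."""

    NORMAL = "Normal"
    PVC = "PVC"
    APC = "APC"
    INVALID = "Invalid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class BeatAnnotation:
    """Ground-truth description of one beat.

    ``intervals`` maps each wave-state name to its half-open sample span;
    states that do not occur in the beat (the P wave and PQ segment of a
    ventricular ectopic) are present with a zero-length span so the six
    states always partition the beat.
    """

    index: int
    beat_class: BeatClass
    onset: int
    offset: int
    r_peak: int
    intervals: dict[str, tuple[int, int]]

    def interval_samples(self, state: str) -> int:
        on, off = self.intervals[state]
        return off - on


@dataclass
class GroundTruth:
    beats: list[BeatAnnotation]
    state_labels: Optional[np.ndarray] = None  # int8 per sample, index into WAVE_STATES


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead ECG voltage series (mV)."""

    samples: np.ndarray
    sampling_rate: float
    record_id: str = ""
    annotations: Optional[GroundTruth] = None
    warmup_samples: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class BeatFeatures:
    """Per-beat interval measurements in milliseconds.

    ``None`` marks an undefined quantity: the first beat of a record has no
    preceding R peak (``rr_interval``/``pp_interval``), a beat without a
    detected P wave has no P-Q interval, and a trailing partial beat may
    lack a T duration.  ``pr_interval`` and ``pq_interval`` both measure the
    P-wave onset to QRS onset (the two names are clinical synonyms).
    """

    beat_index: int
    pr_interval: Optional[float] = None
    pq_interval: Optional[float] = None
    qrs_duration: Optional[float] = None
    t_duration: Optional[float] = None
    rr_interval: Optional[float] = None
    pp_interval: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("pr_interval", "pq_interval", "qrs_duration", "t_duration",
                     "rr_interval", "pp_interval"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class BeatLabel:
    """One classification outcome per beat."""

    beat_index: int
    beat_class: BeatClass
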
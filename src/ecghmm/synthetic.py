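"""Seeded synthetic ECG generator with exact ground truth.

The generator renders periodic beats as smooth raised-cosine lobes — P
wave, QRS complex and T wave — separated by isoelectric segments, and
contaminates them with the three noise components the denoising filter
targets or tolerates: sub-0.5 Hz baseline wander, 50 Hz power-line
interference with harmonics, and broadband white noise.  Every rhythm is a
pure function of its :class:`RhythmPlan` (which carries the seed), and the
per-sample state labels plus per-beat wave boundaries are returned as
ground truth, so downstream delineation and classification can be scored
exactly.

Abnormal-beat morphology follows the qualitative clinical picture:

* **PVC** (premature ventricular contraction): absent P wave, widened QRS
  (default x1.6, inverted polarity), prolonged T (x1.5), short preceding
  R-R interval (x0.7);
* **APC** (atrial premature contraction): early beat (R-R x0.8) whose P-Q
  interval falls outside the normal range (default 240 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .records import (
    WAVE_STATES,
    BeatAnnotation,
    BeatClass,
    BeatFeatures,
    EcgRecord,
    GroundTruth,
)

__all__ = [
    "BeatTemplate",
    "NoiseSettings",
    "RhythmPlan",
    "normal_template",
    "pvc_template",
    "apc_template",
    "make_beat",
    "make_rhythm",
    "make_plan",
    "true_features",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat; durations in ms, amplitudes in mV.

    ``pq_interval`` is the clinical P-Q (= P-R) interval: P-wave onset to
    QRS onset, so the isoelectric PQ segment lasts
    ``pq_interval - p_duration``.  Setting ``p_amplitude = 0`` (ventricular
    ectopy) removes the P wave and PQ segment entirely.
    """

    p_amplitude: float = 0.15
    p_duration: float = 90.0
    pq_interval: float = 160.0
    qrs_amplitude: float = 1.0
    qrs_duration: float = 80.0
    st_interval: float = 100.0
    t_amplitude: float = 0.3
    t_duration: float = 180.0
    beat_class: BeatClass = BeatClass.NORMAL

    def __post_init__(self) -> None:
        for name in ("p_duration", "qrs_duration", "st_interval", "t_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_amplitude != 0 and self.pq_interval <= self.p_duration:
            raise ValueError("pq_interval must exceed p_duration when a P wave is present")

    @property
    def content_ms(self) -> float:
        """Duration of the beat excluding the leading isoelectric segment."""
        pq = self.pq_interval if self.p_amplitude != 0 else 0.0
        return pq + self.qrs_duration + self.st_interval + self.t_duration


def normal_template() -> BeatTemplate:
    return BeatTemplate()


def pvc_template(base: Optional[BeatTemplate] = None, *,
                 qrs_factor: float = 1.6, t_factor: float = 1.5,
                 qrs_polarity: float = -1.25) -> BeatTemplate:
    """Ventricular ectopic: no P, wide (inverted) QRS, prolonged T."""
    base = base or normal_template()
    return replace(
        base,
        p_amplitude=0.0,
        qrs_duration=base.qrs_duration * qrs_factor,
        qrs_amplitude=base.qrs_amplitude * qrs_polarity,
        t_duration=base.t_duration * t_factor,
        beat_class=BeatClass.PVC,
    )


def apc_template(base: Optional[BeatTemplate] = None, *,
                 pq_ms: float = 240.0) -> BeatTemplate:
    """Atrial ectopic: early beat with an out-of-range P-Q interval."""
    base = base or normal_template()
    return replace(base, pq_interval=pq_ms, beat_class=BeatClass.APC)


@dataclass(frozen=True)
class NoiseSettings:
    """Additive contamination; all amplitudes in mV."""

    baseline_freq_hz: float = 0.25   # respiration-rate wander (< 0.5 Hz)
    baseline_amp_mv: float = 0.3
    powerline_freq_hz: float = 50.0
    powerline_amps_mv: tuple[float, ...] = (0.05, 0.02)  # fundamental, harmonics
    white_noise_sd_mv: float = 0.01

    @classmethod
    def none(cls) -> "NoiseSettings":
        return cls(baseline_amp_mv=0.0, powerline_amps_mv=(), white_noise_sd_mv=0.0)


@dataclass
class RhythmPlan:
    """Beat sequence plus noise settings; the seed fixes all randomness."""

    beats: list[tuple[BeatClass, float]]  # (class, beat period in ms)
    noise: NoiseSettings = field(default_factory=NoiseSettings)
    seed: int = 0
    templates: dict[BeatClass, BeatTemplate] = field(default_factory=lambda: {
        BeatClass.NORMAL: normal_template(),
        BeatClass.PVC: pvc_template(),
        BeatClass.APC: apc_template(),
    })


def _lobe(n: int, amplitude: float) -> np.ndarray:
    """Raised-cosine lobe of n samples: zero at the edges, peak ~amplitude."""
    i = np.arange(n)
    return amplitude * np.sin(np.pi * (i + 0.5) / n) ** 2


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


@dataclass
class BeatSegment:
    samples: np.ndarray
    intervals: dict[str, tuple[int, int]]  # state name -> half-open span
    state_labels: np.ndarray
    r_peak: int
    beat_class: BeatClass


def make_beat(template: BeatTemplate, sampling_rate: float,
              period_ms: float = 850.0) -> BeatSegment:
    """Render one beat of ``period_ms`` total duration.

    The leading isoelectric segment absorbs the period slack; the six wave
    states tile the beat exactly (absent P/PQ states get zero-length
    spans).  Raises if the intra-beat intervals exceed the beat period.
    """
    fs = sampling_rate
    has_p = template.p_amplitude != 0
    p_n = _ms_to_samples(template.p_duration, fs) if has_p else 0
    gap_n = _ms_to_samples(template.pq_interval - template.p_duration, fs) if has_p else 0
    qrs_n = _ms_to_samples(template.qrs_duration, fs)
    st_n = _ms_to_samples(template.st_interval, fs)
    t_n = _ms_to_samples(template.t_duration, fs)
    period_n = _ms_to_samples(period_ms, fs)
    content = p_n + gap_n + qrs_n + st_n + t_n
    iso_n = period_n - content
    if iso_n < 0:
        raise ValueError(
            f"intra-beat intervals ({content} samples) exceed the beat period ({period_n})"
        )
    samples = np.zeros(period_n)
    labels = np.empty(period_n, dtype=np.int8)
    intervals: dict[str, tuple[int, int]] = {}
    pos = 0
    for state, width in zip(WAVE_STATES, (iso_n, p_n, gap_n, qrs_n, st_n, t_n)):
        intervals[state] = (pos, pos + width)
        labels[pos:pos + width] = WAVE_STATES.index(state)
        pos += width
    p_on, _ = intervals["P"]
    if has_p:
        samples[p_on:p_on + p_n] = _lobe(p_n, template.p_amplitude)
    q_on, q_off = intervals["QRS"]
    samples[q_on:q_off] = _lobe(qrs_n, template.qrs_amplitude)
    t_on, t_off = intervals["T"]
    samples[t_on:t_off] = _lobe(t_n, template.t_amplitude)
    return BeatSegment(samples=samples, intervals=intervals, state_labels=labels,
                       r_peak=q_on + qrs_n // 2, beat_class=template.beat_class)


def make_rhythm(plan: RhythmPlan, sampling_rate: float = 400.0) -> EcgRecord:
    """Concatenate the planned beats and add the three noise components.

    Ground truth (beat classes, wave boundaries, per-sample state labels)
    is attached to the returned record.  An empty plan yields an empty,
    valid record.
    """
    rng = np.random.default_rng(plan.seed)
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    beats: list[BeatAnnotation] = []
    offset = 0
    for idx, (cls, period_ms) in enumerate(plan.beats):
        template = plan.templates[cls]
        seg = make_beat(template, sampling_rate, period_ms)
        chunks.append(seg.samples)
        labels.append(seg.state_labels)
        beats.append(BeatAnnotation(
            index=idx,
            beat_class=cls,
            onset=offset,
            offset=offset + seg.samples.size,
            r_peak=offset + seg.r_peak,
            intervals={s: (on + offset, off + offset)
                       for s, (on, off) in seg.intervals.items()},
        ))
        offset += seg.samples.size
    x = np.concatenate(chunks) if chunks else np.zeros(0)
    state_labels = np.concatenate(labels) if labels else np.zeros(0, dtype=np.int8)
    n = x.size
    noise = plan.noise
    if n:
        t = np.arange(n) / sampling_rate
        if noise.baseline_amp_mv:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + noise.baseline_amp_mv * np.sin(
                2 * np.pi * noise.baseline_freq_hz * t + phase)
        for k, amp in enumerate(noise.powerline_amps_mv, start=1):
            if amp:
                phase = rng.uniform(0, 2 * np.pi)
                x = x + amp * np.sin(2 * np.pi * k * noise.powerline_freq_hz * t + phase)
        if noise.white_noise_sd_mv:
            x = x + rng.normal(0.0, noise.white_noise_sd_mv, n)
    return EcgRecord(
        samples=x,
        sampling_rate=sampling_rate,
        record_id=f"synthetic-{plan.seed}",
        annotations=GroundTruth(beats=beats, state_labels=state_labels),
    )


def make_plan(n_beats: int, pvc_rate: float = 0.05, apc_rate: float = 0.05,
              rr_ms: float = 850.0, rr_jitter: float = 0.03, seed: int = 0,
              noise: Optional[NoiseSettings] = None,
              templates: Optional[dict[BeatClass, BeatTemplate]] = None,
              pvc_rr_factor: float = 0.7, apc_rr_factor: float = 0.8) -> RhythmPlan:
    """Draw a seeded beat plan with ectopics injected at the given rates."""
    if pvc_rate + apc_rate > 1:
        raise ValueError("class rates must sum to at most 1")
    rng = np.random.default_rng(seed)
    beats: list[tuple[BeatClass, float]] = []
    for _ in range(n_beats):
        u = rng.uniform()
        if u < pvc_rate:
            cls, factor = BeatClass.PVC, pvc_rr_factor
        elif u < pvc_rate + apc_rate:
            cls, factor = BeatClass.APC, apc_rr_factor
        else:
            cls, factor = BeatClass.NORMAL, 1.0
        period = rr_ms * factor * (1.0 + rr_jitter * rng.uniform(-1, 1))
        beats.append((cls, period))
    plan = RhythmPlan(beats=beats, seed=seed)
    if noise is not None:
        plan.noise = noise
    if templates is not None:
        plan.templates = templates
    return plan


def true_features(record: EcgRecord) -> list[BeatFeatures]:
    """Ground-truth per-beat interval features, from the attached annotation."""
    if record.annotations is None:
        raise ValueError("record carries no ground-truth annotations")
    ms = 1000.0 / record.sampling_rate
    out: list[BeatFeatures] = []
    prev_r: Optional[int] = None
    prev_p: Optional[int] = None
    for b in record.annotations.beats:
        p_on, p_off = b.intervals["P"]
        q_on, q_off = b.intervals["QRS"]
        t_on, t_off = b.intervals["T"]
        has_p = p_off > p_on
        pq = (q_on - p_on) * ms if has_p else None
        out.append(BeatFeatures(
            beat_index=b.index,
            pr_interval=pq,
            pq_interval=pq,
            qrs_duration=(q_off - q_on) * ms,
            t_duration=(t_off - t_on) * ms,
            rr_interval=(q_on - prev_r) * ms if prev_r is not None else None,
            pp_interval=(p_on - prev_p) * ms if (prev_p is not None and has_p) else None,
        ))
        prev_r = q_on
        if has_p:
            prev_p = p_on
    return out
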
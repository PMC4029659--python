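"""Layer II: four-state beat-classification HMM.

Each beat is summarized by two binary interval symbols — T-wave duration
normal/abnormal (V1/V2) and P-Q interval normal/abnormal (V3/V4) — and the
beat sequence is decoded into {Normal, PVC, APC, Invalid} by Viterbi.  A
beat emits the *pair* (v_t, v_pq); the default model's per-state emission
over the joint four-letter alphabet factorizes as the product of a
T-categorical and a PQ-categorical, while trained models live on the joint
alphabet directly (strictly more general).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hmm import HmmModel, viterbi
from .records import BeatClass, BeatFeatures, BeatLabel

__all__ = [
    "NormalRanges",
    "BeatObservation",
    "BEAT_STATES",
    "LAYER2_ALPHABET",
    "symbolize_beats",
    "default_layer2_model",
    "classify_beats",
]

BEAT_STATES: tuple[str, ...] = ("Normal", "PVC", "APC", "Invalid")

#: Joint observation alphabet: (T symbol, PQ symbol) pairs.
LAYER2_ALPHABET: tuple[str, ...] = ("V1V3", "V1V4", "V2V3", "V2V4")


@dataclass(frozen=True)
class NormalRanges:
    """Normal limits (ms) for the two discriminating intervals.

    Defaults follow standard clinical limits; out-of-range on *either*
    side counts as abnormal (ventricular T prolongation and the
    conflicting atrial P-Q deviations are both captured this way).
    """

    t_duration: tuple[float, float] = (100.0, 250.0)
    pq_interval: tuple[float, float] = (120.0, 200.0)

    def __post_init__(self) -> None:
        for name in ("t_duration", "pq_interval"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must satisfy lo < hi")


@dataclass
class BeatObservation:
    """Per-beat symbols: v_t in {0: V1 normal T, 1: V2 abnormal T},
    v_pq in {0: V3 normal PQ, 1: V4 abnormal PQ}."""

    beat_index: int
    v_t: int
    v_pq: int

    @property
    def joint_symbol(self) -> int:
        return 2 * self.v_t + self.v_pq


def symbolize_beats(features: Sequence[BeatFeatures],
                    ranges: NormalRanges = NormalRanges()) -> list[BeatObservation]:
    """Map interval features to the V1..V4 symbols.

    A missing P-Q interval (absent P wave) maps to V4; a missing T
    duration maps to V2.  Negative durations are rejected upstream by
    :class:`BeatFeatures`, and again here for features built by hand.
    """
    if not features:
        raise ValueError("need at least one beat's features")
    out: list[BeatObservation] = []
    for f in features:
        for name in ("t_duration", "pq_interval"):
            v = getattr(f, name)
            if v is not None and v < 0:
                raise ValueError(f"negative {name} for beat {f.beat_index}")
        t_lo, t_hi = ranges.t_duration
        q_lo, q_hi = ranges.pq_interval
        v_t = 0 if (f.t_duration is not None and t_lo <= f.t_duration <= t_hi) else 1
        v_pq = 0 if (f.pq_interval is not None and q_lo <= f.pq_interval <= q_hi) else 1
        out.append(BeatObservation(beat_index=f.beat_index, v_t=v_t, v_pq=v_pq))
    return out


def default_layer2_model(
    t_given_state: Optional[np.ndarray] = None,
    pq_given_state: Optional[np.ndarray] = None,
) -> HmmModel:
    """Prior four-state model with factorized emissions.

    Normal strongly favors (V1, V3); PVC favors V2 with a mild lean to V4
    (its absent P maps to V4); APC favors V4 and is nearly T-agnostic;
    Invalid is close to uniform.  Transitions favor persistence of Normal
    with rare excursions.  All values are priors for subsequent training.
    """
    if t_given_state is None:
        t_given_state = np.array([
            [0.95, 0.05],   # Normal:  P(V1), P(V2)
            [0.10, 0.90],   # PVC
            [0.70, 0.30],   # APC
            [0.50, 0.50],   # Invalid
        ])
    if pq_given_state is None:
        pq_given_state = np.array([
            [0.95, 0.05],   # Normal:  P(V3), P(V4)
            [0.40, 0.60],   # PVC (absent P maps to V4)
            [0.10, 0.90],   # APC
            [0.50, 0.50],   # Invalid
        ])
    b = np.einsum("st,sq->stq", t_given_state, pq_given_state).reshape(4, 4)
    a = np.array([
        [0.92, 0.03, 0.03, 0.02],
        [0.85, 0.10, 0.03, 0.02],
        [0.85, 0.03, 0.10, 0.02],
        [0.85, 0.05, 0.05, 0.05],
    ])
    pi = np.array([0.90, 0.04, 0.04, 0.02])
    return HmmModel(BEAT_STATES, LAYER2_ALPHABET, a, b, pi)


def classify_beats(observations: Sequence[BeatObservation],
                   model: HmmModel) -> list[BeatLabel]:
    """Viterbi-decode the beat sequence into beat-class labels."""
    if not observations:
        return []
    idx = [o.beat_index for o in observations]
    if any(b < a for a, b in zip(idx, idx[1:])):
        raise ValueError("observations must be ordered by beat_index")
    symbols = np.array([o.joint_symbol for o in observations], dtype=np.int64)
    path, _ = viterbi(model, symbols)
    return [BeatLabel(beat_index=o.beat_index, beat_class=BeatClass(model.states[s]))
            for o, s in zip(observations, path)]
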
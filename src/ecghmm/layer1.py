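"""Layer I: six-state cyclic left-right waveform HMM.

The hidden states are the six phases of one cardiac cycle —
``ISO1 -> P -> PQ -> QRS -> ST -> T`` — connected as a left-right chain
with self-loops, closed cyclically (``T -> ISO1``) so the model runs over
multi-beat records.  Decoding operates on the unit-level symbol stream
(not per sample) for tractability; state boundaries are projected back to
samples through the token spans.  From the decoded state intervals the
per-beat interval features (P-Q, QRS, T, R-R, P-P) are measured in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hmm import HmmModel, left_right_mask, viterbi
from .records import WAVE_STATES, BeatFeatures
from .segmentation import LAYER1_ALPHABET, SymbolStream

__all__ = [
    "StateInterval",
    "WaveStateLabeling",
    "default_layer1_model",
    "decode_waveform",
    "decoded_r_peaks",
    "extract_features",
]


@dataclass
class StateInterval:
    state: int           # index into WAVE_STATES
    onset: int           # samples, half-open span
    offset: int
    contains_unit: bool  # whether any detected sub-waveform lies inside

    @property
    def name(self) -> str:
        return WAVE_STATES[self.state]


@dataclass
class WaveStateLabeling:
    """Viterbi state labels per token plus merged sample-resolved intervals."""

    stream: SymbolStream
    token_states: np.ndarray
    intervals: list[StateInterval]
    log_probability: float


def default_layer1_model() -> HmmModel:
    """Untrained six-state model with physiologically informed priors.

    Emission priors favor the isoelectric symbol in ISO1/PQ/ST, the
    tall-narrow symbol in QRS, and the small unit symbols in P and T; the
    trained path (expert-assisted Baum-Welch) is the normative one, these
    priors just make the untrained model usable and give training a start.
    """
    mask = left_right_mask(6, cyclic=True)
    a = np.where(mask, 0.5, 0.0)
    a /= a.sum(axis=1, keepdims=True)
    #                 iso   tall  small-narrow  small-wide
    b = np.array([
        [0.88, 0.02, 0.06, 0.04],   # ISO1
        [0.15, 0.03, 0.70, 0.12],   # P
        [0.88, 0.04, 0.05, 0.03],   # PQ
        [0.06, 0.86, 0.04, 0.04],   # QRS
        [0.88, 0.03, 0.04, 0.05],   # ST
        [0.12, 0.03, 0.15, 0.70],   # T
    ])
    pi = np.array([0.90, 0.02, 0.02, 0.02, 0.02, 0.02])
    return HmmModel(WAVE_STATES, LAYER1_ALPHABET, a, b, pi, mask)


def decode_waveform(stream: SymbolStream, model: HmmModel) -> WaveStateLabeling:
    """Viterbi-decode the token stream under the cyclic left-right mask.

    Contiguous same-state token runs are merged into sample-resolved
    intervals.  The mask guarantees (and the output asserts) that decoded
    intervals honor the cyclic state order.
    """
    if not stream.tokens:
        return WaveStateLabeling(stream, np.zeros(0, dtype=np.int64), [], 0.0)
    path, logp = viterbi(model, stream.symbols)
    intervals: list[StateInterval] = []
    for token, state in zip(stream.tokens, path):
        s = int(state)
        if intervals and intervals[-1].state == s and intervals[-1].offset == token.onset:
            intervals[-1].offset = token.offset
            intervals[-1].contains_unit |= token.is_unit
        else:
            intervals.append(StateInterval(state=s, onset=token.onset,
                                           offset=token.offset,
                                           contains_unit=token.is_unit))
    k = len(WAVE_STATES)
    for prev, cur in zip(intervals, intervals[1:]):
        assert cur.state == (prev.state + 1) % k, "decoded intervals violate cyclic order"
    return WaveStateLabeling(stream=stream, token_states=path,
                             intervals=intervals, log_probability=logp)


def decoded_r_peaks(labeling: WaveStateLabeling) -> list[int]:
    """Sample index of the R peak of each decoded beat (the unit peak
    inside each QRS interval, or the interval midpoint if none)."""
    qrs_idx = WAVE_STATES.index("QRS")
    peaks: list[int] = []
    units = [t.unit for t in labeling.stream.tokens if t.is_unit]
    for interval in labeling.intervals:
        if interval.state != qrs_idx:
            continue
        peak = (interval.onset + interval.offset) // 2
        for u in units:
            if interval.onset <= u.peak_time < interval.offset:
                peak = u.peak_time
                break
        peaks.append(peak)
    return peaks


def extract_features(labeling: WaveStateLabeling, sampling_rate: float
                     ) -> list[BeatFeatures]:
    """One :class:`BeatFeatures` per decoded QRS interval.

    P-Q runs from the P-interval onset to the QRS onset and is undefined
    when the cycle's P interval contains no detected unit (an absent P
    wave); R-R/P-P are onset-to-onset distances of consecutive QRS/P
    intervals and are undefined for the first beat.
    """
    ms = 1000.0 / sampling_rate
    iv = labeling.intervals
    qrs_idx = WAVE_STATES.index("QRS")
    p_idx = WAVE_STATES.index("P")
    t_idx = WAVE_STATES.index("T")
    unit_spans = [(t.onset, t.offset) for t in labeling.stream.tokens if t.is_unit]

    def wave_span(interval: StateInterval) -> tuple[int, int]:
        # the wave itself is the detected unit inside the decoded interval;
        # neighboring isoelectric tokens absorbed by a self-loop do not count
        for on, off in unit_spans:
            if interval.onset <= on and off <= interval.offset:
                return on, off
        return interval.onset, interval.offset

    out: list[BeatFeatures] = []
    prev_q_on: Optional[int] = None
    prev_p_on: Optional[int] = None
    last_p: Optional[StateInterval] = None
    beat = 0
    for i, interval in enumerate(iv):
        if interval.state == p_idx:
            last_p = interval
        if interval.state != qrs_idx:
            continue
        q_on, q_off = wave_span(interval)
        p_ok = last_p is not None and last_p.contains_unit
        p_on = wave_span(last_p)[0] if p_ok else None
        pq = (q_on - p_on) * ms if p_ok else None
        t_dur = None
        for nxt in iv[i + 1:]:
            if nxt.state == qrs_idx:
                break
            if nxt.state == t_idx and nxt.contains_unit:
                t_on, t_off = wave_span(nxt)
                t_dur = (t_off - t_on) * ms
                break
        rr = (q_on - prev_q_on) * ms if prev_q_on is not None else None
        pp = ((p_on - prev_p_on) * ms
              if (p_ok and prev_p_on is not None) else None)
        out.append(BeatFeatures(
            beat_index=beat,
            pr_interval=pq,
            pq_interval=pq,
            qrs_duration=(q_off - q_on) * ms,
            t_duration=t_dur,
            rr_interval=rr,
            pp_interval=pp,
        ))
        prev_q_on = q_on
        if p_ok:
            prev_p_on = p_on
        last_p = None
        beat += 1
    return out
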
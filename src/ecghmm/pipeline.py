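"""End-to-end pipeline: simulate/read -> filter -> segment -> delineate ->
features -> beat symbols -> classify -> evaluate.

The pipeline is a pure function of (input record or plan, configuration,
seed).  When the record carries ground truth, the two HMM layers are
trained with the expert-annotation-assisted Baum-Welch loop, the expert
annotations being disjoint labeled prefixes of the observation streams;
without ground truth the default prior models are used (or models loaded
from files).

The band-stop filter delays its output by the matched group delay; the
pipeline advances the filtered series by that delay so sample indices stay
aligned with the input and its annotations.  Beats overlapping the filter
warm-up, plus the first two and final beats, are excluded from evaluation
(not from detection or classification).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .filters import IcbsFilterSpec, apply_bandstop
from .hmm import (AnnotatedSequence, ExpertTrainConfig, HmmModel,
                  expert_assisted_train, left_right_mask)
from .layer1 import (decode_waveform, decoded_r_peaks, default_layer1_model,
                     extract_features)
from .layer2 import (BEAT_STATES, LAYER2_ALPHABET, BeatObservation,
                     NormalRanges, classify_beats, default_layer2_model,
                     symbolize_beats)
from .metrics import (beat_confusion, classification_report, validate_features)
from .records import WAVE_STATES, BeatClass, EcgRecord
from .segmentation import (QuantizerConfig, SymbolStream, auto_merge_thresholds,
                           detect_local_maxima, merge_non_maximal,
                           symbolize_units)
from .synthetic import NoiseSettings, make_plan, make_rhythm, true_features

__all__ = ["PipelineConfig", "run_pipeline", "align_filtered",
           "segment_record", "train_layer1", "train_layer2"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end run depends on; the seed fixes all
    stochastic stages (simulation and training data splits)."""

    seed: int = 0
    sampling_rate: float = 400.0
    # simulation (used when no input record is supplied)
    n_beats: int = 200
    pvc_rate: float = 0.05
    apc_rate: float = 0.05
    noise: Optional[NoiseSettings] = None   # None -> generator defaults
    # filtering / segmentation
    filter_spec: IcbsFilterSpec = field(default_factory=IcbsFilterSpec)
    search_window: int = 40
    min_prominence: float = 0.06
    span_epsilon: float = 0.04
    quantizer: QuantizerConfig = field(default_factory=QuantizerConfig)
    # classification
    ranges: NormalRanges = field(default_factory=NormalRanges)
    # training
    train: bool = True
    n_experts: int = 3
    beats_per_expert: int = 40
    train_config: ExpertTrainConfig = field(default_factory=ExpertTrainConfig)
    layer1_model: Optional[HmmModel] = None
    layer2_model: Optional[HmmModel] = None
    # evaluation
    feature_tolerance_ms: float = 10.0
    match_tolerance_ms: float = 150.0


def align_filtered(record: EcgRecord, spec: IcbsFilterSpec) -> EcgRecord:
    """Band-stop filter and advance by the group delay so the output is
    sample-aligned with the input (and its annotations).

    The input is extended with ``allpass_delay`` trailing zeros before
    filtering so the delayed output covers the final samples too (the tail
    then sees silence where the record ends, symmetric to the zero-padded
    start)."""
    d = spec.allpass_delay
    n = len(record)
    padded = EcgRecord(np.concatenate([record.samples, np.zeros(d)]),
                       record.sampling_rate, record.record_id)
    filtered = apply_bandstop(padded, spec)
    return EcgRecord(samples=filtered.samples[d:d + n],
                     sampling_rate=record.sampling_rate,
                     record_id=(record.record_id + "-icbs") if record.record_id else "icbs",
                     annotations=record.annotations,
                     warmup_samples=max(0, min(filtered.warmup_samples, n + d) - d))


def segment_record(filtered: EcgRecord, config: PipelineConfig) -> SymbolStream:
    units = detect_local_maxima(filtered, search_window=config.search_window,
                                min_prominence=config.min_prominence,
                                span_epsilon=config.span_epsilon)
    thr = auto_merge_thresholds(units, filtered.sampling_rate)
    units = merge_non_maximal(units, thr)
    return symbolize_units(units, len(filtered), filtered.sampling_rate,
                           config.quantizer)


def _token_truth_labels(stream: SymbolStream, state_labels: np.ndarray) -> np.ndarray:
    """Ground-truth wave state per token: at the unit peak, or the token
    midpoint for isoelectric tokens."""
    out = np.empty(len(stream), dtype=np.int64)
    n = state_labels.size
    for i, tok in enumerate(stream.tokens):
        idx = tok.unit.peak_time if tok.is_unit else tok.midpoint
        out[i] = state_labels[min(idx, n - 1)]
    return out


def _expert_slices(stream: SymbolStream, record: EcgRecord, n_experts: int,
                   beats_per_expert: int, skip_beats: int = 2) -> list[slice]:
    beats = record.annotations.beats
    slices = []
    for e in range(n_experts):
        b0 = skip_beats + e * beats_per_expert
        b1 = min(b0 + beats_per_expert, len(beats))
        if b0 >= b1:
            break
        lo = beats[b0].onset
        hi = beats[b1 - 1].offset
        idx = [i for i, t in enumerate(stream.tokens) if lo <= t.onset < hi]
        if idx:
            slices.append(slice(idx[0], idx[-1] + 1))
    return slices


def train_layer1(stream: SymbolStream, record: EcgRecord,
                 config: PipelineConfig) -> HmmModel:
    """Expert-assisted training of the waveform HMM from ground truth.

    The simulated experts annotate disjoint blocks of beats (their short
    labeled sequences), while the full token stream serves as the long
    unlabeled observation sequence."""
    truth = _token_truth_labels(stream, record.annotations.state_labels)
    symbols = stream.symbols
    anns = [AnnotatedSequence(symbols[s], truth[s], annotator_id=f"expert-{k}")
            for k, s in enumerate(_expert_slices(stream, record, config.n_experts,
                                                 config.beats_per_expert))]
    if not anns:
        return default_layer1_model()
    result = expert_assisted_train(anns, symbols, WAVE_STATES,
                                   stream.alphabet,
                                   structure_mask=left_right_mask(len(WAVE_STATES)),
                                   config=config.train_config)
    return result.model


def train_layer2(observations: list[BeatObservation], truth_classes: list[BeatClass],
                 config: PipelineConfig) -> HmmModel:
    """Expert-assisted training of the beat-classification HMM from
    ground-truth beat classes over disjoint prefix blocks."""
    symbols = np.array([o.joint_symbol for o in observations], dtype=np.int64)
    labels = np.array([BEAT_STATES.index(c.value) for c in truth_classes],
                      dtype=np.int64)
    n = symbols.size
    per = max(10, min(150, n // max(1, config.n_experts)))
    anns = []
    for e in range(config.n_experts):
        lo, hi = e * per, min((e + 1) * per, n)
        if lo >= hi:
            break
        anns.append(AnnotatedSequence(symbols[lo:hi], labels[lo:hi],
                                      annotator_id=f"expert-{e}"))
    if not anns:
        return default_layer2_model()
    result = expert_assisted_train(anns, symbols, BEAT_STATES, LAYER2_ALPHABET,
                                   config=config.train_config)
    return result.model


def _greedy_match(a_times: list[int], b_times: list[int],
                  tol: int) -> list[tuple[int, int]]:
    pairs = []
    i = j = 0
    while i < len(a_times) and j < len(b_times):
        if abs(a_times[i] - b_times[j]) <= tol:
            pairs.append((i, j))
            i += 1
            j += 1
        elif a_times[i] < b_times[j]:
            i += 1
        else:
            j += 1
    return pairs


def run_pipeline(config: PipelineConfig,
                 record: Optional[EcgRecord] = None) -> dict:
    """Run the full chain and return a JSON-serializable report.

    With no input record, a rhythm is simulated from the config.  The
    report carries detection counts over all decoded beats and, when
    ground truth is available, feature-extraction accuracy and per-class
    sensitivity/positive predictivity over the evaluable beats.
    """
    if record is None:
        plan = make_plan(config.n_beats, config.pvc_rate, config.apc_rate,
                         seed=config.seed, noise=config.noise)
        record = make_rhythm(plan, config.sampling_rate)
    report: dict = {
        "record_id": record.record_id,
        "seed": config.seed,
        "n_samples": len(record),
    }
    if len(record) == 0:
        report.update({"n_beats_detected": 0, "labels": [], "warning": "empty record"})
        return report
    filtered = align_filtered(record, config.filter_spec)
    stream = segment_record(filtered, config)
    truth = record.annotations
    if config.layer1_model is not None:
        model1 = config.layer1_model
    elif config.train and truth is not None and truth.state_labels is not None:
        model1 = train_layer1(stream, record, config)
    else:
        model1 = default_layer1_model()
    labeling = decode_waveform(stream, model1)
    features = extract_features(labeling, record.sampling_rate)
    report["n_beats_detected"] = len(features)
    if not features:
        report.update({"labels": [], "warning": "no QRS detected"})
        return report
    observations = symbolize_beats(features, config.ranges)

    tol = int(round(config.match_tolerance_ms * record.sampling_rate / 1000.0))
    pred_peaks = decoded_r_peaks(labeling)
    matches: list[tuple[int, int]] = []
    if truth is not None:
        true_peaks = [b.r_peak for b in truth.beats]
        matches = _greedy_match(true_peaks, pred_peaks, tol)

    if config.layer2_model is not None:
        model2 = config.layer2_model
    elif config.train and truth is not None and matches:
        truth_classes = [truth.beats[i].beat_class for i, _ in matches]
        matched_obs = [observations[j] for _, j in matches]
        model2 = train_layer2(matched_obs, truth_classes, config)
    else:
        model2 = default_layer2_model()
    labels = classify_beats(observations, model2)
    counts: dict[str, int] = {c.value: 0 for c in BeatClass}
    for lab in labels:
        counts[lab.beat_class.value] += 1
    report["class_counts"] = counts
    report["labels"] = [{"beat_index": l.beat_index, "class": l.beat_class.value}
                        for l in labels]

    if truth is not None and matches:
        n_true = len(truth.beats)
        evaluable = {i for i, _ in matches
                     if 2 <= i < n_true - 1
                     and truth.beats[i].onset >= filtered.warmup_samples}
        # feature validation against ground-truth intervals
        expert = true_features(record)
        expert_aligned = [replace(expert[i], beat_index=j)
                          for i, j in matches if i in evaluable]
        if expert_aligned:
            val = validate_features(features, expert_aligned,
                                    tolerance_ms=config.feature_tolerance_ms)
            report["feature_validation"] = dataclasses.asdict(val)
        # beat-class confusion over evaluable beats
        label_by_index = {l.beat_index: l.beat_class for l in labels}
        true_pairs = [(truth.beats[i].r_peak, truth.beats[i].beat_class)
                      for i, _ in matches if i in evaluable]
        pred_pairs = [(pred_peaks[j], label_by_index[features[j].beat_index])
                      for i, j in matches if i in evaluable]
        confusion = beat_confusion(true_pairs, pred_pairs, tol)
        report["classification"] = classification_report(confusion)
    return report
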
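"""Waveform unit detection, non-maximal merging and symbolization.

The filtered signal is scanned for strict local maxima of the absolute
amplitude (so inverted ectopic QRS complexes are found too).  Each peak
becomes a :class:`Unit` whose span runs to the surrounding near-zero
crossings; adjacent units whose peak values *and* peak times are both
within the merge thresholds are fused (the non-maximal constraint, which
repairs over-segmentation).  Units and the isoelectric gaps between them
are then quantized into a small discrete alphabet — the observation
symbols of the first HMM layer.

Unit spans are measured at a small amplitude floor and extrapolated to the
true lobe edge under a raised-cosine edge model, so measured wave
durations track the underlying lobe width rather than the detection
threshold (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .records import EcgRecord

__all__ = [
    "Unit",
    "MergeThresholds",
    "QuantizerConfig",
    "Token",
    "SymbolStream",
    "detect_local_maxima",
    "auto_merge_thresholds",
    "merge_non_maximal",
    "symbolize_units",
    "LAYER1_ALPHABET",
]

#: Layer-I observation alphabet: isoelectric gap, tall-narrow (QRS-like),
#: small-narrow (P-like) and small-wide (T-like) units.
LAYER1_ALPHABET: tuple[str, ...] = ("iso", "tall", "small-narrow", "small-wide")


@dataclass
class Unit:
    """A candidate sub-waveform: signed peak value, peak time, span."""

    peak_value: float
    peak_time: int
    onset: int
    offset: int  # half-open

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak_time < self.offset):
            raise ValueError("unit span must contain the peak time")

    @property
    def span(self) -> int:
        return self.offset - self.onset


@dataclass(frozen=True)
class MergeThresholds:
    """Non-maximal-constraint thresholds: amplitude (mV) and time (samples)."""

    delta_p: float
    delta_t: float

    def __post_init__(self) -> None:
        if self.delta_p <= 0 or self.delta_t <= 0:
            raise ValueError("merge thresholds must be positive")


def _edge_corrected_span(a: np.ndarray, peak: int, eps: float,
                         lo: int, hi: int) -> tuple[int, int]:
    """Span of the lobe around ``peak``: amplitude-floor crossings, then
    extrapolated outward assuming a raised-cosine edge shape."""
    onset = peak
    while onset > lo and a[onset - 1] > eps:
        onset -= 1
    offset = peak + 1
    while offset < hi and a[offset] > eps:
        offset += 1
    amp = a[peak]
    if eps > 0 and amp > eps:
        # raised-cosine lobe f(u) = A cos^2(pi u / d) around its peak crosses
        # eps at u = (d/2)(1 - phi/pi), phi = arccos(1 - 2 eps/A)
        phi = np.arccos(np.clip(1.0 - 2.0 * eps / amp, -1.0, 1.0))
        factor = 1.0 / (1.0 - phi / np.pi)
        onset = peak - int(round((peak - onset) * factor))
        offset = peak + int(round((offset - 1 - peak) * factor)) + 1
    return max(lo, onset), min(hi, offset)


def detect_local_maxima(record: EcgRecord, search_window: int = 40,
                        min_prominence: float = 0.06,
                        span_epsilon: float = 0.04) -> list[Unit]:
    """Find strict local maxima of ``|signal|`` and wrap them as units.

    Because the band-stop filter nulls DC, the filtered record's
    isoelectric plateau sits at minus the local beat average; amplitudes
    are therefore measured against the isoelectric level: first the record
    median (a global estimate), then — after a provisional span pass — a
    per-sample baseline interpolated through the isoelectric stretches
    between lobes.  A sample is a peak when its baseline-referenced
    absolute amplitude exceeds ``min_prominence`` and is not exceeded
    anywhere within ``+-search_window`` samples; of two equal peaks inside
    one window the earlier is kept (documented tie-break).  Unit spans
    extend to the surrounding crossings of the ``span_epsilon`` amplitude
    floor, extrapolated to the lobe edge (raised-cosine edge model), and
    are clipped so they never overlap.
    """
    x = record.samples
    n = x.size
    if n == 0:
        return []
    x = x - np.median(x)
    a = np.abs(x)
    win_max = maximum_filter1d(a, size=2 * search_window + 1, mode="constant", cval=0.0)
    candidates = np.flatnonzero((a >= win_max) & (a > min_prominence))
    peaks: list[int] = []
    for i in candidates:
        if peaks and i - peaks[-1] <= search_window:
            continue  # equal-valued tie inside the window: keep the earlier
        peaks.append(int(i))
    if not peaks:
        return []
    # Iteratively estimate the isoelectric baseline: spans of the current
    # pass mask the lobes, the baseline is interpolated through what
    # remains, and the next pass re-measures spans against it.  The first
    # pass caps the mask half-width so a pedestal under an ectopic complex
    # cannot swallow the short isoelectric gaps that anchor the baseline.
    pad = max(2, search_window // 6)
    cap = 2 * search_window
    smooth = uniform_filter1d(x, size=9)
    xr, ar = x, a
    for first_pass in (True, False):
        iso_mask = np.ones(n, dtype=bool)
        for i in peaks:
            on, off = _edge_corrected_span(ar, i, span_epsilon, 0, n)
            if first_pass:
                on, off = max(on, i - cap), min(off, i + cap + 1)
            iso_mask[max(0, on - pad):min(n, off + pad)] = False
        idx = np.flatnonzero(iso_mask)
        if idx.size < 2:
            break
        baseline = np.interp(np.arange(n), idx, smooth[idx])
        xr = x - baseline
        ar = np.abs(xr)
    units: list[Unit] = []
    for i in peaks:
        if ar[i] <= min_prominence:
            continue
        onset, offset = _edge_corrected_span(ar, i, span_epsilon, 0, n)
        units.append(Unit(peak_value=float(xr[i]), peak_time=i, onset=onset, offset=offset))
    for prev, cur in zip(units, units[1:]):  # enforce non-overlapping spans
        if cur.onset < prev.offset:
            mid = (prev.peak_time + cur.peak_time + 1) // 2
            prev.offset = min(prev.offset, max(mid, prev.peak_time + 1))
            cur.onset = max(cur.onset, min(mid, cur.peak_time))
    return units


def auto_merge_thresholds(units: Sequence[Unit], sampling_rate: float,
                          delta_t_ms: float = 40.0) -> MergeThresholds:
    """Data-driven defaults: delta_p = 10% of the median tall-peak (R)
    amplitude, delta_t = 40 ms (below the shortest inter-wave gap)."""
    delta_t = max(1.0, delta_t_ms * sampling_rate / 1000.0)
    if not units:
        return MergeThresholds(delta_p=0.1, delta_t=delta_t)
    amps = np.array([abs(u.peak_value) for u in units])
    tall = amps[amps >= 0.5 * amps.max()]
    return MergeThresholds(delta_p=max(1e-6, 0.1 * float(np.median(tall))), delta_t=delta_t)


def merge_non_maximal(units: Sequence[Unit], thr: MergeThresholds) -> list[Unit]:
    """Fuse adjacent units that agree in both peak value and peak time.

    Adjacent units with ``|P1 - P2| <= delta_p`` and ``|T1 - T2| <= delta_t``
    belong to the same observation symbol; they are merged (span union,
    peak taken from the larger ``|P|``) left-to-right until a fixed point.
    """
    times = [u.peak_time for u in units]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("units must be ordered by peak_time")
    out = [Unit(u.peak_value, u.peak_time, u.onset, u.offset) for u in units]
    changed = True
    while changed:
        changed = False
        merged: list[Unit] = []
        for u in out:
            if merged:
                prev = merged[-1]
                if (abs(prev.peak_value - u.peak_value) <= thr.delta_p
                        and abs(prev.peak_time - u.peak_time) <= thr.delta_t):
                    keep = u if abs(u.peak_value) > abs(prev.peak_value) else prev
                    merged[-1] = Unit(peak_value=keep.peak_value,
                                      peak_time=keep.peak_time,
                                      onset=min(prev.onset, u.onset),
                                      offset=max(prev.offset, u.offset))
                    changed = True
                    continue
            merged.append(u)
        out = merged
    return out


@dataclass(frozen=True)
class QuantizerConfig:
    """Binning of units and gaps into the layer-I alphabet.

    ``n_symbols`` of 4 (the default) distinguishes isoelectric gaps,
    tall-narrow units (normalized amplitude >= ``amp_high``; QRS-like),
    small-narrow units (span <= ``dur_split_ms``; P-like) and small-wide
    units (T-like).  K=3 folds the two small bins together; K=2 keeps only
    gap vs unit.  Long gaps are emitted as chunks of at most
    ``gap_chunk_ms`` so the decoder can place state boundaries inside them.
    """

    n_symbols: int = 4
    amp_high: float = 0.5
    dur_split_ms: float = 130.0
    gap_chunk_ms: float = 25.0
    reference_amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_symbols < 2:
            raise ValueError("need at least 2 observation symbols")
        if self.n_symbols > 4:
            raise ValueError("the layer-I quantizer defines at most 4 bins")


@dataclass
class Token:
    """One element of the layer-I observation sequence with its sample span."""

    symbol: int
    onset: int
    offset: int
    unit: Optional[Unit] = None

    @property
    def is_unit(self) -> bool:
        return self.unit is not None

    @property
    def midpoint(self) -> int:
        return (self.onset + self.offset) // 2


@dataclass
class SymbolStream:
    tokens: list[Token]
    alphabet: tuple[str, ...]
    sampling_rate: float

    @property
    def symbols(self) -> np.ndarray:
        return np.array([t.symbol for t in self.tokens], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.tokens)


def _unit_symbol(unit: Unit, ref: float, fs: float, cfg: QuantizerConfig) -> int:
    if cfg.n_symbols == 2:
        return 1
    namp = abs(unit.peak_value) / ref if ref > 0 else 0.0
    if namp >= cfg.amp_high:
        return 1  # tall-narrow
    if cfg.n_symbols == 3:
        return 2
    span_ms = unit.span * 1000.0 / fs
    return 2 if span_ms <= cfg.dur_split_ms else 3


def symbolize_units(units: Sequence[Unit], n_samples: int, sampling_rate: float,
                    config: QuantizerConfig = QuantizerConfig()) -> SymbolStream:
    """Quantize units and inter-unit gaps into the discrete alphabet.

    Deterministic given the config; the amplitude reference defaults to the
    median of the tall peaks (a running R-amplitude estimate).
    """
    ref = config.reference_amplitude
    if ref is None:
        if units:
            amps = np.array([abs(u.peak_value) for u in units])
            tall = amps[amps >= 0.5 * amps.max()]
            ref = float(np.median(tall))
        else:
            ref = 1.0
    chunk = max(1, int(round(config.gap_chunk_ms * sampling_rate / 1000.0)))
    tokens: list[Token] = []

    def emit_gap(lo: int, hi: int) -> None:
        width = hi - lo
        if width <= 0:
            return
        k = max(1, -(-width // chunk))  # ceil division: every chunk <= gap_chunk_ms
        edges = np.linspace(lo, hi, k + 1).round().astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                tokens.append(Token(symbol=0, onset=int(a), offset=int(b)))

    pos = 0
    for u in units:
        emit_gap(pos, u.onset)
        tokens.append(Token(symbol=_unit_symbol(u, ref, sampling_rate, config),
                            onset=u.onset, offset=u.offset, unit=u))
        pos = u.offset
    emit_gap(pos, n_samples)
    alphabet = LAYER1_ALPHABET[:config.n_symbols] if config.n_symbols >= 2 else LAYER1_ALPHABET
    return SymbolStream(tokens=tokens, alphabet=tuple(alphabet), sampling_rate=sampling_rate)
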
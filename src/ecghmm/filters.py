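"""Integer-coefficient band-stop (comb-subtraction) denoising filter.

The filter removes baseline wander and power-line interference from a
single-lead ECG sampled at ``fs`` (400 Hz by design).  A linear-phase comb
band-pass

.. math::

    H_{bp}(z) = \\frac{1}{2^{q}}\\left(\\frac{1-z^{-L}}{1-z^{-S}}\\right)^{k}

(defaults ``L = 256``, ``S = 8``, ``k = 2``, ``q = 10``) passes exactly the
narrow bands around every multiple of ``fs/S`` Hz — DC (the wander) and
50 Hz plus harmonics at the default rate — with unit gain and constant
group delay ``D = k(L-S)/2 = 248`` samples.  Subtracting it from a matched
pure delay yields the band-stop

.. math::

    H(z) = z^{-D} - H_{bp}(z),

whose magnitude is exactly zero at every multiple of ``fs/S``.  Because
every coefficient is an integer and the scale is a power of two, the filter
runs on integer hardware with additions, subtractions and one arithmetic
right shift — the integer path here reproduces that arithmetic bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .records import EcgRecord

__all__ = [
    "IcbsFilterSpec",
    "FilterResponse",
    "build_bandpass_coefficients",
    "apply_bandstop",
    "apply_bandstop_integer",
    "frequency_response",
    "group_delay",
]


@dataclass(frozen=True)
class IcbsFilterSpec:
    """Structural parameters of the band-pass/band-stop pair.

    ``scale_shift`` and ``allpass_delay`` may be omitted; they are then
    derived from the comb lags (they are fully determined by the
    requirement of unit DC gain and matched group delay).
    """

    comb_long_lag: int = 256
    comb_short_lag: int = 8
    squaring_order: int = 2
    scale_shift: Optional[int] = None
    allpass_delay: Optional[int] = None
    sampling_rate: float = 400.0

    def __post_init__(self) -> None:
        L, S, k = self.comb_long_lag, self.comb_short_lag, self.squaring_order
        if S <= 0 or L <= S:
            raise ValueError("need comb_long_lag > comb_short_lag > 0")
        if k < 1:
            raise ValueError("squaring_order must be >= 1")
        if L % S != 0:
            raise ValueError(
                f"comb_long_lag ({L}) must be an integer multiple of comb_short_lag ({S})"
            )
        ratio = L // S
        gain = ratio**k  # DC gain of the unscaled band-pass
        if gain & (gain - 1):
            raise ValueError(
                f"(comb_long_lag/comb_short_lag)**order = {gain} is not a power of two; "
                "the scale cannot be realized as a bit shift"
            )
        shift = gain.bit_length() - 1
        if self.scale_shift is None:
            object.__setattr__(self, "scale_shift", shift)
        elif self.scale_shift != shift:
            raise ValueError(
                f"scale_shift must be {shift} so that 2**scale_shift equals the "
                f"band-pass DC gain {gain}"
            )
        if (k * (L - S)) % 2 != 0:
            raise ValueError("k*(L-S) must be even for an integer matched delay")
        delay = k * (L - S) // 2
        if self.allpass_delay is None:
            object.__setattr__(self, "allpass_delay", delay)
        elif self.allpass_delay != delay:
            raise ValueError(
                f"allpass_delay must equal squaring_order*(L-S)/2 = {delay}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def span(self) -> int:
        """Length of the FIR transient: k*(L-S) samples."""
        return self.squaring_order * (self.comb_long_lag - self.comb_short_lag)

    @property
    def notch_spacing_hz(self) -> float:
        """Spacing between consecutive spectral nulls of the band-stop."""
        return self.sampling_rate / self.comb_short_lag


def build_bandpass_coefficients(spec: IcbsFilterSpec) -> np.ndarray:
    """Expanded integer FIR numerator of the comb band-pass.

    ``(1-z^-L)/(1-z^-S)`` divides exactly to a comb of ``L/S`` unit taps at
    stride ``S``; raising to ``squaring_order`` by self-convolution gives an
    integer sequence spanning lags 0..k(L-S), symmetric about the matched
    delay, with coefficient sum ``2**scale_shift``.
    """
    L, S = spec.comb_long_lag, spec.comb_short_lag
    comb = np.zeros(L - S + 1, dtype=np.int64)
    comb[::S] = 1
    coeffs = comb
    for _ in range(spec.squaring_order - 1):
        coeffs = np.convolve(coeffs, comb)
    assert int(coeffs.sum()) == 2**spec.scale_shift
    return coeffs


def apply_bandstop(record: EcgRecord, spec: IcbsFilterSpec) -> EcgRecord:
    """Band-stop filter a record (floating-point reference path).

    ``y[n] = x[n-D] - 2**-q * (c * x)[n]`` with zero padding before the
    record start.  The output keeps the input length and sample indexing
    (hence lags the input by ``D`` samples); the first ``span`` samples are
    flagged as warm-up via ``warmup_samples``.
    """
    if record.sampling_rate != spec.sampling_rate:
        raise ValueError(
            f"record sampling rate {record.sampling_rate} Hz does not match "
            f"filter design rate {spec.sampling_rate} Hz"
        )
    x = record.samples
    n = x.size
    if n < spec.span:
        warnings.warn(
            f"record shorter than the filter span ({n} < {spec.span}); "
            "the whole output is transient",
            stacklevel=2,
        )
    coeffs = build_bandpass_coefficients(spec) / float(2**spec.scale_shift)
    if n == 0:
        bp = np.zeros(0)
    elif n > 4096:
        bp = _signal.oaconvolve(x, coeffs)[:n]
    else:
        bp = np.convolve(x, coeffs)[:n]
    delay = spec.allpass_delay
    ap = np.concatenate([np.zeros(min(delay, n)), x])[:n]
    return EcgRecord(
        samples=ap - bp,
        sampling_rate=record.sampling_rate,
        record_id=(record.record_id + "-icbs") if record.record_id else "icbs",
        annotations=record.annotations,
        warmup_samples=min(n, spec.span),
    )


def _running_comb(x: np.ndarray, long_lag: int, short_lag: int) -> np.ndarray:
    """One pass of (1-z^-L)/(1-z^-S) as running sums, exact in int64."""
    d = x.copy()
    if x.size > long_lag:
        d[long_lag:] -= x[:-long_lag]
    out = np.empty_like(d)
    for r in range(min(short_lag, x.size)):
        out[r::short_lag] = np.cumsum(d[r::short_lag])
    return out


def apply_bandstop_integer(samples: Sequence[int] | np.ndarray,
                           spec: IcbsFilterSpec) -> np.ndarray:
    """Shift-only integer band-stop path (microcontroller arithmetic).

    Uses only additions, subtractions and a single arithmetic right shift
    by ``scale_shift`` at the end, i.e. floor-toward-minus-infinity
    rounding applied exactly once:
    ``y[n] = (x[n-D]*2**q - acc[n]) >> q``.
    """
    x = np.asarray(samples)
    if x.dtype.kind == "f":
        if not np.all(x == np.round(x)):
            raise TypeError(
                "apply_bandstop_integer requires integer-valued samples; "
                "use apply_bandstop for floating-point data"
            )
        x = x.astype(np.int64)
    elif x.dtype.kind not in "iu":
        raise TypeError("apply_bandstop_integer requires an integer array")
    else:
        x = x.astype(np.int64)
    if x.size == 0:
        return x
    ratio = spec.comb_long_lag // spec.comb_short_lag
    bound = int(np.abs(x).max()) * ratio**spec.squaring_order
    if bound >= 2**62:
        raise OverflowError("input magnitude too large for the int64 accumulator")
    acc = x
    for _ in range(spec.squaring_order):
        acc = _running_comb(acc, spec.comb_long_lag, spec.comb_short_lag)
    delay = spec.allpass_delay
    ap = np.concatenate([np.zeros(min(delay, x.size), dtype=np.int64), x])[: x.size]
    return ((ap << spec.scale_shift) - acc) >> spec.scale_shift


@dataclass
class FilterResponse:
    frequencies: np.ndarray
    complex_gain: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray  # unwrapped, radians


def frequency_response(spec: IcbsFilterSpec,
                       frequencies: Sequence[float] | np.ndarray) -> FilterResponse:
    """Evaluate the band-stop transfer function on the unit circle.

    The band-stop FIR (delta at D minus the scaled band-pass) is symmetric
    about lag D, so ``H = exp(-jDw) * R(w)`` with a *real* zero-phase factor
    ``R``; evaluating ``R`` directly keeps the spectral nulls exact to
    machine precision and makes the linear phase explicit.
    """
    f = np.asarray(frequencies, dtype=float)
    nyq = spec.sampling_rate / 2.0
    if f.size and (f.min() < 0 or f.max() > nyq):
        raise ValueError(f"frequencies must lie within [0, {nyq}] Hz")
    coeffs = build_bandpass_coefficients(spec).astype(float)
    d = spec.allpass_delay
    scale = float(2**spec.scale_shift)
    w = 2.0 * np.pi * f / spec.sampling_rate
    ds = np.arange(spec.comb_short_lag, d + 1, spec.comb_short_lag)
    # symmetric cosine sum about the center tap
    r = 1.0 - (coeffs[d] + 2.0 * np.cos(np.outer(w, ds)) @ coeffs[d - ds]) / scale
    h = np.exp(-1j * d * w) * r
    phase = np.unwrap(np.angle(h)) if f.size > 1 else np.angle(h)
    return FilterResponse(frequencies=f, complex_gain=h, magnitude=np.abs(r), phase=phase)


def group_delay(spec: IcbsFilterSpec) -> int:
    """Constant group delay of the linear-phase band-pass branch (samples).

    Computed as the centroid of the symmetric coefficient sequence in exact
    integer arithmetic; equals ``allpass_delay`` by construction.
    """
    coeffs = build_bandpass_coefficients(spec)
    lags = np.arange(coeffs.size, dtype=np.int64)
    total = int(coeffs.sum())
    moment = int((lags * coeffs).sum())
    if moment % total != 0:  # pragma: no cover - impossible for valid specs
        raise ValueError("coefficient centroid is not an integer sample count")
    centroid = moment // total
    assert centroid == spec.allpass_delay
    return centroid
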
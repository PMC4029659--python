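"""Remove power-line interference and baseline wander from a noisy rhythm.

Builds a short synthetic rhythm contaminated with 0.3 mV baseline wander
at 0.25 Hz and 50/100 Hz power-line interference, applies the
integer-coefficient band-stop filter, and prints how much of each noise
component survives.  The 50 Hz component lands exactly on a spectral null
and is annihilated; the wander sits deep in the stop band around DC.
"""

import numpy as np

from ecghmm import (IcbsFilterSpec, NoiseSettings, apply_bandstop,
                    frequency_response, make_plan, make_rhythm)


def band_power(x: np.ndarray, fs: float, f0: float, half_width: float = 1.0) -> float:
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    sel = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    return spectrum[sel].sum()


noise = NoiseSettings(baseline_freq_hz=0.25, baseline_amp_mv=0.3,
                      powerline_amps_mv=(0.1, 0.05), white_noise_sd_mv=0.0)
record = make_rhythm(make_plan(40, pvc_rate=0, apc_rate=0, seed=1, noise=noise), 400.0)
spec = IcbsFilterSpec()
filtered = apply_bandstop(record, spec)

x = record.samples
y = filtered.samples[filtered.warmup_samples:]
x = x[: y.size]
print(f"filtered {len(record)} samples; warm-up {filtered.warmup_samples} samples\n")
for f0, name in [(0.25, "baseline wander"), (50.0, "power line"), (100.0, "2nd harmonic")]:
    before = band_power(x, 400.0, f0)
    after = band_power(y, 400.0, f0)
    drop = 10 * np.log10(after / before)
    predicted = frequency_response(spec, [f0]).magnitude[0]
    print(f"{name:16s} ({f0:6.2f} Hz): power {drop:7.1f} dB "
          f"(transfer-function gain {predicted:.3e})")
print("\nNegative dB = removed; the 50/100 Hz components sit on exact nulls.")
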
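"""Delineate P / QRS / T waves and measure per-beat intervals.

Simulates 80 noise-free beats, filters and segments them, trains the
six-state waveform model with the expert-annotation-assisted loop (the
experts are labeled prefixes of the ground truth), decodes the waveform
states, and compares the measured intervals with the generator's truth.
"""

import numpy as np

from ecghmm import NoiseSettings, make_plan, make_rhythm, true_features
from ecghmm.layer1 import decode_waveform, extract_features
from ecghmm.pipeline import (PipelineConfig, align_filtered, segment_record,
                             train_layer1)

config = PipelineConfig(seed=3)
record = make_rhythm(make_plan(80, pvc_rate=0.05, apc_rate=0.05, seed=3,
                               noise=NoiseSettings.none()), 400.0)
filtered = align_filtered(record, config.filter_spec)
stream = segment_record(filtered, config)
model = train_layer1(stream, record, config)
labeling = decode_waveform(stream, model)
features = extract_features(labeling, record.sampling_rate)
truth = true_features(record)

print(f"{len(features)} beats delineated from {len(stream)} observation tokens\n")
print("interval        measured (mean)   truth (mean)   mean |error|")
for name in ("pq_interval", "qrs_duration", "t_duration", "rr_interval"):
    pairs = [(getattr(f, name), getattr(t, name))
             for f, t in zip(features[2:-1], truth[2:-1])
             if getattr(f, name) is not None and getattr(t, name) is not None]
    got = np.array([p[0] for p in pairs])
    want = np.array([p[1] for p in pairs])
    print(f"{name:14s} {got.mean():10.1f} ms {want.mean():12.1f} ms"
          f" {np.abs(got - want).mean():10.2f} ms")
print("\nP-Q and R-R track the generator within a couple of milliseconds;")
print("ventricular ectopics are measured with no P wave, as rendered.")
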
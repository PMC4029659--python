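# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic-data
tests do and do not demonstrate.

## Band-stop filter

The denoising filter is the difference of a pure delay and a comb
band-pass, `H(z) = z^-D - (1/2^q) * ((1-z^-L)/(1-z^-S))^k`, with defaults
`L = 256`, `S = 8`, `k = 2` at `fs = 400` Hz.  Three identities tie the
parameters together and are enforced by `IcbsFilterSpec`:

* `L` is a multiple of `S`, so the comb ratio divides exactly into an
  integer FIR (L/S taps at stride S; squared by self-convolution);
* the scale is the band-pass DC gain, `(L/S)^k = 1024 = 2^q`, so the
  pass-through gain is exactly 1 and the divisor is a bit shift;
* the matched delay is the symmetric FIR's centroid, `D = k(L-S)/2 = 248`
  samples (620 ms at 400 Hz).

Consequences used throughout: the band-stop magnitude is exactly zero at
every multiple of `fs/S = 50` Hz (DC, 50, 100, 150, 200 Hz), the phase is
strictly linear, and the stop band around DC removes everything below
roughly 0.8 Hz (21.8 dB at the 0.25 Hz default wander frequency, 18.7 dB
at 0.3 Hz — the attenuation falls off quickly toward 0.5 Hz, so slow
wander is suppressed rather than annihilated).

Numerics.  The recursive comb (pole-zero cancellation on the unit circle)
is marginally stable in floating point, so the float path uses the
algebraically identical expanded FIR; the integer path uses the recursive
running-sum form, which cancels exactly in integer arithmetic
(accumulators bounded by `max|x| * (L/S)^k`, checked against int64).
Rounding in the integer path is a single arithmetic right shift — floor
toward minus infinity, applied once at the output, matching typical
microcontroller shift semantics.  Frequency responses are evaluated
through the symmetric (zero-phase) cosine form so the nulls come out
exact to machine precision rather than as small residuals of complex
phase arithmetic.

Edge policy: the record is zero-padded before its start; the first
`k(L-S) = 496` raw output samples are flagged as warm-up, not trimmed, so
sample indices stay aligned with annotations.  The pipeline additionally
advances the output by the group delay (padding the input tail with `D`
zeros first), after which the warm-up shrinks to 248 samples at the head
and the tail sees silence beyond the record end.

## Synthetic rhythm generator

The generator is the package's test fixture and defines its study
conditions.  One beat is rendered as raised-cosine lobes (P, QRS, T)
separated by true-zero isoelectric segments; the leading isoelectric
segment absorbs the beat-period slack, so the six states tile every beat
exactly.  Defaults, chosen once as typical textbook values: beat period
850 ms (~71 bpm, ±3% uniform jitter), P 0.15 mV / 90 ms, P-Q interval
160 ms, QRS 1.0 mV / 80 ms, ST segment 100 ms, T 0.3 mV / 180 ms.
Ectopics follow their qualitative clinical signatures: a PVC has no P
wave, a 1.6x wider inverted QRS, a 1.5x longer T and a 0.7x preceding
beat period; an APC is early (0.8x period) with a 240 ms P-Q interval,
outside the 120–200 ms normal range.  All factors are config-exposed.

Noise defaults ("moderate"): 0.3 mV baseline wander at 0.25 Hz (15
breaths/min respiration; below-0.5 Hz as the filter assumes), 0.05 mV
power-line fundamental at 50 Hz plus a 0.02 mV second harmonic, and
0.01 mV white noise standing in for EMG/motion residue.  Everything is
drawn from one seeded generator; a rhythm is a pure function of its plan.

What the generator does *not* emulate: heart-rate variability spectra,
respiratory amplitude modulation, electrode motion artifacts, biphasic or
notched QRS morphologies, U waves, and ST-level pathologies.  Tests that
pass on these rhythms therefore demonstrate the internal consistency of
the chain (filter → segmentation → decoding → classification) under the
stated morphology and noise model — not clinical performance on real
recordings.

## Segmentation

Peaks are strict local maxima of the absolute amplitude within a ±100 ms
window (so inverted ectopic QRS complexes are found), above a 0.06 mV
prominence floor; of two equal peaks in one window the earlier is kept.

Because the filter nulls DC, the filtered record's isoelectric level sits
at minus the local beat average rather than at zero.  Amplitudes are
therefore referenced to an estimated isoelectric baseline: the record
median globally, then a per-sample baseline interpolated through the
isoelectric stretches between lobes.  The lobe masks come from the
current span estimates and the procedure runs twice (the first pass caps
mask half-widths at 200 ms so a pedestal under an ectopic complex cannot
swallow the short gaps that anchor the baseline).

Unit spans extend to the crossings of a 0.04 mV amplitude floor and are
then extrapolated outward to the true lobe edge under a raised-cosine
edge model (`u_true = u_measured / (1 - arccos(1 - 2*eps/A)/pi)`); without
this, the floor crossing undercuts wave durations by ~12% of the lobe
width per side, which would both break the 10 ms interval tolerance and
blur the normal/prolonged T-duration boundary the classifier relies on.
Spans are clipped at midpoints so they never overlap.

The non-maximal merge fuses adjacent units whose peak values and peak
times both fall within the thresholds (defaults: delta_p = 10% of the
median tall-peak amplitude — a scale-free running R estimate — and
delta_t = 40 ms, below the shortest inter-wave gap), applied left-to-right
to a fixed point; the result matches a transitive-closure oracle on small
inputs and is idempotent.

Symbolization uses four bins: isoelectric gap; tall (normalized amplitude
≥ 0.5: QRS-like); small-narrow (span ≤ 130 ms: P-like); small-wide
(T-like).  Long gaps are emitted in chunks of ≤ 25 ms.  The chunking
matters: a premature beat compresses the gap before its R wave to well
under 100 ms, and the cyclic left-right decoder must still place ISO1, P
and PQ tokens inside it — with one monolithic gap token a single PVC
would desynchronize the six-state cycle permanently.

## Hidden Markov models

The core is a discrete-observation HMM (λ = (A, B, π)) with a boolean
structure mask; masked transitions are never given probability by any
operation (supervised counts, EM re-estimation and blending all preserve
exact zeros).  Forward/backward use per-step normalization (scaling)
rather than log-space arithmetic; Viterbi runs in log space with ties
broken toward the lower state index, for determinism.

Layer I is the six-state cyclic left-right chain (self-loops + successor,
T wrapping to ISO1 over multi-beat records).  Decoding operates on the
unit/gap token stream, not per sample, for tractability; boundaries are
projected back through token spans, and interval durations are measured
from the unit span inside each decoded interval so isoelectric tokens
absorbed by a self-loop do not inflate wave durations.  Features: P-Q
from P onset to QRS onset (undefined when the decoded P interval contains
no unit — an absent P), QRS and T from their unit spans, R-R/P-P from
consecutive onsets (undefined for the first beat).

Layer II observes one pair per beat: T-duration symbol (V1 normal / V2
abnormal against 100–250 ms) and P-Q symbol (V3 normal / V4 abnormal
against 120–200 ms; out-of-range on either side is abnormal, and a
missing interval is abnormal).  The pair is encoded on the joint 4-letter
alphabet; the default model's per-state emission factorizes as the
product of a T-categorical and a PQ-categorical (Normal peaked on
(V1,V3); PVC peaked on V2 with a lean to V4; APC peaked on V4, nearly
T-agnostic; Invalid near uniform), while trained models estimate the
joint emission directly, which is strictly more general.  The alternative
design — interleaving T- and PQ-symbols into one alternating stream — was
rejected because it pollutes the transition statistics with intra-beat
structure.

### Expert-annotation-assisted training

Step 1 estimates (A, B, π) by counting from the first expert's short
labeled sequence (additive smoothing 1e-3, so short annotations cannot
zero out legal events); step 2 runs exactly one Baum-Welch iteration on
the long unlabeled stream.  Each further expert re-derives a supervised
initialization from its own annotation, runs one EM iteration, and is
compared to the running model: if the mean total-variation distance
across corresponding rows of A and B exceeds the gate, the annotation is
declared invalid and skipped; otherwise the candidate is blended in by an
equal-weight convex combination and the stream is re-decoded.  "One
iteration per expert" is taken literally, so the total EM effort equals
the number of accepted experts.

The rejection gate defaults to 0.25.  Under a left-right mask most rows
of A are pinned by the topology (at most two free entries), which dilutes
the row-mean TV: a randomly scrambled annotation measures ~0.25–0.3 while
faithful annotators in this pipeline measure ≤ 0.17, so a 0.5 gate would
never fire and 0.25 separates the two regimes.  The blend weight,
smoothing and gate are all config-exposed.

EM caveat: Baum-Welch from an uninformed random start recovers generating
parameters only for favorable starts; other starts hit local maxima.
That failure mode is precisely the motivation for supervised
initialization from expert annotations, and the parameter-recovery tests
initialize that way (a 200-symbol labeled prefix, then 50 iterations,
recovering a known six-state cyclic left-right transition matrix within
0.05).

## Pipeline and evaluation

The pipeline (simulate/read → filter → segment → decode → features →
beat symbols → classify → score) is a pure function of its inputs, its
configuration and one seed.  When ground truth is present the two layers
are trained with the expert-assisted loop, the simulated experts being
three disjoint blocks of ~40 labeled beats (layer I tokens / layer II
beat symbols); otherwise prior default models are used.

Scoring matches decoded to true beats greedily by R-peak time within
150 ms.  Beats overlapping the filter warm-up and the first two/last
beats of a record are excluded from *scoring* (not from detection or
classification), since their context is truncated.  Feature validation
counts an interval erroneous when it differs from the reference by more
than 10 ms (or is present on only one side); intervals absent on both
sides — the P-Q of a ventricular ectopic — are not counted.  A record is
flagged invalid when interval accuracy falls below 95%.

Problem sizes in the shipped tests: the delineation-accuracy check runs
1,000 noise-free beats (≈ 7 minutes of signal), the classification check
2,000 beats (≈ 28 minutes) under the default moderate noise; both
complete in seconds.

## Known limitations

* The isoelectric-baseline re-referencing and the raised-cosine edge
  extrapolation assume smooth unimodal lobes; heavily fragmented QRS
  complexes or biphasic T waves would need a different span model.
* The layer-II symbol set carries only T-duration and P-Q abnormality;
  rhythms whose signature is amplitude- or axis-based (bundle-branch
  block, ST elevation) are outside the model, as are classes other than
  PVC/APC.
* Fixed 50 Hz-grid nulls: a 60 Hz mains environment needs a different
  (lag, rate) pair; the parameterization allows it but no preset is
  shipped.
* The "Invalid" class has near-uniform default emissions and no
  synthetic-data calibration target; it acts as a fallback for beats the
  physiological classes explain poorly.
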
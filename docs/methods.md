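# Methods

`fmgkit` implements the software half of a pneumatic force-myography (pFMG)
human–machine interface: a five-chamber soft armband reads forearm muscle
deformation as chamber-pressure changes, a classifier maps windows of those
signals to one of five static hand gestures, and the stabilised gesture
stream teleoperates infrared consumer devices. Participant recordings for
such systems are typically not redistributable, so the package ships a
synthetic-signal generator that reproduces the statistical structure the
pipeline assumes; every downstream stage is developed and tested against it.

## Signal model

A recording of gesture *g* on chamber *c* is modelled as

```
p_c(t) = r(t) · μ_gc + δ_c + β·t + ε_c(t)
```

where `μ_gc` is the gesture's relative-pressure plateau (rest = 0; the
resting baseline is subtracted at acquisition, matching the convention that
classification pressures are relative to initial user pressure), `δ_c ~
N(0, σ_trial²)` is drawn once per (trial, chamber) and models gesture
re-execution variability, `β` is a slow linear drift, `ε` is i.i.d. Gaussian
sensor noise, and `r(t)` is a sigmoid onset ramp from rest to the plateau.

Defaults and their reasoning:

| parameter | default | unit | why |
|---|---|---|---|
| sampling period | 1.35 ms (740 Hz) | s | armband acquisition rate |
| samples / recording | 2000 (≈2.7 s) | — | standard training-capture length |
| trials / session | 3 | — | standard protocol; 2 sessions pooled for the inter-session protocol |
| `μ_gc` | invented per gesture, 0.6–4.0 | kPa-equiv. | no numeric plateaus are published; values mimic the qualitative structure of real characterisations (chamber 1 separates Fist from Spread Fingers; chamber 2, over the pronator teres, is nearly common to all five gestures) |
| `σ_noise` | 0.01 | kPa-equiv. | noise floor of amplified board-mount pressure sensors (~0.05 % of full scale) against kPa-scale gesture deltas |
| `σ_trial` | 0.05 | kPa-equiv. | re-execution offsets dominate sensor noise but stay small against plateau separations (min pairwise distance ≈ 2) |
| `β` | 0.01 | units/s | pressure-chamber systems are near drift-free; a token slope keeps the term exercised |
| onset ramp | 0 s in recordings | s | a training recording captures an already-established hold — recordings of held gestures show stable plateaus, and any rest→plateau transition inside the window would (correctly) trip the spike alert. Gesture formation is modelled by setting a per-gesture sigmoid ramp (e.g. 0.2 s) when streaming online scenarios |
| Euler sweep | linear over the recording | deg | quasi-dynamic gestures are specified only as "slow" orientation changes; linear is the least-structured choice |

What the generator deliberately does **not** model: chamber mechanics
(hysteresis, lifetime cycling), inter-subject variability structure beyond
the exposed parameters, armband re-donning shifts between sessions, and
fatigue trends. Consequently, a perfect synthetic benchmark score shows the
pipeline is correct and information-preserving, not that any particular
accuracy would be reached on human data — published accuracies on real
recordings of this kind are in the high-80s/low-90s (%), driven by exactly
the effects the generator idealises away.

## Windowing and integrity checks

Streams are cut into 100-sample windows (≈135 ms) at a 50-sample stride
(50 % overlap). The general count is `floor((N−W)/S)+1`; for the canonical
W=2S with S | N this is the familiar `N/S − 1` (2000 samples → 39 windows).
Trailing partial windows are dropped.

Two fail-safes mirror the acquisition-side checks; both only *inform* — the
classification path always consumes unfiltered data:

* **Spike alert** — flags `(channel, t)` when
  `|p(t) − p(t−τ)| / max(|p(t−τ)|, floor) > 0.20` for any lag `τ` under 1 s.
  The denominator floor (1 % of the stream's dynamic range) prevents
  blow-ups near zero relative pressure.
* **Band-energy check** — a 5th-order Butterworth band-pass (0.5–330 Hz,
  i.e. inside a 10 % margin of the 370 Hz Nyquist) plus a flag raised when
  any channel carries >25 % of its *linearly detrended* energy outside the
  band. Linear detrending is deliberate: the plateau offset and slow drift
  are expected signal content, not contamination. Channels whose detrend
  residual is at rounding level are never flagged.

## Features

17 classical time-domain features per (window, channel): IAV, WL, AAC, SSC,
SSI, RMS, VAR, MAV, MAV1, MAV2, ZC, TM3, TM4, TM5, WAMP, DASDV, MYOP.
A *featured frame* concatenates the five chambers' vectors (85 values) and
is the classifier's input row. `MAV3` is accepted as an alias for plain MAV
(the third member of the MAV family).

Threshold conventions (no published values exist):

* ZC/SSC/WAMP/MYOP deadbands default to 1 % of the window's per-channel
  dynamic range.
* SSC counts a slope reversal only when at least one adjacent amplitude
  step reaches the deadband. This amplitude-threshold form (rather than a
  threshold on the product of the steps) keeps the count invariant when the
  signal and threshold are scaled together, and coincides with the
  product-sign form at threshold 0.

All features satisfy exact identities used as tests: `SSI = W·RMS²`,
`MAV = IAV/W`, `AAC = WL/W`, constant windows zero out every
difference/count feature, and positive homogeneity holds with the known
degree per feature (1 for amplitudes, 2 for SSI/VAR, k for TMk).

## Feature selection

For feature *f*, chamber *c*, gesture *g*:

* intra CV(g,f,c) = sd/|mean| over g's frames (sample sd), and
* inter CV(f,c) = sd/|mean| across gestures of the per-gesture means.

Near-zero means are flagged "unstable" and the CV denominator floored at a
configurable ε (default 1e−12). Features are ranked by
`2·rank(inter, desc) + 1·rank(intra, asc)` — separation between gestures is
weighted above within-gesture stability for borderline cases — with
alphabetical tie-breaks for a deterministic total order; the top half is
kept (floor convention for odd counts, so 14 → 7 and 17 → 8). A hard-mask
diagnostic view (intra < 10 % AND inter > 20 %) is retained for inspection
only; per-chamber disagreement makes it unusable as a selector. The whole
procedure is a pure filter: no classifier is consulted.

On the synthetic generator, magnitude-family features (IAV/SSI/MAV family
and the temporal moments) occupy the entire top half and the count features
sink to the bottom — a held gesture is a stable plateau whose *level*
separates gestures, while counts see only noise. Two differences from what
real recordings of this kind show are expected and understood: TM3–TM5 rank
high here because Gaussian plateau noise gives them low intra CV (real FMG
penalises them with high within-gesture variance), and VAR ranks low
because on baseline-subtracted plateaus it measures noise, not signal
level.

## Classifier evaluation

Frames from the same trial are strongly correlated, so entire trials are
held out: with `n` trials and `r = round(n/3)` held out, all
`C(n,r)` partitions are enumerated in lexicographic order and scores
averaged — 3 splits for the inter-trial protocol (one session), 15 for the
inter-session protocol (two pooled sessions, r=2). Trial segregation is
asserted on every partition; a partition whose training folds lack a label
present in its test folds raises instead of being skipped (silent skipping
would bias the average; the balanced protocol cannot produce it).

Seven models are benchmarked with scikit-learn: GaussianNB, NuSVC, QDA,
LDA, RF, K-NN, DT. Numerical choices:

* features are standardised (fit on training folds only) inside **every**
  model's pipeline — required for the distance/discriminant models, harmless
  for the rest, and one code path is easier to audit;
* QDA uses `reg_param = 1e−3`: selected feature sets can contain exactly
  collinear pairs (MAV = IAV/W), and the unregularised per-class covariance
  is then singular. On standardised features this shrinkage is negligible;
* RF is fixed at 100 trees with a seeded RNG; all other hyper-parameters
  are library defaults;
* log loss is averaged per partition (not pooled), and wall-clock
  fit+predict time is reported for interface parity only — it is
  hardware-dependent and never asserted.

Confusion matrices pool test-fold predictions over all partitions and
row-normalise by true-label counts.

## Post-processing and spatial augmentation

Window predictions (~10/s) enter a rolling queue of 10. Once full, the
modal label is the final decision if it fills ≥ 75 % of the buffer, else
`Unknown` (optionally the last confident gesture, for fatigued users);
until first fill the decision is `pending` rather than a guess. The buffer
slides by one per prediction — sliding (vs. flushing) was chosen for
latency; the paper-style description does not fix this. Ties in the mode
break alphabetically for determinism. Commands are debounced: a
transmission happens only when the final decision *changes* to a real
gesture.

Orientation is excluded from featurisation entirely, so a quasi-dynamic
gesture (held pose + slow arm rotation) classifies identically to its
static counterpart — asserted bit-exactly in tests. On gesture onset the
Euler triplet is latched as the setpoint; while held, the controller output
is `gain ×` the signed angular difference on the gesture's configured axis,
using the shortest-arc convention on [−180°, 180°) (the wraparound
convention is this package's choice; 170° → −170° is +20°, not −340°).
Three consumption modes: `repeat_rate` (codes/s, clamped at 0),
`index_increment` (`floor(value/step)`, default step 10°, clamped to the
stored-code range), `discrete` (three-way state at ±10° default thresholds
— the demonstrated LED red/blue behaviour prints no angles, so the value is
a design choice). With no active gesture the device is not locked on and
orientation does nothing.

## IR code model

NEC is implemented as a full codec (it dominates consumer devices): 9000 µs
leader, 4500 µs space, 32 pulse-distance bits (562.5 µs pulse; 562.5/1687.5
µs space for 0/1, MSB first), 562.5 µs trailer — 67 ticks. Decoding
tolerates ±25 % relative timing jitter per tick (common decoder practice;
no published figure) and returns a failure value rather than raising, so
unrecognised frames fall through to raw tick recording. Sony (12/20-bit)
and RC5 (14-bit) codes round-trip via their raw ticks; full codecs for them
are out of scope. An unknown-protocol recording is accepted only when ≥2
captures agree tick-wise within tolerance (largest agreeing cluster wins,
element-wise mean kept): scrambled captures are effectively random and
never repeat. Transmission is simulated on an append-only JSON-lines
virtual bus; carrier modulation and line-of-sight physics are non-goals.

## Problem sizes

Tests and the acceptance script use the study-protocol sizes throughout:
2000-sample recordings, 5 gestures × 3 trials × 2 sessions (585 frames per
session, 1170 pooled), 1000-window feature cross-checks, 1000-payload NEC
round-trips. The full suite and the acceptance script each run in well
under a minute on a single CPU.

## Known limitations

* Synthetic plateaus are easier than human data; end-to-end accuracies here
  validate machinery, not expected field performance.
* The variance-ratio selector scores features independently; redundant
  selected features (the MAV family is mutually collinear by construction)
  are not pruned.
* Only NEC has a true codec; raw round-tripping covers other protocols
  functionally but cannot validate their payloads.
* The spike alert is O(N·lags) per channel; fine at 740 Hz/2.7 s scales,
  not optimised for hours-long streams.
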
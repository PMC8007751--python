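# Methods

## Model and assumptions

The pipeline assumes that (i) emotional excitation is localised in time —
within each trial there is one frame, the *epoch*, where band-limited
activity deviates most from the subject's neutral baseline; (ii) the set of
electrodes that react is specific to the subject, the emotional state and
the rhythm band; and (iii) reactions are *relative*: what matters is the
signed fractional change of band energy against the same subject's neutral
reference, not absolute power.  All stages are per subject; no
cross-subject transfer is attempted.

Band energy is the bin-index-weighted sum `Σ_k k·|S[k]|` over the band's
bins, with `S` either the DFT magnitude or the NGD spectrum
(`Re(X)·Re(Y) + Im(X)·Im(Y)`, `Y` transforming `n·x[n]`).  Two printed-form
choices are implemented exactly as stated and kept toggleable because they
are unusual: the leading `k` weight (a plain sum is available via the
band-energy helper), and the magnitude `|S[k]|` (raw signed values via
`use_magnitude=False`).  Magnitude is the default because NGD values can be
negative and energies must stay non-negative.

Hz→bin conversion uses `round(f·N/fs)` with both edges inclusive.  The θ
and α bands ([4,7] and [8,12] Hz) are disjoint in bins at all frame sizes
used; β and γ share the printed edge values 12 and 36 Hz with their
neighbours, so one boundary bin is counted in both bands — a deliberate
reproduction of the published band table rather than a half-open
re-interpretation.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| κ (kappa) | 15 | s | epoch frame length |
| shift | 15 | s | frame hop; equal to κ ⇒ non-overlapping frames |
| α_threshold | 0.5 | – | min fraction of significant trials for relevance |
| β_threshold | 0.5 | – | min \|Δ\| for a trial to count as significant |
| folds | 10 | – | stratified cross-validation |
| hidden layers | 3 × 3 tanh units | – | LM-trained network |
| LM iterations | 5 | – | accepted steps per training |
| LM damping λ₀ / factor | 3 / 10 | – | initial damping; multiplied on reject, divided on accept |
| init range | ±0.5 | – | uniform weight/bias initialisation |
| error target | 1e−10 | – | LM stopping cost |

Threshold comparisons are inclusive (ρ ≥ α, |Δ| ≥ β); strict forms are
available by flag.  All tie-breaks (frame tags, plurality, majority,
discriminant argmax, fusion accuracy ties) go to the smallest index /
earliest element in canonical order, so every stage is deterministic.

## Numerical and design choices

**Epoch-selection baseline.**  The per-electrode neutral reference for
frame tagging defaults to the *windowed* mode: the mean ZTW-frame NGD
energy over all frames of the subject's neutral trials.  This puts the
reference on the same scale as the frame energies it is compared against.
The whole-trial (unwindowed) reference is retained as `baseline="trial"`;
measured on synthetic data, windowed frame energies sit two to three
orders of magnitude above the whole-trial value, so with that reference
the |relative deviation| criterion degenerates to "largest frame energy" —
correct for energy increases but blind to decreases.

**Epoch-segment energies.**  Relevance scoring and feature extraction on
the epoch frame use the *raw* frame slice (`segment="epoch"`).  Applying
the zero-time window first (`segment="epoch-windowed"`, kept for
sensitivity analysis) concentrates nearly all weight on the first few
samples of the frame — ψ decays as 1/n² from a very large ψ[1] — which
makes trial-level band energies noise-dominated: on synthetic data the
modulated/unmodulated |Δ| medians collapse from 2.8 vs 0.1 (raw) to 1.0 vs
0.85 (windowed).  The window stays where its temporal resolution is the
point: frame-level tagging inside epoch selection.

**QDC covariance rescue.**  Adaptive electrode selection yields feature
dimensions (Σ_f |Γ|, often 60–80) well above the per-class sample counts
(≈9 target trials in a training fold), so class sample covariances are
rank-deficient and the quadratic discriminant is undefined.  Positive
definiteness is tested by a relative eigenvalue criterion (a bare Cholesky
accepts matrices whose smallest eigenvalue has underflowed), and singular
classes receive the Ledoit–Wolf shrinkage estimate, whose data-driven
intensity adapts per class (measured ≈0.75 for a 10-sample class, ≈0.10
for an 80-sample class).  A fixed ridge `reg·(trace/d)·I` is available via
a float `reg`; ridges small enough not to distort well-conditioned fits
are far too small to make n ≪ d Mahalanobis terms meaningful.

**Network input scaling and decision threshold.**  The one-vs-all and
all-together networks standardise features with training-fold statistics
and scale inputs by 1/√d; without this, delta features (entries ≈ effect−1
across tens of dimensions, weights initialised in ±0.5) saturate every
tanh unit and the net collapses to a constant output.  The scalar output
is thresholded at 0.5 — the midpoint of the 0/1 target codes — because
least squares on imbalanced one-vs-all sets (≈1:8) pulls target outputs
toward ≈0.8, and higher thresholds systematically vote *outlier*.

**LM training.**  The Jacobian is computed by exact per-sample
backpropagation (a finite-difference oracle verifies it in the tests).
Damping uses Marquardt's `λ·diag(JᵀWJ)` scaling with zero diagonal entries
floored; singular normal equations raise λ and retry up to a bounded
number of rescues.  The residual weight matrix W is the identity — no
per-sample measurement variances exist in this setting.  The network has
no input/internal/output delays, making it a static (feedforward) map.

**Fusion and accounting.**  REJECT (a majority of one-vs-all members
claiming the trial) is a first-class outcome.  Final-decision accuracy is
reported both with rejects counted as errors and with rejects excluded,
since either accounting is defensible.

**Rating grid.**  The valence/arousal → nine-label mapping uses terciles
of the 1–9 scale (cut points 3.667/6.333) and a circumplex-style 3×3
placement (e.g. high-arousal row: distressed / excited / happy with rising
valence).  The placement is configuration, not a fixed fact: the grid and
cut points are arguments of `vad_to_emotion`.  "Pleasant" is accepted as
an alias of "pleased".

**Neutral trials and voting.**  Neutral trials define the baseline and by
default do not vote in epoch selection (`include_neutral_votes` adds
them); they do serve as outlier examples for the one-vs-all classifiers.
If no frame location reaches a strict electrode majority, the plurality
winner is used and the sub-0.5 margin is recorded with a warning rather
than aborting — the pipeline is total.

## The synthetic generator

`ztweeg.synthetic.generate` emulates exactly the structure the method
assumes: per band, three unit sinusoids at jittered in-band frequencies
with independent channel phases; white Gaussian noise at a configured
oscillation-to-noise RMS ratio (default 3); a per-subject epoch frame in
which the band amplitude of a per-(emotion, band) electrode subset
(default 60% of channels) is multiplied by the effect size (default 2.0;
values below 1 model suppression).  Defaults: 32 channels, 128 Hz, 60-s
trials, 10 trials per state including neutral.

What it does **not** emulate — hence what passing tests do *not* show
about real recordings: 1/f background spectra (a pink-noise flag exists
but the default is white), volume conduction and inter-channel
correlation, artifacts (ocular, muscular), non-stationary baselines,
rating noise in the valence/arousal labels, and any overlap structure
between emotions beyond random electrode-set intersections.  Recovery
rates near 100% here are a correctness check of the algorithmic chain,
not a performance claim for real EEG.  Notably, the whole-trial NGD
baseline variant finds almost no relevant electrodes on this generator at
β = 0.5 (a one-frame modulation is diluted by the trial-long time
weighting `n·x[n]`), so its accuracy sits near chance while the DFT
variant lands midway and the full method on top; on real recordings the
published ordering between the two whole-trial variants may well differ.

## Problem sizes

The test suite runs the recovery study at 50 simulated subjects at the
default conditions and the paired variant comparison at 10 seeds;
`scripts/acceptance.py` uses 20 subjects and 5 paired stores.  Unit tests
use a compact 8-channel, 16-s-trial configuration of the same generator.
All randomness is seeded; the acceptance script derives every simulation
seed from its `--seed` argument.

## Known limitations

* Single-subject pipelines only; no subject-independent decoding.
* The epoch is resolved at frame granularity (κ/shift); no sample-level
  localisation and no significance testing of the winning frame.
* No multiple-testing correction across the (emotion, band, electrode)
  grid — the selector is a screening rule, not an inference procedure.
* QDC with Ledoit–Wolf rescue remains a high-variance classifier when the
  relevant-electrode sets are large relative to the trial count.
* The native store layout requires equal trial shapes per store.
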
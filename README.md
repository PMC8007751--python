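# ztweeg

EEG-based emotion recognition with **zero-time-windowing (ZTW) epoch
estimation** and **adaptive, per-subject electrode selection**.

Most EEG emotion-recognition pipelines extract features from the same fixed
set of channels for every person, and from the whole trial — including long
stretches where nothing emotional is happening.  This toolkit implements the
opposite philosophy: brain responses to emotion differ between people and
between emotional states, so the channels worth listening to, and the moment
worth listening at, must be found per subject.  It is aimed at affective-BCI
researchers who want a testable, fully seeded reference implementation of
that idea, usable both on simulated data (a ground-truthed generator is
included) and on per-subject arrays in the layout of the common
valence/arousal-rated EEG corpora.

## The method

For a subject *s* with trials φ(s, η) per emotional state η (η₀ = neutral is
the reference state), and rhythm bands θ [4–7], α [8–12], β [12–36],
γ [36–42] Hz:

1. **Spectra.** Band activity is measured either from the DFT magnitude or
   from the *numerator of the group delay* (NGD),
   `NGD[k] = Re(X[k])·Re(Y[k]) + Im(X[k])·Im(Y[k])`, where `X = DFT(x)` and
   `Y = DFT(n·x[n])`.  The NGD keeps the formant (peak) structure of the
   group-delay spectrum without ever dividing by near-zero magnitudes.
   Band energy is the bin-weighted sum `Σ_k k·|S[k]|` over the band's bins.
2. **Epoch selection (ZTWBES).**  Every trial is cut into sliding frames
   (default κ = 15 s, shift = 15 s).  Each frame is multiplied by the
   zero-time window ψ[0] = 0, ψ[n] = 1/(4 sin²(πn/2N)) — a window shaped
   like a zero-frequency resonator that yields high-temporal-resolution
   spectra — and its multiband NGD energy is compared with the subject's
   neutral baseline.  Per (trial, electrode) the frame with maximal
   |relative deviation| is tagged; per electrode the tags are combined by
   plurality vote; across electrodes a majority vote elects the subject's
   epoch location `Epoch[s]`, and the agreeing electrodes form `Elite[s]`.
3. **Relevant electrodes.**  For each elite electrode e, emotion η and band
   f, the signed relative change Δ = (E − Ref)/Ref against the neutral-state
   reference is computed per trial; trials with |Δ| ≥ β_threshold count as
   significant, and ρ(s,η,f,e) is their fraction.  Electrodes with
   ρ ≥ α_threshold form Γ(s,η,f) (defaults α = β = 0.5).
4. **Classification.**  Feature vectors are the signed Δ values at the
   relevant electrodes (ordered by band, electrode).  Eight one-vs-all
   classifiers — quadratic discriminant (QDC) or a small 3×3×3-unit tanh
   network trained by Levenberg–Marquardt — are fused by three rules: all
   vote *outlier* → neutral; a minority vote *target* → the claimant with
   the best training accuracy; a majority vote *target* → reject.  An
   all-together network with one output per label is available as a second
   scheme.  Evaluation is stratified 10-fold cross-validation with every
   data-derived quantity (baseline, epoch, elite set, relevant electrodes)
   re-derived inside each training fold.

## Worked example

Simulate one subject at the default study conditions (60-s trials at 128 Hz,
32 channels, 10 trials per emotion, band-energy effect ×2 inside one hidden
frame, SNR 3), then run the pipeline:

```bash
$ ztweeg simulate --subjects 1 --seed 42 --out store --truth truth.json
wrote 90 trials to store
wrote ground truth to truth.json

$ ztweeg epoch-select --store store --subject s01 --out epoch.json
subject s01: epoch at frame 1 (margin 1.00, 32 elite electrodes)

$ ztweeg relevance --store store --subject s01 --epoch epoch.json --out relevance.json
wrote relevance map for s01 to relevance.json

$ ztweeg experiment --store store --variant proposed --mode qdc --seed 7 --out report
proposed/qdc: mean final accuracy 0.967 (0.967 excluding rejects)
```

The generator had planted the epoch in frame 1 (`truth.json` records
`"epoch_frame": {"s01": 1}`), and the epoch selector recovered it with a
unanimous electrode vote.  `relevance.json` lists, per band and emotion, the
electrodes whose activity change was significant in at least half of that
emotion's trials — e.g. 19 of the 32 electrodes for `alpha/calm` in this
run, matching the planted 60% modulation fraction.  The final line is the
10-fold cross-validated nine-class accuracy of the fused one-vs-all QDC
ensemble: 0.967, against a chance level of 1/9.

The same `experiment` command with `--variant dft` (whole-trial DFT
energies, no epoch selection) shows what the epoch/electrode refinement
buys; `--mode nn1`/`nn2` switch to the LM-trained network schemes.

The library mirrors the CLI one-to-one (`ztweeg.generate`,
`ztweeg.run_ztwbes`, `ztweeg.select_relevant`, `ztweeg.crossvalidate`,
`ztweeg.run_experiment`) and is the more convenient interface for scripted
studies.

## Scope notes

Headline accuracies on the access-restricted real recordings are *not*
claimed or reproduced here; the per-subject array adapter
(`ztweeg.read_subject_array`) exists so the pipeline can be applied when
one has the data.  Artifact removal beyond generic band-pass filtering,
scalp-topography plotting, and cross-subject transfer are out of scope.
See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
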
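"""Ground-truthed synthetic emotional EEG.

The generator emulates the statistical structure the pipeline assumes:

* every subject has neutral-baseline trials consisting of band-limited
  oscillations (a few sinusoids per rhythm band at jittered frequencies with
  random phases per channel) plus broadband white Gaussian noise;
* emotional trials are built the same way, except that the oscillatory
  amplitude of band ``f`` in a per-(subject, emotion, band) subset of
  electrodes is multiplied by ``effect_size`` — but only within the samples
  of one per-subject time frame (the planted epoch);
* both the epoch location and the modulated electrode sets vary from subject
  to subject, mirroring the inter-individual variability of real emotional
  EEG topographies.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dataset import (
    DEFAULT_BANDS,
    EMOTIONS,
    NEUTRAL,
    BandSpec,
    Trial,
    TrialStore,
    standard_montage,
)
from .exceptions import ValidationError

N_COMPONENTS_PER_BAND = 3  # sinusoids per rhythm band
FREQ_JITTER_FRACTION = 0.8  # components span centre +/- 0.4 of the band width


@dataclass
class SimConfig:
    """Conditions of a simulated recording session."""

    n_subjects: int = 1
    n_channels: int = 32
    fs: float = 128.0
    trial_len_s: float = 60.0
    trials_per_emotion: int = 10  # applies to every state incl. neutral
    kappa: float = 15.0  # epoch frame length, seconds
    shift: float = 15.0  # frame hop, seconds
    effect_size: float = 2.0  # multiplicative band-amplitude factor (<1 = decrease)
    relevant_fraction: float = 0.6  # fraction of channels modulated per (emotion, band)
    snr: float = 3.0  # oscillation-to-noise amplitude (RMS) ratio
    bands: Sequence[BandSpec] = field(default_factory=lambda: DEFAULT_BANDS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if not (0 < self.relevant_fraction <= 1):
            raise ValidationError("relevant_fraction must be in (0, 1]")
        if self.fs <= 2 * max(b.hi for b in self.bands):
            raise ValidationError("fs must exceed twice the top band edge")
        if self.kappa > self.trial_len_s or self.shift <= 0:
            raise ValidationError("invalid frame parameters")
        if self.snr <= 0:
            raise ValidationError("snr must be > 0")

    @property
    def n_frames(self) -> int:
        return int((self.trial_len_s - self.kappa) // self.shift) + 1


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    epoch_frame: dict[str, int]  # subject -> 1-based frame index
    relevant: dict[tuple[str, str, str], frozenset[str]]  # (subject, emotion, band) -> labels
    sign: dict[str, int]  # trial_id -> +1 (increase) / -1 (decrease)
    config: SimConfig


def _component_frequencies(band: BandSpec, rng: np.random.Generator) -> np.ndarray:
    centre = 0.5 * (band.lo + band.hi)
    half = 0.5 * FREQ_JITTER_FRACTION * (band.hi - band.lo) / 2
    return rng.uniform(centre - half, centre + half, size=N_COMPONENTS_PER_BAND)


def _band_oscillation(
    freqs: np.ndarray, t: np.ndarray, phases: np.ndarray
) -> np.ndarray:
    """Sum of unit sinusoids; ``phases`` is (channels, components)."""
    # sin(2 pi f t + phi) expanded so each component costs two rank-1 updates
    out = np.zeros((phases.shape[0], t.size))
    for j, f in enumerate(freqs):
        s = np.sin(2 * np.pi * f * t)
        c = np.cos(2 * np.pi * f * t)
        out += np.cos(phases[:, j])[:, None] * s + np.sin(phases[:, j])[:, None] * c
    return out


def generate(config: SimConfig) -> tuple[TrialStore, GroundTruth]:
    """Generate a trial store and its ground truth."""
    rng = np.random.default_rng(config.seed)
    montage = standard_montage()[: config.n_channels]
    if len(montage) < config.n_channels:
        raise ValidationError("n_channels exceeds the standard 32-channel montage")
    labels = [e.label for e in montage]
    n_samples = int(round(config.trial_len_s * config.fs))
    t = np.arange(n_samples) / config.fs
    n_mod = max(1, int(round(config.relevant_fraction * config.n_channels)))
    n_total_comp = N_COMPONENTS_PER_BAND * len(config.bands)
    # unit-amplitude sinusoids with independent phases: RMS = sqrt(n_comp / 2)
    noise_sigma = np.sqrt(n_total_comp / 2.0) / config.snr
    sign = 1 if config.effect_size >= 1.0 else -1

    trials: list[Trial] = []
    epoch_frame: dict[str, int] = {}
    relevant: dict[tuple[str, str, str], frozenset[str]] = {}
    signs: dict[str, int] = {}

    for si in range(config.n_subjects):
        subject = f"s{si + 1:02d}"
        k_star = int(rng.integers(1, config.n_frames + 1))
        epoch_frame[subject] = k_star
        frame_start = int(round((k_star - 1) * config.shift * config.fs))
        frame_stop = frame_start + int(round(config.kappa * config.fs))
        mod_sets: dict[tuple[str, str], np.ndarray] = {}
        for emotion in EMOTIONS:
            for band in config.bands:
                idx = rng.choice(config.n_channels, size=n_mod, replace=False)
                mod_sets[(emotion, band.name)] = np.sort(idx)
                relevant[(subject, emotion, band.name)] = frozenset(
                    labels[i] for i in idx
                )
        for emotion in (NEUTRAL,) + EMOTIONS:
            for rep in range(config.trials_per_emotion):
                data = np.zeros((config.n_channels, n_samples))
                for band in config.bands:
                    freqs = _component_frequencies(band, rng)
                    phases = rng.uniform(
                        0, 2 * np.pi, size=(config.n_channels, N_COMPONENTS_PER_BAND)
                    )
                    osc = _band_oscillation(freqs, t, phases)
                    if emotion != NEUTRAL:
                        rows = mod_sets[(emotion, band.name)]
                        gain = np.ones(n_samples)
                        gain[frame_start:frame_stop] = config.effect_size
                        osc[rows] *= gain
                    data += osc
                data += rng.normal(0.0, noise_sigma, size=data.shape)
                trial_id = f"{subject}_{emotion}_{rep:02d}"
                signs[trial_id] = sign
                trials.append(
                    Trial(
                        trial_id=trial_id,
                        subject=subject,
                        emotion=emotion,
                        data=data.astype(np.float32),
                        fs=config.fs,
                    )
                )

    store = TrialStore(trials, montage=montage, bands=config.bands)
    return store, GroundTruth(
        epoch_frame=epoch_frame, relevant=relevant, sign=signs, config=config
    )


def truth_report(
    gt: GroundTruth,
    epoch_result: Optional["EpochSelectionResult"] = None,
    relmap: Optional["RelevanceMap"] = None,
) -> dict:
    """Score recovered epoch/electrode structure against the planted truth.

    Returns ``epoch_hit`` (bool), per-(emotion, band) precision/recall of the
    relevant-electrode sets, and their macro averages.  Precision of an empty
    recovered set is undefined and reported as NaN with ``undefined_precision``
    counting such cells.
    """
    report: dict = {}
    subject = None
    if epoch_result is not None:
        subject = epoch_result.subject
        if subject not in gt.epoch_frame:
            raise ValidationError(f"subject {subject!r} not in ground truth")
        report["epoch_hit"] = bool(
            epoch_result.winner_location == gt.epoch_frame[subject]
        )
    if relmap is not None:
        if subject is not None and relmap.subject != subject:
            raise ValidationError("epoch result and relevance map disagree on subject")
        subject = relmap.subject
        if subject not in gt.epoch_frame:
            raise ValidationError(f"subject {subject!r} not in ground truth")
        cells = {}
        precisions, recalls = [], []
        undefined = 0
        for (emotion, band_name), found in relmap.relevant.items():
            truth = gt.relevant[(subject, emotion, band_name)]
            found = set(found)
            tp = len(found & truth)
            recall = tp / len(truth) if truth else float("nan")
            if found:
                precision = tp / len(found)
                precisions.append(precision)
            else:
                precision = float("nan")
                undefined += 1
            recalls.append(recall)
            cells[(emotion, band_name)] = {"precision": precision, "recall": recall}
        report["cells"] = cells
        report["macro_precision"] = float(np.mean(precisions)) if precisions else float("nan")
        report["macro_recall"] = float(np.mean(recalls)) if recalls else float("nan")
        report["undefined_precision"] = undefined
    return report
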
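"""Zero-time-windowing-based epoch selection (ZTWBES).

For every subject the algorithm locates the *epoch* — the time frame within
the subject's trials where band-limited activity deviates most from the
subject's neutral baseline — and the *elite* electrode set that agrees on
that location:

1. compute, per electrode, the subject's neutral-state reference energy;
2. decompose every emotional trial into overlapping frames; window each frame
   with the zero-time window, take its NGD spectrum and its multiband
   bin-weighted energy;
3. per (trial, electrode), tag the frame with the maximum absolute relative
   energy deviation from the reference;
4. per electrode, take the plurality vote of its tags across trials;
5. across electrodes, take the majority vote; electrodes agreeing with the
   winner form the elite set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .dataset import DEFAULT_BANDS, NEUTRAL, BandSpec, Trial, TrialStore
from .exceptions import (
    DegenerateBaselineError,
    MissingBaselineError,
    ValidationError,
)
from .spectral import apply_ztw, multiband_energy, ngd_spectrum, ztw_window

log = logging.getLogger(__name__)


@dataclass
class FramePlan:
    """Sliding-frame decomposition of a trial.

    Frame ``k`` (1-based) starts at ``(k - 1) * shift`` seconds and lasts
    ``kappa`` seconds; ``n = floor((trial_len - kappa) / shift) + 1``.
    """

    kappa: float
    shift: float
    fs: float
    frames: tuple[tuple[float, float], ...]

    @property
    def n(self) -> int:
        return len(self.frames)

    def sample_slice(self, k: int) -> slice:
        """Half-open sample range of frame ``k`` (1-based)."""
        if not (1 <= k <= self.n):
            raise ValidationError(f"frame index {k} outside 1..{self.n}")
        start, _ = self.frames[k - 1]
        i0 = int(round(start * self.fs))
        return slice(i0, i0 + self.frame_samples)

    @property
    def frame_samples(self) -> int:
        return int(round(self.kappa * self.fs))


def decompose_frames(trial_len_s: float, kappa: float, shift: float, fs: float) -> FramePlan:
    """Build the frame plan for a trial of ``trial_len_s`` seconds."""
    if kappa > trial_len_s:
        raise ValidationError(f"kappa ({kappa} s) exceeds trial length ({trial_len_s} s)")
    if shift <= 0 or kappa <= 0:
        raise ValidationError("kappa and shift must be positive")
    n = int((trial_len_s - kappa) // shift) + 1
    frames = tuple(
        ((k - 1) * shift, (k - 1) * shift + kappa) for k in range(1, n + 1)
    )
    return FramePlan(kappa=kappa, shift=shift, fs=fs, frames=frames)


@dataclass
class NeutralReference:
    """Per-electrode average multiband NGD energy of the neutral state."""

    subject: str
    per_electrode: dict[str, float]  # electrode label -> reference energy


@dataclass
class EpochSelectionResult:
    """Outcome of ZTWBES for one subject."""

    subject: str
    winner_location: int  # 1-based frame index
    elite: tuple[str, ...]  # electrode labels agreeing with the winner
    per_electrode_votes: dict[str, int]  # label -> elected frame index
    vote_margin: float  # |elite| / |montage|
    plan: FramePlan


def frame_energies(
    data: np.ndarray, plan: FramePlan, bands: Sequence[BandSpec], fs: float
) -> np.ndarray:
    """Multiband ZTW+NGD energy of every frame of ``data``.

    ``data`` is (channels, samples) or (samples,); returns (channels, n)
    or (n,) energies.
    """
    w = ztw_window(plan.frame_samples)
    single = data.ndim == 1
    arr = np.atleast_2d(data)
    frames = np.stack(
        [arr[:, plan.sample_slice(k)] for k in range(1, plan.n + 1)], axis=1
    )  # (channels, n, frame_samples)
    spec = ngd_spectrum(apply_ztw(frames, w), fs)
    energies = multiband_energy(spec, bands)
    return energies[0] if single else energies


def neutral_reference(
    store: TrialStore,
    subject: str,
    bands: Optional[Sequence[BandSpec]] = None,
    plan: Optional[FramePlan] = None,
    baseline: str = "windowed",
) -> NeutralReference:
    """Average neutral-state multiband NGD energy per electrode.

    ``baseline="windowed"`` (default) averages ZTW-windowed frame energies
    over every frame of every neutral trial, putting the reference on the
    same scale as the frame energies it is compared against.
    ``baseline="trial"`` averages whole-trial NGD energies (no window).
    """
    bands = tuple(bands) if bands is not None else store.bands
    neutral = store.neutral_trials(subject)
    if not neutral:
        raise MissingBaselineError(f"subject {subject!r} has no neutral trials")
    per_trial = []
    for trial in neutral:
        if baseline == "windowed":
            if plan is None:
                raise ValidationError("windowed baseline requires a frame plan")
            per_trial.append(frame_energies(trial.data, plan, bands, trial.fs).mean(axis=1))
        elif baseline == "trial":
            spec = ngd_spectrum(trial.data, trial.fs)
            per_trial.append(np.atleast_1d(multiband_energy(spec, bands)))
        else:
            raise ValidationError(f"unknown baseline mode: {baseline!r}")
    mean = np.mean(per_trial, axis=0)
    labels = [e.label for e in store.montage]
    return NeutralReference(subject=subject, per_electrode=dict(zip(labels, mean)))


def frame_variation(
    frame: np.ndarray, ref_energy: float, bands: Sequence[BandSpec], fs: float
) -> float:
    """Absolute relative deviation of a frame's ZTW+NGD energy from a reference.

    The absolute value is taken because activity may increase or decrease
    relative to the neutral state.
    """
    if ref_energy <= 0:
        raise DegenerateBaselineError(f"reference energy must be > 0, got {ref_energy}")
    frame = np.asarray(frame, dtype=float)
    w = ztw_window(frame.shape[-1])
    energy = multiband_energy(ngd_spectrum(apply_ztw(frame, w), fs), bands)
    return float(np.abs((energy - ref_energy) / ref_energy))


def tag_trial(
    trial: Trial,
    channel: int,
    plan: FramePlan,
    ref_energy: float,
    bands: Optional[Sequence[BandSpec]] = None,
) -> int:
    """Frame index (1-based) with maximal energy variation; ties go earliest."""
    if ref_energy <= 0:
        raise DegenerateBaselineError(f"reference energy must be > 0, got {ref_energy}")
    bands = tuple(bands) if bands is not None else DEFAULT_BANDS
    energies = frame_energies(trial.data[channel], plan, bands, trial.fs)
    variations = np.abs((energies - ref_energy) / ref_energy)
    return int(np.argmax(variations)) + 1  # argmax takes the first maximum


def plurality_vote(tags: Sequence[int]) -> int:
    """Most frequent tag; ties break to the smallest frame index."""
    if len(tags) == 0:
        raise ValidationError("plurality vote over an empty tag list")
    counts = Counter(tags)
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)


def majority_vote(candidates: Mapping[str, int]) -> tuple[int, tuple[str, ...], float]:
    """Cross-electrode majority vote.

    Returns ``(winner, elite, margin)``.  The winner is the frame location
    backed by more than half of the electrodes; if no location reaches a
    strict majority the plurality winner is used instead (logged) and the
    recorded margin stays below 0.5.
    """
    if not candidates:
        raise ValidationError("majority vote over an empty candidate map")
    counts = Counter(candidates.values())
    best = max(counts.values())
    winner = min(k for k, c in counts.items() if c == best)
    margin = best / len(candidates)
    if margin <= 0.5:
        log.warning(
            "no strict majority across electrodes (top margin %.3f); "
            "falling back to plurality winner %d",
            margin,
            winner,
        )
    elite = tuple(lb for lb, vote in candidates.items() if vote == winner)
    return winner, elite, margin


def run_ztwbes(
    store: TrialStore,
    subject: str,
    kappa: float = 15.0,
    shift: float = 15.0,
    bands: Optional[Sequence[BandSpec]] = None,
    include_neutral_votes: bool = False,
    baseline: str = "windowed",
) -> EpochSelectionResult:
    """Run the full epoch-selection algorithm for one subject.

    Neutral trials define the baseline and by default do not vote
    (``include_neutral_votes`` adds them to the voting pool).
    """
    bands = tuple(bands) if bands is not None else store.bands
    trials = store.query(subject=subject)
    voters = [
        t for t in trials if include_neutral_votes or t.emotion != NEUTRAL
    ]
    if not voters:
        raise ValidationError(f"subject {subject!r} has no trials to vote with")
    durations = {t.duration_s for t in voters}
    if len(durations) != 1:
        raise ValidationError("ZTWBES requires equal-length trials")
    plan = decompose_frames(durations.pop(), kappa, shift, store.fs)
    ref = neutral_reference(store, subject, bands=bands, plan=plan, baseline=baseline)
    labels = [e.label for e in store.montage]
    ref_vec = np.array([ref.per_electrode[lb] for lb in labels])
    if np.any(ref_vec <= 0):
        bad = labels[int(np.argmin(ref_vec))]
        raise DegenerateBaselineError(f"non-positive reference energy at {bad!r}")

    # tags[trial, electrode]: frame with maximal |relative deviation|
    tags = np.empty((len(voters), len(labels)), dtype=int)
    for i, trial in enumerate(voters):
        energies = frame_energies(trial.data, plan, bands, trial.fs)  # (C, n)
        variations = np.abs((energies - ref_vec[:, None]) / ref_vec[:, None])
        tags[i] = np.argmax(variations, axis=1) + 1

    votes = {
        lb: plurality_vote(tags[:, c].tolist()) for c, lb in enumerate(labels)
    }
    winner, elite, margin = majority_vote(votes)
    return EpochSelectionResult(
        subject=subject,
        winner_location=winner,
        elite=elite,
        per_electrode_votes=votes,
        vote_margin=margin,
        plan=plan,
    )
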
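"""Per-(subject, emotion, band) relevant-electrode identification.

For each elite electrode ``e`` and band ``f`` the pipeline measures, trial by
trial, the signed relative change of band energy against the subject's
neutral-state reference:

    delta = (Energy(e, t, f) - Ref_Energy(e, f)) / Ref_Energy(e, f)

A trial counts as *significant* when ``|delta| >= beta_threshold`` (activity
may rise or fall during emotion, hence the absolute value).  The probability
that electrode ``e`` reacts to emotion ``eta`` in band ``f`` is the fraction
of that emotion's trials that are significant; electrodes whose probability
reaches ``alpha_threshold`` form the relevant set ``Gamma(s, eta, f)``.

Energies can be measured on the whole trial (the transform-only baselines)
or on the ZTW-windowed epoch frame located by epoch selection (the full
method), with either the DFT-magnitude or the NGD spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import EMOTIONS, NEUTRAL, BandSpec, Trial, TrialStore
from .exceptions import (
    DegenerateBaselineError,
    MissingBaselineError,
    ValidationError,
)
from .spectral import apply_ztw, band_energy, dft_spectrum, ngd_spectrum, ztw_window
from .ztwbes import FramePlan

log = logging.getLogger(__name__)


def segment_band_energies(
    data: np.ndarray,
    fs: float,
    bands: Sequence[BandSpec],
    transform: str = "ngd",
    segment: str = "trial",
    plan: Optional[FramePlan] = None,
    epoch: Optional[int] = None,
) -> np.ndarray:
    """Band energies of the configured signal segment.

    ``data`` is (channels, samples) or (samples,); returns shape
    ``(channels, n_bands)`` (or ``(n_bands,)``).  ``segment="epoch"`` windows
    the epoch frame (``plan`` + 1-based ``epoch`` index) with the zero-time
    window before the transform; ``segment="trial"`` uses the raw full trial.
    """
    single = data.ndim == 1
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if segment in ("epoch", "epoch-windowed"):
        if plan is None or epoch is None:
            raise ValidationError("segment='epoch' requires a frame plan and epoch index")
        arr = arr[:, plan.sample_slice(epoch)]
        if segment == "epoch-windowed":
            # sensitivity-analysis mode: the zero-time window concentrates
            # nearly all weight on the first few samples, which makes
            # trial-level band energies extremely noisy; plain slicing is
            # the default for relevance scoring and feature extraction.
            arr = apply_ztw(arr, ztw_window(plan.frame_samples))
    elif segment != "trial":
        raise ValidationError(f"unknown segment mode: {segment!r}")
    if transform == "ngd":
        spec = ngd_spectrum(arr, fs)
    elif transform == "dft":
        spec = dft_spectrum(arr, fs)
    else:
        raise ValidationError(f"unknown transform: {transform!r}")
    out = np.stack([band_energy(spec, b) for b in bands], axis=-1)
    return out[0] if single else out


@dataclass
class BandReference:
    """Per-(electrode, band) average neutral-state band energy."""

    subject: str
    values: dict[tuple[str, str], float]  # (electrode label, band name) -> energy

    def get(self, electrode: str, band: str) -> float:
        try:
            return self.values[(electrode, band)]
        except KeyError:
            raise MissingBaselineError(
                f"no reference energy for electrode {electrode!r}, band {band!r}"
            ) from None


@dataclass
class RelevanceMap:
    """Relevant-electrode sets with the underlying probabilities."""

    subject: str
    alpha_threshold: float
    beta_threshold: float
    rho: dict[tuple[str, str, str], float] = field(default_factory=dict)
    gamma_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    relevant: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def electrodes(self, emotion: str, band: str) -> tuple[str, ...]:
        return self.relevant.get((emotion, band), ())


def band_reference(
    store: TrialStore,
    subject: str,
    electrodes: Sequence[str],
    bands: Optional[Sequence[BandSpec]] = None,
    transform: str = "ngd",
    segment: str = "trial",
    plan: Optional[FramePlan] = None,
    epoch: Optional[int] = None,
    neutral_pool: Optional[Sequence[Trial]] = None,
) -> BandReference:
    """Average neutral-state band energy per (electrode, band).

    ``neutral_pool`` restricts the baseline to a subset of neutral trials
    (used by cross-validation to avoid leakage).
    """
    bands = tuple(bands) if bands is not None else store.bands
    neutral = list(neutral_pool) if neutral_pool is not None else store.neutral_trials(subject)
    if not neutral:
        raise MissingBaselineError(f"subject {subject!r} has no neutral trials")
    idx = [store.channel_index(lb) for lb in electrodes]
    acc = np.zeros((len(idx), len(bands)))
    for trial in neutral:
        acc += segment_band_energies(
            trial.data[idx], trial.fs, bands, transform, segment, plan, epoch
        )
    acc /= len(neutral)
    values = {}
    for i, lb in enumerate(electrodes):
        for j, b in enumerate(bands):
            if acc[i, j] <= 0:
                raise DegenerateBaselineError(
                    f"zero reference energy at electrode {lb!r}, band {b.name!r}"
                )
            values[(lb, b.name)] = float(acc[i, j])
    return BandReference(subject=subject, values=values)


def delta_change(energy: float, ref: float) -> float:
    """Signed relative change ``(energy - ref) / ref`` against the baseline."""
    if ref <= 0:
        raise DegenerateBaselineError(f"reference energy must be > 0, got {ref}")
    return (energy - ref) / ref


def significant_trials(
    deltas: Sequence[float], beta_threshold: float
) -> list[int]:
    """Indices of trials whose ``|delta| >= beta_threshold`` (inclusive)."""
    return [i for i, d in enumerate(deltas) if abs(d) >= beta_threshold]


def relevance_probability(gamma_count: int, trial_count: int) -> float:
    """Fraction of an emotion's trials with significant change."""
    if trial_count < 1:
        raise ValidationError("trial_count must be >= 1")
    if not (0 <= gamma_count <= trial_count):
        raise ValidationError("gamma_count outside 0..trial_count")
    return gamma_count / trial_count


def select_relevant(
    store: TrialStore,
    subject: str,
    elite: Sequence[str],
    bands: Optional[Sequence[BandSpec]] = None,
    alpha_threshold: float = 0.5,
    beta_threshold: float = 0.5,
    transform: str = "ngd",
    segment: str = "trial",
    plan: Optional[FramePlan] = None,
    epoch: Optional[int] = None,
    strict: bool = False,
    trial_pool: Optional[Sequence[Trial]] = None,
    refs: Optional[BandReference] = None,
) -> RelevanceMap:
    """Build the relevant-electrode map over the elite set.

    Iterates over the eight non-neutral emotions (the neutral state is the
    reference and is never scored).  ``strict=True`` uses a strict inequality
    for the ``alpha_threshold`` comparison instead of the default inclusive
    one.  ``trial_pool`` restricts scoring to a subset of the subject's
    trials (cross-validation); ``refs`` supplies precomputed references.
    """
    if not elite:
        log.warning("empty elite set: all relevant sets will be empty")
    bands = tuple(bands) if bands is not None else store.bands
    if refs is None:
        neutral_pool = None
        if trial_pool is not None:
            neutral_pool = [t for t in trial_pool if t.emotion == NEUTRAL]
        refs = band_reference(
            store, subject, elite, bands, transform, segment, plan, epoch,
            neutral_pool=neutral_pool,
        )
    relmap = RelevanceMap(
        subject=subject, alpha_threshold=alpha_threshold, beta_threshold=beta_threshold
    )
    pool = list(trial_pool) if trial_pool is not None else store.query(subject=subject)
    idx = [store.channel_index(lb) for lb in elite]
    for emotion in EMOTIONS:
        trials = [t for t in pool if t.emotion == emotion]
        if not trials:
            log.warning("subject %s has no %r trials; relevant set left empty", subject, emotion)
            for b in bands:
                relmap.relevant[(emotion, b.name)] = ()
            continue
        # energies: (trials, elite, bands)
        energies = np.stack(
            [
                segment_band_energies(
                    t.data[idx], t.fs, bands, transform, segment, plan, epoch
                )
                for t in trials
            ]
        )
        for j, b in enumerate(bands):
            selected = []
            for i, lb in enumerate(elite):
                ref = refs.get(lb, b.name)
                deltas = (energies[:, i, j] - ref) / ref
                count = len(significant_trials(deltas, beta_threshold))
                rho = relevance_probability(count, len(trials))
                relmap.gamma_counts[(emotion, b.name, lb)] = count
                relmap.rho[(emotion, b.name, lb)] = rho
                hit = rho > alpha_threshold if strict else rho >= alpha_threshold
                if hit:
                    selected.append(lb)
            relmap.relevant[(emotion, b.name)] = tuple(selected)
    return relmap
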
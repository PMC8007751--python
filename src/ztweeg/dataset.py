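"""Core domain model: frequency bands, electrodes, trials and the trial store.

The store groups multi-channel EEG trials by ``(subject, emotion)``.  Emotions
follow the nine-state discrete model used throughout the toolkit (eight
non-neutral states plus ``neutral``, which serves as the per-subject reference
state).  Continuous valence/arousal ratings on the usual 1-9 self-assessment
scale can be mapped onto the discrete labels with :func:`vad_to_emotion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exceptions import StoreLookupError, ValidationError

# Canonical emotion order; used for tie-breaking and fixed iteration order.
EMOTIONS: tuple[str, ...] = (
    "happy",
    "pleased",
    "relaxed",
    "excited",
    "calm",
    "distressed",
    "miserable",
    "depressed",
)
NEUTRAL = "neutral"
ALL_EMOTIONS: tuple[str, ...] = EMOTIONS + (NEUTRAL,)

#: Alternate spellings accepted on input and normalised to canonical labels.
EMOTION_ALIASES: Mapping[str, str] = {"pleasant": "pleased"}


def canonical_emotion(label: str) -> str:
    """Normalise an emotion label (case and known aliases)."""
    name = label.strip().lower()
    name = EMOTION_ALIASES.get(name, name)
    if name not in ALL_EMOTIONS:
        raise ValidationError(f"unknown emotion label: {label!r}")
    return name


@dataclass(frozen=True, order=True)
class BandSpec:
    """A named frequency band with edges in Hz (``lo < hi``)."""

    lo: float
    hi: float
    name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ValidationError(
                f"band {self.name!r}: lo ({self.lo}) must be < hi ({self.hi})"
            )


#: The four rhythm bands used by default, ordered by lower edge.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(4.0, 7.0, "theta"),
    BandSpec(8.0, 12.0, "alpha"),
    BandSpec(12.0, 36.0, "beta"),
    BandSpec(36.0, 42.0, "gamma"),
)


@dataclass(frozen=True)
class Electrode:
    """A scalp electrode.

    ``label`` names the cerebral region (e.g. ``"Fp1"``); ``serial`` is the
    integer suffix of the 10-20 label — odd for the left hemisphere, even for
    the right, and 0 for midline ("z") sites.
    """

    label: str
    serial: int

    @property
    def left(self) -> bool:
        return self.serial % 2 == 1

    @property
    def right(self) -> bool:
        return self.serial != 0 and self.serial % 2 == 0

    @property
    def midline(self) -> bool:
        return self.serial == 0


def electrode_from_label(label: str) -> Electrode:
    """Build an :class:`Electrode` from a 10-20 label such as ``"CP5"`` or ``"Oz"``."""
    digits = "".join(ch for ch in label if ch.isdigit())
    serial = int(digits) if digits else 0
    return Electrode(label=label, serial=serial)


#: EEG channel order of the standard 32-channel recording cap (the layout used
#: by the public emotional-EEG corpora this toolkit interoperates with).
STANDARD_32_LABELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)


def standard_montage(labels: Sequence[str] = STANDARD_32_LABELS) -> tuple[Electrode, ...]:
    montage = tuple(electrode_from_label(lb) for lb in labels)
    if len({(e.label, e.serial) for e in montage}) != len(montage):
        raise ValidationError("montage contains duplicate electrodes")
    return montage


@dataclass
class Trial:
    """One multi-channel EEG recording segment tied to (subject, emotion).

    ``data`` is a real matrix of shape ``(channels, samples)``; ``ratings``
    optionally carries (valence, arousal, dominance, liking), each in [1, 9].
    """

    trial_id: str
    subject: str
    data: np.ndarray
    fs: float
    emotion: Optional[str] = None
    ratings: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError(
                f"trial {self.trial_id!r}: data must be 2-D (channels x samples)"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"trial {self.trial_id!r}: data contains non-finite samples")
        if self.fs <= 0:
            raise ValidationError(f"trial {self.trial_id!r}: fs must be positive")
        if self.emotion is not None:
            self.emotion = canonical_emotion(self.emotion)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


class TrialStore:
    """A collection of trials with a shared montage and band list.

    Every trial maps to exactly one ``(subject, emotion)`` pair, so subject
    sets and emotion sets each partition the store.
    """

    def __init__(
        self,
        trials: Iterable[Trial],
        montage: Sequence[Electrode] = None,
        bands: Sequence[BandSpec] = DEFAULT_BANDS,
    ) -> None:
        self.trials: list[Trial] = sorted(trials, key=lambda t: t.trial_id)
        self.montage: tuple[Electrode, ...] = (
            tuple(montage) if montage is not None else standard_montage()
        )
        self.bands: tuple[BandSpec, ...] = tuple(sorted(bands))
        self._validate()

    def _validate(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate trial_id in store")
        max_hi = max(b.hi for b in self.bands)
        for t in self.trials:
            if t.n_channels != len(self.montage):
                raise ValidationError(
                    f"trial {t.trial_id!r}: {t.n_channels} channels, "
                    f"montage has {len(self.montage)}"
                )
            if t.fs <= 2 * max_hi:
                raise ValidationError(
                    f"trial {t.trial_id!r}: fs={t.fs} must exceed twice the top "
                    f"band edge ({max_hi} Hz)"
                )

    # -- index functions ---------------------------------------------------

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({t.subject for t in self.trials}))

    @property
    def emotions(self) -> tuple[str, ...]:
        present = {t.emotion for t in self.trials if t.emotion is not None}
        return tuple(e for e in ALL_EMOTIONS if e in present)

    @property
    def fs(self) -> float:
        if not self.trials:
            raise ValidationError("empty store has no sampling rate")
        return self.trials[0].fs

    def channel_index(self, label: str) -> int:
        for i, e in enumerate(self.montage):
            if e.label == label:
                return i
        raise StoreLookupError(f"electrode {label!r} not in montage")

    def query(self, subject: Optional[str] = None, emotion: Optional[str] = None) -> list[Trial]:
        """Return trials for a subject, an emotion, or their intersection.

        With only ``subject`` this is the subject's full trial set; with only
        ``emotion`` the cross-subject set for that state; with both, their
        intersection.  Results are ordered by ``trial_id``.
        """
        if subject is None and emotion is None:
            raise ValidationError("query needs at least one of subject / emotion")
        if subject is not None and subject not in self.subjects:
            raise StoreLookupError(f"unknown subject: {subject!r}")
        if emotion is not None:
            emotion = canonical_emotion(emotion)
            if emotion not in self.emotions:
                raise StoreLookupError(f"no trials with emotion: {emotion!r}")
        out = [
            t
            for t in self.trials
            if (subject is None or t.subject == subject)
            and (emotion is None or t.emotion == emotion)
        ]
        return out

    def neutral_trials(self, subject: str) -> list[Trial]:
        """The subject's neutral-state (reference) trials; may be empty."""
        if subject not in self.subjects:
            raise StoreLookupError(f"unknown subject: {subject!r}")
        return [t for t in self.trials if t.subject == subject and t.emotion == NEUTRAL]


def query_trials(
    store: TrialStore, subject: Optional[str] = None, emotion: Optional[str] = None
) -> list[Trial]:
    """Functional alias for :meth:`TrialStore.query`."""
    return store.query(subject=subject, emotion=emotion)


# -- valence/arousal grid --------------------------------------------------

#: Default thresholds splitting the 1-9 rating axis into thirds.
DEFAULT_CUTPOINTS: tuple[float, float] = (1 + 8 / 3, 1 + 16 / 3)  # (3.667, 6.333)

#: 3x3 grid, rows = arousal tercile (low, mid, high), columns = valence
#: tercile (low, mid, high).  The placement follows the circumplex layout;
#: it is configuration, not a fixed fact, and may be overridden.
DEFAULT_VAD_GRID: tuple[tuple[str, str, str], ...] = (
    ("depressed", "calm", "relaxed"),  # low arousal
    ("miserable", "neutral", "pleased"),  # mid arousal
    ("distressed", "excited", "happy"),  # high arousal
)


def _tercile(x: float, cutpoints: tuple[float, float]) -> int:
    lo, hi = cutpoints
    if x < lo:
        return 0
    if x < hi:
        return 1
    return 2


def vad_to_emotion(
    valence: float,
    arousal: float,
    cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS,
    grid: Sequence[Sequence[str]] = DEFAULT_VAD_GRID,
) -> str:
    """Map (valence, arousal) ratings in [1, 9] onto one of the nine labels.

    Each axis is split at ``cutpoints`` (defaults at thirds of the scale) and
    the pair indexes the 3x3 ``grid``.  The mapping is total on [1, 9]^2 and
    its preimage cells tile the square.
    """
    for name, v in (("valence", valence), ("arousal", arousal)):
        if not (1.0 <= v <= 9.0):
            raise ValidationError(f"{name} rating {v} outside [1, 9]")
    return grid[_tercile(arousal, cutpoints)][_tercile(valence, cutpoints)]
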
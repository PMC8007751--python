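"""End-to-end per-subject pipeline and cross-validated evaluation.

Three experiment variants share this code path:

* ``dft`` — whole-trial DFT-magnitude band energies, all montage electrodes
  eligible, no epoch selection;
* ``ngd`` — identical but with NGD band energies;
* ``proposed`` — NGD energies plus ZTW-based epoch selection: features come
  from the epoch frame only and only elite electrodes are eligible.

Cross-validation is stratified by emotion, and everything derived from data
(neutral references, epoch location, elite set, relevant electrodes) is
re-derived inside each training fold so no information leaks into the test
fold.  Band energies themselves depend only on the individual trial, so they
are computed once per store and cached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .classify import (
    EMOTIONS,
    REJECT,
    EmotionEnsemble,
    FeatureSpec,
    LmNet,
    fuse_votes,
    init_lm_net,
    lm_fit,
    nn_predict,
    qdc_fit,
    qdc_predict,
)
from .dataset import ALL_EMOTIONS, NEUTRAL, TrialStore
from .exceptions import MissingBaselineError, ValidationError
from .spectral import (
    apply_ztw,
    band_energy,
    dft_spectrum,
    multiband_energy,
    ngd_spectrum,
    ztw_window,
)
from .ztwbes import decompose_frames, majority_vote, plurality_vote

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable stage parameters of one experiment run."""

    variant: str = "proposed"  # "dft" | "ngd" | "proposed"
    mode: str = "qdc"  # "qdc" | "nn1" | "nn2"
    kappa: float = 15.0
    shift: float = 15.0
    alpha_threshold: float = 0.5
    beta_threshold: float = 0.5
    folds: int = 10
    seed: int = 0
    baseline: str = "windowed"  # epoch-selection baseline mode
    include_neutral_votes: bool = False
    qdc_reg: "float | str" = "auto"
    nn_hidden: tuple[int, ...] = (3, 3, 3)
    nn_max_iter: int = 5
    nn_lambda_init: float = 3.0
    nn_lambda_factor: float = 10.0
    nn_init_range: float = 0.5
    nn_err_target: float = 1e-10

    def __post_init__(self) -> None:
        if self.variant not in ("dft", "ngd", "proposed"):
            raise ValidationError(f"unknown variant: {self.variant!r}")
        if self.mode not in ("qdc", "nn1", "nn2"):
            raise ValidationError(f"unknown classifier mode: {self.mode!r}")

    @property
    def transform(self) -> str:
        return "dft" if self.variant == "dft" else "ngd"

    @property
    def uses_epoch(self) -> bool:
        return self.variant == "proposed"


@dataclass
class NnMember:
    """A trained network plus the training-fold feature standardisation.

    Inputs are standardised (training-fold mean/std) and scaled by
    ``1/sqrt(d)`` so that pre-activations stay within the responsive range of
    tanh regardless of the feature dimension; without this, high-dimensional
    delta features saturate every hidden unit and the network degenerates to
    a constant output.
    """

    net: LmNet
    mu: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / (self.sd * np.sqrt(max(1, X.shape[1])))


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


class StoreEnergies:
    """Per-(trial, electrode) energy cache for one subject.

    Caches quantities that depend only on the raw trial data:

    * ``frame_multi`` — ZTW-windowed NGD multiband energy of every sliding
      frame (drives epoch selection);
    * ``band_trial`` — whole-trial band energies under both transforms;
    * ``band_frame`` — raw (unwindowed) NGD band energies of every frame
      slice, so epoch-segment features are available for any epoch location.
    """

    def __init__(self, store: TrialStore, subject: str, kappa: float, shift: float):
        self.store = store
        self.subject = subject
        self.trials = store.query(subject=subject)
        if not self.trials:
            raise ValidationError(f"subject {subject!r} has no trials")
        durations = {t.duration_s for t in self.trials}
        if len(durations) != 1:
            raise ValidationError("pipeline requires equal-length trials")
        self.plan = decompose_frames(durations.pop(), kappa, shift, store.fs)
        self.labels = [e.label for e in store.montage]
        self.emotions = np.array([t.emotion for t in self.trials])
        bands = store.bands
        T, C, nF, B = len(self.trials), len(self.labels), self.plan.n, len(bands)
        self.frame_multi = np.empty((T, C, nF))
        self.band_frame = np.empty((T, C, nF, B))
        self.band_trial = {"ngd": np.empty((T, C, B)), "dft": np.empty((T, C, B))}
        w = ztw_window(self.plan.frame_samples)
        for i, trial in enumerate(self.trials):
            frames = np.stack(
                [trial.data[:, self.plan.sample_slice(k)] for k in range(1, nF + 1)],
                axis=1,
            )  # (C, nF, L)
            spec_w = ngd_spectrum(apply_ztw(frames, w), trial.fs)
            self.frame_multi[i] = multiband_energy(spec_w, bands)
            spec_raw = ngd_spectrum(frames, trial.fs)
            for j, b in enumerate(bands):
                self.band_frame[i, :, :, j] = band_energy(spec_raw, b)
            for name, fn in (("ngd", ngd_spectrum), ("dft", dft_spectrum)):
                spec = fn(trial.data, trial.fs)
                for j, b in enumerate(bands):
                    self.band_trial[name][i, :, j] = band_energy(spec, b)

    def indices(self, emotion: str, within: Optional[np.ndarray] = None) -> np.ndarray:
        mask = self.emotions == emotion
        idx = np.flatnonzero(mask)
        if within is not None:
            idx = np.intersect1d(idx, within)
        return idx

    # -- fold-level derivations -------------------------------------------

    def epoch_selection(
        self, train_idx: np.ndarray, cfg: PipelineConfig
    ) -> tuple[int, tuple[str, ...], float]:
        """ZTWBES winner/elite/margin computed from training trials only."""
        neutral = self.indices(NEUTRAL, train_idx)
        if neutral.size == 0:
            raise MissingBaselineError(f"no neutral trials in training fold")
        if cfg.baseline == "windowed":
            ref = self.frame_multi[neutral].mean(axis=(0, 2))  # (C,)
        else:
            full = self.band_trial["ngd"][neutral].sum(axis=2)  # multiband = sum of bands
            ref = full.mean(axis=0)
        voters = np.array(
            [
                i
                for i in train_idx
                if cfg.include_neutral_votes or self.emotions[i] != NEUTRAL
            ]
        )
        variations = np.abs(
            (self.frame_multi[voters] - ref[None, :, None]) / ref[None, :, None]
        )
        tags = np.argmax(variations, axis=2) + 1  # (T_train, C)
        votes = {
            lb: plurality_vote(tags[:, c].tolist()) for c, lb in enumerate(self.labels)
        }
        return majority_vote(votes)

    def band_energies(self, cfg: PipelineConfig, epoch: Optional[int]) -> np.ndarray:
        """(T, C, B) band energies at the configured segment/transform."""
        if cfg.uses_epoch:
            if epoch is None:
                raise ValidationError("proposed variant needs an epoch location")
            return self.band_frame[:, :, epoch - 1, :]
        return self.band_trial[cfg.transform]

    def fold_deltas(
        self, energies: np.ndarray, train_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """References from training-fold neutral trials and the delta tensor."""
        neutral = self.indices(NEUTRAL, train_idx)
        if neutral.size == 0:
            raise MissingBaselineError("no neutral trials in training fold")
        refs = energies[neutral].mean(axis=0)  # (C, B)
        if np.any(refs <= 0):
            raise ValidationError("non-positive band reference energy")
        return refs, (energies - refs) / refs

    def fold_relevance(
        self, deltas: np.ndarray, train_idx: np.ndarray, cfg: PipelineConfig,
        eligible: Sequence[str],
    ) -> dict[tuple[str, str], tuple[str, ...]]:
        """Relevant-electrode sets per (emotion, band) from the training fold."""
        relevant: dict[tuple[str, str], tuple[str, ...]] = {}
        col = {lb: c for c, lb in enumerate(self.labels)}
        for emotion in EMOTIONS:
            rows = self.indices(emotion, train_idx)
            for j, b in enumerate(self.store.bands):
                if rows.size == 0:
                    relevant[(emotion, b.name)] = ()
                    continue
                sel = []
                for lb in eligible:
                    d = deltas[rows, col[lb], j]
                    rho = np.mean(np.abs(d) >= cfg.beta_threshold)
                    if rho >= cfg.alpha_threshold:
                        sel.append(lb)
                relevant[(emotion, b.name)] = tuple(sel)
        return relevant

    def features(
        self, deltas: np.ndarray, spec: FeatureSpec, idx: np.ndarray
    ) -> np.ndarray:
        col = {lb: c for c, lb in enumerate(self.labels)}
        bandcol = {b.name: j for j, b in enumerate(self.store.bands)}
        if spec.dimension == 0:
            return np.zeros((idx.size, 0))
        cols = [(bandcol[bn], col[lb]) for bn, lb in spec.entries()]
        return np.stack([deltas[idx, c, j] for j, c in cols], axis=1)


# -- ensemble training and prediction ---------------------------------------


def _train_one_vs_all(
    cache: StoreEnergies,
    deltas: np.ndarray,
    relevant: dict[tuple[str, str], tuple[str, ...]],
    train_idx: np.ndarray,
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> EmotionEnsemble:
    members: dict = {}
    training_acc: dict[str, float] = {}
    specs: dict[str, FeatureSpec] = {}
    y_emotions = cache.emotions[train_idx]
    for emotion in EMOTIONS:
        per_band = {
            b.name: relevant[(emotion, b.name)] for b in cache.store.bands
        }
        spec = FeatureSpec(emotion=emotion, per_band=per_band)
        specs[emotion] = spec
        y = (y_emotions == emotion).astype(int)
        if spec.dimension == 0 or y.sum() < 2:
            # nothing to discriminate on: degenerate member always votes outlier
            members[emotion] = None
            training_acc[emotion] = float(np.mean(y == 0))
            continue
        X = cache.features(deltas, spec, train_idx)
        if cfg.mode == "qdc":
            model = qdc_fit(X, y, reg=cfg.qdc_reg)
            pred, _ = qdc_predict(model, X)
            training_acc[emotion] = float(np.mean(np.asarray(pred) == y))
        else:
            net = init_lm_net(
                spec.dimension, 1, cfg.nn_hidden, rng, cfg.nn_init_range
            )
            mu, sd = _standardise(X)
            member = NnMember(net=net, mu=mu, sd=sd)
            Xn = member.transform(X)
            lm_fit(
                net, Xn, y.astype(float),
                max_iter=cfg.nn_max_iter, err_target=cfg.nn_err_target,
                lambda_init=cfg.nn_lambda_init, lambda_factor=cfg.nn_lambda_factor,
            )
            model = member
            training_acc[emotion] = float(np.mean(nn_predict(net, Xn) == y))
        members[emotion] = model
    mode = "one-vs-all-qdc" if cfg.mode == "qdc" else "one-vs-all-nn"
    return EmotionEnsemble(
        mode=mode, members=members, training_acc=training_acc, feature_specs=specs
    )


def _member_votes(
    ensemble: EmotionEnsemble,
    cache: StoreEnergies,
    deltas: np.ndarray,
    idx: np.ndarray,
    cfg: PipelineConfig,
) -> dict[str, np.ndarray]:
    votes: dict[str, np.ndarray] = {}
    for emotion in EMOTIONS:
        model = ensemble.members[emotion]
        if model is None:
            votes[emotion] = np.zeros(idx.size, dtype=int)
            continue
        X = cache.features(deltas, ensemble.feature_specs[emotion], idx)
        if cfg.mode == "qdc":
            pred, _ = qdc_predict(model, X)
            votes[emotion] = np.asarray(pred, dtype=int)
        else:
            votes[emotion] = np.asarray(
                nn_predict(model.net, model.transform(X)), dtype=int
            )
    return votes


def crossvalidate(
    store: TrialStore,
    subject: str,
    cfg: Optional[PipelineConfig] = None,
    cache: Optional[StoreEnergies] = None,
) -> dict:
    """Stratified k-fold evaluation of the configured pipeline for a subject.

    Returns per-emotion one-vs-all accuracies, the final-decision accuracy
    (with rejected trials counted both as errors and as excluded), a
    confusion matrix, and per-fold epoch/elite diagnostics.  Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    if cache is None:
        cache = StoreEnergies(store, subject, cfg.kappa, cfg.shift)
    y_all = cache.emotions
    counts = {e: int(np.sum(y_all == e)) for e in set(y_all.tolist())}
    rng = np.random.default_rng(cfg.seed)
    if min(counts.values()) < cfg.folds:
        log.warning(
            "smallest class has %d < %d trials; falling back to leave-one-out",
            min(counts.values()), cfg.folds,
        )
        splits = list(LeaveOneOut().split(np.zeros(len(y_all))))
    else:
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        splits = list(skf.split(np.zeros(len(y_all)), y_all))

    label_order = list(ALL_EMOTIONS) + [REJECT]
    confusion = {t: {p: 0 for p in label_order} for t in ALL_EMOTIONS}
    member_hits = {e: 0 for e in EMOTIONS}
    member_total = {e: 0 for e in EMOTIONS}
    finals: list[tuple[str, str]] = []
    fold_info = []

    for train_idx, test_idx in splits:
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        if cfg.uses_epoch:
            epoch, elite, margin = cache.epoch_selection(train_idx, cfg)
        else:
            epoch, elite, margin = None, tuple(cache.labels), 1.0
        energies = cache.band_energies(cfg, epoch)
        refs, deltas = cache.fold_deltas(energies, train_idx)
        relevant = cache.fold_relevance(deltas, train_idx, cfg, elite)
        fold_info.append(
            {"epoch": epoch, "n_elite": len(elite), "margin": margin,
             "mean_gamma_size": float(np.mean([len(v) for v in relevant.values()]))}
        )
        if cfg.mode in ("qdc", "nn1"):
            ensemble = _train_one_vs_all(cache, deltas, relevant, train_idx, cfg, rng)
            votes = _member_votes(ensemble, cache, deltas, test_idx, cfg)
            for e in EMOTIONS:
                truth = (cache.emotions[test_idx] == e).astype(int)
                member_hits[e] += int(np.sum(votes[e] == truth))
                member_total[e] += test_idx.size
            for row, ti in enumerate(test_idx):
                vote_map = {e: bool(votes[e][row]) for e in EMOTIONS}
                final = fuse_votes(vote_map, ensemble.training_acc)
                truth = cache.emotions[ti]
                finals.append((truth, final))
                confusion[truth][final] += 1
        else:  # nn2: all-together network with one output per label
            # union feature layout over all emotions' relevant electrodes
            union_spec = FeatureSpec(
                emotion="all",
                per_band=_union_per_band(relevant, cache.store.bands),
            )
            class_order = list(ALL_EMOTIONS)
            if union_spec.dimension == 0:
                for ti in test_idx:
                    truth = cache.emotions[ti]
                    finals.append((truth, NEUTRAL))
                    confusion[truth][NEUTRAL] += 1
                continue
            Xtr = cache.features(deltas, union_spec, train_idx)
            ytr = np.zeros((train_idx.size, len(class_order)))
            for i, ti in enumerate(train_idx):
                ytr[i, class_order.index(cache.emotions[ti])] = 1.0
            net = init_lm_net(
                union_spec.dimension, len(class_order), cfg.nn_hidden, rng,
                cfg.nn_init_range,
            )
            mu, sd = _standardise(Xtr)
            member = NnMember(net=net, mu=mu, sd=sd)
            lm_fit(
                net, member.transform(Xtr), ytr,
                max_iter=cfg.nn_max_iter, err_target=cfg.nn_err_target,
                lambda_init=cfg.nn_lambda_init, lambda_factor=cfg.nn_lambda_factor,
            )
            Xte = cache.features(deltas, union_spec, test_idx)
            pred_idx = np.asarray(nn_predict(net, member.transform(Xte)))
            for row, ti in enumerate(test_idx):
                final = class_order[int(pred_idx[row])]
                truth = cache.emotions[ti]
                finals.append((truth, final))
                confusion[truth][final] += 1

    per_emotion_acc = {
        e: member_hits[e] / member_total[e] if member_total[e] else float("nan")
        for e in EMOTIONS
    }
    n = len(finals)
    n_reject = sum(1 for _, p in finals if p == REJECT)
    correct = sum(1 for t, p in finals if t == p)
    scored = n - n_reject
    return {
        "subject": subject,
        "config": cfg,
        "per_emotion_accuracy": per_emotion_acc,
        "final_accuracy": correct / n if n else float("nan"),
        "final_accuracy_excluding_rejects": correct / scored if scored else float("nan"),
        "n_trials": n,
        "n_reject": n_reject,
        "confusion": confusion,
        "folds": fold_info,
    }


def _union_per_band(
    relevant: dict[tuple[str, str], tuple[str, ...]], bands
) -> dict[str, tuple[str, ...]]:
    per_band: dict[str, tuple[str, ...]] = {}
    for b in bands:
        seen: list[str] = []
        for emotion in EMOTIONS:
            for lb in relevant.get((emotion, b.name), ()):
                if lb not in seen:
                    seen.append(lb)
        per_band[b.name] = tuple(seen)
    return per_band
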
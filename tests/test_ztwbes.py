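"""Frame decomposition, voting, and end-to-end epoch recovery."""

import numpy as np
import pytest

from ztweeg.dataset import Trial, TrialStore
from ztweeg.exceptions import (
    DegenerateBaselineError,
    MissingBaselineError,
    ValidationError,
)
from ztweeg.spectral import apply_ztw, multiband_energy, ngd_spectrum, ztw_window
from ztweeg.ztwbes import (
    decompose_frames,
    frame_energies,
    frame_variation,
    majority_vote,
    neutral_reference,
    plurality_vote,
    run_ztwbes,
    tag_trial,
)

FS = 128.0


def test_frame_decomposition_worked_example():
    plan = decompose_frames(8.0, kappa=6.0, shift=2.0, fs=FS)
    assert plan.n == 2
    assert plan.frames == ((0.0, 6.0), (2.0, 8.0))
    s = plan.sample_slice(1)
    assert (s.start, s.stop) == (0, 768)  # half-open, round(start*fs)
    s = plan.sample_slice(2)
    assert (s.start, s.stop) == (256, 1024)


def test_default_frame_plan_partitions_a_minute_trial():
    plan = decompose_frames(60.0, kappa=15.0, shift=15.0, fs=FS)
    assert plan.n == 4
    slices = [plan.sample_slice(k) for k in range(1, 5)]
    # contiguous, non-overlapping, covering the first n*kappa seconds
    assert slices[0].start == 0
    for a, b in zip(slices[:-1], slices[1:]):
        assert a.stop == b.start
    assert slices[-1].stop == int(60 * FS)


def test_single_frame_when_kappa_equals_trial_length():
    plan = decompose_frames(10.0, kappa=10.0, shift=5.0, fs=FS)
    assert plan.n == 1
    assert plan.frames == ((0.0, 10.0),)


def test_frame_plan_rejects_oversized_kappa():
    with pytest.raises(ValidationError):
        decompose_frames(8.0, kappa=10.0, shift=2.0, fs=FS)


def test_plurality_vote_majorities_and_tie_breaks():
    assert plurality_vote([2, 2, 3]) == 2
    assert plurality_vote([1, 2]) == 1  # tie -> smallest index
    assert plurality_vote([3]) == 3
    with pytest.raises(ValidationError):
        plurality_vote([])


def test_majority_vote_margins_and_fallback():
    # 20 of 32 electrodes agree
    votes = {f"e{i}": (2 if i < 20 else 3) for i in range(32)}
    winner, elite, margin = majority_vote(votes)
    assert (winner, len(elite), margin) == (2, 20, 0.625)
    # exact half: falls back to plurality with margin 0.5 recorded
    votes = {f"e{i}": (2 if i < 16 else 3) for i in range(32)}
    winner, elite, margin = majority_vote(votes)
    assert winner == 2 and margin == 0.5
    # unanimity
    votes = {f"e{i}": 4 for i in range(8)}
    winner, elite, margin = majority_vote(votes)
    assert winner == 4 and len(elite) == 8 and margin == 1.0
    with pytest.raises(ValidationError):
        majority_vote({})


def test_frame_variation_matches_relative_deviation(rng):
    frame = rng.normal(size=512)
    bands = None
    from ztweeg.dataset import DEFAULT_BANDS

    w = ztw_window(512)
    energy = multiband_energy(ngd_spectrum(apply_ztw(frame, w), FS), DEFAULT_BANDS)
    assert frame_variation(frame, energy, DEFAULT_BANDS, FS) == pytest.approx(0.0)
    assert frame_variation(frame, energy / 2, DEFAULT_BANDS, FS) == pytest.approx(1.0)
    assert frame_variation(frame, energy * 2, DEFAULT_BANDS, FS) == pytest.approx(0.5)
    with pytest.raises(DegenerateBaselineError):
        frame_variation(frame, 0.0, DEFAULT_BANDS, FS)


def test_neutral_reference_is_the_mean_over_neutral_trials(small_sim):
    _, store, _ = small_sim
    subject = store.subjects[0]
    plan = decompose_frames(16.0, 4.0, 4.0, FS)
    ref = neutral_reference(store, subject, plan=plan)
    neutral = store.neutral_trials(subject)
    expected = np.mean(
        [frame_energies(t.data, plan, store.bands, FS).mean(axis=1) for t in neutral],
        axis=0,
    )
    got = np.array([ref.per_electrode[e.label] for e in store.montage])
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_neutral_reference_requires_neutral_trials():
    from ztweeg.dataset import standard_montage

    rng = np.random.default_rng(0)
    trials = [
        Trial("t1", "s1", rng.normal(size=(2, 512)), FS, emotion="happy"),
    ]
    store = TrialStore(trials, montage=standard_montage()[:2])
    with pytest.raises(MissingBaselineError):
        neutral_reference(store, "s1", plan=decompose_frames(4.0, 2.0, 2.0, FS))


def test_tag_trial_prefers_the_planted_frame():
    # a strong, clean effect so individual (trial, electrode) tags are reliable
    from ztweeg.synthetic import SimConfig, generate

    cfg = SimConfig(
        n_subjects=1, n_channels=8, trial_len_s=16.0, kappa=4.0, shift=4.0,
        trials_per_emotion=4, effect_size=4.0, snr=10.0, seed=3,
    )
    store, gt = generate(cfg)
    subject = store.subjects[0]
    k_star = gt.epoch_frame[subject]
    plan = decompose_frames(cfg.trial_len_s, cfg.kappa, cfg.shift, cfg.fs)
    ref = neutral_reference(store, subject, plan=plan)
    emotion = "happy"
    modulated = set().union(
        *[gt.relevant[(subject, emotion, b.name)] for b in store.bands]
    )
    hits = total = 0
    for trial in store.query(subject=subject, emotion=emotion):
        for lb in modulated:
            c = store.channel_index(lb)
            tag = tag_trial(trial, c, plan, ref.per_electrode[lb], store.bands)
            hits += tag == k_star
            total += 1
    assert hits / total > 0.7


def test_run_ztwbes_recovers_planted_epochs_per_subject(small_sim):
    cfg, store, gt = small_sim
    for subject in store.subjects:
        res = run_ztwbes(store, subject, kappa=cfg.kappa, shift=cfg.shift)
        assert res.winner_location == gt.epoch_frame[subject]
        assert res.vote_margin > 0.5
        assert set(res.elite) <= {e.label for e in store.montage}
        assert 1 <= res.winner_location <= res.plan.n
        # elite electrodes are exactly those voting for the winner
        assert set(res.elite) == {
            lb for lb, v in res.per_electrode_votes.items() if v == res.winner_location
        }


def test_epoch_location_differs_across_subjects():
    from ztweeg.synthetic import SimConfig, generate

    cfg = SimConfig(
        n_subjects=5, n_channels=8, trial_len_s=16.0, kappa=4.0, shift=4.0,
        trials_per_emotion=4, seed=2,
    )
    store, gt = generate(cfg)
    locations = {gt.epoch_frame[s] for s in store.subjects}
    assert len(locations) > 1  # the generator varies the epoch per subject
    recovered = {
        s: run_ztwbes(store, s, kappa=cfg.kappa, shift=cfg.shift).winner_location
        for s in store.subjects
    }
    assert recovered == gt.epoch_frame


def test_winner_is_invariant_to_electrode_permutation(small_sim):
    cfg, store, gt = small_sim
    subject = store.subjects[0]
    base = run_ztwbes(store, subject, kappa=cfg.kappa, shift=cfg.shift)
    perm = np.random.default_rng(4).permutation(len(store.montage))
    trials = [
        Trial(t.trial_id, t.subject, t.data[perm], t.fs, emotion=t.emotion)
        for t in store.trials
    ]
    permuted = TrialStore(
        trials, montage=[store.montage[i] for i in perm], bands=store.bands
    )
    res = run_ztwbes(permuted, subject, kappa=cfg.kappa, shift=cfg.shift)
    assert res.winner_location == base.winner_location
    assert set(res.elite) == set(base.elite)


def test_single_trial_subject_uses_its_consensus_tag(small_sim):
    cfg, store, _ = small_sim
    subject = store.subjects[0]
    one = store.query(subject=subject, emotion="happy")[:1]
    neutral = store.neutral_trials(subject)
    sub = TrialStore(one + neutral, montage=store.montage, bands=store.bands)
    res = run_ztwbes(sub, subject, kappa=cfg.kappa, shift=cfg.shift)
    tags = list(res.per_electrode_votes.values())
    assert res.winner_location == plurality_vote(tags)
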
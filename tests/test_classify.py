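"""QDC discriminants, LM network training, fusion rules and cross-validation."""

import itertools

import numpy as np
import pytest

from ztweeg.classify import (
    NN_OUTPUT_THRESHOLD,
    REJECT,
    FeatureSpec,
    fuse_votes,
    init_lm_net,
    lm_fit,
    nn_forward,
    nn_predict,
    qdc_fit,
    qdc_predict,
    qdc_scores,
)
from ztweeg.dataset import EMOTIONS, NEUTRAL, Trial, TrialStore
from ztweeg.exceptions import TrainingError, ValidationError
from ztweeg.pipeline import PipelineConfig, crossvalidate


def brute_qdc_score(mean, cov, prior, x):
    """Term-by-term evaluation of the quadratic discriminant."""
    d = x - mean
    return (
        -0.5 * np.log(np.linalg.det(cov))
        - 0.5 * float(d @ np.linalg.inv(cov) @ d)
        + np.log(prior)
    )


# -- feature extraction ------------------------------------------------------


def test_extract_features_are_signed_deltas_in_spec_order(small_sim):
    from ztweeg.classify import extract_features
    from ztweeg.relevance import BandReference, segment_band_energies

    cfg, store, _ = small_sim
    subject = store.subjects[0]
    trial = store.query(subject=subject, emotion="happy")[0]
    labels = [e.label for e in store.montage][:3]
    spec = FeatureSpec(emotion="happy", per_band={"alpha": tuple(labels)})
    assert spec.dimension == 3
    # references equal to the trial's own energies -> exactly zero features
    energies = {
        lb: segment_band_energies(
            trial.data[store.channel_index(lb)], trial.fs, store.bands
        )
        for lb in labels
    }
    alpha_idx = [b.name for b in store.bands].index("alpha")
    refs = BandReference(
        subject=subject,
        values={(lb, "alpha"): float(energies[lb][alpha_idx]) for lb in labels},
    )
    feats = extract_features(trial, spec, refs, store)
    np.testing.assert_allclose(feats, 0.0, atol=1e-12)
    # halved references -> every delta is +1
    refs2 = BandReference(
        subject=subject,
        values={k: v / 2 for k, v in refs.values.items()},
    )
    np.testing.assert_allclose(extract_features(trial, spec, refs2, store), 1.0)


def test_extract_features_names_the_missing_reference(small_sim):
    from ztweeg.classify import extract_features
    from ztweeg.exceptions import MissingBaselineError
    from ztweeg.relevance import BandReference

    cfg, store, _ = small_sim
    trial = store.trials[0]
    spec = FeatureSpec(
        emotion="happy", per_band={"alpha": (store.montage[0].label,)}
    )
    refs = BandReference(subject=trial.subject, values={})
    with pytest.raises(MissingBaselineError, match="alpha"):
        extract_features(trial, spec, refs, store)


# -- QDC -------------------------------------------------------------------


def test_qdc_scores_match_term_by_term_evaluation(rng):
    d, n = 4, 40
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(3, 2, (n, d))])
    y = np.array([0] * n + [1] * n)
    model = qdc_fit(X, y)
    for x in rng.normal(size=(10, d)):
        scores = qdc_scores(model, x)
        for i in range(2):
            expected = brute_qdc_score(
                model.means[i], model.covariances[i], model.priors[i], x
            )
            assert abs(scores[i] - expected) < 1e-9


def test_qdc_estimates_match_well_separated_clouds(rng):
    n = 200
    X = np.vstack(
        [rng.normal([0, 0], 1.0, (n, 2)), rng.normal([10, 10], 1.0, (n, 2))]
    )
    y = np.array([0] * n + [1] * n)
    model = qdc_fit(X, y)
    se = 1.0 / np.sqrt(n)
    assert np.all(np.abs(model.means[0] - 0.0) < 3 * se)
    assert np.all(np.abs(model.means[1] - 10.0) < 3 * se)


def test_qdc_one_dimensional_closed_form_decision():
    rng = np.random.default_rng(0)
    X = np.concatenate([rng.normal(0, 1, 100), rng.normal(10, 1, 100)])[:, None]
    y = np.array([0] * 100 + [1] * 100)
    model = qdc_fit(X, y)
    label, scores = qdc_predict(model, np.array([2.0]))
    assert label == 0 and scores[0] > scores[1]


def test_qdc_priors_reflect_class_proportions(rng):
    X = rng.normal(size=(40, 3))
    y = np.array([0] * 30 + [1] * 10)
    model = qdc_fit(X, y)
    np.testing.assert_allclose(model.priors, [0.75, 0.25])


def test_qdc_prior_only_decision_with_identical_classes(rng):
    X = rng.normal(size=(40, 2))
    y = np.array([0] * 36 + [1] * 4)
    # force identical class parameters, unequal priors
    model = qdc_fit(X, y)
    model.means[1] = model.means[0]
    model.covariances[1] = model.covariances[0]
    for x in rng.normal(size=(20, 2)):
        label, _ = qdc_predict(model, x)
        assert label == 0  # the 0.9-prior class always wins


def test_qdc_handles_duplicated_degenerate_samples():
    X = np.vstack([np.ones((5, 3)), 2 * np.ones((5, 3))])
    y = np.array([0] * 5 + [1] * 5)
    model = qdc_fit(X, y)  # singular covariances must be rescued
    label, _ = qdc_predict(model, np.ones(3) * 1.9)
    assert label == 1


def test_qdc_rejects_single_sample_classes_and_dim_mismatch(rng):
    X = rng.normal(size=(3, 2))
    with pytest.raises(TrainingError):
        qdc_fit(X, [0, 0, 1])
    model = qdc_fit(rng.normal(size=(8, 2)), [0] * 4 + [1] * 4)
    with pytest.raises(ValidationError):
        qdc_predict(model, np.zeros(5))


def test_qdc_reduces_to_nearest_mean_with_shared_spherical_covariance():
    from ztweeg.classify import QdcModel

    means = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    cov = np.stack([np.eye(2)] * 3)
    model = QdcModel(
        classes=(0, 1, 2), means=means, covariances=cov,
        priors=np.full(3, 1 / 3),
    )
    rng = np.random.default_rng(1)
    for x in rng.normal(0, 3, size=(50, 2)):
        label, _ = qdc_predict(model, x)
        assert label == int(np.argmin(np.linalg.norm(means - x, axis=1)))


def test_qdc_agrees_with_sklearn_qda_on_separable_data(rng):
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

    n = 100
    X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(4, 1.5, (n, 3))])
    y = np.array([0] * n + [1] * n)
    model = qdc_fit(X, y)
    ours, _ = qdc_predict(model, X)
    sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y).predict(X)
    assert np.mean(np.asarray(ours) == sk) == 1.0


# -- LM-trained network ----------------------------------------------------


def test_lm_jacobian_matches_finite_differences(rng):
    from ztweeg.classify import _jacobian, _pack, _unpack

    net = init_lm_net(3, 2, hidden=(3, 3), rng=rng)
    X = rng.normal(size=(5, 3))
    yhat, J = _jacobian(net, X)
    p0 = _pack(net)
    eps = 1e-6
    for col in rng.choice(p0.size, size=12, replace=False):
        p = p0.copy()
        p[col] += eps
        _unpack(net, p)
        plus = nn_forward(net, X)
        p[col] -= 2 * eps
        _unpack(net, p)
        minus = nn_forward(net, X)
        _unpack(net, p0)
        fd = ((plus - minus) / (2 * eps)).ravel()
        np.testing.assert_allclose(J[:, col], fd, atol=1e-5)


def test_lm_descent_on_a_linear_target(rng):
    X = np.linspace(-1, 1, 10)[:, None]
    y = 0.5 * X[:, 0]
    net = init_lm_net(1, 1, rng=rng)
    net = lm_fit(net, X, y, max_iter=5)
    assert net.trace[-1] < net.trace[0]
    # every accepted step strictly decreased the cost
    assert all(b < a for a, b in zip(net.trace[:-1], net.trace[1:]))


def test_lm_zero_iterations_leaves_the_network_unchanged(rng):
    net = init_lm_net(2, 1, rng=rng)
    before = [w.copy() for w in net.weights]
    lm_fit(net, rng.normal(size=(6, 2)), rng.normal(size=6), max_iter=0)
    for a, b in zip(before, net.weights):
        np.testing.assert_array_equal(a, b)


def test_lm_learns_xor_with_the_three_layer_tanh_net():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0.0, 1.0, 1.0, 0.0])
    net = init_lm_net(2, 1, hidden=(3, 3, 3), rng=np.random.default_rng(7))
    net = lm_fit(net, X, y, max_iter=200)
    pred = nn_predict(net, X)
    np.testing.assert_array_equal(pred, y.astype(int))


def test_lm_with_huge_damping_takes_vanishing_steps(rng):
    from ztweeg.classify import _pack

    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    net = init_lm_net(2, 1, rng=np.random.default_rng(0))
    p_before = _pack(net).copy()
    lm_fit(net, X, y, max_iter=1, lambda_init=1e12)
    step = np.linalg.norm(_pack(net) - p_before)
    assert step < 1e-6  # lambda -> infinity behaves as a vanishing-step descent


def test_nn_predict_thresholds_and_degenerate_net(rng):
    net = init_lm_net(2, 1, rng=rng)
    # force specific outputs through the final linear layer
    for w in net.weights:
        w[...] = 0.0
    for b in net.biases:
        b[...] = 0.0
    assert nn_predict(net, np.zeros(2)) == 0  # tanh(0) = 0 everywhere
    net.biases[-1][...] = 1.5
    assert nn_predict(net, np.zeros(2)) == 1
    net.biases[-1][...] = 0.0
    assert nn_predict(net, np.ones(2)) == 0
    with pytest.raises(ValidationError):
        nn_predict(net, np.zeros(3))
    assert 0.0 < NN_OUTPUT_THRESHOLD < 1.0


# -- fusion ------------------------------------------------------------------


def fusion_oracle(votes, acc):
    """Direct restatement of the three fusion rules."""
    claimants = [e for e in EMOTIONS if votes[e]]
    if not claimants:
        return NEUTRAL
    if len(claimants) >= 5:
        return REJECT
    return max(claimants, key=lambda e: (acc[e], -EMOTIONS.index(e)))


def test_fusion_examples():
    acc = {e: 0.8 for e in EMOTIONS}
    assert fuse_votes({e: False for e in EMOTIONS}, acc) == NEUTRAL
    votes = {e: e == "happy" for e in EMOTIONS}
    assert fuse_votes(votes, acc) == "happy"
    votes = {e: e in ("happy", "calm") for e in EMOTIONS}
    acc2 = dict(acc, happy=0.91, calm=0.93)
    assert fuse_votes(votes, acc2) == "calm"
    votes = {e: e in EMOTIONS[:5] for e in EMOTIONS}
    assert fuse_votes(votes, acc) == REJECT
    with pytest.raises(ValidationError):
        fuse_votes({e: False for e in EMOTIONS[:-1]}, acc)


def test_fusion_matches_rule_oracle_on_all_vote_patterns(rng):
    for pattern in itertools.product([False, True], repeat=8):
        votes = dict(zip(EMOTIONS, pattern))
        acc = dict(zip(EMOTIONS, rng.uniform(0.5, 1.0, 8)))
        assert fuse_votes(votes, acc) == fusion_oracle(votes, acc)


# -- cross-validation --------------------------------------------------------


def test_crossvalidate_is_deterministic(small_sim):
    cfg, store, _ = small_sim
    pc = PipelineConfig(
        variant="proposed", mode="qdc", folds=4, kappa=cfg.kappa, shift=cfg.shift,
        seed=5,
    )
    a = crossvalidate(store, store.subjects[0], pc)
    b = crossvalidate(store, store.subjects[0], pc)
    assert a["final_accuracy"] == b["final_accuracy"]
    assert a["per_emotion_accuracy"] == b["per_emotion_accuracy"]
    assert a["confusion"] == b["confusion"]


def test_crossvalidate_accuracy_collapses_under_label_permutation(small_sim):
    cfg, store, _ = small_sim
    subject = store.subjects[0]
    trials = store.query(subject=subject)
    emotions = [t.emotion for t in trials]
    rng = np.random.default_rng(0)
    rng.shuffle(emotions)
    permuted = TrialStore(
        [
            Trial(t.trial_id, t.subject, t.data, t.fs, emotion=e)
            for t, e in zip(trials, emotions)
        ],
        montage=store.montage,
        bands=store.bands,
    )
    pc = PipelineConfig(
        variant="proposed", mode="qdc", folds=4, kappa=cfg.kappa, shift=cfg.shift,
        seed=1,
    )
    res = crossvalidate(permuted, subject, pc)
    n = res["n_trials"]
    chance = 1 / 9
    # within 3 sigma of the binomial null
    assert res["final_accuracy"] <= chance + 3 * np.sqrt(chance * (1 - chance) / n)


def test_crossvalidate_end_to_end_recovers_emotions(default_sim):
    """At the study conditions (10 trials/emotion, effect 2.0, SNR 3) the
    one-vs-all QDC ensemble recovers the trial labels well above 0.8."""
    cfg, store, _ = default_sim
    pc = PipelineConfig(variant="proposed", mode="qdc", seed=3)
    res = crossvalidate(store, "s01", pc)
    assert res["final_accuracy"] >= 0.8
    assert set(res["per_emotion_accuracy"]) == set(EMOTIONS)
    assert all(0 <= a <= 1 for a in res["per_emotion_accuracy"].values())


def test_crossvalidate_falls_back_to_leave_one_out(small_sim):
    cfg, store, _ = small_sim
    pc = PipelineConfig(
        variant="proposed", mode="qdc", folds=10, kappa=cfg.kappa, shift=cfg.shift,
        seed=2,
    )
    res = crossvalidate(store, store.subjects[0], pc)  # 4 trials/class < 10 folds
    assert res["n_trials"] == len(store.query(subject=store.subjects[0]))
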
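"""Classification: features, QDC, an LM-trained tanh network, and fusion.

Features are the signed baseline-relative band-energy changes (delta values)
at the electrodes relevant to each emotion, ordered by (band, electrode).

Two classifier families are provided:

* a quadratic discriminant classifier (QDC): per-class Gaussian with its own
  covariance; decision by ``argmax_k delta_k(x)`` with
  ``delta_k(x) = -1/2 log|S_k| - 1/2 (x - mu_k)^T S_k^{-1} (x - mu_k) + log p_k``;
* a small feedforward tanh network (three hidden layers of three units)
  trained by Levenberg-Marquardt least squares.  The network is configured
  with no input/internal/output delays, so despite its recurrent-network
  lineage it is a static map.

Multi-class decisions use either eight one-vs-all members fused by a
three-rule vote (all-outlier -> neutral; a minority of target votes -> the
target-voting member with the best training accuracy; a majority of target
votes -> reject), or a single all-together network with one output per label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .dataset import EMOTIONS, NEUTRAL, BandSpec, Trial, TrialStore
from .exceptions import TrainingError, ValidationError
from .relevance import BandReference, RelevanceMap, segment_band_energies
from .ztwbes import FramePlan

log = logging.getLogger(__name__)

#: Sentinel label returned by the fusion rule when a majority of one-vs-all
#: members claim the trial (an inconsistent, hence rejected, outcome).
REJECT = "reject"


# -- feature extraction ----------------------------------------------------


@dataclass
class FeatureSpec:
    """Fixed (band, electrode) layout of a feature vector.

    The electrode order is frozen at construction and reused at predict
    time, so train and test features always align.
    """

    emotion: str  # target label, or "all" for the all-together scheme
    per_band: dict[str, tuple[str, ...]]  # band name -> ordered electrode labels

    @property
    def dimension(self) -> int:
        return sum(len(v) for v in self.per_band.values())

    def entries(self) -> list[tuple[str, str]]:
        return [(band, lb) for band, labels in self.per_band.items() for lb in labels]


def feature_spec_for(relmap: RelevanceMap, emotion: str) -> FeatureSpec:
    """Feature layout for one emotion: its relevant electrodes per band."""
    per_band = {
        band: tuple(labels)
        for (emo, band), labels in sorted(relmap.relevant.items())
        if emo == emotion
    }
    return FeatureSpec(emotion=emotion, per_band=per_band)


def feature_spec_union(relmap: RelevanceMap) -> FeatureSpec:
    """All-together layout: the union of relevant electrodes over emotions."""
    bands: dict[str, set[str]] = {}
    order: dict[str, list[str]] = {}
    for (emo, band), labels in sorted(relmap.relevant.items()):
        seen = bands.setdefault(band, set())
        ordered = order.setdefault(band, [])
        for lb in labels:
            if lb not in seen:
                seen.add(lb)
                ordered.append(lb)
    return FeatureSpec(emotion="all", per_band={b: tuple(v) for b, v in order.items()})


def extract_features(
    trial: Trial,
    spec: FeatureSpec,
    refs: BandReference,
    store: TrialStore,
    transform: str = "ngd",
    segment: str = "trial",
    plan: Optional[FramePlan] = None,
    epoch: Optional[int] = None,
) -> np.ndarray:
    """Signed delta feature vector of one trial under a feature layout."""
    bands_by_name = {b.name: b for b in store.bands}
    out = np.empty(spec.dimension)
    for i, (band_name, lb) in enumerate(spec.entries()):
        band = bands_by_name[band_name]
        energy = segment_band_energies(
            trial.data[store.channel_index(lb)], trial.fs, [band],
            transform, segment, plan, epoch,
        )[0]
        ref = refs.get(lb, band_name)
        out[i] = (energy - ref) / ref
    return out


# -- quadratic discriminant classifier -------------------------------------


@dataclass
class QdcModel:
    """Per-class Gaussian model for the quadratic discriminant rule."""

    classes: tuple
    means: np.ndarray  # (n_classes, d)
    covariances: np.ndarray  # (n_classes, d, d), regularised SPD
    priors: np.ndarray  # (n_classes,), sums to 1

    @property
    def dimension(self) -> int:
        return self.means.shape[1]


def qdc_fit(X: np.ndarray, y: Sequence, reg: "float | str" = "auto") -> QdcModel:
    """Fit per-class means, covariances and empirical priors.

    Class sample covariances are used as-is when positive definite.  A class
    with fewer samples than features has a singular sample covariance, for
    which the quadratic discriminant is undefined; with ``reg="auto"`` (the
    default) such classes get the Ledoit-Wolf shrinkage estimate, whose
    data-driven shrinkage intensity keeps the discriminant statistically
    usable even when ``n_k << d``.  A float ``reg`` instead adds
    ``reg * trace/d * I`` (a fixed-ridge rescue; adequate only for mild
    rank deficiency).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("X must be (samples, features) with >= 1 feature")
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    d = X.shape[1]
    means = np.empty((len(classes), d))
    covs = np.empty((len(classes), d, d))
    priors = np.empty(len(classes))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        if Xi.shape[0] < 2:
            raise TrainingError(f"class {c!r} has {Xi.shape[0]} sample(s); need >= 2")
        means[i] = Xi.mean(axis=0)
        cov = np.cov(Xi, rowvar=False, bias=False).reshape(d, d)
        if not _is_positive_definite(cov):
            cov = _rescue_covariance(Xi, cov, d, reg)
        covs[i] = cov
        priors[i] = Xi.shape[0] / X.shape[0]
    return QdcModel(classes=classes, means=means, covariances=covs, priors=priors)


def _rescue_covariance(
    Xi: np.ndarray, cov: np.ndarray, d: int, reg: "float | str"
) -> np.ndarray:
    if reg == "auto":
        from sklearn.covariance import ledoit_wolf

        cov, _ = ledoit_wolf(Xi)
        cov = np.asarray(cov).reshape(d, d)
        if _is_positive_definite(cov):
            return cov
        reg = 1e-6  # fully degenerate data (e.g. duplicated samples)
    # ridge scaled to the data's magnitude so it cannot underflow for
    # zero-variance classes
    scale = max(float(np.trace(cov)) / d, float(np.mean(Xi**2)))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    return cov + float(reg) * scale * np.eye(d)


def _is_positive_definite(a: np.ndarray) -> bool:
    # numerically PD: smallest eigenvalue clearly positive relative to the
    # largest (a bare Cholesky can succeed on rank-deficient matrices whose
    # smallest eigenvalue underflows to ~1e-20)
    try:
        ev = np.linalg.eigvalsh(a)
    except np.linalg.LinAlgError:
        return False
    if not np.all(np.isfinite(ev)) or ev[-1] <= 0:
        return False
    return ev[0] > ev[-1] * a.shape[0] * np.finfo(float).eps * 100


def qdc_scores(model: QdcModel, x: np.ndarray) -> np.ndarray:
    """Per-class quadratic discriminant scores for one sample or a batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.dimension:
        raise ValidationError(
            f"feature dimension {X.shape[1]} != model dimension {model.dimension}"
        )
    out = np.empty((X.shape[0], len(model.classes)))
    for i in range(len(model.classes)):
        cov = model.covariances[i]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise TrainingError("covariance is not positive definite")
        diff = X - model.means[i]
        maha = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
        out[:, i] = -0.5 * logdet - 0.5 * maha + np.log(model.priors[i])
    return out[0] if single else out


def qdc_predict(model: QdcModel, x: np.ndarray):
    """Predicted label(s) and discriminant scores; ties go to the first class."""
    scores = qdc_scores(model, x)
    if scores.ndim == 1:
        return model.classes[int(np.argmax(scores))], scores
    idx = np.argmax(scores, axis=1)
    return [model.classes[i] for i in idx], scores


# -- Levenberg-Marquardt tanh network ---------------------------------------


@dataclass
class LmNet:
    """Small feedforward tanh network with a linear output layer."""

    weights: list[np.ndarray]  # per layer, (n_out, n_in)
    biases: list[np.ndarray]  # per layer, (n_out,)
    trace: list[float] = field(default_factory=list)  # accepted-step costs

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[0]


def init_lm_net(
    n_inputs: int,
    n_outputs: int = 1,
    hidden: Sequence[int] = (3, 3, 3),
    rng: Optional[np.random.Generator] = None,
    init_range: float = 0.5,
) -> LmNet:
    """Initialise weights and biases uniformly in ``[-init_range, init_range]``."""
    if n_inputs < 1 or n_outputs < 1:
        raise ValidationError("network needs >= 1 input and output")
    rng = rng if rng is not None else np.random.default_rng()
    sizes = [n_inputs, *hidden, n_outputs]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-init_range, init_range, size=(b, a)))
        biases.append(rng.uniform(-init_range, init_range, size=b))
    return LmNet(weights=weights, biases=biases)


def _forward(net: LmNet, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; returns outputs (m, n_out) and per-layer activations."""
    acts = [X]
    a = X
    n_layers = len(net.weights)
    for li, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = a @ W.T + b
        a = z if li == n_layers - 1 else np.tanh(z)  # linear output layer
        acts.append(a)
    return a, acts


def nn_forward(net: LmNet, X: np.ndarray) -> np.ndarray:
    """Raw network outputs for a sample or batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise ValidationError(f"input dimension {X.shape[1]} != {net.n_inputs}")
    out, _ = _forward(net, X)
    return out


def _pack(net: LmNet) -> np.ndarray:
    return np.concatenate([w.ravel() for w in net.weights] + [b for b in net.biases])


def _unpack(net: LmNet, p: np.ndarray) -> None:
    i = 0
    for w in net.weights:
        w[...] = p[i : i + w.size].reshape(w.shape)
        i += w.size
    for b in net.biases:
        b[...] = p[i : i + b.size]
        i += b.size


def _jacobian(net: LmNet, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outputs and the Jacobian d y_hat / d p by exact backpropagation.

    Returns ``(yhat (m, q), J (m * q, p))`` with residual rows ordered
    sample-major.
    """
    m = X.shape[0]
    q = net.n_outputs
    yhat, acts = _forward(net, X)
    n_layers = len(net.weights)
    n_params = sum(w.size for w in net.weights) + sum(b.size for b in net.biases)
    J = np.zeros((m * q, n_params))
    for out_i in range(q):
        # delta at the linear output layer: d y[out_i] / d z_L
        delta = np.zeros((m, q))
        delta[:, out_i] = 1.0
        deltas = [None] * n_layers
        deltas[-1] = delta
        for li in range(n_layers - 2, -1, -1):
            upstream = deltas[li + 1] @ net.weights[li + 1]
            deltas[li] = upstream * (1.0 - acts[li + 1] ** 2)  # tanh'
        rows = slice(out_i, m * q, q)
        col = 0
        for li in range(n_layers):
            a_in = acts[li]  # (m, n_in)
            d = deltas[li]  # (m, n_out)
            block = d[:, :, None] * a_in[:, None, :]  # (m, n_out, n_in)
            J[rows, col : col + block[0].size] = block.reshape(m, -1)
            col += block[0].size
        for li in range(n_layers):
            d = deltas[li]
            J[rows, col : col + d.shape[1]] = d
            col += d.shape[1]
    return yhat, J


def lm_fit(
    net: LmNet,
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 5,
    err_target: float = 1e-10,
    lambda_init: float = 3.0,
    lambda_factor: float = 10.0,
    weights: Optional[np.ndarray] = None,
    max_rescues: int = 50,
) -> LmNet:
    """Train by damped Gauss-Newton (Levenberg-Marquardt) least squares.

    Each iteration solves ``(J^T W J + lambda diag(J^T W J)) h = J^T W r``
    for the step ``h``; a step is accepted only if it strictly decreases the
    weighted squared error, in which case ``lambda`` is divided by
    ``lambda_factor``; a rejected step multiplies it instead.  Stops after
    ``max_iter`` accepted steps, at ``err_target``, or when ``max_rescues``
    consecutive rejections exhaust the damping schedule.

    ``weights`` are per-residual inverse variances (identity by default; no
    per-sample measurement variances exist in this setting).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y disagree on sample count")
    if y.shape[1] != net.n_outputs:
        raise ValidationError("y width disagrees with network outputs")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float).ravel()
    lam = lambda_init

    def cost(yhat: np.ndarray) -> float:
        r = (y - yhat).ravel()
        return float(np.sum(w * r * r))

    yhat, J = _jacobian(net, X)
    current = cost(yhat)
    net.trace = [current]
    accepted = 0
    rescues = 0
    p = _pack(net)
    while accepted < max_iter and current > err_target:
        r = (y - yhat).ravel()
        JtW = J.T * w
        A = JtW @ J
        diag = np.diag(A).copy()
        diag[diag <= 0] = max(diag.max(), 1.0) * 1e-12  # keep damping effective
        g = JtW @ r
        try:
            h = np.linalg.solve(A + lam * np.diag(diag), g)
        except np.linalg.LinAlgError:
            lam *= lambda_factor
            rescues += 1
            if rescues > max_rescues:
                raise TrainingError("LM normal equations remained singular")
            continue
        candidate = p + h
        _unpack(net, candidate)
        yhat_new, J_new = _jacobian(net, X)
        new = cost(yhat_new)
        if new < current:
            p, yhat, J, current = candidate, yhat_new, J_new, new
            lam /= lambda_factor
            accepted += 1
            rescues = 0
            net.trace.append(current)
        else:
            _unpack(net, p)
            lam *= lambda_factor
            rescues += 1
            if rescues > max_rescues:
                break  # no further descent possible at any damping
    _unpack(net, p)
    return net


#: Raw network outputs are rounded to the nearer of the two codes 0 (outlier)
#: and 1 (target): the decision threshold sits midway between them.  With
#: imbalanced one-vs-all training sets the least-squares fit pulls target
#: outputs well below 1, so thresholds near the top of the output range
#: systematically miss targets.
NN_OUTPUT_THRESHOLD = 0.5


def nn_predict(net: LmNet, x: np.ndarray, threshold: float = NN_OUTPUT_THRESHOLD):
    """Thresholded (binary) or argmax (multi-output) network decision."""
    out = nn_forward(net, x)
    single = np.asarray(x).ndim == 1
    if net.n_outputs == 1:
        dec = (out[:, 0] > threshold).astype(int)
        return int(dec[0]) if single else dec
    idx = np.argmax(out, axis=1)
    return int(idx[0]) if single else idx


# -- one-vs-all fusion ------------------------------------------------------


def fuse_votes(
    votes: Mapping[str, bool],
    training_acc: Mapping[str, float],
    emotion_order: Sequence[str] = EMOTIONS,
) -> str:
    """Fuse eight one-vs-all target/outlier votes into a final label.

    * no target votes: the trial belongs to the neutral reference state;
    * a minority (1..4) of target votes: the target-voting member with the
      highest training accuracy wins (ties to the earliest emotion in
      ``emotion_order``);
    * a majority (>= 5) of target votes is inconsistent: ``REJECT``.
    """
    if set(votes) != set(emotion_order):
        missing = set(emotion_order) - set(votes)
        raise ValidationError(f"fusion needs one vote per emotion; missing {sorted(missing)}")
    claimants = [e for e in emotion_order if votes[e]]
    if not claimants:
        return NEUTRAL
    if len(claimants) > len(emotion_order) // 2:
        return REJECT
    best = max(training_acc[e] for e in claimants)
    return next(e for e in claimants if training_acc[e] == best)


@dataclass
class EmotionEnsemble:
    """Eight one-vs-all members (or one all-together model) plus fusion data."""

    mode: str  # "one-vs-all-qdc" | "one-vs-all-nn" | "all-together-nn"
    members: dict  # emotion -> model (or {"all": model})
    training_acc: dict[str, float]
    feature_specs: dict[str, FeatureSpec]

    def __post_init__(self) -> None:
        if self.mode.startswith("one-vs-all") and len(self.members) != len(EMOTIONS):
            raise ValidationError("one-vs-all ensemble needs exactly 8 members")
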
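"""Bidirectional LSTM classifier over scattering feature matrices.

Each 81 x 20 feature matrix is consumed as a length-20 sequence of
81-dimensional frame vectors. A single bidirectional LSTM layer reads
the sequence in both directions; the two final hidden states feed a
softmax head over the three quality grades. Training minimizes
cross-entropy with the Adam optimizer.

The network, backpropagation through time and Adam are implemented
directly in NumPy, which keeps training fully deterministic for a given
seed. Defaults mirror the study conditions (mini-batch 490, maximum
1 000 epochs); a reduced desk preset is provided for quick experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synth import Label

CLASS_ORDER = (Label.A, Label.B, Label.C)
#: argmax ties resolve toward the worse grade: C beats B beats A
_TIE_PRIORITY = (Label.C, Label.B, Label.A)


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_units: int = 128
    bidirectional: bool = True
    learning_rate: float = 1e-3
    max_epochs: int = 1000
    batch_size: int = 490
    seed: int = 0
    standardize: bool = False
    allow_single_class: bool = False

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1 or self.hidden_units < 1:
            raise ValueError("hidden_units, max_epochs and batch_size must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "ClassifierConfig":
        """Small, fast preset for desk-scale experiments."""
        base = cls(max_epochs=60)
        return replace(base, **overrides)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection:
    """One direction of the LSTM: parameters and cached forward state."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        h = hidden
        s_x = np.sqrt(6.0 / (d_in + 4 * h))
        s_h = np.sqrt(6.0 / (h + 4 * h))
        self.Wx = rng.uniform(-s_x, s_x, (d_in, 4 * h))
        self.Wh = rng.uniform(-s_h, s_h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.h = h

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray):
        """x: (B, T, D) -> final hidden (B, H); caches gates for backward."""
        B, T, _ = x.shape
        h = self.h
        hs = np.zeros((T + 1, B, h))
        cs = np.zeros((T + 1, B, h))
        gates = np.zeros((T, B, 4 * h))
        tanh_c = np.zeros((T, B, h))
        for t in range(T):
            z = x[:, t] @ self.Wx + hs[t] @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            cs[t + 1] = f * cs[t] + i * g
            tanh_c[t] = np.tanh(cs[t + 1])
            hs[t + 1] = o * tanh_c[t]
            gates[t] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, hs, cs, gates, tanh_c)
        return hs[T]

    def backward(self, dh_last: np.ndarray):
        """Gradient of the loss w.r.t. parameters, given d(final hidden)."""
        x, hs, cs, gates, tanh_c = self._cache
        B, T, _ = x.shape
        h = self.h
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh = dh_last.copy()
        dc = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            i, f, g, o = (gates[t][:, k * h : (k + 1) * h] for k in range(4))
            dc = dc + dh * o * (1 - tanh_c[t] ** 2)
            do = dh * tanh_c[t]
            di, df, dg = dc * g, dc * cs[t], dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += hs[t].T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [dWx, dWh, db]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    config: ClassifierConfig
    class_order: tuple = CLASS_ORDER
    training_log: list[float] = field(default_factory=list)
    _fwd: _LSTMDirection | None = None
    _bwd: _LSTMDirection | None = None
    Wo: np.ndarray | None = None
    bo: np.ndarray | None = None
    feature_shape: tuple[int, int] | None = None   # (P, T)
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None
    constant_class: Label | None = None

    def _params(self):
        ps = self._fwd.params() + (self._bwd.params() if self._bwd else [])
        return ps + [self.Wo, self.bo]


def _as_array(features) -> np.ndarray:
    """Accept (n, P, T) arrays or lists of feature matrices / arrays."""
    if isinstance(features, np.ndarray) and features.ndim == 3:
        return features
    rows = [f.values if hasattr(f, "values") else np.asarray(f) for f in features]
    return np.stack(rows)


def _encode(labels) -> np.ndarray:
    lut = {lab: k for k, lab in enumerate(CLASS_ORDER)}
    return np.asarray([lut[Label(l)] for l in labels])


def train(features, labels, config: ClassifierConfig | None = None) -> TrainedModel:
    """Fit the Bi-LSTM on (feature matrix, grade) pairs.

    Feature matrices (P paths x T frames) are transposed to sequences of
    T frame vectors. With ``standardize`` the per-path mean/std of the
    training set is applied (and stored for prediction). Training is a
    pure function of ``config.seed``.
    """
    config = config or ClassifierConfig()
    X = _as_array(features)            # (n, P, T)
    y = _encode(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels differ in length")
    classes = np.unique(y)
    if classes.size < 2:
        if not config.allow_single_class:
            raise ValueError("training set has a single class; set allow_single_class")
        return TrainedModel(
            config,
            training_log=[0.0],
            feature_shape=X.shape[1:],
            constant_class=CLASS_ORDER[int(classes[0])],
        )

    model = TrainedModel(config, feature_shape=X.shape[1:])
    if config.standardize:
        model.norm_mean = X.mean(axis=(0, 2), keepdims=True)
        model.norm_std = X.std(axis=(0, 2), keepdims=True) + 1e-8
        X = (X - model.norm_mean) / model.norm_std

    Xseq = np.ascontiguousarray(X.transpose(0, 2, 1))   # (n, T, P)
    n, T, D = Xseq.shape
    H = config.hidden_units
    rng = np.random.default_rng(config.seed)
    model._fwd = _LSTMDirection(D, H, rng)
    model._bwd = _LSTMDirection(D, H, rng) if config.bidirectional else None
    width = 2 * H if config.bidirectional else H
    s_o = np.sqrt(6.0 / (width + 3))
    model.Wo = rng.uniform(-s_o, s_o, (width, 3))
    model.bo = np.zeros(3)

    opt = _Adam(model._params(), config.learning_rate)
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = _train_batch(model, Xseq[idx], y[idx], opt)
            losses.append(loss * idx.size)
        model.training_log.append(float(np.sum(losses) / n))
    return model


def _train_batch(model: TrainedModel, xb: np.ndarray, yb: np.ndarray, opt: _Adam) -> float:
    B = xb.shape[0]
    h_f = model._fwd.forward(xb)
    parts = [h_f]
    if model._bwd is not None:
        h_b = model._bwd.forward(xb[:, ::-1])
        parts.append(h_b)
    hcat = np.concatenate(parts, axis=1)
    logits = hcat @ model.Wo + model.bo
    logits -= logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    probs = expz / expz.sum(axis=1, keepdims=True)
    loss = float(-np.mean(np.log(probs[np.arange(B), yb] + 1e-300)))

    dlogits = probs.copy()
    dlogits[np.arange(B), yb] -= 1.0
    dlogits /= B
    dWo = hcat.T @ dlogits
    dbo = dlogits.sum(axis=0)
    dhcat = dlogits @ model.Wo.T
    H = model.config.hidden_units
    grads = model._fwd.backward(dhcat[:, :H])
    if model._bwd is not None:
        grads += model._bwd.backward(dhcat[:, H:])
    grads += [dWo, dbo]
    opt.step(model._params(), grads)
    return loss


def predict(model: TrainedModel, features) -> list[tuple[Label, np.ndarray]]:
    """Per-item grade and probability triple (order A, B, C).

    Items are processed independently, so batch composition and order
    cannot change any single item's output. Ties in the argmax resolve
    toward the worse grade.
    """
    X = _as_array(features)
    if model.feature_shape is not None and X.shape[1:] != tuple(model.feature_shape):
        raise ValueError(
            f"feature shape {X.shape[1:]} does not match training shape "
            f"{tuple(model.feature_shape)}"
        )
    if model.constant_class is not None:
        p = np.zeros(3)
        p[CLASS_ORDER.index(model.constant_class)] = 1.0
        return [(model.constant_class, p.copy()) for _ in range(X.shape[0])]
    if model.norm_mean is not None:
        X = (X - model.norm_mean) / model.norm_std
    Xseq = np.ascontiguousarray(X.transpose(0, 2, 1))
    parts = [model._fwd.forward(Xseq)]
    if model._bwd is not None:
        parts.append(model._bwd.forward(Xseq[:, ::-1]))
    logits = np.concatenate(parts, axis=1) @ model.Wo + model.bo
    logits -= logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    probs = expz / expz.sum(axis=1, keepdims=True)
    out = []
    for p in probs:
        best = max(_TIE_PRIORITY, key=lambda lab: p[CLASS_ORDER.index(lab)])
        out.append((best, p))
    return out


def predict_labels(model: TrainedModel, features) -> list[Label]:
    return [lab for lab, _ in predict(model, features)]


def save_model(model: TrainedModel, path) -> None:
    """Write weights as .npz plus a JSON config sidecar (<path>.json)."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    if model.constant_class is None:
        for name, d in (("fwd", model._fwd), ("bwd", model._bwd)):
            if d is None:
                continue
            arrays[f"{name}_Wx"], arrays[f"{name}_Wh"], arrays[f"{name}_b"] = d.params()
        arrays["Wo"], arrays["bo"] = model.Wo, model.bo
        if model.norm_mean is not None:
            arrays["norm_mean"], arrays["norm_std"] = model.norm_mean, model.norm_std
    np.savez(path, **arrays)
    sidecar = {
        "config": dataclasses.asdict(model.config),
        "class_order": [c.value for c in model.class_order],
        "feature_shape": list(model.feature_shape) if model.feature_shape else None,
        "constant_class": model.constant_class.value if model.constant_class else None,
        "training_log": model.training_log,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> TrainedModel:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = ClassifierConfig(**sidecar["config"])
    model = TrainedModel(
        config,
        training_log=sidecar["training_log"],
        feature_shape=tuple(sidecar["feature_shape"]) if sidecar["feature_shape"] else None,
        constant_class=Label(sidecar["constant_class"])
        if sidecar["constant_class"]
        else None,
    )
    if model.constant_class is not None:
        return model
    with np.load(path) as z:
        d_in = z["fwd_Wx"].shape[0]
        rng = np.random.default_rng(0)
        for name in ("fwd", "bwd"):
            if f"{name}_Wx" not in z:
                continue
            direction = _LSTMDirection(d_in, config.hidden_units, rng)
            direction.Wx = z[f"{name}_Wx"]
            direction.Wh = z[f"{name}_Wh"]
            direction.b = z[f"{name}_b"]
            setattr(model, f"_{name}", direction)
        model.Wo, model.bo = z["Wo"], z["bo"]
        if "norm_mean" in z:
            model.norm_mean, model.norm_std = z["norm_mean"], z["norm_std"]
    return model


def kfold_indices(n: int, k: int, seed: int,
                  labels=None, stratified: bool = False) -> list[np.ndarray]:
    """Random partition of range(n) into k folds of near-equal size.

    With ``stratified`` (requires ``labels``) each class is permuted and
    dealt round-robin so class proportions are preserved per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds the dataset size")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    if labels is None:
        raise ValueError("stratified folds need labels")
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for lab in sorted(set(labels), key=str):
        idx = rng.permutation([i for i, l in enumerate(labels) if l == lab])
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def crossvalidate(features, labels, k: int, config: ClassifierConfig | None = None,
                  seed: int = 0, stratified: bool = False):
    """k-fold cross-validation; returns (per-fold reports, mean report).

    Folds are a plain random partition by default (optionally
    stratified); each fold's metrics are computed on held-out data only.
    """
    from .evaluation import confusion, mean_reports, metrics

    config = config or ClassifierConfig()
    X = _as_array(features)
    y = [Label(l) for l in labels]
    folds = kfold_indices(X.shape[0], k, seed, labels=y, stratified=stratified)
    all_idx = np.arange(X.shape[0])
    reports = []
    for fold in folds:
        mask = np.isin(all_idx, fold)
        model = train(X[~mask], [y[i] for i in all_idx[~mask]], config)
        pred = predict_labels(model, X[mask])
        actual = [y[i] for i in all_idx[mask]]
        reports.append(metrics(confusion(actual, pred), strict=False))
    return reports, mean_reports(reports)
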
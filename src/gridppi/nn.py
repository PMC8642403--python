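"""A compact 3D convolutional network for feature-grid classification and
regression, implemented directly on numpy arrays.

The default architecture follows the conv/batch-norm/max-pool pattern used
for interface grids: two convolution blocks (8 then 16 filters, kernel 3,
2x2x2 max pooling, batch normalization) followed by a fully connected layer
of width 84 and a linear output head (2 logits for classification, 1 value
for regression).  Training supports weighted cross-entropy over log-softmax
scores (for heavily imbalanced near-native/wrong labels), plain MSE for
regression, SGD with momentum and weight decay, Adam, and early stopping
that restores the best-validation-loss weights.  All randomness (weight
initialization, batch shuffling) flows from a single seed, so runs are
reproducible bit-for-bit given (seed, data, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "WeightingError",
    "ConfigError",
    "class_weights",
    "train",
    "predict",
    "app1_preset",
    "app2_preset",
    "save_model",
    "load_model",
]


class ConfigError(ValueError):
    pass


class WeightingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv3D:
    """Valid 3D convolution (stride 1) via chunked im2col matmuls.

    Patch matrices are materialized for only a few samples at a time
    (~200 MB bound) so large grids stay within desk-scale memory.
    """

    _CHUNK_BYTES = 2e8

    def __init__(self, in_ch, out_ch, k, rng):
        scale = np.sqrt(2.0 / (in_ch * k ** 3))
        self.W = rng.normal(0.0, scale, (out_ch, in_ch, k, k, k))
        self.b = np.zeros(out_ch)
        self.k = k

    def _col(self, x):
        """(b, P, C*k^3) patch matrix for a sample chunk."""
        k = self.k
        patches = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        b, c, do, dh, dw = patches.shape[:5]
        return (patches.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                       .reshape(b, do * dh * dw, c * k ** 3)), (do, dh, dw)

    def _chunk_size(self, x):
        k = self.k
        c = x.shape[1]
        p = np.prod([s - k + 1 for s in x.shape[2:]])
        return max(1, int(self._CHUNK_BYTES / (c * k ** 3 * p * 8)))

    def forward(self, x, training):
        self._x = x
        n, out_ch = x.shape[0], self.W.shape[0]
        wmat = self.W.reshape(out_ch, -1)
        chunk = self._chunk_size(x)
        y = None
        for s in range(0, n, chunk):
            col, (do, dh, dw) = self._col(x[s:s + chunk])
            if y is None:
                y = np.empty((n, out_ch, do, dh, dw))
            y[s:s + chunk] = (col @ wmat.T).transpose(0, 2, 1).reshape(
                -1, out_ch, do, dh, dw)
        return y + self.b[None, :, None, None, None]

    def backward(self, dy):
        x = self._x
        n, c = x.shape[:2]
        out_ch = self.W.shape[0]
        do, dh, dw = dy.shape[2:]
        k = self.k
        self.db = dy.sum(axis=(0, 2, 3, 4))
        dw_mat = np.zeros((out_ch, c * k ** 3))
        chunk = self._chunk_size(x)
        for s in range(0, n, chunk):
            col, _ = self._col(x[s:s + chunk])
            dy_mat = dy[s:s + chunk].reshape(-1, out_ch, do * dh * dw)
            dw_mat += (dy_mat.transpose(0, 2, 1).reshape(-1, out_ch).T
                       @ col.reshape(-1, c * k ** 3))
        self.dW = dw_mat.reshape(self.W.shape)
        dx = np.zeros_like(x)
        for i, j, l in product(range(k), range(k), range(k)):
            dx[:, :, i:i + do, j:j + dh, l:l + dw] += np.einsum(
                "nodhw,oc->ncdhw", dy, self.W[:, :, i, j, l], optimize=True)
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm3D:
    def __init__(self, n_ch, momentum=0.1, eps=1e-5):
        self.W = np.ones(n_ch)      # gamma
        self.b = np.zeros(n_ch)     # beta
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        sh = (1, -1, 1, 1, 1)
        self._xhat = (x - mean.reshape(sh)) * self._inv_std.reshape(sh)
        return self.W.reshape(sh) * self._xhat + self.b.reshape(sh)

    def backward(self, dy):
        axes = (0, 2, 3, 4)
        sh = (1, -1, 1, 1, 1)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.dW = (dy * self._xhat).sum(axis=axes)
        self.db = dy.sum(axis=axes)
        dxhat = dy * self.W.reshape(sh)
        dx = (self._inv_std.reshape(sh) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(sh)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(sh))
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool3D:
    """2x2x2 max pooling with floor cropping of odd trailing planes."""

    def __init__(self, size=2):
        self.size = size

    def forward(self, x, training):
        s = self.size
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // s, h // s, w // s
        if min(d2, h2, w2) == 0:
            raise ConfigError(
                f"spatial size {(d, h, w)} too small to max-pool; "
                f"use a larger grid or fewer conv blocks")
        self._in_shape = x.shape
        self._crop = (d2 * s, h2 * s, w2 * s)
        xc = x[:, :, :d2 * s, :h2 * s, :w2 * s]
        xr = (xc.reshape(n, c, d2, s, h2, s, w2, s)
                .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                .reshape(n, c, d2, h2, w2, s ** 3))
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        s = self.size
        n, c, d2, h2, w2 = dy.shape
        flat = np.zeros((n, c, d2, h2, w2, s ** 3))
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        dxc = (flat.reshape(n, c, d2, h2, w2, s, s, s)
                   .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                   .reshape(n, c, d2 * s, h2 * s, w2 * s))
        dx = np.zeros(self._in_shape)
        cd, ch, cw = self._crop
        dx[:, :, :cd, :ch, :cw] = dxc
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [("W", self), ("b", self)]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    input_channels: int
    task: str = "classification"              # "classification" | "regression"
    conv_blocks: list = field(default_factory=lambda: [(8, 3, 2), (16, 3, 2)])
    fc_widths: list = field(default_factory=lambda: [84])
    optimizer: str = "sgd"                    # "sgd" | "adam"
    learning_rate: float = 0.0005
    momentum: float = 0.9
    weight_decay: float = 0.001
    batch_size: int = 8
    max_epochs: int = 50
    patience: int = 10
    class_weights: object = "auto"            # (w_neg, w_pos) or "auto"
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")

    @property
    def output_width(self) -> int:
        return 2 if self.task == "classification" else 1


def app1_preset(input_channels: int = 20, **overrides) -> ModelConfig:
    """SGD preset: lr 5e-4, momentum 0.9, weight decay 1e-3, batch 8."""
    cfg = dict(task="classification", optimizer="sgd", learning_rate=0.0005,
               momentum=0.9, weight_decay=0.001, batch_size=8)
    cfg.update(overrides)
    return ModelConfig(input_channels=input_channels, **cfg)


def app2_preset(input_channels: int = 36, **overrides) -> ModelConfig:
    """Adam preset: lr 1e-3, batch 100, automatic class weights."""
    cfg = dict(task="classification", optimizer="adam", learning_rate=0.001,
               momentum=0.0, weight_decay=0.0, batch_size=100,
               class_weights="auto")
    cfg.update(overrides)
    return ModelConfig(input_channels=input_channels, **cfg)


def class_weights(labels) -> tuple[float, float]:
    """Loss weights proportional to the opposite class size.

    w_negative = fraction of positives, w_positive = fraction of negatives,
    so expected penalties on the two classes balance; weights sum to 1.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise WeightingError("both classes must be present to derive weights")
    return (n_pos / n, n_neg / n)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class _Network:
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.layers = []
        in_ch = config.input_channels
        for filters, kernel, pool in config.conv_blocks:
            self.layers.append(_Conv3D(in_ch, filters, kernel, rng))
            self.layers.append(_BatchNorm3D(filters))
            self.layers.append(_ReLU())
            if pool and pool > 1:
                self.layers.append(_MaxPool3D(pool))
            in_ch = filters
        self.layers.append(_Flatten())
        self._fc_built = False

    def _build_fc(self, n_flat: int):
        width_in = n_flat
        for w in self.config.fc_widths:
            self.layers.append(_Linear(width_in, w, self.rng))
            self.layers.append(_ReLU())
            width_in = w
        self.layers.append(_Linear(width_in, self.config.output_width, self.rng))
        self._fc_built = True

    def forward(self, x, training=False):
        if getattr(self, "_spatial_shape", None) is not None:
            if tuple(x.shape[2:]) != self._spatial_shape:
                raise ConfigError(
                    f"grid shape {tuple(x.shape[2:])} does not match the shape "
                    f"this network was built for ({self._spatial_shape})")
        else:
            self._spatial_shape = tuple(x.shape[2:])
        for layer in self.layers:
            x = layer.forward(x, training)
            if isinstance(layer, _Flatten) and not self._fc_built:
                idx = len(self.layers)
                self._build_fc(x.shape[1])
                for extra in self.layers[idx:]:
                    x = extra.forward(x, training)
                break
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for li, layer in enumerate(self.layers):
            for name, owner in layer.params():
                out.append((f"layer{li}_{name}", owner, name))
        return out

    def get_state(self):
        state = {key: getattr(owner, name).copy()
                 for key, owner, name in self.parameters()}
        for li, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm3D):
                state[f"layer{li}_running_mean"] = layer.running_mean.copy()
                state[f"layer{li}_running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state):
        for key, owner, name in self.parameters():
            getattr(owner, name)[...] = state[key]
        for li, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm3D):
                layer.running_mean[...] = state[f"layer{li}_running_mean"]
                layer.running_var[...] = state[f"layer{li}_running_var"]


def _log_softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _classification_loss(logits, y, weights):
    """Weighted NLL over log-softmax scores; returns (loss, dlogits)."""
    n = len(y)
    logp = _log_softmax(logits)
    w = np.where(y == 1, weights[1], weights[0]).astype(float)
    wsum = w.sum()
    if wsum == 0:
        return 0.0, np.zeros_like(logits)
    loss = float(-(w * logp[np.arange(n), y]).sum() / wsum)
    onehot = np.zeros_like(logits)
    onehot[np.arange(n), y] = 1.0
    dlogits = (np.exp(logp) - onehot) * (w / wsum)[:, None]
    return loss, dlogits


def _regression_loss(pred, y):
    diff = pred[:, 0] - y
    loss = float((diff ** 2).mean())
    dpred = np.zeros_like(pred)
    dpred[:, 0] = 2.0 * diff / len(y)
    return loss, dpred


class _SGD:
    def __init__(self, net, lr, momentum, weight_decay):
        self.net, self.lr, self.mu, self.wd = net, lr, momentum, weight_decay
        self.v = {k: np.zeros_like(getattr(o, n))
                  for k, o, n in net.parameters()}

    def step(self):
        for key, owner, name in self.net.parameters():
            p = getattr(owner, name)
            g = getattr(owner, "d" + name) + self.wd * p
            self.v[key] = self.mu * self.v[key] - self.lr * g
            p += self.v[key]


class _Adam:
    def __init__(self, net, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(getattr(o, n)) for k, o, n in net.parameters()}
        self.v = {k: np.zeros_like(getattr(o, n)) for k, o, n in net.parameters()}
        self.t = 0

    def step(self):
        self.t += 1
        for key, owner, name in self.net.parameters():
            p = getattr(owner, name)
            g = getattr(owner, "d" + name)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    network: _Network
    config: ModelConfig
    history: dict
    best_epoch: int


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def _materialize(stream):
    """Accept (X, y) arrays or an iterable of read_selection tuples."""
    if isinstance(stream, tuple) and len(stream) == 2:
        X, y = stream
        n = len(X)
        return np.asarray(X, dtype=float), np.asarray(y), [str(i) for i in range(n)]
    ids, xs, ys = [], [], []
    for model_id, _case_id, tensor, target in stream:
        ids.append(model_id)
        xs.append(tensor)
        ys.append(target)
    if not xs:
        raise ConfigError("empty dataset stream")
    return np.asarray(xs, dtype=float), np.asarray(ys), ids


def train(dataset_stream, config: ModelConfig, validation_stream=None,
          val_fraction: float = 0.2, history_path=None) -> TrainedModel:
    """Train the CNN with early stopping on the validation loss.

    ``dataset_stream`` is either an ``(X, y)`` pair or an iterable of
    ``(model_id, case_id, tensor, target)`` tuples as produced by
    :func:`gridppi.store.read_selection`.  Without an explicit validation
    stream, a seeded tail fraction of the training data is held out.
    The best-validation-loss weights are restored before returning.
    """
    X, y, _ = _materialize(dataset_stream)
    if X.ndim != 5 or X.shape[1] != config.input_channels:
        raise ConfigError(
            f"data shape {X.shape} does not match input_channels="
            f"{config.input_channels}")
    rng = np.random.default_rng(config.seed)

    if validation_stream is not None:
        Xv, yv, _ = _materialize(validation_stream)
    else:
        n_val = int(round(val_fraction * len(X)))
        if n_val == 0:
            raise ConfigError("validation set is empty but early stopping is on")
        perm = rng.permutation(len(X))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xv, yv = X[val_idx], y[val_idx]
        X, y = X[train_idx], y[train_idx]
    if len(Xv) == 0:
        raise ConfigError("validation set is empty but early stopping is on")

    classification = config.task == "classification"
    if classification:
        y = y.astype(int)
        yv = yv.astype(int)
        weights = (class_weights(y) if config.class_weights == "auto"
                   else tuple(config.class_weights))
    net = _Network(config, rng)
    net.forward(X[:1], training=False)  # build FC layers for this grid shape
    opt = (_SGD(net, config.learning_rate, config.momentum, config.weight_decay)
           if config.optimizer == "sgd" else _Adam(net, config.learning_rate))

    history = {"train_loss": [], "val_loss": [], "val_metric": []}
    best_loss, best_epoch, best_state = np.inf, -1, net.get_state()
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start:start + config.batch_size]
            out = net.forward(X[idx], training=True)
            if classification:
                loss, dout = _classification_loss(out, y[idx], weights)
            else:
                loss, dout = _regression_loss(out, y[idx])
            net.backward(dout)
            opt.step()
            losses.append(loss)
        out_v = net.forward(Xv, training=False)
        if classification:
            val_loss, _ = _classification_loss(out_v, yv, weights)
            val_metric = float((out_v.argmax(axis=1) == yv).mean())
        else:
            val_loss, _ = _regression_loss(out_v, yv)
            val_metric = val_loss
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        history["val_metric"].append(val_metric)
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    net.set_state(best_state)

    if history_path is not None:
        import h5py
        with h5py.File(history_path, "w") as fh:
            hist = fh.create_group("history")
            for k, v in history.items():
                hist.create_dataset(k, data=np.asarray(v))
            fh.attrs["best_epoch"] = best_epoch
    return TrainedModel(network=net, config=config, history=history,
                        best_epoch=best_epoch)


def predict(model: TrainedModel, dataset_stream):
    """Apply a trained model; returns ``{model_id: scores}``.

    Classification yields the two log-softmax scores per entry; the first
    (wrong-class) score is the ranking score — lower means the model is
    predicted to be of higher quality.  Regression yields one value.
    """
    X, _, ids = _materialize_for_predict(dataset_stream)
    if X.shape[1] != model.config.input_channels:
        raise ConfigError(
            f"channel count {X.shape[1]} does not match the trained model "
            f"({model.config.input_channels})")
    out = model.network.forward(X, training=False)
    result = {}
    for i, model_id in enumerate(ids):
        if model.config.task == "classification":
            result[model_id] = _log_softmax(out[i:i + 1])[0]
        else:
            result[model_id] = float(out[i, 0])
    return result


def _materialize_for_predict(stream):
    if isinstance(stream, tuple) and len(stream) == 2:
        X, y = stream
        return np.asarray(X, dtype=float), y, [str(i) for i in range(len(X))]
    if isinstance(stream, np.ndarray):
        return stream.astype(float), None, [str(i) for i in range(len(stream))]
    ids, xs = [], []
    for model_id, _case, tensor, _target in stream:
        ids.append(model_id)
        xs.append(tensor)
    if not xs:
        raise ConfigError("empty dataset stream")
    return np.asarray(xs, dtype=float), None, ids


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    state = model.network.get_state()
    cfg = asdict(model.config)
    spatial = getattr(model.network, "_spatial_shape", None) or (0, 0, 0)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8),
        __best_epoch__=np.array(model.best_epoch),
        __spatial__=np.array(spatial), **state)


def load_model(path) -> TrainedModel:
    data = np.load(path)
    cfg = json.loads(bytes(data["__config__"]).decode())
    cfg["conv_blocks"] = [tuple(b) for b in cfg["conv_blocks"]]
    if isinstance(cfg["class_weights"], list):
        cfg["class_weights"] = tuple(cfg["class_weights"])
    config = ModelConfig(**cfg)
    net = _Network(config, np.random.default_rng(config.seed))
    # infer FC sizes from the stored state
    state = {k: data[k] for k in data.files if not k.startswith("__")}
    fc_keys = sorted((k for k in state
                      if k.startswith("layer") and k.endswith("_W")
                      and state[k].ndim == 2),
                     key=lambda k: int(k[len("layer"):-len("_W")]))
    width_in = state[fc_keys[0]].shape[1] if fc_keys else None
    if width_in is not None and not net._fc_built:
        net._build_fc(width_in)
    net.set_state(state)
    if "__spatial__" in data.files and int(data["__spatial__"][0]) > 0:
        net._spatial_shape = tuple(int(v) for v in data["__spatial__"])
    return TrainedModel(network=net, config=config, history={},
                        best_epoch=int(data["__best_epoch__"]))
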
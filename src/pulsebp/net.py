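"""ABP-net: a hybrid-feature 1D convolutional network for SBP/DBP regression.

The model fuses two kinds of per-beat input: the *formal* feature — the PPG
cycle waveform, resampled to a fixed length — and the *numerical* features —
the two pulse transit times (R peak to main-wave peak, R peak to
repetition-wave peak).  A small 1D convolutional branch (conv -> batch norm
-> ReLU -> max pool, three blocks, one residual connection) summarizes the
waveform, a global average (AVG) turns the final feature maps into a vector,
the z-scored transit times are concatenated, and a fully connected stack
emits the two pressures.

Everything — convolution, batch normalization, pooling, the dense layers and
their gradients — is implemented here directly from the operator equations,
in float64 numpy.  Convolutions are valid-mode (no padding):

    v_j(x) = sum_i sum_{p=0}^{K-1} k_{i,j}(p) * u_i(x*S + p) + b_j

Batch normalization uses the biased variance (divide by n) and learned
per-map scale/shift; at inference it applies running averages of the batch
statistics.  Training is plain (mini-)batch gradient descent on the mean
squared error, with no momentum or adaptive step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TrainConfig",
    "ABPNet",
    "conv1d_forward",
    "batch_norm_forward",
    "relu",
    "pool",
    "global_average",
    "mse_loss",
    "train",
    "predict",
    "save_model",
    "load_model",
    "resample_cycles",
]


# ---------------------------------------------------------------------------
# operator primitives (forward definitions; the layer classes add gradients)
# ---------------------------------------------------------------------------

def conv1d_forward(u, weights, biases, stride: int = 1):
    """Valid-mode 1D convolution over named feature maps.

    ``u`` has shape ``(..., N, L)``, ``weights`` ``(N, M, K)`` (one kernel
    per input/output map pair), ``biases`` ``(M,)``.  Output length is
    ``floor((L - K) / stride) + 1``.
    """
    u = np.asarray(u, dtype=float)
    weights = np.asarray(weights, dtype=float)
    biases = np.asarray(biases, dtype=float)
    n, m, k = weights.shape
    if u.shape[-2] != n:
        raise ValueError(f"expected {n} input maps, got {u.shape[-2]}")
    if u.shape[-1] < k:
        raise ValueError(f"input length {u.shape[-1]} shorter than kernel {k}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    win = sliding_window_view(u, k, axis=-1)[..., ::stride, :]  # (..., N, Lout, K)
    return np.einsum("...nlk,nmk->...ml", win, weights) + biases[:, None]


def batch_norm_forward(batch, gamma=1.0, beta=0.0, eps: float = 1e-5):
    """Normalize a batch to zero mean, unit (biased) variance, then scale/shift.

    ``batch`` is the set of values normalized together (a 1-D array; for a
    convolutional feature map, all positions of that map across the batch).
    """
    x = np.asarray(batch, dtype=float)
    if x.size < 2:
        raise ValueError("batch normalization needs at least 2 values")
    mu = x.mean()
    var = x.var()  # biased: divide by n
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def relu(x):
    """Rectified linear unit, max(0, x) elementwise."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def pool(u, window: int, stride: int, mode: str = "max"):
    """Max or mean pooling of feature maps over the last axis."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] < window:
        raise ValueError(f"input length {u.shape[-1]} shorter than window {window}")
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    win = sliding_window_view(u, window, axis=-1)[..., ::stride, :]
    if mode == "max":
        return win.max(axis=-1)
    if mode == "mean":
        return win.mean(axis=-1)
    raise ValueError(f"unknown pooling mode {mode!r}")


def global_average(maps):
    """AVG bridge: one scalar per feature map (its mean over positions)."""
    return np.asarray(maps, dtype=float).mean(axis=-1)


def mse_loss(y, y_hat):
    """Mean squared error (1/n) * sum (y_i - y_hat_i)^2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


# ---------------------------------------------------------------------------
# layers with gradients
# ---------------------------------------------------------------------------

class _Conv1D:
    def __init__(self, n_in, n_out, kernel, stride, rng):
        bound = 1.0 / np.sqrt(n_in * kernel)
        self.w = rng.uniform(-bound, bound, size=(n_in, n_out, kernel))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.stride = stride
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return conv1d_forward(x, self.w, self.b, self.stride)

    def backward(self, dv):
        n, m, k = self.w.shape
        s = self.stride
        win = sliding_window_view(self._x, k, axis=-1)[..., ::s, :]
        self.dw[...] = np.einsum("bnlk,bml->nmk", win, dv)
        self.db[...] = dv.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        l_out = dv.shape[-1]
        starts = s * np.arange(l_out)
        dwin = np.einsum("bml,nmk->bnlk", dv, self.w)
        for p in range(k):
            dx[:, :, starts + p] += dwin[..., p]
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _BatchNorm:
    """Per-feature-map batch normalization for (B, C, L) or (B, C) input."""

    def __init__(self, n_features, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)

    @staticmethod
    def _axes(x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, x):
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    def forward(self, x, training):
        axes, shp = self._axes(x), self._shape(x)
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch normalization requires batch size >= 2")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)  # biased
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shp)) * ivstd.reshape(shp)
        self._cache = (xhat, ivstd, x.shape)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, dy):
        xhat, ivstd, shape = self._cache
        axes, shp = self._axes(dy), self._shape(dy)
        n = np.prod([shape[a] for a in axes])
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        g = self.gamma.reshape(shp) * ivstd.reshape(shp)
        dy_sum = dy.sum(axis=axes).reshape(shp)
        dyxhat_sum = (dy * xhat).sum(axis=axes).reshape(shp)
        return g * (dy - dy_sum / n - xhat * dyxhat_sum / n)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool:
    def __init__(self, window, stride):
        self.window = window
        self.stride = stride

    def forward(self, x):
        win = sliding_window_view(x, self.window, axis=-1)[..., ::self.stride, :]
        self._argmax = win.argmax(axis=-1)
        self._xshape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        b, c, l_out = dy.shape
        dx = np.zeros(self._xshape)
        pos = self.stride * np.arange(l_out)[None, None, :] + self._argmax
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dx, (bi, ci, pos), dy)
        return dx

    def params(self):
        return []


class _GlobalAvg:
    def forward(self, x):
        self._l = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dy):
        return np.repeat(dy[..., None], self._l, axis=-1) / self._l

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        bound = 1.0 / np.sqrt(n_in)
        self.w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


# ---------------------------------------------------------------------------
# the assembled network
# ---------------------------------------------------------------------------

class ABPNet:
    """Hybrid-feature network: PPG waveform branch + transit-time features.

    Architecture (defaults; all sizes configurable for small test models)::

        ppg (B, input_len)
          -> Conv(1->c1, K) -> BN -> ReLU -> MaxPool(2,2)      # block 1
          -> Conv(c1->c2, K) -> BN -> ReLU  --+                # block 2
             1x1 Conv skip (center-cropped) --+ (residual add)
          -> MaxPool(2,2)
          -> Conv(c2->c3, K) -> BN -> ReLU -> MaxPool(2,2)     # block 3
          -> AVG -> (B, c3)
        concat z-scored [ptt_p, ptt_d]      -> (B, c3 + 2)
          -> FC -> ReLU -> FC               -> (B, 2) = (SBP, DBP)

    All convolutions are valid-mode, so the residual skip is center-cropped
    to the branch length before the add.  The model predicts z-scored
    pressures internally; :func:`predict` returns mmHg.
    """

    def __init__(
        self,
        input_len: int = 128,
        channels: tuple[int, int, int] = (8, 16, 32),
        kernel: int = 7,
        fc_hidden: int = 32,
        n_ptt: int = 2,
        use_residual: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.input_len = input_len
        self.use_residual = use_residual
        self.n_ptt = n_ptt

        self.conv1 = _Conv1D(1, c1, kernel, 1, rng)
        self.bn1 = _BatchNorm(c1)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool(2, 2)

        self.conv2 = _Conv1D(c1, c2, kernel, 1, rng)
        self.bn2 = _BatchNorm(c2)
        self.relu2 = _ReLU()
        self.skip = _Conv1D(c1, c2, 1, 1, rng)  # 1x1 projection for the residual
        self.pool2 = _MaxPool(2, 2)

        self.conv3 = _Conv1D(c2, c3, kernel, 1, rng)
        self.bn3 = _BatchNorm(c3)
        self.relu3 = _ReLU()
        self.pool3 = _MaxPool(2, 2)

        self.gap = _GlobalAvg()
        self.fc1 = _Dense(c3 + n_ptt, fc_hidden, rng)
        self.relu4 = _ReLU()
        self.fc2 = _Dense(fc_hidden, 2, rng)

        # feature/target normalization statistics, set by train()
        self.ptt_mean = np.zeros(n_ptt)
        self.ptt_std = np.ones(n_ptt)
        self.y_mean = np.zeros(2)
        self.y_std = np.ones(2)

        # sanity-check the layer geometry at build time
        L = input_len - kernel + 1
        L = (L - 2) // 2 + 1
        L2 = L - kernel + 1
        if L2 < 1:
            raise ValueError("input_len too short for this kernel/depth")
        self._crop = (L - L2) // 2
        if self._crop < 0:
            raise ValueError("residual skip cannot be cropped to branch length")
        L = (L2 - 2) // 2 + 1
        L = L - kernel + 1
        if L < 2:
            raise ValueError("input_len too short for this kernel/depth")

    # -- forward / backward -------------------------------------------------

    def forward(self, ppg, ptt, training: bool = False):
        ppg = np.asarray(ppg, dtype=float)
        ptt = np.asarray(ptt, dtype=float)
        if ppg.ndim == 1:
            ppg = ppg[None, :]
        if ptt.ndim == 1:
            ptt = ptt[None, :]
        if ppg.shape[1] != self.input_len:
            raise ValueError(
                f"PPG input length {ppg.shape[1]} != model input_len {self.input_len}"
            )
        x = ppg[:, None, :]
        h = self.pool1.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x), training)))
        branch = self.relu2.forward(self.bn2.forward(self.conv2.forward(h), training))
        if self.use_residual:
            s = self.skip.forward(h)
            c = self._crop
            self._skip_len = s.shape[-1]
            branch = branch + s[:, :, c : c + branch.shape[-1]]
        h = self.pool2.forward(branch)
        h = self.pool3.forward(self.relu3.forward(self.bn3.forward(self.conv3.forward(h), training)))
        g = self.gap.forward(h)
        zptt = (ptt - self.ptt_mean) / self.ptt_std
        self._z = np.concatenate([g, zptt], axis=1)
        out = self.fc2.forward(self.relu4.forward(self.fc1.forward(self._z)))
        return out

    def backward(self, dout):
        dz = self.fc1.backward(self.relu4.backward(self.fc2.backward(dout)))
        c3 = dz.shape[1] - self.n_ptt
        dg = dz[:, :c3]
        dh = self.gap.backward(dg)
        dh = self.conv3.backward(self.bn3.backward(self.relu3.backward(self.pool3.backward(dh))))
        dbranch = self.pool2.backward(dh)
        dskip_in = 0.0
        if self.use_residual:
            dskip = np.zeros((dbranch.shape[0], dbranch.shape[1], self._skip_len))
            c = self._crop
            dskip[:, :, c : c + dbranch.shape[-1]] = dbranch
            dskip_in = self.skip.backward(dskip)
        dh1 = self.conv2.backward(self.bn2.backward(self.relu2.backward(dbranch)))
        dh1 = dh1 + dskip_in
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.pool1.backward(dh1))))
        return dx

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3,
               self.fc1, self.fc2]
        if self.use_residual:
            out.insert(4, self.skip)
        return out

    def parameters(self):
        """All (value, gradient) array pairs; arrays are updated in place."""
        pairs = []
        for layer in self.layers():
            pairs.extend(layer.params())
        return pairs


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Plain batch-gradient-descent settings.

    ``batch_size=None`` means full batch.  The loss is the summed MSE of the
    z-scored SBP and DBP outputs; the recorded history is in mmHg^2.
    """

    learning_rate: float = 0.05
    n_epochs: int = 60
    batch_size: int | None = 32
    val_fraction: float = 0.15
    seed: int = 0

    def validate(self):
        if self.batch_size is not None and self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch norm needs a statistic)")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def train(model: ABPNet, ppg, ptt, y, config: TrainConfig | None = None):
    """Fit ABP-net by mini-batch gradient descent on the MSE.

    Parameters
    ----------
    model
        Freshly built (or warm) :class:`ABPNet`; updated in place.
    ppg, ptt, y
        Arrays of shape (n, input_len), (n, 2) and (n, 2); ``y`` columns are
        (SBP, DBP) in mmHg.
    config
        :class:`TrainConfig`; identical (model seed, data, config) gives an
        identical parameter trajectory.

    Returns
    -------
    history : dict with per-epoch ``train_mse`` and ``val_mse`` (mmHg^2).
    """
    config = config or TrainConfig()
    config.validate()
    ppg = np.asarray(ppg, dtype=float)
    ptt = np.asarray(ptt, dtype=float)
    y = np.asarray(y, dtype=float)
    n = ppg.shape[0]
    bs = config.batch_size or n
    if n < 2 * bs and config.batch_size is not None:
        raise ValueError(f"need at least {2 * bs} examples, got {n}")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    model.ptt_mean = ptt[tr_idx].mean(axis=0)
    model.ptt_std = np.where(ptt[tr_idx].std(axis=0) > 0, ptt[tr_idx].std(axis=0), 1.0)
    model.y_mean = y[tr_idx].mean(axis=0)
    model.y_std = np.where(y[tr_idx].std(axis=0) > 0, y[tr_idx].std(axis=0), 1.0)
    yz = (y - model.y_mean) / model.y_std

    history = {"train_mse": [], "val_mse": []}
    scale2 = model.y_std**2  # z-scored MSE -> mmHg^2 per output
    for epoch in range(config.n_epochs):
        order = tr_idx[rng.permutation(tr_idx.size)]
        se = np.zeros(2)
        n_seen = 0
        for start in range(0, order.size, bs):
            idx = order[start : start + bs]
            if idx.size < 2:
                continue  # a trailing singleton cannot be batch-normalized
            out = model.forward(ppg[idx], ptt[idx], training=True)
            err = out - yz[idx]
            loss = np.mean(err**2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            # d/d out of mean over batch and both outputs
            model.backward(2.0 * err / err.size)
            for value, grad in model.parameters():
                value -= config.learning_rate * grad
            se += (err**2).sum(axis=0) * scale2
            n_seen += idx.size
        history["train_mse"].append(float(se.sum() / (2 * n_seen)))
        if n_val:
            val_out = model.forward(ppg[val_idx], ptt[val_idx], training=False)
            verr = (val_out - yz[val_idx]) ** 2 * scale2
            history["val_mse"].append(float(verr.mean()))
        else:
            history["val_mse"].append(float("nan"))
    return history


def predict(model: ABPNet, ppg, ptt):
    """Per-cycle (SBP, DBP) estimates in mmHg, batch order preserved."""
    out = model.forward(ppg, ptt, training=False)
    return out * model.y_std + model.y_mean


def resample_cycles(cycles, input_len: int = 128):
    """Network inputs from cardiac cycles.

    Each cycle's PPG segment is linearly resampled to ``input_len`` samples
    and min-max normalized (shape is kept, per-beat gain discarded).
    """
    out = np.empty((len(cycles), input_len))
    for i, cyc in enumerate(cycles):
        y = np.asarray(cyc.ppg_segment, dtype=float)
        src = np.linspace(0.0, 1.0, y.size)
        dst = np.linspace(0.0, 1.0, input_len)
        r = np.interp(dst, src, y)
        lo, hi = r.min(), r.max()
        out[i] = (r - lo) / (hi - lo) if hi > lo else 0.0
    return out


# ---------------------------------------------------------------------------
# serialization: one array container + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: ABPNet, path: str) -> None:
    """Write parameters (.npz) plus a JSON sidecar with the model spec."""
    arrays = {}
    for i, layer in enumerate(model.layers()):
        for j, (value, _) in enumerate(layer.params()):
            arrays[f"p{i}_{j}"] = value
        if isinstance(layer, _BatchNorm):
            arrays[f"rm{i}"] = layer.running_mean
            arrays[f"rv{i}"] = layer.running_var
    arrays["ptt_mean"] = model.ptt_mean
    arrays["ptt_std"] = model.ptt_std
    arrays["y_mean"] = model.y_mean
    arrays["y_std"] = model.y_std
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    spec = {
        "input_len": model.input_len,
        "channels": [model.conv1.w.shape[1], model.conv2.w.shape[1], model.conv3.w.shape[1]],
        "kernel": model.conv1.w.shape[2],
        "fc_hidden": model.fc1.w.shape[1],
        "n_ptt": model.n_ptt,
        "use_residual": model.use_residual,
    }
    sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(spec, fh, indent=1)


def load_model(path: str) -> ABPNet:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        spec = json.load(fh)
    spec["channels"] = tuple(spec["channels"])
    model = ABPNet(**spec)
    data = np.load(base + ".npz")
    for i, layer in enumerate(model.layers()):
        for j, (value, _) in enumerate(layer.params()):
            value[...] = data[f"p{i}_{j}"]
        if isinstance(layer, _BatchNorm):
            layer.running_mean = data[f"rm{i}"]
            layer.running_var = data[f"rv{i}"]
    model.ptt_mean = data["ptt_mean"]
    model.ptt_std = data["ptt_std"]
    model.y_mean = data["y_mean"]
    model.y_std = data["y_std"]
    return model
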
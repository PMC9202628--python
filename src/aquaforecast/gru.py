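"""Gated recurrent unit forecaster (numpy implementation).

A GRU cell maintains a hidden state h_t updated through two gates:

    z_t = sigmoid(W_zx x_t + W_zh h_{t-1} + b_z)      (update gate)
    r_t = sigmoid(W_rx x_t + W_rh h_{t-1} + b_r)      (reset gate)
    h~_t = tanh(W_xh x_t + W_hr (r_t . h_{t-1}) + b_h)
    h_t = z_t . h~_t + (1 - z_t) . h_{t-1}

(. is the elementwise product; note the update gate weights the *candidate*
state, so z -> 0 copies the previous state through).  The forecaster stacks
two GRU layers over a length-T window of past samples and applies a linear
head to the final second-layer state, producing one next-step prediction.

Training minimizes mean squared error with mini-batch Adam and full
backpropagation through time, gradient-norm clipping at 5, fan-in-scaled
uniform weight initialization, and is fully deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .timeseries import ScalingTransform, WindowedDataset

__all__ = [
    "GRUHyperparams",
    "LayerWeights",
    "GRUWeights",
    "gru_cell_forward",
    "forward_sequence",
    "init_weights",
    "train_gru",
    "predict",
    "save_weights",
    "load_weights",
]

GRAD_CLIP_NORM = 5.0


@dataclass(frozen=True)
class GRUHyperparams:
    """Trainable-model settings: the six quantities the tuner searches."""

    learning_rate: float = 1e-2
    epochs: int = 30
    hidden1: int = 16
    hidden2: int = 16
    batch_size: int = 32
    timesteps: int = 12

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("epochs", "hidden1", "hidden2", "batch_size", "timesteps"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= (0 if name == "epochs" else 1)):
                raise ValueError(f"{name} must be a positive integer (epochs may be 0)")


@dataclass
class LayerWeights:
    """One GRU layer: rows index hidden units, columns the inputs."""

    W_z: np.ndarray  # (h, in)
    U_z: np.ndarray  # (h, h)
    b_z: np.ndarray  # (h,)
    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray
    W_h: np.ndarray
    U_h: np.ndarray
    b_h: np.ndarray

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in
                ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")}


@dataclass
class GRUWeights:
    """Two stacked GRU layers plus a scalar linear output head."""

    layer1: LayerWeights
    layer2: LayerWeights
    w_out: np.ndarray  # (h2,)
    b_out: float

    @property
    def hidden_sizes(self) -> tuple[int, int]:
        return self.layer1.W_z.shape[0], self.layer2.W_z.shape[0]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def gru_cell_forward(x_t: np.ndarray, h_prev: np.ndarray, weights: LayerWeights
                     ) -> np.ndarray:
    """Single-step GRU state update; supports (in,) or batched (B, in) input."""
    z = _sigmoid(x_t @ weights.W_z.T + h_prev @ weights.U_z.T + weights.b_z)
    r = _sigmoid(x_t @ weights.W_r.T + h_prev @ weights.U_r.T + weights.b_r)
    h_cand = np.tanh(x_t @ weights.W_h.T + (r * h_prev) @ weights.U_h.T + weights.b_h)
    return z * h_cand + (1.0 - z) * h_prev


def forward_sequence(window: np.ndarray, weights: GRUWeights) -> float | np.ndarray:
    """Run both layers over a window (T,) or batch (B, T); linear head on h2_T."""
    w = np.atleast_2d(np.asarray(window, float))
    batch, T = w.shape
    h1, h2 = weights.hidden_sizes
    s1 = np.zeros((batch, h1))
    s2 = np.zeros((batch, h2))
    for t in range(T):
        s1 = gru_cell_forward(w[:, t:t + 1], s1, weights.layer1)
        s2 = gru_cell_forward(s1, s2, weights.layer2)
    out = s2 @ weights.w_out + weights.b_out
    return float(out[0]) if np.asarray(window).ndim == 1 else out


def init_weights(hp: GRUHyperparams, rng: np.random.Generator) -> GRUWeights:
    """Uniform(+-1/sqrt(fan_in)) weights, zero biases."""
    def layer(n_in: int, n_h: int) -> LayerWeights:
        def mat(rows: int, cols: int) -> np.ndarray:
            bound = 1.0 / np.sqrt(cols)
            return rng.uniform(-bound, bound, size=(rows, cols))
        return LayerWeights(
            W_z=mat(n_h, n_in), U_z=mat(n_h, n_h), b_z=np.zeros(n_h),
            W_r=mat(n_h, n_in), U_r=mat(n_h, n_h), b_r=np.zeros(n_h),
            W_h=mat(n_h, n_in), U_h=mat(n_h, n_h), b_h=np.zeros(n_h),
        )
    l1 = layer(1, hp.hidden1)
    l2 = layer(hp.hidden1, hp.hidden2)
    bound = 1.0 / np.sqrt(hp.hidden2)
    return GRUWeights(layer1=l1, layer2=l2,
                      w_out=rng.uniform(-bound, bound, size=hp.hidden2), b_out=0.0)


# ---------------------------------------------------------------------------
# BPTT
# ---------------------------------------------------------------------------

def _layer_forward_cache(x_seq: list[np.ndarray], w: LayerWeights
                         ) -> tuple[list[np.ndarray], list[dict]]:
    """Forward a layer over a T-step batched sequence, caching gate values."""
    batch = x_seq[0].shape[0]
    h = np.zeros((batch, w.W_z.shape[0]))
    states = [h]
    cache = []
    for x_t in x_seq:
        z = _sigmoid(x_t @ w.W_z.T + h @ w.U_z.T + w.b_z)
        r = _sigmoid(x_t @ w.W_r.T + h @ w.U_r.T + w.b_r)
        rh = r * h
        c = np.tanh(x_t @ w.W_h.T + rh @ w.U_h.T + w.b_h)
        h_new = z * c + (1.0 - z) * h
        cache.append({"x": x_t, "h_prev": h, "z": z, "r": r, "rh": rh, "c": c})
        h = h_new
        states.append(h)
    return states, cache


def _layer_backward(dh_ext: list[np.ndarray], cache: list[dict], w: LayerWeights
                    ) -> tuple[dict[str, np.ndarray], list[np.ndarray]]:
    """BPTT through one layer.

    dh_ext[t] is the gradient arriving at h_t from above (head or next
    layer); returns parameter gradients and the per-step gradients w.r.t.
    the layer inputs.
    """
    grads = {k: np.zeros_like(v) for k, v in w.arrays().items()}
    T = len(cache)
    dh_next = np.zeros_like(dh_ext[-1])
    dx_seq: list[np.ndarray] = [None] * T  # type: ignore[list-item]
    for t in range(T - 1, -1, -1):
        cc = cache[t]
        dh = dh_ext[t] + dh_next
        z, r, c, h_prev, x_t = cc["z"], cc["r"], cc["c"], cc["h_prev"], cc["x"]
        dz = dh * (c - h_prev) * z * (1.0 - z)
        dc = dh * z * (1.0 - c ** 2)
        dh_prev = dh * (1.0 - z)
        # candidate path
        grads["W_h"] += dc.T @ x_t
        grads["U_h"] += dc.T @ cc["rh"]
        grads["b_h"] += dc.sum(axis=0)
        drh = dc @ w.U_h
        dr = drh * h_prev * r * (1.0 - r)
        dh_prev += drh * r
        # gate paths
        grads["W_z"] += dz.T @ x_t
        grads["U_z"] += dz.T @ h_prev
        grads["b_z"] += dz.sum(axis=0)
        grads["W_r"] += dr.T @ x_t
        grads["U_r"] += dr.T @ h_prev
        grads["b_r"] += dr.sum(axis=0)
        dh_prev += dz @ w.U_z + dr @ w.U_r
        dx_seq[t] = dc @ w.W_h + dz @ w.W_z + dr @ w.W_r
        dh_next = dh_prev
    return grads, dx_seq


def _batch_loss_and_grads(windows: np.ndarray, targets: np.ndarray, w: GRUWeights
                          ) -> tuple[float, dict]:
    batch, T = windows.shape
    x_seq = [windows[:, t:t + 1] for t in range(T)]
    s1, cache1 = _layer_forward_cache(x_seq, w.layer1)
    s2, cache2 = _layer_forward_cache(s1[1:], w.layer2)
    pred = s2[-1] @ w.w_out + w.b_out
    err = pred - targets
    loss = float(np.mean(err ** 2))

    dpred = (2.0 / batch) * err                       # dL/dpred, (B,)
    d_wout = s2[-1].T @ dpred
    d_bout = float(dpred.sum())
    dh2 = [np.zeros_like(s2[-1]) for _ in range(T)]
    dh2[-1] = np.outer(dpred, w.w_out)
    g2, dx2 = _layer_backward(dh2, cache2, w.layer2)
    g1, _ = _layer_backward(dx2, cache1, w.layer1)
    return loss, {"layer1": g1, "layer2": g2, "w_out": d_wout, "b_out": d_bout}


class _Adam:
    def __init__(self, shapes: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flatten_params(w: GRUWeights) -> dict[str, np.ndarray]:
    out = {}
    for li, layer in (("l1", w.layer1), ("l2", w.layer2)):
        for k, v in layer.arrays().items():
            out[f"{li}.{k}"] = v
    out["w_out"] = w.w_out
    out["b_out"] = np.array([w.b_out])
    return out


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale


def train_gru(data: WindowedDataset, hp: GRUHyperparams, seed: int = 0
              ) -> tuple[GRUWeights, np.ndarray]:
    """Train by mini-batch Adam on MSE; returns weights and per-epoch loss.

    Deterministic given (data, hp, seed): the seed drives initialization and
    epoch shuffling.  Raises on an empty dataset or if the loss becomes
    non-finite.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    bs = min(hp.batch_size, len(data))
    rng = np.random.default_rng(seed)
    weights = init_weights(hp, rng)
    flat = _flatten_params(weights)
    opt = _Adam(flat, hp.learning_rate)

    history = []
    for _epoch in range(hp.epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for start in range(0, len(data), bs):
            idx = order[start:start + bs]
            loss, grads = _batch_loss_and_grads(data.inputs[idx], data.targets[idx], weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; "
                    f"learning rate {hp.learning_rate} likely too large")
            gflat = {}
            for li, g in (("l1", grads["layer1"]), ("l2", grads["layer2"])):
                for k, v in g.items():
                    gflat[f"{li}.{k}"] = v
            gflat["w_out"] = grads["w_out"]
            gflat["b_out"] = np.array([grads["b_out"]])
            _clip_global_norm(gflat, GRAD_CLIP_NORM)
            opt.step(flat, gflat)
            weights.b_out = float(flat["b_out"][0])
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return weights, np.asarray(history)


def predict(weights: GRUWeights, data: WindowedDataset,
            scaling: ScalingTransform | None = None) -> np.ndarray:
    """One prediction per window; inverse-scaled if a transform is given."""
    preds = forward_sequence(data.inputs, weights)
    preds = np.asarray(preds, float).ravel()
    return scaling.inverse(preds) if scaling is not None else preds


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_weights(weights: GRUWeights, path: str | Path) -> None:
    """JSON container: nested lists per array (portable, round-trip exact)."""
    def enc(layer: LayerWeights) -> dict:
        return {k: v.tolist() for k, v in layer.arrays().items()}
    payload = {"layer1": enc(weights.layer1), "layer2": enc(weights.layer2),
               "w_out": weights.w_out.tolist(), "b_out": weights.b_out}
    Path(path).write_text(json.dumps(payload))


def load_weights(path: str | Path) -> GRUWeights:
    payload = json.loads(Path(path).read_text())
    def dec(d: dict) -> LayerWeights:
        return LayerWeights(**{k: np.asarray(v, float) for k, v in d.items()})
    return GRUWeights(layer1=dec(payload["layer1"]), layer2=dec(payload["layer2"]),
                      w_out=np.asarray(payload["w_out"], float),
                      b_out=float(payload["b_out"]))
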
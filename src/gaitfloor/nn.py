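"""The recurrent sequence model, written directly in numpy.

The architecture is one LSTM layer (output size 20, only the final-step
output forwarded) followed by four densely connected layers of 20 rectified
linear units each, and a task head: two softmax units trained with binary
cross-entropy for classification, or a single ReLU unit trained with mean
squared error for regression. Training uses mini-batch Adam with early
stopping on the validation loss (patience 12 epochs, at most 60 epochs by
default); the weights returned are those of the best validation epoch.

Forward pass, backpropagation through time and the optimiser are implemented
here explicitly; a finite-difference gradient check in the test suite pins
the backward pass to the forward pass. The network is small (tens of
thousands of parameters), so plain BLAS-backed numpy is entirely adequate:
the dominant cost, the input-to-gate product, is a single large matrix
multiplication per batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigError, InsufficientDataError

TASKS = ("classification", "regression")


@dataclass(frozen=True)
class NetworkConfig:
    """Shape of the sequence model."""

    input_size: int
    window_length: int = 30
    recurrent_size: int = 20
    n_dense: int = 4
    dense_size: int = 20
    task: str = "classification"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigError(f"task must be one of {TASKS}, got {self.task!r}")
        for name in ("input_size", "window_length", "recurrent_size", "n_dense", "dense_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def output_size(self) -> int:
        return 2 if self.task == "classification" else 1


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; defaults are patience 12 within at most 60 epochs."""

    max_epochs: int = 60
    patience: int = 12
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int | None = None
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ConfigError("early-stopping patience must be below max_epochs")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("batch_size must be >= 1 and learning_rate > 0")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class SequenceNet:
    """LSTM + dense stack with an explicit forward/backward implementation.

    Parameters live in :attr:`params`, a flat dict of numpy arrays. Gate
    layout in the fused LSTM weights is ``[input, forget, cell, output]``;
    the forget-gate bias is initialised to 1 (standard practice, keeps the
    cell state alive early in training).
    """

    def __init__(self, cfg: NetworkConfig, seed: int | None = None, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        D, H, W = cfg.input_size, cfg.recurrent_size, cfg.dense_size
        p: dict[str, np.ndarray] = {}
        p["Wx"] = _glorot(rng, D, 4 * H, dtype)
        p["Wh"] = _glorot(rng, H, 4 * H, dtype)
        p["b"] = np.zeros(4 * H, dtype)
        p["b"][H : 2 * H] = 1.0  # forget gate
        sizes = [H] + [W] * cfg.n_dense
        for k in range(cfg.n_dense):
            p[f"Wd{k}"] = _glorot(rng, sizes[k], sizes[k + 1], dtype)
            p[f"bd{k}"] = np.zeros(sizes[k + 1], dtype)
        p["Wo"] = _glorot(rng, sizes[-1], cfg.output_size, dtype)
        p["bo"] = np.zeros(cfg.output_size, dtype)
        self.params = p

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        p = self.params
        B, T, D = X.shape
        H = self.cfg.recurrent_size
        XW = X.reshape(B * T, D) @ p["Wx"]
        XW = XW.reshape(B, T, 4 * H) + p["b"]
        h = np.zeros((B, H), self.dtype)
        c = np.zeros((B, H), self.dtype)
        gates, cells, tanhs, hs = [], [], [], []
        for t in range(T):
            a = XW[:, t, :] + h @ p["Wh"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c = f * c + i * g
            hc = np.tanh(c)
            h = o * hc
            if want_cache:
                gates.append((i, f, g, o))
                cells.append(c)
                tanhs.append(hc)
                hs.append(h)
        acts = [h]
        zs = []
        a_cur = h
        for k in range(self.cfg.n_dense):
            z = a_cur @ p[f"Wd{k}"] + p[f"bd{k}"]
            a_cur = np.maximum(z, 0.0)
            if want_cache:
                zs.append(z)
                acts.append(a_cur)
        z_out = a_cur @ p["Wo"] + p["bo"]
        if self.cfg.task == "classification":
            z_shift = z_out - z_out.max(axis=1, keepdims=True)
            e = np.exp(z_shift)
            out = e / e.sum(axis=1, keepdims=True)
        else:
            out = np.maximum(z_out, 0.0)
        cache = None
        if want_cache:
            cache = dict(X=X, gates=gates, cells=cells, tanhs=tanhs, hs=hs, zs=zs,
                         acts=acts, z_out=z_out, out=out)
        return out, cache

    def predict_proba(self, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Network outputs: class probabilities (B, 2) or regression values (B,)."""
        X = np.asarray(X, self.dtype)
        outs = [self._forward(X[i : i + chunk])[0] for i in range(0, len(X), chunk)]
        out = np.concatenate(outs, axis=0)
        return out if self.cfg.task == "classification" else out[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class labels (classification) or predicted values (regression)."""
        out = self.predict_proba(X)
        if self.cfg.task == "classification":
            return np.argmax(out, axis=1)
        return out

    # -- loss and gradients ------------------------------------------------

    def loss(self, X: np.ndarray, y: np.ndarray, chunk: int = 2048) -> float:
        """Mean loss (binary cross-entropy or MSE) without gradient bookkeeping."""
        X = np.asarray(X, self.dtype)
        total, n = 0.0, len(X)
        for i in range(0, n, chunk):
            out, _ = self._forward(X[i : i + chunk])
            yi = y[i : i + chunk]
            if self.cfg.task == "classification":
                pcorrect = out[np.arange(len(yi)), yi.astype(int)]
                total += float(-np.log(np.clip(pcorrect, 1e-12, None)).sum())
            else:
                total += float(((out[:, 0] - yi) ** 2).sum())
        return total / n

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean loss on the batch plus gradients for every parameter."""
        p = self.params
        B, T, D = X.shape
        H = self.cfg.recurrent_size
        out, cache = self._forward(X, want_cache=True)
        if self.cfg.task == "classification":
            yi = y.astype(int)
            pcorrect = out[np.arange(B), yi]
            loss = float(-np.log(np.clip(pcorrect, 1e-12, None)).mean())
            dz_out = out.copy()
            dz_out[np.arange(B), yi] -= 1.0
            dz_out /= B
        else:
            diff = out[:, 0] - y
            loss = float((diff**2).mean())
            dz_out = (2.0 * diff / B)[:, None] * (cache["z_out"] > 0)
        grads: dict[str, np.ndarray] = {}
        acts, zs = cache["acts"], cache["zs"]
        grads["Wo"] = acts[-1].T @ dz_out
        grads["bo"] = dz_out.sum(axis=0)
        da = dz_out @ p["Wo"].T
        for k in reversed(range(self.cfg.n_dense)):
            dz = da * (zs[k] > 0)
            grads[f"Wd{k}"] = acts[k].T @ dz
            grads[f"bd{k}"] = dz.sum(axis=0)
            da = dz @ p[f"Wd{k}"].T
        # backpropagation through time
        gates, cells, tanhs, hs = cache["gates"], cache["cells"], cache["tanhs"], cache["hs"]
        dG = np.zeros((B, T, 4 * H), self.dtype)
        dh = da.astype(self.dtype)
        dc = np.zeros((B, H), self.dtype)
        for t in reversed(range(T)):
            i, f, g, o = gates[t]
            hc = tanhs[t]
            c_prev = cells[t - 1] if t > 0 else np.zeros_like(cells[0])
            do = dh * hc
            dc = dc + dh * o * (1.0 - hc * hc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dG[:, t, :H] = di * i * (1.0 - i)
            dG[:, t, H : 2 * H] = df * f * (1.0 - f)
            dG[:, t, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dG[:, t, 3 * H :] = do * o * (1.0 - o)
            dh = dG[:, t] @ p["Wh"].T
            dc = dc * f
        grads["Wx"] = X.reshape(B * T, D).T @ dG.reshape(B * T, 4 * H)
        grads["b"] = dG.sum(axis=(0, 1))
        dWh = np.zeros_like(p["Wh"])
        for t in range(1, T):
            dWh += hs[t - 1].T @ dG[:, t]
        grads["Wh"] = dWh
        return loss, grads

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        tcfg: TrainingConfig | None = None,
        callback: Callable[[int, float, float], None] | None = None,
    ) -> dict:
        """Mini-batch Adam with early stopping on the validation loss.

        Stops once the validation loss has not strictly improved for
        ``patience`` consecutive epochs (or at ``max_epochs``), then restores
        the weights of the best validation epoch. Returns the history dict
        with per-epoch train/validation losses and the best epoch (1-based).
        Fully deterministic for a fixed ``tcfg.seed``.
        """
        tcfg = tcfg or TrainingConfig()
        if len(X_train) == 0:
            raise InsufficientDataError("empty training set")
        if len(X_val) == 0:
            raise InsufficientDataError("empty validation set")
        X_train = np.asarray(X_train, self.dtype)
        X_val = np.asarray(X_val, self.dtype)
        y_train = np.asarray(y_train)
        y_val = np.asarray(y_val)
        if self.cfg.task == "regression" and np.allclose(self.params["bo"], 0.0):
            # start the ReLU head in its active region at the target mean,
            # otherwise a dead output unit never receives gradient
            self.params["bo"] = np.full(1, float(np.mean(y_train)), self.dtype)
        rng = np.random.default_rng(tcfg.seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = math.inf
        best_epoch = 0
        best_params: dict[str, np.ndarray] = {}
        history: dict = {"train_loss": [], "val_loss": []}
        for epoch in range(1, tcfg.max_epochs + 1):
            order = rng.permutation(len(X_train))
            epoch_loss, n_seen = 0.0, 0
            for start in range(0, len(order), tcfg.batch_size):
                idx = order[start : start + tcfg.batch_size]
                loss, grads = self.loss_and_grads(X_train[idx], y_train[idx])
                epoch_loss += loss * len(idx)
                n_seen += len(idx)
                step += 1
                corr1 = 1.0 - beta1**step
                corr2 = 1.0 - beta2**step
                for k, gr in grads.items():
                    m[k] = beta1 * m[k] + (1 - beta1) * gr
                    v[k] = beta2 * v[k] + (1 - beta2) * gr * gr
                    self.params[k] = self.params[k] - (
                        tcfg.learning_rate * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + eps)
                    ).astype(self.dtype)
            val_loss = self.loss(X_val, y_val)
            history["train_loss"].append(epoch_loss / n_seen)
            history["val_loss"].append(val_loss)
            if callback is not None:
                callback(epoch, epoch_loss / n_seen, val_loss)
            if val_loss < best_val:  # any strict improvement resets patience
                best_val = val_loss
                best_epoch = epoch
                best_params = {k: vv.copy() for k, vv in self.params.items()}
            if epoch - best_epoch >= tcfg.patience:
                break
        if best_params:
            self.params = best_params
        history["best_epoch"] = best_epoch
        history["best_val_loss"] = best_val
        history["n_epochs"] = len(history["val_loss"])
        return history

    # -- bookkeeping -------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def build_network(cfg: NetworkConfig, seed: int | None = None, dtype=np.float32) -> SequenceNet:
    """Construct the sequence model for a task."""
    return SequenceNet(cfg, seed=seed, dtype=dtype)
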
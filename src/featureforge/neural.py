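"""Bidirectional-LSTM sequence labeller with a feed-forward head, in numpy.

Architecture: a stack of bidirectional LSTM layers over variable-length
per-residue feature sequences (padding never enters the recurrence), a
linear bridge where the top Bi-LSTM output width differs from the head
input width, then a position-wise feed-forward head with ReLU activations
ending in 9 logits — the eight DSSP classes plus the technical mask class
(Ø). Masked positions are excluded from the cross-entropy loss (and all
metrics) via an ignore index, and the mask class is never predicted.

Forward and backward passes (full BPTT) are implemented directly on numpy
arrays and validated against numerical differentiation in the test suite.
Training uses Adam with weight decay, an annealed dropout schedule (the
rate steps down by 0.1 whenever validation accuracy plateaus), a stepwise
learning-rate decay toward a floor once dropout reaches zero, and early
stopping with best-checkpoint retention.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

IGNORE_INDEX = 8  # the Ø class


@dataclass
class NetConfig:
    """Hyperparameters; defaults mirror the full-scale recipe, tests shrink them."""

    input_dim: int
    lstm_layers: int = 2
    hidden_per_direction: int = 512
    head_dims: tuple = (2048, 1024, 512, 9)
    dropout_start: float = 0.7
    dropout_end: float = 0.0
    dropout_step: float = 0.1
    lr: float = 1e-4
    weight_decay: float = 1e-4
    lr_floor: float = 1e-5
    lr_decay: float = 0.5
    early_stop_patience: int = 13
    plateau_patience: int = 5
    plateau_min_improvement: float = 1e-4
    n_classes: int = 9

    def __post_init__(self):
        if self.head_dims[-1] != self.n_classes:
            raise ValueError("head must end in n_classes logits")
        if self.lstm_layers < 1 or self.hidden_per_direction < 1:
            raise ValueError("invalid recurrent stack shape")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class BiLstmClassifier:
    """Stacked Bi-LSTM + feed-forward head; parameters in a flat dict."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        H = config.hidden_per_direction
        in_dim = config.input_dim
        for layer in range(config.lstm_layers):
            for direction in ("fw", "bw"):
                k = 1.0 / np.sqrt(H)
                pre = f"lstm{layer}_{direction}"
                self.params[f"{pre}_Wx"] = rng.uniform(-k, k, size=(in_dim, 4 * H))
                self.params[f"{pre}_Wh"] = rng.uniform(-k, k, size=(H, 4 * H))
                b = rng.uniform(-k, k, size=4 * H)
                b[H:2 * H] += 1.0  # forget-gate bias init
                self.params[f"{pre}_b"] = b
            in_dim = 2 * H
        dims = list(config.head_dims)
        self.has_bridge = in_dim != dims[0]
        if self.has_bridge:
            k = 1.0 / np.sqrt(in_dim)
            self.params["bridge_W"] = rng.uniform(-k, k, size=(in_dim, dims[0]))
            self.params["bridge_b"] = np.zeros(dims[0])
        for i in range(len(dims) - 1):
            k = 1.0 / np.sqrt(dims[i])
            self.params[f"head{i}_W"] = rng.uniform(-k, k, size=(dims[i], dims[i + 1]))
            self.params[f"head{i}_b"] = np.zeros(dims[i + 1])
        self.n_head = len(dims) - 1

    # ------------------------------------------------------------------ LSTM

    def _lstm_forward(self, X, mask, prefix):
        """One direction over (B, T, D); mask (B, T) gates state updates so
        padded steps leave h and c untouched."""
        Wx = self.params[f"{prefix}_Wx"]
        Wh = self.params[f"{prefix}_Wh"]
        b = self.params[f"{prefix}_b"]
        B, T, _ = X.shape
        H = Wh.shape[0]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.zeros((B, T, H))
        cache = []
        for t in range(T):
            m = mask[:, t:t + 1].astype(float)
            z = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((X[:, t], h, c, i, f, g, o, tanh_c, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            Hs[:, t] = h
        return Hs, cache

    def _lstm_backward(self, dHs, cache, prefix, grads):
        Wx = self.params[f"{prefix}_Wx"]
        Wh = self.params[f"{prefix}_Wh"]
        B, T, H = dHs.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.zeros((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c, m = cache[t]
            dh = dHs[:, t] + dh_next
            dh_new = dh * m
            dh_prev_skip = dh * (1 - m)
            dc_new = dh_new * o * (1 - tanh_c ** 2) + dc_next * m
            dc_prev_skip = dc_next * (1 - m)
            do = dh_new * tanh_c
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T + dh_prev_skip
            dc_next = dc_new * f + dc_prev_skip
        grads[f"{prefix}_Wx"] = grads.get(f"{prefix}_Wx", 0) + dWx
        grads[f"{prefix}_Wh"] = grads.get(f"{prefix}_Wh", 0) + dWh
        grads[f"{prefix}_b"] = grads.get(f"{prefix}_b", 0) + db
        return dX

    @staticmethod
    def _reverse(X, lengths):
        """Reverse each sequence within its own length (padding stays put)."""
        out = np.array(X)
        for bi, L in enumerate(lengths):
            out[bi, :L] = X[bi, :L][::-1]
        return out

    # --------------------------------------------------------------- forward

    def forward(self, X, lengths, dropout_rate=0.0, rng=None):
        """Full forward pass: (B, T, input_dim) -> logits (B, T, n_classes).

        Returns (logits, cache) where the cache holds everything backward
        needs. Dropout (inverted) is applied to each Bi-LSTM layer output
        when ``dropout_rate`` > 0 and an rng is given.
        """
        B, T, _ = X.shape
        mask = np.zeros((B, T), dtype=bool)
        for bi, L in enumerate(lengths):
            mask[bi, :L] = True
        cache = {"mask": mask, "lengths": lengths, "drop": []}
        layer_in = X
        for layer in range(self.config.lstm_layers):
            fw, cache_fw = self._lstm_forward(layer_in, mask, f"lstm{layer}_fw")
            rev_in = self._reverse(layer_in, lengths)
            bw_rev, cache_bw = self._lstm_forward(rev_in, mask, f"lstm{layer}_bw")
            bw = self._reverse(bw_rev, lengths)
            out = np.concatenate([fw, bw], axis=2)
            if dropout_rate > 0 and rng is not None:
                keep = (rng.random(out.shape) >= dropout_rate) / (1 - dropout_rate)
            else:
                keep = None
            cache["drop"].append(keep)
            if keep is not None:
                out = out * keep
            cache[f"layer{layer}"] = (cache_fw, cache_bw, layer_in.shape)
            layer_in = out
        flat = layer_in.reshape(B * T, -1)
        cache["head_in_shape"] = layer_in.shape
        acts = [flat]
        if self.has_bridge:
            flat = flat @ self.params["bridge_W"] + self.params["bridge_b"]
            acts.append(flat)
        for i in range(self.n_head):
            flat = flat @ self.params[f"head{i}_W"] + self.params[f"head{i}_b"]
            if i < self.n_head - 1:
                flat = np.maximum(flat, 0.0)
            acts.append(flat)
        cache["acts"] = acts
        logits = flat.reshape(B, T, -1)
        return logits, cache

    # -------------------------------------------------------------- backward

    def backward(self, dlogits, cache):
        """Backpropagate d(loss)/d(logits); returns the gradient dict."""
        grads: dict[str, np.ndarray] = {}
        B, T, F = cache["head_in_shape"]
        d = dlogits.reshape(dlogits.shape[0] * dlogits.shape[1], -1)
        acts = cache["acts"]
        off = 1 if self.has_bridge else 0
        # acts layout: [head_in] (+ [bridge_out]) + [post-activation output
        # of each head layer]; input to head layer i is acts[off + i].
        for i in reversed(range(self.n_head)):
            a_in = acts[off + i]
            grads[f"head{i}_W"] = a_in.T @ d
            grads[f"head{i}_b"] = d.sum(axis=0)
            d = d @ self.params[f"head{i}_W"].T
            if i > 0:
                d = d * (a_in > 0)  # ReLU applied after the previous layer
        if self.has_bridge:
            a_in = acts[0]
            grads["bridge_W"] = a_in.T @ d
            grads["bridge_b"] = d.sum(axis=0)
            d = d @ self.params["bridge_W"].T
        d = d.reshape(B, T, F)
        lengths = cache["lengths"]
        for layer in reversed(range(self.config.lstm_layers)):
            keep = cache["drop"][layer]
            if keep is not None:
                d = d * keep
            cache_fw, cache_bw, in_shape = cache[f"layer{layer}"]
            H = self.config.hidden_per_direction
            d_fw = d[:, :, :H]
            d_bw = d[:, :, H:]
            dX_fw = self._lstm_backward(d_fw, cache_fw, f"lstm{layer}_fw", grads)
            d_bw_rev = self._reverse(d_bw, lengths)
            dX_bw_rev = self._lstm_backward(d_bw_rev, cache_bw, f"lstm{layer}_bw", grads)
            dX_bw = self._reverse(dX_bw_rev, lengths)
            d = dX_fw + dX_bw
        return grads


def masked_cross_entropy(logits, targets, lengths):
    """Mean cross-entropy over valid positions; targets equal to the ignore
    index (Ø) and padded positions contribute nothing to loss or gradient.

    Returns (loss, dlogits).
    """
    B, T, C = logits.shape
    valid = np.zeros((B, T), dtype=bool)
    for bi, L in enumerate(lengths):
        valid[bi, :L] = True
    valid &= targets != IGNORE_INDEX
    n_valid = int(valid.sum())
    shifted = logits - logits.max(axis=2, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=2, keepdims=True)
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    safe_targets = np.where(valid, targets, 0)
    picked = np.take_along_axis(probs, safe_targets[..., None], axis=2)[..., 0]
    loss = -np.sum(np.log(np.clip(picked, 1e-300, None)) * valid) / n_valid
    dlogits = probs.copy()
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, safe_targets[..., None], 1.0, axis=2)
    dlogits -= onehot
    dlogits *= valid[..., None] / n_valid
    return float(loss), dlogits


class Adam:
    """Adam with (coupled) weight decay, matching the classic formulation."""

    def __init__(self, params, lr=1e-4, weight_decay=1e-4,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            g = g + self.weight_decay * p
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g ** 2
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_model(config: NetConfig, seed: int = 0) -> BiLstmClassifier:
    """Construct an initialized (untrained) classifier."""
    return BiLstmClassifier(config, seed=seed)


def _pad_batch(features, labels):
    lengths = [len(x) for x in features]
    B, T = len(features), max(lengths)
    D = features[0].shape[1]
    X = np.zeros((B, T, D))
    y = np.full((B, T), IGNORE_INDEX, dtype=int)
    for bi, (x, lab) in enumerate(zip(features, labels)):
        X[bi, :len(x)] = x
        y[bi, :len(x)] = lab
    return X, y, lengths


def predict_labels(model: BiLstmClassifier, features: np.ndarray) -> np.ndarray:
    """Per-residue class indices for one chain, argmax over the eight
    biological classes only — the mask class is never predicted."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.config.input_dim:
        raise ValueError("feature dimension mismatch")
    logits, _ = model.forward(X[None], [len(X)])
    return np.argmax(logits[0, :, :IGNORE_INDEX], axis=1)


def accuracy(model, features_list, labels_list) -> float:
    """Residue accuracy over chains, Ø positions excluded."""
    correct = total = 0
    for x, y in zip(features_list, labels_list):
        pred = predict_labels(model, x)
        keep = np.asarray(y) != IGNORE_INDEX
        correct += int(np.sum((pred == np.asarray(y)) & keep))
        total += int(keep.sum())
    return correct / max(total, 1)


@dataclass
class TrainLog:
    epoch_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    dropout: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0


def train_model(
    model: BiLstmClassifier,
    train: tuple[Sequence[np.ndarray], Sequence[np.ndarray]],
    val: Optional[tuple[Sequence[np.ndarray], Sequence[np.ndarray]]] = None,
    epochs: int = 100,
    batch_size: int = 8,
    seed: int = 0,
) -> TrainLog:
    """Train with Adam under masked cross-entropy.

    Schedule: whenever validation accuracy fails to improve by at least
    ``plateau_min_improvement`` for ``plateau_patience`` consecutive epochs,
    the dropout rate steps down by ``dropout_step``; once it reaches the end
    value, further plateau events decay the learning rate by ``lr_decay``
    down to ``lr_floor``. Training stops early after
    ``early_stop_patience`` epochs without a new best validation accuracy;
    the best parameters are restored. Fully deterministic for a given seed.
    """
    cfg = model.config
    feats, labels = train
    if len(feats) == 0:
        raise ValueError("empty training set")
    if val is None:
        val = train
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    # Length-sorted bucketing keeps padding waste low and batches deterministic.
    order = sorted(range(len(feats)), key=lambda i: len(feats[i]))
    batches = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    log = TrainLog()
    dropout = cfg.dropout_start
    best_params = copy.deepcopy(model.params)
    plateau_count = 0
    since_best = 0
    for epoch in range(epochs):
        total_loss = 0.0
        for batch in batches:
            X, y, lengths = _pad_batch([feats[i] for i in batch],
                                       [labels[i] for i in batch])
            logits, cache = model.forward(X, lengths, dropout_rate=dropout, rng=rng)
            loss, dlogits = masked_cross_entropy(logits, y, lengths)
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            total_loss += loss * len(batch)
        log.epoch_loss.append(total_loss / len(feats))
        val_acc = accuracy(model, val[0], val[1])
        log.val_accuracy.append(val_acc)
        log.dropout.append(dropout)
        log.lr.append(opt.lr)
        if val_acc > log.best_val_accuracy + 0:
            best_params = copy.deepcopy(model.params)
            log.best_val_accuracy = val_acc
            log.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        # Plateau bookkeeping for the dropout / lr schedule.
        window = log.val_accuracy[-(cfg.plateau_patience + 1):]
        plateaued = (len(window) == cfg.plateau_patience + 1 and
                     max(window[1:]) < window[0] + cfg.plateau_min_improvement)
        if plateaued:
            if dropout > cfg.dropout_end + 1e-12:
                dropout = max(cfg.dropout_end, dropout - cfg.dropout_step)
            elif opt.lr > cfg.lr_floor:
                opt.lr = max(cfg.lr_floor, opt.lr * cfg.lr_decay)
        if since_best >= cfg.early_stop_patience:
            break
    model.params = best_params
    return log
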
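"""Compact deterministic feedforward net for dosage inputs.

Architecture: two equal-width ReLU hidden layers and a single sigmoid output
unit. Training: Adam with the classic per-update learning-rate decay
lr_t = lr0 / (1 + decay * t), binary cross-entropy loss, mini-batches with
seeded shuffling, per-epoch validation checkpointing. All arithmetic is
NumPy float64, so a (seed, data) pair reproduces bit-identically.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-7  # probability clamp inside the cross-entropy

_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3")


def glorot_uniform(rng, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(rng, n_inputs: int, width: int) -> dict[str, np.ndarray]:
    return {
        "W1": glorot_uniform(rng, n_inputs, width), "b1": np.zeros(width),
        "W2": glorot_uniform(rng, width, width), "b2": np.zeros(width),
        "W3": glorot_uniform(rng, width, 1), "b3": np.zeros(1),
    }


def forward(params, x: np.ndarray) -> np.ndarray:
    """Case probability for each row of x."""
    h1 = np.maximum(x @ params["W1"] + params["b1"], 0.0)
    h2 = np.maximum(h1 @ params["W2"] + params["b2"], 0.0)
    z = h2 @ params["W3"] + params["b3"]
    return 1.0 / (1.0 + np.exp(-z[:, 0]))


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def n_parameters(n_inputs: int, width: int) -> int:
    """Trainable parameter count of the fixed architecture."""
    return (width * (n_inputs + 1)) + (width * (width + 1)) + (width + 1)


def train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    width: int,
    seed: int,
    epochs: int = 100,
    batch_size: int = 32,
    lr0: float = 5e-3,
    decay: float = 1e-5,
    beta1: float = 0.9,
    beta2: float = 0.999,
    adam_eps: float = 1e-8,
) -> dict:
    """Train and return the checkpoint with minimal validation loss.

    Ties on validation loss break toward higher training accuracy, then the
    earlier epoch. Returns a dict with the restored ``params``, the restored
    checkpoint's ``train_loss``/``val_loss``/``train_accuracy``/``epoch``,
    and the per-epoch ``history``.
    """
    x_train = np.ascontiguousarray(x_train, dtype=float)
    x_val = np.ascontiguousarray(x_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(seed)
    d = x_train.shape[1]
    pd = init_params(rng, d, width)

    # flat parameter vector with reshaped views, so Adam runs vectorized
    shapes = [pd[k].shape for k in _KEYS]
    sizes = [int(np.prod(s)) for s in shapes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    theta = np.concatenate([pd[k].ravel() for k in _KEYS])
    views = [theta[offsets[i]:offsets[i + 1]].reshape(shapes[i])
             for i in range(len(_KEYS))]
    gvec = np.empty_like(theta)
    gviews = [gvec[offsets[i]:offsets[i + 1]].reshape(shapes[i])
              for i in range(len(_KEYS))]
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    t = 0

    best = None  # (val_loss, -train_acc, epoch, params copy, train_loss)
    history = []
    n = x_train.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            W1, b1, W2, b2, W3, b3 = views

            h1_pre = xb @ W1 + b1
            h1 = np.maximum(h1_pre, 0.0)
            h2_pre = h1 @ W2 + b2
            h2 = np.maximum(h2_pre, 0.0)
            z = h2 @ W3 + b3
            p = 1.0 / (1.0 + np.exp(-z[:, 0]))
            dz = (p - yb)[:, None] / xb.shape[0]
            dh2 = (dz @ W3.T) * (h2_pre > 0)
            dh1 = (dh2 @ W2.T) * (h1_pre > 0)
            np.matmul(xb.T, dh1, out=gviews[0])
            gviews[1][:] = dh1.sum(axis=0)
            np.matmul(h1.T, dh2, out=gviews[2])
            gviews[3][:] = dh2.sum(axis=0)
            np.matmul(h2.T, dz, out=gviews[4])
            gviews[5][:] = dz.sum(axis=0)

            lr = lr0 / (1.0 + decay * t)
            t += 1
            m *= beta1
            m += (1 - beta1) * gvec
            v *= beta2
            v += (1 - beta2) * gvec * gvec
            theta -= lr * (m / (1.0 - beta1 ** t)) / (
                np.sqrt(v / (1.0 - beta2 ** t)) + adam_eps)

        pdict = dict(zip(_KEYS, views))
        p_train = forward(pdict, x_train)
        p_val = forward(pdict, x_val)
        train_loss = bce_loss(p_train, y_train)
        val_loss = bce_loss(p_val, y_val)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} (lr={lr0 / (1 + decay * t):.3g})")
        train_acc = float(np.mean((p_train >= 0.5) == (y_train == 1)))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "train_acc": train_acc,
                        "lr": lr0 / (1.0 + decay * t)})
        key = (val_loss, -train_acc, epoch)
        if best is None or key < best[:3]:
            best = (val_loss, -train_acc, epoch,
                    {k: p.copy() for k, p in pdict.items()}, train_loss)

    return {
        "params": best[3],
        "val_loss": best[0],
        "train_accuracy": -best[1],
        "train_loss": best[4],
        "epoch": best[2],
        "history": history,
    }
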
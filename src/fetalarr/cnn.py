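"""1-D CNN segment classifier.

Architecture: two (convolution + ReLU + max-pool) blocks followed by a dense
ReLU layer and a softmax output — binary (normal/arrhythmia) for the main
method, ternary (normal/moderate/arrhythmia) for the per-subject variant.
Trained with cross-entropy and Adam (lr 3e-4).  The network is implemented
directly on numpy (im2col convolutions, hand-derived backward pass), which
keeps training bit-reproducible given the seed and fast enough on one CPU
for the segment sizes involved (1500 samples at 500 Hz).

Segments are z-score normalised per segment before entering the network, so
electrode-dependent amplitude cannot act as a class cue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .types import (
    ARRHYTHMIA_SEG,
    MODERATE_SEG,
    NORMAL_SEG,
    Segment,
    SegmentPrediction,
)

BINARY_CLASSES = (NORMAL_SEG, ARRHYTHMIA_SEG)
TERNARY_CLASSES = (NORMAL_SEG, MODERATE_SEG, ARRHYTHMIA_SEG)


@dataclass
class CNNConfig:
    """Hyperparameters of the segment classifier."""

    n_classes: int = 2
    input_len: int = 1500
    filters: tuple[int, int] = (8, 16)
    kernel_size: int = 9
    pool_size: int = 4
    dense_units: int = 64
    lr: float = 3e-4
    epochs: int = 20
    batch_size: int = 64
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if len(self.filters) != 2:
            raise ValueError("exactly two convolution blocks are used")

    @property
    def classes(self) -> tuple[str, ...]:
        return BINARY_CLASSES if self.n_classes == 2 else TERNARY_CLASSES


def normalize_segments(X: np.ndarray) -> np.ndarray:
    """Per-segment z-score; constant segments map to all-zeros."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def build_training_set(
    segments: list[Segment],
    labels: list[str],
    mode: str = "binary",
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Assemble (inputs, integer targets, class order) from labeled segments.

    Binary mode drops moderate segments entirely; ternary mode keeps all
    three classes.  Raises if any retained class has no segments.
    """
    if len(segments) != len(labels):
        raise ValueError("one label per segment required")
    classes = BINARY_CLASSES if mode == "binary" else TERNARY_CLASSES
    keep = [
        (s, l) for s, l in zip(segments, labels)
        if not (mode == "binary" and l == MODERATE_SEG)
    ]
    counts = {c: sum(1 for _, l in keep if l == c) for c in classes}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"no training segments for class(es): {missing} (counts {counts})")
    X = normalize_segments(np.stack([s.samples for s, _ in keep]))
    y = np.asarray([classes.index(l) for _, l in keep], dtype=int)
    return X, y, classes


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L, k*C) windows with zero 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, C, k)
    return win.transpose(0, 1, 3, 2).reshape(x.shape[0], x.shape[1], k * x.shape[2])


def _col2im(dcols: np.ndarray, k: int, L: int, C: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    B = dcols.shape[0]
    p = k // 2
    d = dcols.reshape(B, L, k, C)
    dxp = np.zeros((B, L + 2 * p, C), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, j : j + L, :] += d[:, :, j, :]
    return dxp[:, p : p + L, :]


class CNN1D:
    """The trained model: parameters, forward/backward, Adam optimiser."""

    def __init__(self, config: CNNConfig):
        self.config = config
        self.classes = config.classes
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        f1, f2 = config.filters
        L = config.input_len
        L1 = L // config.pool_size
        L2 = (L1 // config.pool_size)
        self._flat = L2 * f2
        he = lambda fan_in, shape: rng.normal(0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)
        self.params = {
            "W1": he(k, (k, f1)), "b1": np.zeros(f1, dtype=np.float32),
            "W2": he(k * f1, (k * f1, f2)), "b2": np.zeros(f2, dtype=np.float32),
            "W3": he(self._flat, (self._flat, config.dense_units)),
            "b3": np.zeros(config.dense_units, dtype=np.float32),
            "W4": he(config.dense_units, (config.dense_units, config.n_classes)),
            "b4": np.zeros(config.n_classes, dtype=np.float32),
        }
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0
        self.history: list[dict] = []

    # -- forward ------------------------------------------------------------

    def _pool(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        ps = self.config.pool_size
        B, L, C = x.shape
        Lp = L // ps
        xr = x[:, : Lp * ps, :].reshape(B, Lp, ps, C)
        arg = xr.argmax(axis=2)
        out = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
        return out, arg, L

    def _forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        x0 = X[:, :, None]  # (B, L, 1)
        c1 = _im2col(x0, self.config.kernel_size)
        z1 = c1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        p1, arg1, L1full = self._pool(a1)
        c2 = _im2col(p1, self.config.kernel_size)
        z2 = c2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        p2, arg2, L2full = self._pool(a2)
        flat = p2.reshape(X.shape[0], -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["W4"] + p["b4"]
        if not cache:
            return logits, None
        return logits, dict(
            c1=c1, z1=z1, p1=p1, arg1=arg1, L1full=L1full,
            c2=c2, z2=z2, arg2=arg2, L2full=L2full,
            flat=flat, z3=z3, a3=a3,
        )

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    # -- backward -----------------------------------------------------------

    def _unpool(self, dout: np.ndarray, arg: np.ndarray, Lfull: int) -> np.ndarray:
        ps = self.config.pool_size
        B, Lp, C = dout.shape
        dx = np.zeros((B, Lp, ps, C), dtype=dout.dtype)
        np.put_along_axis(dx, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = dx.reshape(B, Lp * ps, C)
        if Lp * ps < Lfull:
            dx = np.pad(dx, ((0, 0), (0, Lfull - Lp * ps), (0, 0)))
        return dx

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        p = self.params
        k = self.config.kernel_size
        g = {}
        g["W4"] = cache["a3"].T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["W4"].T
        dz3 = da3 * (cache["z3"] > 0)
        g["W3"] = cache["flat"].T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        B = dlogits.shape[0]
        f2 = self.config.filters[1]
        dp2 = dflat.reshape(B, -1, f2)
        da2 = self._unpool(dp2, cache["arg2"], cache["L2full"])
        dz2 = da2 * (cache["z2"] > 0)
        c2f = cache["c2"].reshape(-1, cache["c2"].shape[2])
        g["W2"] = c2f.T @ dz2.reshape(-1, f2)
        g["b2"] = dz2.sum(axis=(0, 1))
        dc2 = dz2 @ p["W2"].T
        dp1 = _col2im(dc2, k, cache["c2"].shape[1], self.config.filters[0])
        da1 = self._unpool(dp1, cache["arg1"], cache["L1full"])
        dz1 = da1 * (cache["z1"] > 0)
        f1 = self.config.filters[0]
        c1f = cache["c1"].reshape(-1, cache["c1"].shape[2])
        g["W1"] = c1f.T @ dz1.reshape(-1, f1)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    def _adam_step(self, grads: dict) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.config.lr, 0.9, 0.999, 1e-8
        for n, gr in grads.items():
            self._adam_m[n] = b1 * self._adam_m[n] + (1 - b1) * gr
            self._adam_v[n] = b2 * self._adam_v[n] + (1 - b2) * gr**2
            mhat = self._adam_m[n] / (1 - b1**self._adam_t)
            vhat = self._adam_v[n] / (1 - b2**self._adam_t)
            self.params[n] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNN1D":
        """Train with shuffled mini-batches; deterministic given the seed."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if X.shape[1] != cfg.input_len:
            raise ValueError(f"inputs must have length {cfg.input_len}, got {X.shape[1]}")
        if np.unique(y).size < 2:
            raise ValueError("training targets contain a single class")
        if cfg.class_weighting:
            counts = np.bincount(y, minlength=cfg.n_classes).astype(float)
            cw = np.where(counts > 0, counts.sum() / (cfg.n_classes * np.maximum(counts, 1)), 0.0)
        else:
            cw = np.ones(cfg.n_classes)
        rng = np.random.default_rng(cfg.seed + 1)
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for i0 in range(0, n, cfg.batch_size):
                idx = order[i0 : i0 + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                logits, cache = self._forward(xb, cache=True)
                probs = self._softmax(logits)
                w = cw[yb]
                wsum = w.sum()
                eps = 1e-12
                loss = float(-(w * np.log(probs[np.arange(len(yb)), yb] + eps)).sum() / wsum)
                if not np.isfinite(loss):
                    raise RuntimeError("training diverged: non-finite loss")
                losses.append(loss)
                correct += int((probs.argmax(axis=1) == yb).sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits *= (w / wsum)[:, None]
                self._adam_step(self._backward(dlogits, cache))
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
            )
        return self

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        if X.shape[1] != self.config.input_len:
            raise ValueError(
                f"inputs must have length {self.config.input_len}, got {X.shape[1]}"
            )
        out = [self._softmax(self._forward(X[i : i + batch])[0]) for i in range(0, X.shape[0], batch)]
        return np.vstack(out)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "CNN1D":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg["filters"] = tuple(cfg["filters"])
        model = cls(CNNConfig(**cfg))
        data = np.load(path.with_suffix(".npz"))
        model.params = {n: data[n] for n in data.files}
        return model


def train(config: CNNConfig, X: np.ndarray, y: np.ndarray) -> CNN1D:
    """Build and fit a classifier; returns the trained model handle."""
    return CNN1D(config).fit(X, y)


def predict(model: CNN1D, segments: list[Segment]) -> list[SegmentPrediction]:
    """Classify segments (normalised exactly as in training)."""
    X = normalize_segments(np.stack([s.samples for s in segments]))
    probs = model.predict_proba(X)
    preds = []
    for s, p in zip(segments, probs):
        j = int(np.argmax(p))
        preds.append(
            SegmentPrediction(
                subject_id=s.subject_id,
                start_time=s.start_time,
                predicted=model.classes[j],
                scores={c: float(v) for c, v in zip(model.classes, p)},
            )
        )
    return preds


def save_training_log(model: CNN1D, path: str | Path) -> None:
    """Per-epoch loss/accuracy as CSV."""
    lines = ["epoch,loss,accuracy"]
    lines += [f"{h['epoch']},{h['loss']:.6f},{h['accuracy']:.6f}" for h in model.history]
    Path(path).write_text("\n".join(lines) + "\n")
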
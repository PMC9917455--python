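"""Minimal convolutional embedding network in pure numpy.

A compact CNN (three blocks of two 3x3 convolutions + ReLU followed by 2x2
max-pooling, then two fully connected layers) mapping square grayscale crops
to L2-normalized 64-dimensional embeddings, trained with a Euclidean triplet
loss and Adam.  Forward and backward passes are hand-written; convolution
uses nine shifted slices of the padded input (equivalent to im2col for a 3x3
kernel) so everything stays vectorized.

Sized for desk-scale experiments: hundreds of small crops train in seconds to
minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvEmbedder", "triplet_loss", "triplet_loss_grad"]


def triplet_loss(anchor, positive, negative, margin: float = 0.2, squared: bool = False):
    """Mean triplet loss max(0, ||a-p|| - ||a-n|| + margin) over a batch.

    Distances are Euclidean (optionally squared).  Inputs are (d,) vectors or
    (n, d) batches; dimensions must agree.
    """
    a = np.atleast_2d(np.asarray(anchor, dtype=np.float64))
    p = np.atleast_2d(np.asarray(positive, dtype=np.float64))
    n = np.atleast_2d(np.asarray(negative, dtype=np.float64))
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"embedding shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    d_ap = np.linalg.norm(a - p, axis=1)
    d_an = np.linalg.norm(a - n, axis=1)
    if squared:
        d_ap, d_an = d_ap**2, d_an**2
    return float(np.mean(np.maximum(0.0, d_ap - d_an + margin)))


def triplet_loss_grad(a, p, n, margin: float = 0.2):
    """Loss and gradients w.r.t. (a, p, n) for the mean Euclidean triplet loss."""
    eps = 1e-9
    ap = a - p
    an = a - n
    d_ap = np.sqrt((ap**2).sum(axis=1) + eps)
    d_an = np.sqrt((an**2).sum(axis=1) + eps)
    viol = d_ap - d_an + margin
    active = (viol > 0).astype(np.float64)
    loss = float(np.mean(np.maximum(viol, 0.0)))
    scale = active / len(a)
    u_ap = ap / d_ap[:, None]
    u_an = an / d_an[:, None]
    ga = scale[:, None] * (u_ap - u_an)
    gp = -scale[:, None] * u_ap
    gn = scale[:, None] * u_an
    return loss, ga, gp, gn


class _Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _conv_forward(x, w, b):
    """3x3 same-padding convolution; x (N, C, H, W), w (F, C, 3, 3)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    out = np.einsum("nchwij,fcij->nfhw", v, w, optimize=True)
    out += b[None, :, None, None]
    return out, xp


def _conv_backward(dout, xp, w):
    n, f, h, wd = dout.shape
    c = w.shape[1]
    v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    dw = np.einsum("nfhw,nchwij->fcij", dout, v, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.einsum("nfhw,fcij->ncijhw", dout, w, optimize=True)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + wd] += dcols[:, :, di, dj]
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _pool_forward(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    return out, mask


def _pool_backward(dout, mask, shape):
    n, c, h, w = shape
    expanded = mask * dout[:, :, :, None, :, None]
    return expanded.reshape(n, c, h, w)


class ConvEmbedder:
    """3-block CNN embedder: crops (n, s, s) in [0, 1] -> unit 64-vectors."""

    def __init__(
        self,
        input_px: int = 64,
        channels: tuple[int, int, int] = (8, 16, 32),
        fc_hidden: int = 128,
        embedding_dim: int = 64,
        seed: int = 0,
    ):
        if input_px % 8 != 0:
            raise ValueError("input_px must be a multiple of 8 (three 2x2 pools)")
        self.input_px = input_px
        self.channels = channels
        self.embedding_dim = embedding_dim
        rng = np.random.default_rng([int(seed) % (2**31), 424242])
        c_prev = 1
        self.params: list[np.ndarray] = []
        self._conv_shapes = []
        for c_out in channels:
            for c_in in (c_prev, c_out):
                w = rng.normal(0, np.sqrt(2.0 / (c_in * 9)), size=(c_out, c_in, 3, 3)).astype(np.float32)
                self.params += [w, np.zeros(c_out, dtype=np.float32)]
            c_prev = c_out
        feat = channels[-1] * (input_px // 8) ** 2
        w1 = rng.normal(0, np.sqrt(2.0 / feat), size=(feat, fc_hidden)).astype(np.float32)
        w2 = rng.normal(0, np.sqrt(1.0 / fc_hidden), size=(fc_hidden, embedding_dim)).astype(np.float32)
        self.params += [w1, np.zeros(fc_hidden, dtype=np.float32), w2, np.zeros(embedding_dim, dtype=np.float32)]
        self._opt = None

    # -- forward / backward -------------------------------------------------

    def _forward(self, images: np.ndarray):
        x = (np.asarray(images, dtype=np.float32)[:, None] - 0.5) * 2.0
        if x.shape[2] != self.input_px or x.shape[3] != self.input_px:
            raise ValueError(f"expected {self.input_px}px square crops, got {x.shape[2:]}")
        cache = []
        pi = 0
        for _ in self.channels:
            for _ in range(2):
                w, b = self.params[pi], self.params[pi + 1]
                z, xp = _conv_forward(x, w, b)
                relu = z > 0
                x = z * relu
                cache.append(("conv", xp, w, relu))
                pi += 2
            x, mask = _pool_forward(x)
            cache.append(("pool", mask, x.shape))
        n = x.shape[0]
        pre_flat_shape = x.shape
        x = x.reshape(n, -1)
        w1, b1, w2, b2 = self.params[pi : pi + 4]
        z1 = x @ w1 + b1
        relu1 = z1 > 0
        h1 = z1 * relu1
        emb = h1 @ w2 + b2
        norm = np.sqrt((emb**2).sum(axis=1, keepdims=True) + 1e-12)
        out = emb / norm
        cache.append(("head", x, relu1, h1, emb, norm, pre_flat_shape))
        return out, cache

    def _backward(self, dout, cache):
        grads = [np.zeros_like(p) for p in self.params]
        kind, flat, relu1, h1, emb, norm, pre_flat_shape = cache[-1]
        assert kind == "head"
        y = emb / norm
        demb = (dout - y * (y * dout).sum(axis=1, keepdims=True)) / norm
        pi = len(self.params) - 4
        w1, _, w2, _ = self.params[pi : pi + 4]
        grads[pi + 2] = h1.T @ demb
        grads[pi + 3] = demb.sum(axis=0)
        dh1 = (demb @ w2.T) * relu1
        grads[pi] = flat.T @ dh1
        grads[pi + 1] = dh1.sum(axis=0)
        dx = (dh1 @ w1.T).reshape(pre_flat_shape)
        ci = pi - 2
        for item in reversed(cache[:-1]):
            if item[0] == "pool":
                _, mask, shape_after = item
                n, c, hh, ww = mask.shape[0], mask.shape[1], mask.shape[2] * 2, mask.shape[4] * 2
                dx = _pool_backward(dx, mask, (n, c, hh, ww))
            else:
                _, xp, w, relu = item
                dx, dw, db = _conv_backward(dx * relu, xp, w)
                grads[ci], grads[ci + 1] = dw, db
                ci -= 2
        return grads

    # -- public API ---------------------------------------------------------

    def embed(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Embed crops (n, s, s) into unit-norm (n, 64) vectors."""
        images = np.asarray(images, dtype=np.float64)
        outs = []
        for i in range(0, len(images), batch_size):
            out, _ = self._forward(images[i : i + batch_size])
            outs.append(out)
        return np.concatenate(outs) if outs else np.zeros((0, self.embedding_dim))

    def train_triplets(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 20,
        batch_size: int = 32,
        margin: float = 0.2,
        lr: float = 1e-3,
        seed: int = 0,
        verbose: bool = False,
    ) -> list[float]:
        """Train with within-batch triplet sampling; returns per-epoch losses.

        Each anchor is paired with a random same-label positive and a random
        different-label negative.  Raises on non-finite loss.
        """
        images = np.asarray(images, dtype=np.float64)
        labels = np.asarray(labels)
        ids = np.unique(labels)
        if len(ids) < 2:
            raise ValueError("need at least 2 identities to form triplets")
        by_id = {i: np.flatnonzero(labels == i) for i in ids}
        rng = np.random.default_rng([int(seed) % (2**31), 99991])
        if self._opt is None:
            self._opt = _Adam(self.params, lr=lr)
        history = []
        n = len(images)
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, n, batch_size):
                anchor_idx = order[s : s + batch_size]
                if len(anchor_idx) < 2:
                    continue
                pos_idx = np.array(
                    [rng.choice(by_id[labels[i]]) for i in anchor_idx]
                )
                neg_idx = np.array(
                    [rng.choice(by_id[rng.choice(ids[ids != labels[i]])]) for i in anchor_idx]
                )
                batch = np.concatenate([images[anchor_idx], images[pos_idx], images[neg_idx]])
                out, cache = self._forward(batch)
                b = len(anchor_idx)
                a, p, ng = out[:b], out[b : 2 * b], out[2 * b :]
                loss, ga, gp, gn = triplet_loss_grad(a, p, ng, margin)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite triplet loss at epoch {epoch}")
                dout = np.concatenate([ga, gp, gn])
                grads = self._backward(dout, cache)
                self._opt.step(self.params, grads)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}: loss {history[-1]:.4f}")
        return history

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            input_px=self.input_px,
            channels=np.array(self.channels),
            embedding_dim=self.embedding_dim,
            **{f"p{i}": p for i, p in enumerate(self.params)},
        )

    @classmethod
    def load(cls, path) -> "ConvEmbedder":
        data = np.load(path)
        obj = cls(
            input_px=int(data["input_px"]),
            channels=tuple(int(c) for c in data["channels"]),
            embedding_dim=int(data["embedding_dim"]),
        )
        obj.params = [data[f"p{i}"].copy() for i in range(len(obj.params))]
        return obj
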
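"""Individual re-identification from appearance.

High-resolution crops of individual animals carry idiosyncratic texture (for
larval zebrafish, the melanophore pigmentation pattern), which a small
convolutional network can embed into a space where images of the same
individual cluster.  The network is trained with a Euclidean triplet loss on
(anchor, positive, negative) crop triplets; validation is *temporal* -- the
earliest fraction of frames generates training images, the latest the test
images -- so the evaluation probes re-identification across time rather than
memorization of frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from scipy.ndimage import shift as nd_shift

from .nnet import ConvEmbedder, triplet_loss

__all__ = [
    "EmbedderSpec",
    "IdentityDataset",
    "build_identity_dataset",
    "train_embedder",
    "triplet_satisfaction",
    "identity_assignment",
    "triplet_loss",
]


@dataclass(frozen=True)
class EmbedderSpec:
    """Training configuration for the identity embedder.

    Defaults are desk-scale: 64 px inputs, 64-d embeddings, margin 0.2,
    62 epochs, batch 32, Adam.
    """

    input_px: int = 64
    channels: tuple[int, int, int] = (8, 16, 32)
    fc_hidden: int = 128
    embedding_dim: int = 64
    margin: float = 0.2
    epochs: int = 62
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")


@dataclass
class IdentityDataset:
    images: np.ndarray  # (n, s, s) float in [0, 1]
    labels: np.ndarray  # (n,) int identity
    timestamps: np.ndarray  # (n,) source frame time


def _augment(
    crop: np.ndarray,
    size: int,
    rng: np.random.Generator,
    max_rotation_deg: float = 15.0,
    flip: bool = False,
) -> np.ndarray:
    """Small rotation + optional flip + brightness jitter + shift, resized.

    Crops are assumed roughly canonically oriented (detection crops are
    aligned to the body axis before embedding), so augmentation jitters the
    orientation rather than randomizing it.
    """
    img = crop
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    img = nd_rotate(img, angle, reshape=False, order=1, mode="nearest")
    if flip and rng.random() < 0.5:
        img = img[:, ::-1]
    img = nd_shift(img, rng.uniform(-1.5, 1.5, size=2), order=1, mode="nearest")
    img = img * rng.uniform(0.85, 1.15) + rng.normal(0.0, 0.01)
    # resize to the target size by linear interpolation on the pixel grid
    h, w = img.shape
    ys = np.linspace(0, h - 1, size)
    xs = np.linspace(0, w - 1, size)
    tmp = np.empty((size, w))
    for i, y in enumerate(ys):
        y0 = min(int(y), h - 2)
        f = y - y0
        tmp[i] = img[y0] * (1 - f) + img[y0 + 1] * f
    out = np.empty((size, size))
    for j, x in enumerate(xs):
        x0 = min(int(x), w - 2)
        f = x - x0
        out[:, j] = tmp[:, x0] * (1 - f) + tmp[:, x0 + 1] * f
    return np.clip(out, 0.0, 1.0)


def build_identity_dataset(
    per_identity_crops: dict[int, list[tuple[float, np.ndarray]]],
    n_augmented_per_id: int = 250,
    temporal_split_fraction: float = 0.8,
    seed: int = 0,
    crop_px: int = 64,
    max_rotation_deg: float = 15.0,
    flip: bool = False,
) -> tuple[IdentityDataset, IdentityDataset]:
    """Augment time-stamped crops and split them temporally into train/test.

    ``per_identity_crops[identity]`` is a list of ``(timestamp, crop)``
    pairs.  Per identity, the earliest ``temporal_split_fraction`` of source
    crops (by timestamp) generate the training images and the remainder the
    test images -- the split is never random across time, so
    ``max(train timestamps) < min(test timestamps)`` whenever both sides are
    non-empty.  Augmentation (rotation, flip, brightness jitter, sub-pixel
    shifts) expands each identity to ``n_augmented_per_id`` images total.
    """
    if len(per_identity_crops) < 2:
        raise ValueError("need at least 2 identities")
    if not 0.0 < temporal_split_fraction <= 1.0:
        raise ValueError("temporal_split_fraction must be in (0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 808])
    tr_imgs, tr_lab, tr_t = [], [], []
    te_imgs, te_lab, te_t = [], [], []
    n_train_target = int(round(n_augmented_per_id * temporal_split_fraction))
    for ident in sorted(per_identity_crops):
        crops = sorted(per_identity_crops[ident], key=lambda p: p[0])
        if len(crops) < 2:
            raise ValueError(f"identity {ident} has fewer than 2 source crops")
        n_src_train = max(1, int(round(len(crops) * temporal_split_fraction)))
        if temporal_split_fraction >= 1.0:
            n_src_train = len(crops)
        train_src, test_src = crops[:n_src_train], crops[n_src_train:]
        for k in range(n_train_target):
            t, crop = train_src[k % len(train_src)]
            tr_imgs.append(_augment(crop, crop_px, rng, max_rotation_deg, flip))
            tr_lab.append(ident)
            tr_t.append(t)
        n_test_target = n_augmented_per_id - n_train_target
        if test_src:
            for k in range(n_test_target):
                t, crop = test_src[k % len(test_src)]
                te_imgs.append(_augment(crop, crop_px, rng, max_rotation_deg, flip))
                te_lab.append(ident)
                te_t.append(t)
    if not te_imgs:
        import warnings

        warnings.warn("temporal split produced an empty test set", stacklevel=2)
    train = IdentityDataset(
        images=np.array(tr_imgs), labels=np.array(tr_lab), timestamps=np.array(tr_t)
    )
    test = IdentityDataset(
        images=np.array(te_imgs) if te_imgs else np.zeros((0, crop_px, crop_px)),
        labels=np.array(te_lab, dtype=int),
        timestamps=np.array(te_t),
    )
    return train, test


def train_embedder(dataset: IdentityDataset, spec: EmbedderSpec | None = None) -> ConvEmbedder:
    """Train the triplet embedder on an identity dataset (deterministic per seed)."""
    spec = spec or EmbedderSpec()
    model = ConvEmbedder(
        input_px=spec.input_px,
        channels=spec.channels,
        fc_hidden=spec.fc_hidden,
        embedding_dim=spec.embedding_dim,
        seed=spec.seed,
    )
    history = model.train_triplets(
        dataset.images,
        dataset.labels,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        margin=spec.margin,
        lr=spec.learning_rate,
        seed=spec.seed,
    )
    model.training_history = history
    emb = model.embed(dataset.images[: min(len(dataset.images), 256)])
    # embedding collapse check: all training embeddings nearly identical
    model.collapsed = bool(np.linalg.norm(emb - emb.mean(axis=0), axis=1).max() < 1e-3)
    return model


def triplet_satisfaction(
    embeddings: np.ndarray, labels: np.ndarray, n_triplets: int = 2000, seed: int = 0
) -> float:
    """Fraction of random (a, p, n) triplets with ||a-p|| < ||a-n||."""
    rng = np.random.default_rng([int(seed) % (2**31), 313])
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need >= 2 identities")
    by_id = {i: np.flatnonzero(labels == i) for i in ids}
    ok = 0
    for _ in range(n_triplets):
        ia = rng.choice(ids)
        a, p = rng.choice(by_id[ia], size=2, replace=len(by_id[ia]) < 2)
        ng = rng.choice(by_id[rng.choice(ids[ids != ia])])
        d_ap = np.linalg.norm(embeddings[a] - embeddings[p])
        d_an = np.linalg.norm(embeddings[a] - embeddings[ng])
        ok += d_ap < d_an
    return ok / n_triplets


def identity_assignment(
    embeddings: np.ndarray,
    reference_embeddings: np.ndarray,
    reference_labels: np.ndarray,
    true_labels: np.ndarray | None = None,
):
    """Nearest-centroid identity assignment in embedding space.

    Returns ``(assigned_labels, purity)``; purity (fraction correctly
    assigned) is None unless ``true_labels`` is given.  With a single
    reference identity the assignment is trivially that identity (warned).
    """
    reference_embeddings = np.asarray(reference_embeddings)
    reference_labels = np.asarray(reference_labels)
    if len(reference_embeddings) == 0:
        raise ValueError("empty reference set")
    ids = np.unique(reference_labels)
    if len(ids) == 1:
        import warnings

        warnings.warn("single reference identity: purity is uninformative", stacklevel=2)
    centroids = np.stack([reference_embeddings[reference_labels == i].mean(axis=0) for i in ids])
    d = np.linalg.norm(np.asarray(embeddings)[:, None, :] - centroids[None], axis=2)
    assigned = ids[np.argmin(d, axis=1)]
    purity = None
    if true_labels is not None:
        purity = float(np.mean(assigned == np.asarray(true_labels)))
    return assigned, purity
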
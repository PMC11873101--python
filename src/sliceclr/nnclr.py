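"""Nearest-Neighbor Contrastive Learning (NNCLR).

NNCLR is an InfoNCE-style contrastive objective in which the anchor view's
projection is replaced by its nearest neighbor from a FIFO queue of recent
projections before similarities are computed. For a batch of N positive
pairs whose 2N projections are ordered (pair k occupies rows 2k and 2k+1,
0-based), the directed loss for views (i, j) is

    l_n(i, j) = -log  exp(cos(S(z_i, Q), z_j) / tau)
                      -----------------------------------------
                      sum_{k != i} exp(cos(S(z_i, Q), z_k) / tau)

with S(z, Q) the Euclidean nearest neighbor of z in the queue Q, and the
batch objective averages both directions of every pair. The denominator
runs over the 2N batch views only; queue entries act solely through the
nearest-neighbor substitution and are treated as constants during
backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import AdamW, Tensor, cosine_annealing_lr
from .augment import AugmentConfig, make_view_pair
from .backbone import ConvNeXtBackbone
from .volume import SliceRecord

__all__ = ["EmbeddingQueue", "ProjectionHead", "SSLConfig",
           "cosine_similarity", "nearest_neighbor",
           "nnclr_pair_loss", "batch_loss", "train_ssl"]

_NEG_MASK = -1e9  # exp(-1e9/1) underflows to exactly 0 in float64


class EmbeddingQueue:
    """Fixed-capacity FIFO of unit-normalized projection embeddings.

    Stored vectors are plain numpy arrays: they never carry gradient
    linkage to the live model. Oldest entries sit first.
    """

    def __init__(self, capacity: int = 8192):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._entries: np.ndarray | None = None

    def __len__(self) -> int:
        return 0 if self._entries is None else self._entries.shape[0]

    @property
    def vectors(self) -> np.ndarray:
        if self._entries is None:
            raise RuntimeError("queue is empty")
        return self._entries

    def push(self, new: np.ndarray) -> "EmbeddingQueue":
        """FIFO append (normalizing if needed); oldest entries are evicted."""
        new = np.atleast_2d(np.asarray(new, dtype=np.float64)).copy()
        norms = np.linalg.norm(new, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot enqueue a zero vector")
        new /= norms
        self._entries = new if self._entries is None else np.vstack(
            [self._entries, new])
        if self._entries.shape[0] > self.capacity:
            self._entries = self._entries[-self.capacity:]
        return self


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


def nearest_neighbor(z: np.ndarray, Q: EmbeddingQueue) -> np.ndarray:
    """Queue entry with minimal Euclidean distance to z (ties: oldest wins)."""
    if len(Q) == 0:
        raise RuntimeError("nearest-neighbor lookup on an empty queue")
    z = np.asarray(z, dtype=np.float64).ravel()
    d2 = ((Q.vectors - z) ** 2).sum(axis=1)
    return Q.vectors[int(np.argmin(d2))].copy()


def _nn_matrix(z: np.ndarray, Q: EmbeddingQueue) -> np.ndarray:
    """Row-wise nearest queue neighbors for a (M, d) stack of projections."""
    q = Q.vectors
    # ||z - q||^2 = ||z||^2 - 2 z.q + ||q||^2; argmin over q
    d2 = (z * z).sum(axis=1, keepdims=True) - 2.0 * z @ q.T + (q * q).sum(axis=1)
    return q[np.argmin(d2, axis=1)]


@dataclass
class ContrastiveBatch:
    """2N view projections ordered as (2k, 2k+1) pairs, plus a temperature."""

    projections: np.ndarray
    temperature: float = 0.1

    def __post_init__(self) -> None:
        self.projections = np.atleast_2d(
            np.asarray(self.projections, dtype=np.float64))
        if self.projections.shape[0] % 2 != 0:
            raise ValueError("a contrastive batch holds an even number of views")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_views(self) -> int:
        return self.projections.shape[0]

    def normalized(self) -> np.ndarray:
        z = self.projections
        norms = np.linalg.norm(z, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero projection vector")
        return z / norms


def nnclr_pair_loss(i: int, j: int, batch: ContrastiveBatch,
                    Q: EmbeddingQueue) -> float:
    """Directed NNCLR loss for the view pair (i, j) against the whole batch."""
    if i == j:
        raise ValueError("i and j must index distinct views")
    z = batch.normalized()
    m = batch.n_views
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError("view index out of range")
    nn_i = nearest_neighbor(z[i], Q)
    sims = (z @ nn_i) / batch.temperature        # cos(S(z_i,Q), z_k), all k
    sims[i] = _NEG_MASK                          # k != i in the denominator
    mx = sims.max()
    return float(np.log(np.exp(sims - mx).sum()) + mx - sims[j])


def batch_loss(batch: ContrastiveBatch, Q: EmbeddingQueue) -> float:
    """Symmetric batch objective: mean of both directions of every pair."""
    z = batch.normalized()
    loss = _loss_core(Tensor(z), _nn_matrix(z, Q), batch.temperature)
    return loss.item()


def _loss_core(z: Tensor, nn: np.ndarray, temperature: float) -> Tensor:
    """Differentiable batch loss; ``z`` unit rows, ``nn`` constant neighbors."""
    m = z.data.shape[0]
    partner = np.arange(m) ^ 1                   # 2k <-> 2k+1
    # sims[i, k] = cos(S(z_i, Q), z_k): anchors index rows, comparands columns
    sims = ad.matmul(Tensor(nn), ad.transpose2d(z))
    sims = ad.scale(sims, 1.0 / temperature)
    pos = ad.gather_pairs(sims, partner)
    masked = ad.add(sims, Tensor(np.diag(np.full(m, _NEG_MASK))))
    return ad.mean_all(ad.sub(ad.logsumexp_rows(masked), pos))


class ProjectionHead:
    """Two-layer MLP mapping pooled features to the contrastive space."""

    def __init__(self, in_dim: int, out_dim: int = 128, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9A0D)))
        self.w1 = Tensor(rng.normal(0, 0.02, (in_dim, in_dim)), requires_grad=True)
        self.b1 = Tensor(np.zeros(in_dim), requires_grad=True)
        self.w2 = Tensor(rng.normal(0, 0.02, (in_dim, out_dim)), requires_grad=True)
        self.b2 = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(ad.gelu(ad.linear(x, self.w1, self.b1)),
                         self.w2, self.b2)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


@dataclass
class SSLConfig:
    """Self-supervised pretraining settings.

    ``batch_size`` counts source slices per step; each contributes one
    positive pair, so the network sees 2 x batch_size views per step.
    Defaults mirror the full-scale protocol (1,000 epochs, batch 180,
    queue 8,192); scaled-down runs override them.
    """

    epochs: int = 1000
    batch_size: int = 180
    queue_size: int = 8192
    temperature: float = 0.1
    projection_dim: int = 128
    lr: float = 1e-4
    weight_decay: float = 1e-4
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 (at least 2 views)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def train_ssl(extractor: ConvNeXtBackbone, slices: list[SliceRecord],
              cfg: SSLConfig, checkpoint_dir: str | Path | None = None,
              checkpoint_every: int = 0,
              ) -> tuple[ConvNeXtBackbone, ProjectionHead, pd.DataFrame]:
    """NNCLR pretraining loop over a stream of coronal slices.

    Per step: augment a batch of slices into view pairs, embed and project,
    replace anchors by queue nearest neighbors, minimize the symmetric
    contrastive objective with AdamW, then enqueue the first view's
    projections. Returns the trained extractor, the projection head and a
    (step, epoch, loss) trace. Deterministic given ``cfg.seed``.
    """
    if len(slices) < 2:
        raise ValueError("need at least two slices for contrastive training")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x55D1)))
    head = ProjectionHead(extractor.cfg.embedding_dim,
                          cfg.projection_dim, seed=cfg.seed)
    params = extractor.parameters() + head.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    queue = EmbeddingQueue(cfg.queue_size)
    trace: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        opt.lr = cosine_annealing_lr(cfg.lr, epoch, max(cfg.epochs, 1))
        order = rng.permutation(len(slices))
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            if idx.size < 2:
                continue  # a single pair has zero loss and no gradient
            views = np.empty((2 * idx.size, *slices[idx[0]].pixels.shape))
            for r, si in enumerate(idx):
                pair = make_view_pair(slices[si], cfg.augment, rng)
                views[2 * r] = pair.view_a
                views[2 * r + 1] = pair.view_b
            feats = extractor.forward(Tensor(views[..., None]))
            z = ad.l2_normalize_rows(head(feats))
            if len(queue) == 0:
                queue.push(z.data)               # warm-up: seed with own batch
            loss = _loss_core(z, _nn_matrix(z.data, queue), cfg.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            queue.push(z.data[0::2])             # first view of every pair
            trace.append({"step": step, "epoch": epoch, "loss": loss.item()})
            step += 1
        if checkpoint_dir and checkpoint_every and (epoch + 1) % checkpoint_every == 0:
            extractor.save(Path(checkpoint_dir) / f"backbone_ep{epoch + 1:04d}.npz")
    return extractor, head, pd.DataFrame(trace)
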
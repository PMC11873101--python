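"""Linear probing of the frozen feature extractor, plus scan-level voting.

The classification head is a single fully-connected layer preceded by
layer normalization ("linear probing"). It is trained with cross-entropy
on slice-level labels — every coronal slice inherits its scan's diagnosis —
for 100 epochs by default, batch size 64, with a cosine-annealed learning
rate that warm-restarts every 20 epochs. At inference the head scores each
selected slice of a scan and the scan's final label is the modal slice
prediction (majority voting); ties go to the larger mean softmax score,
then to the lower class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import AdamW, Tensor, cosine_annealing_lr
from .backbone import ConvNeXtBackbone, embed_slices
from .volume import SliceRecord, Volume, prepare_slices

__all__ = ["ProbeConfig", "LinearProbe", "ScanPrediction",
           "extract_features", "train_probe", "train_probe_finetune",
           "majority_vote", "predict_scan", "participant_split"]


@dataclass
class ProbeConfig:
    """Training settings for the classification head."""

    n_classes: int = 2
    class_names: tuple[str, ...] = ()
    freeze_backbone: bool = True
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-2
    restart_period: int = 20      # cosine annealing restarts, in epochs
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not self.class_names:
            self.class_names = tuple(f"class{k}" for k in range(self.n_classes))
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names must match n_classes")
        if self.restart_period < 1:
            raise ValueError("restart_period must be >= 1")


class LinearProbe:
    """Layer normalization followed by one fully-connected layer."""

    def __init__(self, in_dim: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9EAD)))
        self.in_dim = in_dim
        self.n_classes = n_classes
        self.ln_g = Tensor(np.ones(in_dim), requires_grad=True)
        self.ln_b = Tensor(np.zeros(in_dim), requires_grad=True)
        self.w = Tensor(rng.normal(0, 0.02, (in_dim, n_classes)), requires_grad=True)
        self.b = Tensor(np.zeros(n_classes), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(ad.layer_norm(x, self.ln_g, self.ln_b), self.w, self.b)

    def logits(self, features: np.ndarray) -> np.ndarray:
        return self(Tensor(np.atleast_2d(features))).data

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Row-wise softmax class probabilities."""
        lg = self.logits(features)
        lg = lg - lg.max(axis=1, keepdims=True)
        e = np.exp(lg)
        return e / e.sum(axis=1, keepdims=True)

    def parameters(self) -> list[Tensor]:
        return [self.ln_g, self.ln_b, self.w, self.b]

    def save(self, path: str | Path) -> None:
        np.savez(path, ln_g=self.ln_g.data, ln_b=self.ln_b.data,
                 w=self.w.data, b=self.b.data)

    @classmethod
    def load(cls, path: str | Path) -> "LinearProbe":
        with np.load(path) as z:
            head = cls(int(z["w"].shape[0]), int(z["w"].shape[1]))
            head.ln_g.data, head.ln_b.data = z["ln_g"], z["ln_b"]
            head.w.data, head.b.data = z["w"], z["b"]
        return head


def extract_features(extractor: ConvNeXtBackbone,
                     slices: list[SliceRecord]) -> pd.DataFrame:
    """One embedding row per slice, with provenance columns attached."""
    emb = embed_slices(extractor, slices)
    df = pd.DataFrame(emb, columns=[f"f{i}" for i in range(emb.shape[1])])
    df["volume_id"] = [s.volume_id for s in slices]
    df["participant_id"] = [s.participant_id for s in slices]
    df["slice_index"] = [s.slice_index for s in slices]
    df["label"] = [s.label for s in slices]
    return df


def _label_indices(labels, class_names: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    try:
        return np.array([index[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc} not among classes {class_names}") from exc


def train_probe(features: np.ndarray, labels, cfg: ProbeConfig) -> LinearProbe:
    """Train the head on precomputed (frozen-backbone) slice features."""
    features = np.asarray(features, dtype=np.float64)
    y = _label_indices(labels, cfg.class_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    head = LinearProbe(features.shape[1], cfg.n_classes, seed=cfg.seed)
    opt = AdamW(head.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x50B3)))
    n = features.shape[0]
    for epoch in range(cfg.epochs):
        opt.lr = cosine_annealing_lr(cfg.lr, epoch, cfg.restart_period)
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = head(Tensor(features[idx]))
            loss = ad.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    return head


def train_probe_finetune(extractor: ConvNeXtBackbone, slices: list[SliceRecord],
                         cfg: ProbeConfig) -> LinearProbe:
    """Unfrozen variant: the backbone is fine-tuned at 0.1x the head rate."""
    y = _label_indices([s.label for s in slices], cfg.class_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    head = LinearProbe(extractor.cfg.embedding_dim, cfg.n_classes, seed=cfg.seed)
    opt_head = AdamW(head.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    opt_back = AdamW(extractor.parameters(), lr=0.1 * cfg.lr,
                     weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x50B3)))
    n = len(slices)
    for epoch in range(cfg.epochs):
        lr = cosine_annealing_lr(cfg.lr, epoch, cfg.restart_period)
        opt_head.lr, opt_back.lr = lr, 0.1 * lr
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            stack = np.stack([slices[i].pixels for i in idx])[..., None]
            logits = head(extractor.forward(Tensor(stack)))
            loss = ad.softmax_cross_entropy(logits, y[idx])
            opt_head.zero_grad()
            opt_back.zero_grad()
            loss.backward()
            opt_head.step()
            opt_back.step()
    return head


def majority_vote(labels: list, scores: list[np.ndarray] | None = None):
    """Modal label; ties broken by larger mean score, then lower class order.

    ``labels`` may be class indices or names; ``scores`` are per-slice
    class-score vectors aligned with a sorted unique-label order only when
    labels are integer indices.
    """
    if len(labels) == 0:
        raise ValueError("cannot vote over an empty label list")
    uniq, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = uniq[counts == top]
    if len(tied) == 1 or scores is None:
        return tied[0].item() if hasattr(tied[0], "item") else tied[0]
    means = np.mean(np.stack(scores), axis=0)
    best, best_score = None, -np.inf
    for lab in tied:  # uniq is sorted, so the first strict max wins
        s = float(means[int(lab)]) if np.issubdtype(type(lab), np.integer) \
            else -np.inf
        if s > best_score:
            best, best_score = lab, s
    return best.item() if hasattr(best, "item") else best


@dataclass
class ScanPrediction:
    """Slice-level votes and the resulting scan-level assignment."""

    volume_id: str
    slice_labels: list[int]
    slice_scores: np.ndarray
    final_label: str
    vote_margin: int
    mean_scores: np.ndarray


def predict_scan(extractor: ConvNeXtBackbone, head: LinearProbe,
                 volume: Volume, n_keep: int,
                 class_names: tuple[str, ...]) -> ScanPrediction:
    """Score every selected slice of a scan and majority-vote the label."""
    slices = prepare_slices(volume, n_keep)
    feats = embed_slices(extractor, slices)
    scores = head.scores(feats)
    slice_labels = scores.argmax(axis=1)
    final_idx = majority_vote(list(slice_labels), list(scores))
    counts = np.bincount(slice_labels, minlength=head.n_classes)
    ranked = np.sort(counts)[::-1]
    margin = int(ranked[0] - (ranked[1] if len(ranked) > 1 else 0))
    return ScanPrediction(
        volume_id=volume.volume_id,
        slice_labels=[int(l) for l in slice_labels],
        slice_scores=scores,
        final_label=class_names[int(final_idx)],
        vote_margin=margin,
        mean_scores=scores.mean(axis=0),
    )


def participant_split(manifest: pd.DataFrame, test_fraction: float = 0.1,
                      n_trials: int = 3, seed: int = 0,
                      ) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Grouped train/test splits: all scans of a participant stay together.

    Splitting is stratified by diagnosis so every class appears on both
    sides; within each class, whole participants are drawn at random until
    the test side holds about ``test_fraction`` of that class's scans.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if "participant_id" not in manifest.columns:
        raise ValueError("manifest lacks a participant_id column")
    splits = []
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence((seed, trial, 0x5911)))
        test_pids: set[str] = set()
        for _, group in manifest.groupby("diagnosis", sort=True):
            pids = group["participant_id"].unique()
            scans_per_pid = group.groupby("participant_id").size()
            target = test_fraction * len(group)
            got = 0
            for pid in rng.permutation(pids):
                if got >= target:
                    break
                test_pids.add(pid)
                got += int(scans_per_pid[pid])
        is_test = manifest["participant_id"].isin(test_pids)
        train, test = manifest[~is_test].copy(), manifest[is_test].copy()
        if train.empty or test.empty:
            raise ValueError("degenerate split: empty train or test set")
        splits.append((train, test))
    return splits
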
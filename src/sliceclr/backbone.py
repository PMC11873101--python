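"""ConvNeXt-style 2D convolutional feature extractor.

The architecture follows the ConvNeXt recipe: a 4x4/stride-4 patchify stem,
four stages of residual blocks separated by 2x2/stride-2 downsampling, each
block being a depthwise 7x7 convolution, layer normalization, an inverted
bottleneck (pointwise expand 4x, GELU, pointwise project) and a learnable
per-channel layer scale. Features are taken after global average pooling
and a final layer normalization, giving one embedding per slice whose
length equals the last stage's channel count (768 for the tiny variant
with depths (3, 3, 9, 3) and channels (96, 192, 384, 768)).

Input slices are grayscale; internally the layout is channels-last
(B, H, W, C) in float64.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .volume import SliceRecord

__all__ = ["BackboneConfig", "TINY", "TEST_TINY", "ConvNeXtBackbone",
           "build_backbone", "embed_slices"]


@dataclass(frozen=True)
class BackboneConfig:
    """Stage depths and channel widths of the feature extractor."""

    depths: tuple[int, int, int, int] = (3, 3, 9, 3)
    channels: tuple[int, int, int, int] = (96, 192, 384, 768)
    input_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.depths) != 4 or len(self.channels) != 4:
            raise ValueError("depths and channels must each have length 4")
        if min(self.depths) < 1 or min(self.channels) < 1:
            raise ValueError("depths and channels entries must be >= 1")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")

    @property
    def embedding_dim(self) -> int:
        return self.channels[-1]


TINY = BackboneConfig()
# small enough for unit tests and CPU-scale end-to-end runs
TEST_TINY = BackboneConfig(depths=(1, 1, 1, 1), channels=(8, 16, 32, 64))


class _Block:
    """One ConvNeXt residual block."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dw_w = Tensor(rng.normal(0, 0.02, (7, 7, dim)), requires_grad=True)
        self.dw_b = Tensor(np.zeros(dim), requires_grad=True)
        self.ln_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln_b = Tensor(np.zeros(dim), requires_grad=True)
        self.fc1_w = Tensor(rng.normal(0, 0.02, (dim, 4 * dim)), requires_grad=True)
        self.fc1_b = Tensor(np.zeros(4 * dim), requires_grad=True)
        self.fc2_w = Tensor(rng.normal(0, 0.02, (4 * dim, dim)), requires_grad=True)
        self.fc2_b = Tensor(np.zeros(dim), requires_grad=True)
        self.gamma = Tensor(np.full(dim, 1e-6), requires_grad=True)  # layer scale

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.depthwise_conv(x, self.dw_w, self.dw_b)
        y = ad.layer_norm(y, self.ln_g, self.ln_b)
        y = ad.linear(y, self.fc1_w, self.fc1_b)
        y = ad.gelu(y)
        y = ad.linear(y, self.fc2_w, self.fc2_b)
        y = ad.mul(y, self.gamma)
        return ad.add(x, y)

    def parameters(self) -> list[Tensor]:
        return [self.dw_w, self.dw_b, self.ln_g, self.ln_b,
                self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b, self.gamma]


class ConvNeXtBackbone:
    """Feature extractor mapping slice batches to pooled embeddings."""

    def __init__(self, cfg: BackboneConfig = TINY, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
        c = cfg.channels
        self.stem_w = Tensor(rng.normal(0, 0.02, (16 * cfg.input_channels, c[0])),
                             requires_grad=True)
        self.stem_b = Tensor(np.zeros(c[0]), requires_grad=True)
        self.stem_ln = (Tensor(np.ones(c[0]), requires_grad=True),
                        Tensor(np.zeros(c[0]), requires_grad=True))
        self.stages: list[list[_Block]] = [
            [_Block(c[i], rng) for _ in range(cfg.depths[i])] for i in range(4)]
        self.down: list[tuple] = []  # (ln_g, ln_b, w, b) between stages
        for i in range(3):
            self.down.append((
                Tensor(np.ones(c[i]), requires_grad=True),
                Tensor(np.zeros(c[i]), requires_grad=True),
                Tensor(rng.normal(0, 0.02, (4 * c[i], c[i + 1])), requires_grad=True),
                Tensor(np.zeros(c[i + 1]), requires_grad=True),
            ))
        self.final_ln = (Tensor(np.ones(c[-1]), requires_grad=True),
                         Tensor(np.zeros(c[-1]), requires_grad=True))

    # -- forward -----------------------------------------------------------

    def forward(self, x: Tensor) -> Tensor:
        """(B, H, W, C_in) slices -> (B, embedding_dim) pooled features."""
        if x.data.ndim != 4:
            raise ValueError(f"expected (B, H, W, C) input, got {x.data.shape}")
        y = ad.patch_conv(x, self.stem_w, self.stem_b, k=4)
        y = ad.layer_norm(y, *self.stem_ln)
        for i in range(4):
            if i > 0:
                ln_g, ln_b, w, b = self.down[i - 1]
                y = ad.layer_norm(y, ln_g, ln_b)
                y = ad.patch_conv(y, w, b, k=2)
            for block in self.stages[i]:
                y = block(y)
        y = ad.global_avg_pool(y)
        return ad.layer_norm(y, *self.final_ln)

    def embed(self, slices: np.ndarray) -> np.ndarray:
        """Deterministic embeddings for a (B, H, W) stack; no graph kept."""
        x = Tensor(np.asarray(slices, dtype=np.float64)[..., None])
        return self.forward(x).data

    __call__ = forward

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.stem_w, self.stem_b, *self.stem_ln]
        for stage in self.stages:
            for block in stage:
                params.extend(block.parameters())
        for group in self.down:
            params.extend(group)
        params.extend(self.final_ln)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match this configuration")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64)

    def checksum(self) -> float:
        """Order-sensitive digest of all weights; unchanged iff weights unchanged."""
        return float(sum((i + 1) * float(np.abs(p.data).sum())
                         for i, p in enumerate(self.parameters())))

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict(),
                 depths=np.array(self.cfg.depths),
                 channels=np.array(self.cfg.channels),
                 input_channels=np.array(self.cfg.input_channels))

    @classmethod
    def load(cls, path: str | Path) -> "ConvNeXtBackbone":
        with np.load(path) as z:
            cfg = BackboneConfig(
                depths=tuple(int(d) for d in z["depths"]),
                channels=tuple(int(c) for c in z["channels"]),
                input_channels=int(z["input_channels"]))
            model = cls(cfg)
            model.load_state_dict(
                {k: z[k] for k in z.files if k.startswith("p")})
        return model


def build_backbone(cfg: BackboneConfig = TINY, pretrained: bool = False,
                   checkpoint: str | Path | None = None,
                   seed: int = 0) -> ConvNeXtBackbone:
    """Construct a backbone; seeded random init or a saved checkpoint.

    ``pretrained=True`` without a checkpoint path is an error: this package
    ships no natural-image weights, so "pretrained" always means a
    checkpoint produced by an earlier run (e.g. SSL pretraining).
    """
    if checkpoint is not None:
        model = ConvNeXtBackbone.load(checkpoint)
        if model.cfg != cfg:
            raise ValueError(
                f"checkpoint config {model.cfg} does not match requested {cfg}")
        return model
    if pretrained:
        raise ValueError(
            "pretrained=True requires a checkpoint path; no published weights "
            "are bundled with this package")
    return ConvNeXtBackbone(cfg, seed=seed)


def embed_slices(extractor: ConvNeXtBackbone, batch: list[SliceRecord],
                 chunk: int = 64) -> np.ndarray:
    """Pooled embeddings for a list of slice records (uniform shape required)."""
    if not batch:
        return np.zeros((0, extractor.cfg.embedding_dim))
    shape = batch[0].pixels.shape
    if any(s.pixels.shape != shape for s in batch):
        raise ValueError("all slices in a batch must share a shape")
    out = []
    for i in range(0, len(batch), chunk):
        stack = np.stack([s.pixels for s in batch[i:i + chunk]])
        out.append(extractor.embed(stack))
    return np.concatenate(out, axis=0)
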
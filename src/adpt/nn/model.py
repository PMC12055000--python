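"""The cascaded CNN-transformer pose network.

A convolutional backbone produces 1/4-scale features; three branches then
compute features at 1/4, 1/8 and 1/16 of the input resolution, the 1/16
branch additionally passing through a transformer encoder (flatten to
tokens, add positional encodings, self-attention) to capture global
context. All branches are brought to 1/8 scale (stride-2 convolution for
the 1/4 branch, transposed convolution for the 1/16 branch), concatenated
with skip connections and fused by convolutions into four heads:

* ``heatmap`` — K keypoint confidence maps (linear),
* ``locref`` — 2K location-refinement offset maps (linear),
* ``lrss`` — ``n_identities + 1`` segmentation logits (softmax at decode),
* ``baf`` — 2 body-affinity-field channels (linear, optional).

Two backbone presets exist: ``tiny`` (two stride-2 conv blocks, suitable
for CPU-scale experiments) and ``resnet`` (7x7/2 stem + max-pool + one
bottleneck stage, mirroring the first stages of a 50-layer residual
network). Inputs whose sides are not divisible by 16 are zero-padded and
the padding recorded; heads are returned for the padded geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .layers import (
    Conv2d,
    ConvTranspose2d,
    MaxPool2d,
    Module,
    TransformerEncoder,
)
from .tensor import Tensor, concat

__all__ = ["ModelSpec", "PoseModel", "build_model"]


@dataclass
class ModelSpec:
    n_keypoints: int
    n_identities: int = 1
    backbone: str = "tiny"            # "tiny" or "resnet"
    backbone_width: int = 32          # channels of the 1/4-scale features
    branch_width: int = 48            # channels of each 1/8-scale branch
    fuse_width: int = 96              # channels after fusion
    transformer_layers: int = 2
    transformer_heads: int = 4
    transformer_dim: int = 48         # embedding dim of the 1/16 tokens
    transformer_base_grid: tuple[int, int] = (4, 4)
    with_transformer: bool = True
    with_lrss: bool = True
    with_baf: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transformer_base_grid"] = list(d["transformer_base_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "transformer_base_grid" in d:
            d["transformer_base_grid"] = tuple(d["transformer_base_grid"])
        return cls(**d)


class _Bottleneck(Module):
    def __init__(self, cin, mid, cout, rng):
        self.c1 = Conv2d(cin, mid, kernel=1, rng=rng)
        self.c2 = Conv2d(mid, mid, kernel=3, rng=rng)
        self.c3 = Conv2d(mid, cout, kernel=1, rng=rng)
        self.proj = Conv2d(cin, cout, kernel=1, rng=rng) if cin != cout else None

    def forward(self, x):
        y = self.c3(self.c2(self.c1(x).relu()).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).relu()


class _TinyBackbone(Module):
    """Two stride-2 conv blocks -> 1/4-scale features."""

    def __init__(self, width, rng):
        self.c1 = Conv2d(3, max(24, width // 2), kernel=5, stride=2, padding=2, rng=rng)
        self.c2 = Conv2d(max(24, width // 2), width, kernel=3, stride=2, rng=rng)

    def forward(self, x):
        return self.c2(self.c1(x).relu()).relu()


class _ResNetStage12(Module):
    """7x7/2 stem + 3x3/2 max-pool + one 3-block bottleneck stage (1/4 scale)."""

    def __init__(self, width, rng):
        self.stem = Conv2d(3, 64, kernel=7, stride=2, padding=3, rng=rng)
        self.pool = MaxPool2d(kernel=3, stride=2, padding=1)
        self.blocks = [
            _Bottleneck(64, 64, width, rng),
            _Bottleneck(width, 64, width, rng),
            _Bottleneck(width, 64, width, rng),
        ]

    def forward(self, x):
        x = self.pool(self.stem(x).relu())
        for b in self.blocks:
            x = b(x)
        return x


class PoseModel(Module):
    STRIDE = 8

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        bw, br = spec.backbone_width, spec.branch_width
        if spec.backbone == "tiny":
            self.backbone = _TinyBackbone(bw, rng)
        elif spec.backbone == "resnet":
            self.backbone = _ResNetStage12(256 if bw <= 32 else bw, rng)
            bw = 256 if bw <= 32 else bw
        else:
            raise ValueError(f"unknown backbone {spec.backbone!r}")
        # 1/4 branch: refine then bring down to 1/8
        self.b4_c1 = Conv2d(bw, br, kernel=3, rng=rng)
        self.b4_down = Conv2d(br, br, kernel=3, stride=2, rng=rng)
        # 1/8 branch
        self.b8_down = Conv2d(bw, br, kernel=3, stride=2, rng=rng)
        self.b8_c1 = Conv2d(br, br, kernel=3, rng=rng)
        # 1/16 branch (+ transformer) then back up to 1/8
        td = spec.transformer_dim
        self.b16_d1 = Conv2d(bw, br, kernel=3, stride=2, rng=rng)
        self.b16_d2 = Conv2d(br, td, kernel=3, stride=2, rng=rng)
        if spec.with_transformer:
            self.transformer = TransformerEncoder(
                td,
                spec.transformer_layers,
                spec.transformer_heads,
                base_grid=spec.transformer_base_grid,
                rng=rng,
            )
        else:
            self.transformer = None
        self.b16_up = ConvTranspose2d(td, br, stride=2, rng=rng)
        # fusion + heads
        self.fuse = Conv2d(3 * br, spec.fuse_width, kernel=3, rng=rng)
        k = spec.n_keypoints
        self.head_heatmap = Conv2d(spec.fuse_width, k, kernel=1, rng=rng)
        self.head_locref = Conv2d(spec.fuse_width, 2 * k, kernel=1, rng=rng)
        self.head_lrss = (
            Conv2d(spec.fuse_width, spec.n_identities + 1, kernel=1, rng=rng)
            if spec.with_lrss
            else None
        )
        self.head_baf = (
            Conv2d(spec.fuse_width, 2, kernel=1, rng=rng) if spec.with_baf else None
        )
        self.last_padding: tuple[int, int] = (0, 0)

    # -- forward ---------------------------------------------------------
    def forward(self, x: Tensor) -> dict[str, Tensor]:
        """Map an image batch (N, 3, H, W) to head tensors at 1/8 scale."""
        n, c, h, w = x.shape
        ph = (-h) % 16
        pw = (-w) % 16
        self.last_padding = (ph, pw)
        if ph or pw:
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw))), _prev=(x,))
            x._backward = None  # inference-side padding; inputs carry no grad
        f4 = self.backbone(x)
        a = self.b4_down(self.b4_c1(f4).relu()).relu()
        b = self.b8_c1(self.b8_down(f4).relu()).relu()
        c16 = self.b16_d2(self.b16_d1(f4).relu()).relu()
        if self.transformer is not None:
            nb, dc, gh, gw = c16.shape
            tokens = c16.reshape(nb, dc, gh * gw).transpose(0, 2, 1)
            tokens = self.transformer(tokens, (gh, gw))
            c16 = tokens.transpose(0, 2, 1).reshape(nb, dc, gh, gw)
        cup = self.b16_up(c16).relu()
        fused = self.fuse(concat([a, b, cup], axis=1)).relu()
        heads = {
            "heatmap": self.head_heatmap(fused),
            "locref": self.head_locref(fused),
        }
        if self.head_lrss is not None:
            heads["lrss"] = self.head_lrss(fused)
        if self.head_baf is not None:
            heads["baf"] = self.head_baf(fused)
        return heads

    def predict(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Forward a (N, H, W, 3) uint8/float batch; returns numpy heads."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        x = x.transpose(0, 3, 1, 2) / 255.0
        heads = self.forward(Tensor(x))
        return {k: v.data for k, v in heads.items()}


def build_model(spec: ModelSpec, seed: int = 0) -> PoseModel:
    """Instantiate the network with reproducible random initialization."""
    return PoseModel(spec, rng=np.random.default_rng(seed))
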
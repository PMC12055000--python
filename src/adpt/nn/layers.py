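"""Layer modules on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Parameter,
    Tensor,
    conv2d,
    conv_transpose2d,
    layer_norm,
    maxpool2d,
    softmax,
)

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "LayerNorm",
    "MaxPool2d",
    "MultiHeadAttention",
    "TransformerEncoderLayer",
    "TransformerEncoder",
]


class Module:
    def parameters(self) -> list[Parameter]:
        out, seen = [], set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("parameter count mismatch in checkpoint")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(p.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, padding=None, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.w = Parameter(_he(rng, (cout, cin, kernel, kernel), cin * kernel * kernel))
        self.b = Parameter(np.zeros(cout, dtype=np.float32), decay=False) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Upsampling transposed convolution with kernel size == stride."""

    def __init__(self, cin, cout, stride=2, rng=None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.w = Parameter(_he(rng, (cin, cout, stride, stride), cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b, stride=self.stride)


class Linear(Module):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        self.w = Parameter(_he(rng, (cin, cout), cin))
        self.b = Parameter(np.zeros(cout, dtype=np.float32), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32), decay=False)
        self.beta = Parameter(np.zeros(dim, dtype=np.float32), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MaxPool2d(Module):
    def __init__(self, kernel=2, stride=None, padding=0):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class MultiHeadAttention(Module):
    def __init__(self, dim, n_heads, rng=None):
        if dim % n_heads:
            raise ValueError("embed dim must divide by head count")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(n, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (n, h, t, hd)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        att = softmax(att, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: LN -> MHA -> residual, LN -> MLP -> residual."""

    def __init__(self, dim, n_heads, mlp_ratio=2, rng=None):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng=rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng=rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


class TransformerEncoder(Module):
    """Token encoder with learned 2-D positional embeddings.

    Positional embeddings are learned on a base grid and bilinearly
    interpolated (as a fixed linear map, so gradients flow) when the token
    grid of the incoming feature map differs from the base grid.
    """

    def __init__(self, dim, n_layers, n_heads, base_grid=(4, 4), mlp_ratio=2, rng=None):
        rng = rng or np.random.default_rng()
        self.base_grid = tuple(base_grid)
        n_base = base_grid[0] * base_grid[1]
        self.pos = Parameter(
            (rng.standard_normal((n_base, dim)) * 0.02).astype(np.float32), decay=False
        )
        self.layers = [
            TransformerEncoderLayer(dim, n_heads, mlp_ratio, rng=rng)
            for _ in range(n_layers)
        ]
        self.ln = LayerNorm(dim)
        self._interp_cache: dict[tuple[int, int], np.ndarray] = {}

    def _interp_matrix(self, grid: tuple[int, int]) -> np.ndarray:
        """(grid_h*grid_w, base_h*base_w) bilinear interpolation weights."""
        if grid in self._interp_cache:
            return self._interp_cache[grid]
        bh, bw = self.base_grid
        gh, gw = grid
        mat = np.zeros((gh * gw, bh * bw), dtype=np.float32)
        ys = np.linspace(0, bh - 1, gh) if gh > 1 else np.array([(bh - 1) / 2])
        xs = np.linspace(0, bw - 1, gw) if gw > 1 else np.array([(bw - 1) / 2])
        for r, y in enumerate(ys):
            y0 = int(np.floor(y)); y1 = min(y0 + 1, bh - 1); fy = y - y0
            for c, x in enumerate(xs):
                x0 = int(np.floor(x)); x1 = min(x0 + 1, bw - 1); fx = x - x0
                t = r * gw + c
                mat[t, y0 * bw + x0] += (1 - fy) * (1 - fx)
                mat[t, y0 * bw + x1] += (1 - fy) * fx
                mat[t, y1 * bw + x0] += fy * (1 - fx)
                mat[t, y1 * bw + x1] += fy * fx
        self._interp_cache[grid] = mat
        return mat

    def forward(self, x: Tensor, grid: tuple[int, int]) -> Tensor:
        """x: (N, T, D) tokens from a (grid_h, grid_w) feature map."""
        if grid == self.base_grid:
            pos = self.pos
        else:
            pos = Tensor(self._interp_matrix(grid)) @ self.pos
        x = x + pos.reshape(1, grid[0] * grid[1], -1)
        for layer in self.layers:
            x = layer(x)
        return self.ln(x)
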
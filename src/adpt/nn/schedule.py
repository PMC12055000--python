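"""Warmup-cosine learning-rate schedule.

The rate ramps linearly from ``lr_min`` to ``lr_max`` over the warm-up
epochs, then decays back to ``lr_min`` along a half cosine over the
remaining epochs.
"""

from __future__ import annotations

import numpy as np

from ..config import Config

__all__ = ["lr_at", "total_steps"]


def total_steps(config: Config, iters_per_epoch: int | None = None) -> int:
    iters = iters_per_epoch or config.iters_per_epoch or 1
    return config.epochs * iters


def lr_at(step: int, config: Config, iters_per_epoch: int | None = None) -> float:
    """Learning rate at a global step (0 <= step <= total_steps)."""
    iters = iters_per_epoch or config.iters_per_epoch or 1
    warm = config.warmup_epochs * iters
    total = config.epochs * iters
    step = min(max(step, 0), total)
    if step <= warm and warm > 0:
        return config.lr_min + (config.lr_max - config.lr_min) * step / warm
    if total <= warm:
        return config.lr_max
    t = (step - warm) / (total - warm)
    return config.lr_min + (config.lr_max - config.lr_min) * 0.5 * (1.0 + np.cos(np.pi * t))
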
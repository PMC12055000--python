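"""Training-time similarity-transform augmentation.

Three parameter sets are available as modes:

* ``identity_task`` — rotation +-30 deg, translation x in [-100, 100],
  y in [-30, 15] px, scale in [0.9, 1.1] (multi-individual identity
  training protocol);
* ``social_task`` — translation only, same ranges, no rotation or scaling
  (social-interaction training protocol);
* ``default`` — the configurable general-purpose ranges in Config.

Image and keypoints are moved by the same sampled similarity transform;
keypoints pushed outside the image become invisible. A fixed seed gives a
bit-identical result.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import SimilarityTransform, warp

from .config import Config
from .frames import Instance, LabeledFrame

__all__ = ["sample_augmentation", "transform_frame", "augment_frame"]

MODES = ("identity_task", "social_task", "default")


def sample_augmentation(rng: np.random.Generator, mode: str, config: Config | None = None):
    """Sample (rotation_deg, tx, ty, scale) for the given mode."""
    if mode == "identity_task":
        rot = rng.uniform(-30.0, 30.0)
        tx = rng.uniform(-100.0, 100.0)
        ty = rng.uniform(-30.0, 15.0)
        scale = rng.uniform(0.9, 1.1)
    elif mode == "social_task":
        rot = 0.0
        tx = rng.uniform(-100.0, 100.0)
        ty = rng.uniform(-30.0, 15.0)
        scale = 1.0
    elif mode == "default":
        cfg = config or Config()
        rot = rng.uniform(-cfg.aug_rotation, cfg.aug_rotation)
        tx = rng.uniform(*cfg.aug_translate_x)
        ty = rng.uniform(*cfg.aug_translate_y)
        scale = rng.uniform(*cfg.aug_scale)
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}; expected one of {MODES}")
    return rot, tx, ty, scale


def _similarity(frame: LabeledFrame, rotation: float, tx: float, ty: float, scale: float):
    """Forward transform: rotate/scale about the image center, then translate."""
    cy = (frame.height - 1) / 2.0
    cx = (frame.width - 1) / 2.0
    to_origin = SimilarityTransform(translation=(-cx, -cy))
    rs = SimilarityTransform(rotation=np.deg2rad(rotation), scale=scale)
    back = SimilarityTransform(translation=(cx + tx, cy + ty))
    return to_origin + rs + back


def transform_frame(
    frame: LabeledFrame, rotation: float, translation=(0.0, 0.0), scale: float = 1.0
) -> LabeledFrame:
    """Apply one explicit similarity transform to image and keypoints."""
    tform = _similarity(frame, rotation, translation[0], translation[1], scale)
    identity_params = rotation == 0.0 and scale == 1.0 and translation == (0.0, 0.0)
    h, w = frame.height, frame.width
    if identity_params:
        image = frame.image.copy()
    else:
        src = frame.image.astype(np.float64)
        warped = warp(
            src, tform.inverse, order=1, preserve_range=True, mode="constant", cval=0.0
        )
        image = warped
        if frame.image.dtype == np.uint8:
            image = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    instances = []
    for inst in frame.instances:
        kp = tform(inst.keypoints)
        inside = (
            (kp[:, 0] >= -0.5)
            & (kp[:, 0] <= w - 0.5)
            & (kp[:, 1] >= -0.5)
            & (kp[:, 1] <= h - 0.5)
        )
        instances.append(Instance(inst.identity, kp, inst.visibility & inside))
    return LabeledFrame(image, instances, name=frame.name)


def augment_frame(
    frame: LabeledFrame,
    rng_seed: int,
    mode: str = "default",
    config: Config | None = None,
) -> LabeledFrame:
    """Randomly augment a frame; the same seed reproduces the same output."""
    rng = np.random.default_rng(rng_seed)
    rot, tx, ty, scale = sample_augmentation(rng, mode, config)
    return transform_frame(frame, rot, (tx, ty), scale)
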
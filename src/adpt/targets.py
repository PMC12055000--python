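"""Training-target encoding: confidence heatmaps, location refinement,
low-resolution semantic segmentation (LRSS) and body affinity fields (BAF).

All four targets live on one head grid of shape ``(ceil(H/stride),
ceil(W/stride))``. Head cell ``(r, c)`` represents the image point
``(c * stride, r * stride)``; a keypoint at image position ``p`` maps to
``p / stride`` in head-grid units. The heatmap for keypoint ``k`` is an
isotropic Gaussian of that distance with the cell nearest the keypoint
forced to exactly 1, so the argmax cell plus its location-refinement
offset reconstructs the keypoint coordinate exactly.

LRSS paints every limb segment of every instance, at head resolution, with
the instance identity (or 1 in the identity-free variant); everything else
is 0. BAF stores, on each body cell ``p`` of an instance, the vector
``p - center`` in head-grid units, and (0, 0) off-body, so ``p - BAF(p)``
recovers the instance center. Where two instances overlap, the
first-listed instance keeps the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .config import Config
from .frames import Instance, LabeledFrame
from .skeleton import Skeleton

__all__ = [
    "TargetMaps",
    "map_shape",
    "rescale_frame",
    "make_heatmap_and_locref",
    "make_lrss",
    "make_baf",
    "encode_frame",
    "dump_targets",
]


@dataclass
class TargetMaps:
    """Stride-aligned training targets for one frame."""

    heatmaps: np.ndarray            # (K, h, w) in [0, 1]
    locref: np.ndarray              # (2K, h, w), image-pixel offsets
    locref_mask: np.ndarray         # (K, h, w) in {0, 1}
    lrss: np.ndarray | None = None  # (h, w) integer labels, 0 = background
    baf: np.ndarray | None = None   # (2, h, w) per-cell (dx, dy) to center
    warnings: dict = field(default_factory=dict)


def map_shape(height: int, width: int, stride: int) -> tuple[int, int]:
    return (-(-height // stride), -(-width // stride))


def rescale_frame(frame: LabeledFrame, global_scale: float) -> LabeledFrame:
    """Resize image and keypoints by global_scale (no-op at scale 1)."""
    if global_scale == 1.0:
        return frame
    h = max(1, int(round(frame.height * global_scale)))
    w = max(1, int(round(frame.width * global_scale)))
    img = resize(
        frame.image.astype(np.float64), (h, w), order=1, preserve_range=True,
        anti_aliasing=False,
    )
    if frame.image.dtype == np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    instances = []
    for inst in frame.instances:
        kp = inst.keypoints * global_scale
        inside = (
            (kp[:, 0] >= -0.5) & (kp[:, 0] <= w - 0.5)
            & (kp[:, 1] >= -0.5) & (kp[:, 1] <= h - 0.5)
        )
        instances.append(Instance(inst.identity, kp, inst.visibility & inside))
    return LabeledFrame(img, instances, name=frame.name)


def _grid(shape):
    gy, gx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return gx.astype(np.float64), gy.astype(np.float64)


def make_heatmap_and_locref(
    frame: LabeledFrame,
    skeleton: Skeleton,
    config: Config,
    shape: tuple[int, int] | None = None,
) -> TargetMaps:
    """Gaussian confidence heatmaps plus masked location-refinement offsets.

    The frame is expected already rescaled by global_scale. Keypoints
    outside the image are excluded and counted in ``warnings``.
    """
    K = skeleton.n_keypoints
    stride = config.stride
    if shape is None:
        shape = map_shape(frame.height, frame.width, stride)
    h, w = shape
    heat = np.zeros((K, h, w))
    locref = np.zeros((2 * K, h, w))
    mask = np.zeros((K, h, w))
    # nearest squared distance (in cells) of the instance currently owning
    # each cell's locref, per keypoint channel
    best_d2 = np.full((K, h, w), np.inf)
    gx, gy = _grid(shape)
    sig2 = 2.0 * config.sigma**2
    radius = max(1.0, config.locref_supervision_radius)
    n_outside = 0
    for inst in frame.instances:
        for k in range(K):
            if not inst.visibility[k]:
                continue
            x, y = inst.keypoints[k]
            if not (-0.5 <= x <= frame.width - 0.5 and -0.5 <= y <= frame.height - 0.5):
                n_outside += 1
                continue
            mx, my = x / stride, y / stride
            d2 = (gx - mx) ** 2 + (gy - my) ** 2
            np.maximum(heat[k], np.exp(-d2 / sig2), out=heat[k])
            pr = int(np.clip(round(my), 0, h - 1))
            pc = int(np.clip(round(mx), 0, w - 1))
            heat[k, pr, pc] = 1.0
            near = (d2 <= radius**2) & (d2 < best_d2[k])
            locref[2 * k][near] = x - gx[near] * stride
            locref[2 * k + 1][near] = y - gy[near] * stride
            mask[k][near] = 1.0
            best_d2[k][near] = d2[near]
    return TargetMaps(
        heatmaps=heat,
        locref=locref,
        locref_mask=mask,
        warnings={"keypoints_outside": n_outside},
    )


def _segment_mask(shape, a, b, half_thickness: float) -> np.ndarray:
    """Cells whose center lies within half_thickness of segment a-b (map units)."""
    gx, gy = _grid(shape)
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        d2 = (gx - ax) ** 2 + (gy - ay) ** 2
    else:
        t = np.clip(((gx - ax) * dx + (gy - ay) * dy) / seg2, 0.0, 1.0)
        d2 = (gx - (ax + t * dx)) ** 2 + (gy - (ay + t * dy)) ** 2
    return d2 <= half_thickness**2


def _instance_masks(frame, skeleton, config, shape):
    """Per-instance body footprints (union of rasterized limbs),
    with first-listed-instance precedence on overlap."""
    stride = config.stride
    half = config.limb_thickness / 2.0
    claimed = np.zeros(shape, dtype=bool)
    masks = []
    for inst in frame.instances:
        m = np.zeros(shape, dtype=bool)
        for i, j in skeleton.edges:
            if inst.visibility[i] and inst.visibility[j]:
                a = inst.keypoints[i] / stride
                b = inst.keypoints[j] / stride
                m |= _segment_mask(shape, a, b, half)
        m &= ~claimed
        claimed |= m
        masks.append(m)
    return masks


def make_lrss(
    frame: LabeledFrame,
    skeleton: Skeleton,
    config: Config,
    identity_aware: bool = True,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Label map painting each instance's limb segments; 0 elsewhere."""
    if shape is None:
        shape = map_shape(frame.height, frame.width, config.stride)
    out = np.zeros(shape, dtype=np.int64)
    masks = _instance_masks(frame, skeleton, config, shape)
    for inst, m in zip(frame.instances, masks):
        label = inst.identity if identity_aware else 1
        if label > config.n_identities:
            raise ValueError(
                f"identity {label} exceeds n_identities={config.n_identities}"
            )
        out[m] = label
    return out


def make_baf(
    frame: LabeledFrame,
    skeleton: Skeleton,
    config: Config,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-cell (dx, dy) vector to the owning instance's center; 0 off-body."""
    if shape is None:
        shape = map_shape(frame.height, frame.width, config.stride)
    baf = np.zeros((2,) + shape)
    gx, gy = _grid(shape)
    masks = _instance_masks(frame, skeleton, config, shape)
    ci = skeleton.center_index
    n_missing = 0
    for inst, m in zip(frame.instances, masks):
        if not inst.visibility[ci]:
            n_missing += 1
            continue
        cx, cy = inst.keypoints[ci] / config.stride
        baf[0][m] = gx[m] - cx
        baf[1][m] = gy[m] - cy
    make_baf.last_missing_centers = n_missing
    return baf


def encode_frame(
    frame: LabeledFrame,
    skeleton: Skeleton,
    config: Config,
    identity_aware: bool = False,
    with_baf: bool = False,
    shape: tuple[int, int] | None = None,
) -> tuple[LabeledFrame, TargetMaps]:
    """Rescale by global_scale and build all configured target maps."""
    scaled = rescale_frame(frame, config.global_scale)
    tm = make_heatmap_and_locref(scaled, skeleton, config, shape=shape)
    tm.lrss = make_lrss(scaled, skeleton, config, identity_aware, shape=shape)
    if with_baf:
        tm.baf = make_baf(scaled, skeleton, config, shape=shape)
    return scaled, tm


def dump_targets(tm: TargetMaps, path) -> None:
    """Debug dump of all target channels as one multi-page image stack."""
    import imageio.v2 as imageio

    pages = [tm.heatmaps, tm.locref, tm.locref_mask]
    if tm.lrss is not None:
        pages.append(tm.lrss[None].astype(np.float64))
    if tm.baf is not None:
        pages.append(tm.baf)
    stack = np.concatenate([np.asarray(p, dtype=np.float64) for p in pages], axis=0)
    lo, hi = stack.min(), stack.max()
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    u8 = ((stack - lo) * scale).astype(np.uint8)
    imageio.mimwrite(path, list(u8))
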
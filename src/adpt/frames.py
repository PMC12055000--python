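"""In-memory containers: labeled frames, instances, detections, pose tracks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Instance", "LabeledFrame", "Detection", "PoseTrack"]


@dataclass
class Instance:
    """One animal in one frame.

    identity is a small positive integer (1-based; 0 is reserved for
    background in label maps). keypoints is a (K, 2) float array of (x, y)
    in pixels, origin at the top-left, keypoint at pixel center; visibility
    marks keypoints that are annotated and inside the image.
    """

    identity: int
    keypoints: np.ndarray
    visibility: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64).reshape(-1, 2)
        self.visibility = np.asarray(self.visibility, dtype=bool).reshape(-1)
        if self.identity < 1:
            raise ValueError("identity must be a positive integer")
        if self.visibility.shape[0] != self.keypoints.shape[0]:
            raise ValueError("visibility length must match keypoint count")

    @property
    def n_keypoints(self) -> int:
        return self.keypoints.shape[0]

    def copy(self) -> "Instance":
        return Instance(self.identity, self.keypoints.copy(), self.visibility.copy())

    def bbox_area(self) -> float:
        """Axis-aligned bounding-box area of the visible keypoints (px^2)."""
        pts = self.keypoints[self.visibility]
        if len(pts) == 0:
            return 0.0
        w = float(pts[:, 0].max() - pts[:, 0].min())
        h = float(pts[:, 1].max() - pts[:, 1].min())
        return w * h


@dataclass
class LabeledFrame:
    """An image with per-individual keypoint annotations."""

    image: np.ndarray
    instances: list[Instance] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim == 2:
            self.image = self.image[:, :, None]
        if self.image.ndim != 3:
            raise ValueError("image must be HxW or HxWxC")
        ids = [inst.identity for inst in self.instances]
        if len(ids) != len(set(ids)):
            raise ValueError("identities within a frame must be unique")
        h, w = self.image.shape[:2]
        for inst in self.instances:
            vis = inst.visibility
            kp = inst.keypoints
            ok = (
                (kp[:, 0] >= -0.5)
                & (kp[:, 0] <= w - 0.5)
                & (kp[:, 1] >= -0.5)
                & (kp[:, 1] <= h - 0.5)
            )
            if np.any(vis & ~ok):
                raise ValueError("visible keypoints must lie within image bounds")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def copy(self) -> "LabeledFrame":
        return LabeledFrame(
            self.image.copy(), [i.copy() for i in self.instances], self.name
        )


@dataclass
class Detection:
    """A decoded keypoint: full-resolution coordinates plus confidence."""

    keypoint_index: int
    x: float
    y: float
    confidence: float
    detected: bool
    identity: Optional[int] = None
    valid: bool = True


class PoseTrack:
    """Decoded keypoints, confidences and identities over a video.

    Dense array layout with a fixed instance-slot axis:

    - keypoints: (F, I, K, 2) float, NaN where an instance is absent
    - confidences: (F, I, K) float in [0, 1]
    - identities: (F, I) int, 0 where absent
    - centers: (F, I, 2) float, NaN where absent
    """

    def __init__(self, keypoints, confidences, identities, centers=None):
        self.keypoints = np.asarray(keypoints, dtype=np.float64)
        if self.keypoints.ndim != 4 or self.keypoints.shape[-1] != 2:
            raise ValueError("keypoints must have shape (F, I, K, 2)")
        F, I, K, _ = self.keypoints.shape
        if F < 1:
            raise ValueError("a track needs at least one frame")
        self.confidences = np.asarray(confidences, dtype=np.float64).reshape(F, I, K)
        finite = np.isfinite(self.confidences)
        if np.any((self.confidences[finite] < 0) | (self.confidences[finite] > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        self.identities = np.asarray(identities, dtype=np.int64).reshape(F, I)
        if centers is None:
            centers = np.full((F, I, 2), np.nan)
        self.centers = np.asarray(centers, dtype=np.float64).reshape(F, I, 2)

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    @property
    def n_slots(self) -> int:
        return self.keypoints.shape[1]

    @property
    def n_keypoints(self) -> int:
        return self.keypoints.shape[2]

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            self.keypoints.copy(),
            self.confidences.copy(),
            self.identities.copy(),
            self.centers.copy(),
        )

    @classmethod
    def single(cls, keypoints, confidences=None) -> "PoseTrack":
        """Build a one-instance track from (F, K, 2) keypoints."""
        kp = np.asarray(keypoints, dtype=np.float64)
        F, K, _ = kp.shape
        conf = np.ones((F, K)) if confidences is None else np.asarray(confidences)
        return cls(
            kp[:, None], conf.reshape(F, 1, K), np.ones((F, 1), dtype=np.int64)
        )

    @classmethod
    def from_frames(
        cls, frames, center_index: int = 0, n_slots: Optional[int] = None
    ) -> "PoseTrack":
        """Ground-truth track from LabeledFrames (confidence 1 where visible)."""
        F = len(frames)
        if F == 0:
            raise ValueError("empty frame list")
        K = frames[0].instances[0].n_keypoints
        if n_slots is None:
            n_slots = max(len(f.instances) for f in frames)
        kp = np.full((F, n_slots, K, 2), np.nan)
        conf = np.zeros((F, n_slots, K))
        ids = np.zeros((F, n_slots), dtype=np.int64)
        ctr = np.full((F, n_slots, 2), np.nan)
        for f, frame in enumerate(frames):
            for s, inst in enumerate(frame.instances[:n_slots]):
                kp[f, s] = inst.keypoints
                conf[f, s] = inst.visibility.astype(float)
                ids[f, s] = inst.identity
                ctr[f, s] = inst.keypoints[center_index]
        return cls(kp, conf, ids, ctr)
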
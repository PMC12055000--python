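"""Deterministic toy scenes: articulated stick-figure animals on
structured backgrounds.

Each animal is a 5-keypoint body (nose, back = center, tail root, two
paws) rendered as thick limb segments plus an elliptical body blob in a
per-animal texture (base color + stripe pattern keyed by texture id — a
learnable stand-in for coat appearance), with a small distinctly colored
marker disk at every keypoint so that keypoint appearance is a local,
learnable image cue. Ground-truth keypoints and identities are exact by
construction; everything is reproducible from (spec, seed).

Video mode moves animals by a reflected random walk (they never leave the
frame) with slowly drifting orientation. Tracking failure modes — sudden
keypoint jumps and identity swaps — are injected *post hoc* on the
ground-truth track, never rendered, so metric tests know exact expected
values; the event log records where.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Instance, LabeledFrame, PoseTrack
from .skeleton import MOUSE5, Skeleton

__all__ = [
    "SceneSpec",
    "generate_scene",
    "generate_video",
    "gt_track",
    "apply_events",
    "render_background",
]

# fixed marker colors, one per keypoint (nose, back, tail_root, paw_l, paw_r)
_MARKER_COLORS = np.array(
    [(230, 40, 40), (230, 230, 40), (60, 60, 230), (230, 40, 230), (40, 230, 230)],
    dtype=np.float64,
)
# body base colors per texture id (1-based), 10 entries
_BODY_COLORS = np.array(
    [
        (90, 150, 90), (150, 110, 70), (110, 110, 160), (160, 90, 120),
        (90, 160, 150), (160, 150, 80), (120, 85, 85), (85, 120, 150),
        (140, 140, 140), (100, 170, 110),
    ],
    dtype=np.float64,
)


@dataclass
class SceneSpec:
    image_size: tuple[int, int] = (64, 64)   # (H, W)
    n_animals: int = 1
    skeleton: Skeleton = MOUSE5
    texture_ids: tuple[int, ...] = ()        # default: (1, 2, ..., n_animals)
    scale_range: tuple[float, float] = (0.9, 1.1)
    angle_jitter: float = 0.25               # rad, per-limb pose jitter
    background: str = "flat"                 # flat | gradient | checker
    seed: int = 0
    margin: float = 14.0                     # px keep-out border for keypoints
    min_separation: float = 40.0             # px between animal centers
    # video motion model
    step_sigma: float = 1.2                  # px/frame center random walk
    angle_sigma: float = 0.06                # rad/frame orientation drift
    n_jump_events: int = 0
    jump_size: float = 100.0                 # px, persistent offset
    n_swap_events: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.n_animals > 2:
            raise ValueError("n_animals must be 1 or 2")
        if not self.texture_ids:
            self.texture_ids = tuple(range(1, self.n_animals + 1))
        h, w = self.image_size
        if min(h, w) < 4 * self.margin - 24:
            raise ValueError("image too small for the configured margin")


def render_background(spec: SceneSpec) -> np.ndarray:
    h, w = spec.image_size
    if spec.background == "flat":
        img = np.full((h, w, 3), 30.0)
    elif spec.background == "gradient":
        ramp = np.linspace(20, 80, w)
        img = np.repeat(ramp[None, :, None], h, axis=0).repeat(3, axis=2).copy()
    elif spec.background == "checker":
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.where((((yy // 8) + (xx // 8)) % 2)[..., None], 45.0, 25.0)
        img = np.repeat(img, 3, axis=2) if img.shape[2] == 1 else img
    else:
        raise ValueError(f"unknown background kind {spec.background!r}")
    return img


def _pose_keypoints(center, theta, scale, rng, jitter):
    """Keypoints (5, 2) of one animal: nose, back, tail_root, paw_l, paw_r."""
    def at(dist, ang):
        return center + dist * np.array([np.cos(ang), np.sin(ang)])

    j = lambda: rng.uniform(-jitter, jitter)
    kp = np.zeros((5, 2))
    kp[1] = center
    kp[0] = at(10.0 * scale, theta + j())
    kp[2] = at(9.0 * scale, theta + np.pi + j())
    kp[3] = at(7.0 * scale, theta + np.pi / 2 + 0.35 + j())
    kp[4] = at(7.0 * scale, theta - np.pi / 2 - 0.35 + j())
    return kp


def _paint_disk(img, center, radius, color):
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    m = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    img[m] = color
    return m


def _paint_segment(img, a, b, half_thickness, color):
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = b[0] - a[0], b[1] - a[1]
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        t = np.zeros_like(xx, dtype=float)
    else:
        t = np.clip(((xx - a[0]) * dx + (yy - a[1]) * dy) / seg2, 0, 1)
    d2 = (xx - (a[0] + t * dx)) ** 2 + (yy - (a[1] + t * dy)) ** 2
    m = d2 <= half_thickness**2
    img[m] = color
    return m


def _texture_color(texture_id, xx, yy):
    """Striped body texture: base color modulated by an id-keyed pattern."""
    base = _BODY_COLORS[(texture_id - 1) % len(_BODY_COLORS)]
    freq = 0.5 + 0.35 * ((texture_id - 1) % 4)
    phase = 0.9 * ((texture_id - 1) // 4)
    stripes = 0.75 + 0.25 * np.sin(freq * (xx + yy) + phase)
    return base[None] * stripes[:, None]


def _render_animal(img, kp, theta, scale, texture_id):
    """Paint one animal; returns its foreground mask."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    # elliptical body blob around the back, aligned with the heading
    cx, cy = kp[1]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    body = (u / (8.0 * scale)) ** 2 + (v / (4.5 * scale)) ** 2 <= 1.0
    tex = _texture_color(texture_id, xx[body].astype(float), yy[body].astype(float))
    img[body] = tex
    mask |= body
    for i, j in ((1, 0), (1, 2), (1, 3), (1, 4)):
        mask |= _paint_segment(
            img, kp[i], kp[j], 1.5, _BODY_COLORS[(texture_id - 1) % len(_BODY_COLORS)] * 0.85
        )
    for k in range(5):
        mask |= _paint_disk(img, kp[k], 2.0, _MARKER_COLORS[k])
    return mask


def _sample_placement(spec: SceneSpec, rng, existing_centers):
    h, w = spec.image_size
    m = spec.margin
    for _ in range(200):
        center = np.array([rng.uniform(m, w - 1 - m), rng.uniform(m, h - 1 - m)])
        if all(np.linalg.norm(center - c) >= spec.min_separation for c in existing_centers):
            return center
    raise RuntimeError(
        "could not place an animal satisfying margin and min_separation"
    )


def _scene_from_state(spec: SceneSpec, states) -> tuple[LabeledFrame, list[np.ndarray]]:
    """Render animals given per-animal (center, theta, scale, kp)."""
    img = render_background(spec)
    masks = []
    instances = []
    for idx, (center, theta, scale, kp) in enumerate(states):
        masks.append(_render_animal(img, kp, theta, scale, spec.texture_ids[idx]))
        instances.append(
            Instance(spec.texture_ids[idx], kp.copy(), np.ones(5, dtype=bool))
        )
    frame = LabeledFrame(np.clip(img, 0, 255).astype(np.uint8), instances)
    return frame, masks


def _sample_states(spec: SceneSpec, rng):
    states = []
    centers = []
    for _ in range(spec.n_animals):
        center = _sample_placement(spec, rng, centers)
        centers.append(center)
        theta = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(*spec.scale_range)
        kp = _pose_keypoints(center, theta, scale, rng, spec.angle_jitter)
        states.append([center, theta, scale, kp])
    return states


def generate_scene(spec: SceneSpec, return_masks: bool = False):
    """Render one labeled scene; the same (spec, seed) is bit-reproducible."""
    rng = np.random.default_rng(spec.seed)
    states = _sample_states(spec, rng)
    frame, masks = _scene_from_state(spec, states)
    return (frame, masks) if return_masks else frame


def generate_video(spec: SceneSpec, n_frames: int):
    """Smoothly moving scene sequence plus an injected-event log.

    Returns (frames, events); events is
    ``{"jumps": [{frame, slot, keypoint, offset}], "swaps": [frame]}``
    describing failure modes to be applied to the ground-truth track with
    :func:`apply_events` (the rendered images stay clean).
    """
    if n_frames < 2:
        raise ValueError("a video needs at least two frames")
    rng = np.random.default_rng(spec.seed)
    states = _sample_states(spec, rng)
    h, w = spec.image_size
    m = spec.margin
    frames = []
    for _ in range(n_frames):
        for si, st in enumerate(states):
            center, theta, scale, _ = st
            step = rng.normal(0, spec.step_sigma, size=2)
            center = center + step
            # reflect off the keep-out border so animals stay in frame
            for d, limit in ((0, w - 1 - m), (1, h - 1 - m)):
                if center[d] < m:
                    center[d] = 2 * m - center[d]
                if center[d] > limit:
                    center[d] = 2 * limit - center[d]
            # reject steps that would break the minimum separation
            others = [states[o][0] for o in range(len(states)) if o != si]
            if any(np.linalg.norm(center - c) < spec.min_separation for c in others):
                center = st[0]
            theta = theta + rng.normal(0, spec.angle_sigma)
            st[0], st[1] = center, theta
            st[3] = _pose_keypoints(center, theta, scale, rng, spec.angle_jitter * 0.3)
        frame, _ = _scene_from_state(spec, states)
        frames.append(frame)
    events = {"jumps": [], "swaps": []}
    for _ in range(spec.n_jump_events):
        f = int(rng.integers(1, n_frames))
        slot = int(rng.integers(0, spec.n_animals))
        k = int(rng.integers(0, spec.skeleton.n_keypoints))
        ang = rng.uniform(0, 2 * np.pi)
        offset = (spec.jump_size * np.cos(ang), spec.jump_size * np.sin(ang))
        events["jumps"].append(
            {"frame": f, "slot": slot, "keypoint": k, "offset": offset}
        )
    if spec.n_swap_events and spec.n_animals == 2:
        for _ in range(spec.n_swap_events):
            events["swaps"].append(int(rng.integers(1, n_frames - 1)))
    return frames, events


def gt_track(frames, center_index: int | None = None) -> PoseTrack:
    """Ground-truth PoseTrack from generated frames."""
    ci = MOUSE5.center_index if center_index is None else center_index
    return PoseTrack.from_frames(frames, center_index=ci)


def apply_events(track: PoseTrack, events: dict) -> PoseTrack:
    """Inject logged failure modes into a ground-truth track.

    Jumps add a persistent offset to one keypoint from the event frame
    onward (sustained drift); swaps exchange the two identity labels for
    exactly one frame.
    """
    out = track.copy()
    for ev in events.get("jumps", []):
        f, s, k = ev["frame"], ev["slot"], ev["keypoint"]
        out.keypoints[f:, s, k, 0] += ev["offset"][0]
        out.keypoints[f:, s, k, 1] += ev["offset"][1]
    for f in events.get("swaps", []):
        out.identities[f, [0, 1]] = out.identities[f, [1, 0]]
    return out
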
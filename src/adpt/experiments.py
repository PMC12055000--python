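"""Canonical desk-scale experiment protocols.

These functions bundle the package's standard CPU-scale study conditions —
synthetic 64x64 single-animal scenes for training, a 96x96 arena for
two-animal identity decoding, a 160x160 arena for identity-swap videos —
so that tests, examples and the reproduction script all run the exact
same procedures. Problem sizes (128 training frames, 32 held-out frames,
200-frame videos, 100 evaluation scenes) are the package's standard
desk-scale experiment; the training protocol keeps the reference schedule
shape (linear warm-up then cosine decay, batch 8, AdamW with weight decay
1e-4, early stopping on a 30-epoch plateau).
"""

from __future__ import annotations

import numpy as np

from .config import Config
from .decode import (
    build_identity_map,
    decode_single,
    decode_social,
    heads_to_px,
    temporal_identity_correction,
)
from .frames import PoseTrack
from .metrics import centers_by_identity, change_rate, pck
from .nn import ModelSpec, PoseModel, build_model, train
from .skeleton import MOUSE5
from .synth import SceneSpec, apply_events, generate_scene, generate_video, gt_track
from .targets import encode_frame, make_baf, make_heatmap_and_locref, make_lrss

__all__ = [
    "desk_config",
    "desk_model_spec",
    "make_training_frames",
    "train_desk_model",
    "evaluate_pck",
    "predict_track",
    "pair_scene_spec",
    "identity_pipeline_accuracy",
    "swap_correction_change_rates",
]


def desk_config(**overrides) -> Config:
    """Desk-scale training configuration for 64x64 synthetic scenes.

    Sharp heatmaps (sigma 1 cell), tight location-refinement supervision
    (1.5 cells), doubled locref loss weight and full-circle rotation
    augmentation; peak/identity search radii sized for an 8x8 head grid.
    """
    base = dict(
        sigma=1.0,
        locref_radius=1.5,
        w_locref=2.0,
        n_identities=1,
        nms_radius=2,
        identity_radius=1,
        epochs=80,
        warmup_epochs=5,
        batch_size=8,
        patience=30,
        monitor="val",
        aug_rotation=180.0,
        aug_scale=(0.95, 1.05),
        aug_translate_x=(-8.0, 8.0),
        aug_translate_y=(-8.0, 8.0),
    )
    base.update(overrides)
    return Config(**base)


def desk_model_spec(**overrides) -> ModelSpec:
    base = dict(n_keypoints=MOUSE5.n_keypoints, n_identities=1)
    base.update(overrides)
    return ModelSpec(**base)


def make_training_frames(n: int, seed: int, size: int = 64):
    return [
        generate_scene(SceneSpec(image_size=(size, size), seed=seed * 100_000 + i))
        for i in range(n)
    ]


def train_desk_model(
    seed: int = 0,
    n_train: int = 128,
    n_val: int = 8,
    config: Config | None = None,
    spec: ModelSpec | None = None,
    verbose: bool = False,
):
    """Train the tiny network on synthetic single-animal frames.

    Returns (model, config, train_state). Validation frames are drawn
    from a disjoint seed stream; per-epoch similarity-transform
    augmentation regenerates the training pixels every epoch.
    """
    config = config or desk_config()
    spec = spec or desk_model_spec()
    train_frames = make_training_frames(n_train, seed=seed)
    val_frames = make_training_frames(n_val, seed=seed + 7)
    dataset = [encode_frame(f, MOUSE5, config, identity_aware=False) for f in train_frames]
    val = [encode_frame(f, MOUSE5, config, identity_aware=False) for f in val_frames]
    model = build_model(spec, seed=seed)
    state = train(
        model,
        dataset,
        config,
        seed=seed,
        val_dataset=val,
        verbose=verbose,
        augment=(train_frames, MOUSE5, "default"),
    )
    return model, config, state


def evaluate_pck(model: PoseModel, config: Config, frames, tau: float = 0.15) -> float:
    """PCK of single-animal decoding over labeled frames."""
    preds, gts = [], []
    for f in frames:
        heads = heads_to_px(model.predict(f.image), config.stride)
        dets = decode_single(heads, config)
        preds.append([[d.x, d.y] for d in dets])
        gts.append(f.instances[0].keypoints)
    return pck(np.asarray(preds), np.asarray(gts), MOUSE5, tau=tau)


def predict_track(model: PoseModel, config: Config, frames) -> PoseTrack:
    """Single-animal track from decoding each frame of a video."""
    F = len(frames)
    K = model.spec.n_keypoints
    kp = np.zeros((F, 1, K, 2))
    conf = np.zeros((F, 1, K))
    for i, f in enumerate(frames):
        heads = heads_to_px(model.predict(f.image), config.stride)
        for d in decode_single(heads, config):
            kp[i, 0, d.keypoint_index] = (d.x, d.y)
            conf[i, 0, d.keypoint_index] = d.confidence
    track = PoseTrack(kp, conf, np.ones((F, 1), dtype=np.int64))
    track.centers = kp[:, :, MOUSE5.center_index, :].copy()
    return track


def pair_scene_spec(seed: int, video: bool = False, **overrides) -> SceneSpec:
    """Two-animal scene conditions: larger arena, separated instances."""
    base = dict(image_size=(96, 96), n_animals=2, seed=seed)
    if video:
        base.update(image_size=(160, 160), min_separation=100.0)
    base.update(overrides)
    return SceneSpec(**base)


def identity_pipeline_accuracy(
    n_scenes: int = 100, seed: int = 0, config: Config | None = None
) -> float:
    """Fraction of two-animal scenes fully recovered from exact head maps.

    For each scene the exact (oracle) target maps stand in for network
    output; a scene counts as recovered when both instances come back with
    the correct identity and every keypoint within 1e-6 * stride.
    """
    config = (config or desk_config()).replace(n_identities=2)
    ok = 0
    for i in range(n_scenes):
        frame = generate_scene(pair_scene_spec(seed * 100_000 + i))
        tm = make_heatmap_and_locref(frame, MOUSE5, config)
        lrss = make_lrss(frame, MOUSE5, config, identity_aware=True)
        baf = make_baf(frame, MOUSE5, config)
        imap = build_identity_map(lrss, baf, config)
        per_id, _ = decode_social(
            {"heatmap": tm.heatmaps, "locref": tm.locref}, imap, config
        )
        good = True
        for inst in frame.instances:
            dets = {d.keypoint_index: d for d in per_id.get(inst.identity, [])}
            if len(dets) != MOUSE5.n_keypoints:
                good = False
                break
            for k, d in dets.items():
                err = np.hypot(d.x - inst.keypoints[k, 0], d.y - inst.keypoints[k, 1])
                if err > 1e-6 * config.stride:
                    good = False
        ok += good
    return ok / n_scenes


def swap_correction_change_rates(
    seed: int = 0, n_frames: int = 100, config: Config | None = None
):
    """Identity change rate (alpha 75 px) before/after temporal correction
    on a two-animal video with one injected single-frame identity swap."""
    config = (config or desk_config()).replace(n_identities=2)
    frames, events = generate_video(
        pair_scene_spec(seed, video=True, n_swap_events=1), n_frames
    )
    track = apply_events(gt_track(frames), events)
    before, _ = change_rate(centers_by_identity(track, 2), config.change_alpha)
    fixed = temporal_identity_correction(track, config)
    after, _ = change_rate(centers_by_identity(fixed, 2), config.change_alpha)
    return before, after
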
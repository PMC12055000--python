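"""Training loop: batched losses, warmup-cosine schedule, early stopping.

The total loss is a weighted sum of per-head terms: root-mean-square error
for the heatmap, (masked) location-refinement and BAF heads, and sparse
categorical cross-entropy for the LRSS head. Location-refinement targets
are divided by the stride inside the loss so the head regresses offsets in
stride units; decoding multiplies back. Single-animal protocols monitor
the validation loss, identity/social protocols the training loss; either
way training stops once the monitored loss has not improved for
``patience`` epochs, and the best-loss parameters are restored.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..config import Config
from ..targets import TargetMaps
from .model import ModelSpec, PoseModel, build_model
from .optim import AdamW
from .schedule import lr_at
from .tensor import Tensor, sparse_cross_entropy

__all__ = ["TrainState", "train", "batch_loss", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainState:
    epoch: int = 0
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    lr_log: list = field(default_factory=list)
    best_loss: float = np.inf
    best_epoch: int = -1
    plateau: int = 0
    stopped_early: bool = False


def _stack_batch(items, config: Config, with_lrss: bool, with_baf: bool):
    # items are (image-or-LabeledFrame, TargetMaps) pairs
    arrays = [getattr(img, "image", img) for img, _ in items]
    imgs = np.stack(
        [np.asarray(a, dtype=np.float32).transpose(2, 0, 1) / 255.0 for a in arrays]
    )
    tms: list[TargetMaps] = [tm for _, tm in items]
    t = {
        "heatmap": np.stack([tm.heatmaps for tm in tms]).astype(np.float32),
        "locref": (np.stack([tm.locref for tm in tms]) / config.stride).astype(np.float32),
        "locref_mask": np.stack([tm.locref_mask for tm in tms]).astype(np.float32),
    }
    if with_lrss:
        t["lrss"] = np.stack([tm.lrss for tm in tms])
    if with_baf:
        t["baf"] = np.stack([tm.baf for tm in tms]).astype(np.float32)
    return imgs, t


def _reg_loss(pred: Tensor, target: np.ndarray, kind: str, mask: np.ndarray | None = None):
    diff = pred - Tensor(target)
    if mask is not None:
        diff = diff * Tensor(mask)
        denom = float(mask.sum()) + 1e-8
        mse = (diff * diff).sum() * (1.0 / denom)
    else:
        mse = (diff * diff).mean()
    if kind == "mse":
        return mse
    return (mse + 1e-12) ** 0.5


def batch_loss(model: PoseModel, imgs: np.ndarray, targets: dict, config: Config):
    """Weighted multi-head loss for one batch; returns (loss Tensor, parts)."""
    heads = model(Tensor(imgs))
    th, tw = targets["heatmap"].shape[-2:]
    heads = {k: v[:, :, :th, :tw] for k, v in heads.items()}
    kind = config.loss_kind
    parts = {}
    loss = None
    parts["heatmap"] = _reg_loss(heads["heatmap"], targets["heatmap"], kind)
    loss = parts["heatmap"] * config.w_heatmap
    mask2 = np.repeat(targets["locref_mask"], 2, axis=1)
    parts["locref"] = _reg_loss(heads["locref"], targets["locref"], kind, mask2)
    loss = loss + parts["locref"] * config.w_locref
    if "lrss" in targets and "lrss" in heads:
        parts["lrss"] = sparse_cross_entropy(heads["lrss"], targets["lrss"], axis=1)
        loss = loss + parts["lrss"] * config.w_lrss
    if "baf" in targets and "baf" in heads:
        parts["baf"] = _reg_loss(heads["baf"], targets["baf"], kind)
        loss = loss + parts["baf"] * config.w_baf
    return loss, {k: float(v.data) for k, v in parts.items()}


def _eval_loss(model, items, config, with_lrss, with_baf):
    total, nb = 0.0, 0
    for lo in range(0, len(items), config.batch_size):
        imgs, t = _stack_batch(items[lo : lo + config.batch_size], config, with_lrss, with_baf)
        loss, _ = batch_loss(model, imgs, t, config)
        total += float(loss.data)
        nb += 1
    return total / max(nb, 1)


def train(
    model: PoseModel,
    dataset,
    config: Config,
    seed: int = 0,
    val_dataset=None,
    out_dir=None,
    verbose: bool = False,
    augment=None,
) -> TrainState:
    """Train on (image, TargetMaps) pairs; returns the TrainState.

    ``augment``, when given, is ``(frames, skeleton, mode)`` (plus
    optional ``identity_aware`` / ``with_baf`` booleans): each epoch the
    labeled frames are re-augmented with fresh similarity transforms and
    re-encoded, so the network never sees the same pixels twice. The
    model is left holding the best-monitored-loss parameters.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)

    aug_frames = aug_skeleton = None
    aug_mode, aug_identity, aug_baf = "default", False, False
    if augment is not None:
        aug_frames, aug_skeleton, aug_mode = augment[:3]
        if len(augment) > 3:
            aug_identity = augment[3]
        if len(augment) > 4:
            aug_baf = augment[4]
    with_lrss = model.head_lrss is not None and dataset[0][1].lrss is not None
    with_baf = model.head_baf is not None and dataset[0][1].baf is not None

    if val_dataset is None and config.monitor == "val":
        n_val = max(1, int(round(config.val_fraction * len(dataset))))
        if len(dataset) > n_val:
            val_dataset = dataset[-n_val:]
            dataset = dataset[:-n_val]
        else:
            val_dataset = dataset

    n = len(dataset)
    iters = config.iters_per_epoch or -(-n // config.batch_size)
    opt = AdamW(model.parameters(), weight_decay=config.weight_decay)
    state = TrainState()
    best_params = None
    step = 0
    for epoch in range(config.epochs):
        if aug_frames is not None:
            from ..augment import augment_frame
            from ..targets import encode_frame

            dataset = [
                encode_frame(
                    augment_frame(
                        fr, int(rng.integers(2**31)), aug_mode, config
                    ),
                    aug_skeleton,
                    config,
                    identity_aware=aug_identity,
                    with_baf=aug_baf,
                )
                for fr in aug_frames
            ]
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for it in range(iters):
            lo = (it * config.batch_size) % n
            idx = order[lo : lo + config.batch_size]
            if len(idx) < config.batch_size and n >= config.batch_size:
                idx = np.concatenate([idx, order[: config.batch_size - len(idx)]])
            imgs, t = _stack_batch([dataset[i] for i in idx], config, with_lrss, with_baf)
            loss, _ = batch_loss(model, imgs, t, config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iteration {it}"
                )
            model.zero_grad()
            loss.backward()
            lr = lr_at(step, config, iters)
            state.lr_log.append(lr)
            opt.step(lr)
            epoch_loss += float(loss.data)
            nb += 1
            step += 1
        state.epoch = epoch + 1
        train_loss = epoch_loss / nb
        state.train_losses.append(train_loss)
        if config.monitor == "val":
            monitored = _eval_loss(model, val_dataset, config, with_lrss, with_baf)
            state.val_losses.append(monitored)
        else:
            monitored = train_loss
        if verbose:
            print(f"epoch {epoch + 1}: train {train_loss:.5f} monitored {monitored:.5f} lr {lr:.2e}")
        if monitored < state.best_loss - 1e-9:
            state.best_loss = monitored
            state.best_epoch = epoch + 1
            state.plateau = 0
            best_params = [p.data.copy() for p in model.parameters()]
        else:
            state.plateau += 1
            if state.plateau >= config.patience:
                state.stopped_early = True
                break
    if best_params is not None:
        for p, d in zip(model.parameters(), best_params):
            p.data = d
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "checkpoint", model, config, skeleton=aug_skeleton)
        with open(out_dir / "training_log.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "train_loss", "val_loss"])
            for i, tl in enumerate(state.train_losses):
                vl = state.val_losses[i] if i < len(state.val_losses) else ""
                wr.writerow([i + 1, tl, vl])
    return state


def save_checkpoint(prefix, model: PoseModel, config: Config, skeleton=None) -> None:
    """Write weights (<prefix>.npz) plus a JSON sidecar with spec + config
    (and the skeleton, when given, so decoded tracks carry bodypart names)."""
    prefix = Path(prefix)
    np.savez(str(prefix) + ".npz", **model.state_dict())
    meta = {"model_spec": model.spec.to_dict(), "config": config.to_dict()}
    if skeleton is not None:
        meta["skeleton"] = skeleton.to_dict()
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(prefix):
    """Returns (model, config, skeleton-or-None)."""
    from ..skeleton import Skeleton

    prefix = Path(prefix)
    with open(str(prefix) + ".json") as fh:
        meta = json.load(fh)
    spec = ModelSpec.from_dict(meta["model_spec"])
    config = Config.from_dict(meta["config"])
    skeleton = Skeleton.from_dict(meta["skeleton"]) if "skeleton" in meta else None
    model = build_model(spec)
    with np.load(str(prefix) + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config, skeleton
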
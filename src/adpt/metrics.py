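"""Anti-drift and accuracy metrics.

Drift and identity-change statistics operate on tracks: a keypoint
*drifts* in frame ``i`` when its Euclidean displacement from frame
``i - 1`` exceeds the distance threshold ``alpha`` (50 px is the mouse
default, 30 px the monkey one; identity change uses the per-identity
center with alpha 75 px). A keypoint is *missed* when its confidence is
at or below the cutoff (0.2, inclusive). Fractions are normalized by the
frame count F as conventionally printed, although only F - 1
displacements exist.

Accuracy metrics compare predictions against ground truth: PCK@tau (error
within ``tau * L_i`` of a per-instance reference length), OKS (a
scale-normalized Gaussian similarity, denominator ``2 * area * (2s)^2``
with ``s = 0.025``; a strict COCO-convention variant is available behind a
flag), AP@alpha (fraction of instances with OKS strictly above alpha),
mAP (mean AP over thresholds 0.50-0.95 in steps of 0.05) and RMSE with
optional confidence cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import PoseTrack
from .skeleton import Skeleton

__all__ = [
    "OKSParams",
    "DriftReport",
    "drift_fraction",
    "miss_fraction",
    "change_rate",
    "centers_by_identity",
    "pck",
    "oks",
    "map_score",
    "rmse",
    "drift_report",
    "MAP_THRESHOLDS",
]

MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class OKSParams:
    """Scale parameters for object-keypoint similarity."""

    area: float                      # ground-truth bounding-box area (px^2)
    s: float = 0.025                 # uncertainty factor
    visibility: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.s <= 0:
            raise ValueError("s must be positive")


def _as_keypoint_trajectory(track) -> np.ndarray:
    """(F, K, 2) trajectory from an array or a single-instance PoseTrack."""
    if isinstance(track, PoseTrack):
        if track.n_slots != 1:
            raise ValueError("per-keypoint drift expects a single-instance track")
        return track.keypoints[:, 0]
    arr = np.asarray(track, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise ValueError("expected (F, K, 2) keypoint trajectory")
    return arr


def drift_fraction(track, alpha: float, count_stable: bool = False) -> np.ndarray:
    """Per-keypoint fraction of frames whose displacement exceeds alpha.

    ``count_stable=True`` flips the inequality to the printed direction
    (counting displacements <= alpha). Normalization is 1/F.
    """
    traj = _as_keypoint_trajectory(track)
    F = traj.shape[0]
    if F < 2:
        raise ValueError("drift needs at least two frames")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    disp = np.linalg.norm(np.diff(traj, axis=0), axis=-1)  # (F-1, K)
    flagged = disp <= alpha if count_stable else disp > alpha
    return flagged.sum(axis=0) / F


def miss_fraction(track, cutoff: float = 0.2) -> np.ndarray:
    """Per-keypoint fraction of frames with confidence <= cutoff (inclusive)."""
    if isinstance(track, PoseTrack):
        if track.n_slots != 1:
            raise ValueError("per-keypoint miss expects a single-instance track")
        conf = track.confidences[:, 0]
    else:
        conf = np.asarray(track, dtype=np.float64)
        if conf.ndim == 1:
            conf = conf[:, None]
    return (conf <= cutoff).sum(axis=0) / conf.shape[0]


def centers_by_identity(track: PoseTrack, n_identities: int) -> np.ndarray:
    """(F, n_identities, 2) center trajectories keyed by identity label."""
    F = track.n_frames
    out = np.full((F, n_identities, 2), np.nan)
    for f in range(F):
        for s in range(track.n_slots):
            ident = track.identities[f, s]
            if 1 <= ident <= n_identities:
                out[f, ident - 1] = track.centers[f, s]
    return out


def change_rate(centers, alpha: float = 75.0, count_stable: bool = False):
    """Mean per-identity fraction of frames whose center jumps beyond alpha.

    ``centers`` is (F, n_identities, 2); NaN rows (absent identity) yield
    no displacement. Returns (mean rate, per-identity rates).
    """
    centers = np.asarray(centers, dtype=np.float64)
    if centers.ndim == 2:
        centers = centers[:, None, :]
    F = centers.shape[0]
    if F < 2:
        raise ValueError("change rate needs at least two frames")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    disp = np.linalg.norm(np.diff(centers, axis=0), axis=-1)  # (F-1, I)
    with np.errstate(invalid="ignore"):
        flagged = disp <= alpha if count_stable else disp > alpha
    flagged = np.where(np.isfinite(disp), flagged, False)
    per_identity = flagged.sum(axis=0) / F
    return float(per_identity.mean()), per_identity


def _reference_lengths(ground_truth, visibility, skeleton: Skeleton | None):
    """Per-instance PCK normalization length L_i."""
    gt = np.asarray(ground_truth, dtype=np.float64)
    rule = skeleton.pck_reference if skeleton is not None else "bbox_sqrt"
    if rule.startswith("edge:"):
        i, j = (int(v) for v in rule[5:].split("-"))
        return np.linalg.norm(gt[..., i, :] - gt[..., j, :], axis=-1)
    pts = np.where(visibility[..., None], gt, np.nan)
    w = np.nanmax(pts[..., 0], axis=-1) - np.nanmin(pts[..., 0], axis=-1)
    h = np.nanmax(pts[..., 1], axis=-1) - np.nanmin(pts[..., 1], axis=-1)
    return np.sqrt(w * h)


def pck(predictions, ground_truth, skeleton: Skeleton | None = None,
        tau: float = 0.15, visibility=None):
    """Fraction of visible keypoints with error <= tau * L_i.

    predictions/ground_truth: (..., K, 2); L_i follows
    ``skeleton.pck_reference`` (default: sqrt of the GT bounding-box
    area). Returns NaN if no keypoint is visible.
    """
    pred = np.asarray(predictions, dtype=np.float64)
    gt = np.asarray(ground_truth, dtype=np.float64)
    if visibility is None:
        visibility = np.isfinite(gt).all(axis=-1)
    visibility = np.asarray(visibility, dtype=bool)
    n_vis = visibility.sum()
    if n_vis == 0:
        return float("nan")
    L = np.asarray(_reference_lengths(gt, visibility, skeleton), dtype=np.float64)
    d = np.linalg.norm(pred - gt, axis=-1)
    Lb = np.broadcast_to(L[..., None] if L.ndim else L, d.shape)
    if not np.all(Lb[visibility] > 0):
        raise ValueError("PCK reference length must be positive")
    ok = d <= tau * Lb
    return float(ok[visibility].sum() / n_vis)


def oks(predictions, ground_truth, params: OKSParams, coco: bool = False) -> float:
    """Object-keypoint similarity of one instance.

    Default denominator is ``2 * area * (2s)^2`` (as printed alongside the
    SLEAP-style s = 0.025); ``coco=True`` uses the COCO ``2 * area * s^2``
    convention instead.
    """
    pred = np.asarray(predictions, dtype=np.float64).reshape(-1, 2)
    gt = np.asarray(ground_truth, dtype=np.float64).reshape(-1, 2)
    vis = (
        np.asarray(params.visibility, dtype=bool)
        if params.visibility is not None
        else np.isfinite(gt).all(axis=-1)
    )
    n_vis = vis.sum()
    if n_vis == 0:
        raise ValueError("OKS undefined with zero visible keypoints")
    d2 = ((pred - gt) ** 2).sum(axis=-1)
    denom = 2.0 * params.area * (params.s**2 if coco else (2.0 * params.s) ** 2)
    return float(np.exp(-d2[vis] / denom).sum() / n_vis)


def map_score(oks_values, thresholds=MAP_THRESHOLDS):
    """AP at each threshold (strict OKS > alpha) and their mean.

    Returns (mAP, {threshold: AP}).
    """
    vals = np.asarray(list(oks_values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("empty OKS list")
    ap = {float(t): float((vals > t).mean()) for t in thresholds}
    return float(np.mean(list(ap.values()))), ap


def rmse(predictions, ground_truth, confidences=None, confidence_cutoff=None):
    """Root-mean-square Euclidean keypoint error, in pixels.

    With a cutoff, only predictions with confidence strictly above it are
    included; returns NaN when nothing qualifies.
    """
    pred = np.asarray(predictions, dtype=np.float64).reshape(-1, 2)
    gt = np.asarray(ground_truth, dtype=np.float64).reshape(-1, 2)
    include = np.isfinite(gt).all(axis=-1) & np.isfinite(pred).all(axis=-1)
    if confidence_cutoff is not None:
        if confidences is None:
            raise ValueError("confidence_cutoff given without confidences")
        include &= np.asarray(confidences, dtype=np.float64).reshape(-1) > confidence_cutoff
    if not np.any(include):
        return float("nan")
    d2 = ((pred[include] - gt[include]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.mean()))


@dataclass
class DriftReport:
    """Per-bodypart drift/miss decomposition for one track."""

    drift_alpha: float
    conf_cutoff: float
    keypoint_names: list[str]
    drift_per_keypoint: np.ndarray
    miss_per_keypoint: np.ndarray
    overall_drift: float
    overall_miss: float
    change_rate: float | None = None
    change_alpha: float | None = None

    def to_dict(self) -> dict:
        d = {
            "drift_alpha": self.drift_alpha,
            "conf_cutoff": self.conf_cutoff,
            "overall_drift": self.overall_drift,
            "overall_miss": self.overall_miss,
            "per_keypoint": {
                name: {"drift": float(dr), "miss": float(ms)}
                for name, dr, ms in zip(
                    self.keypoint_names, self.drift_per_keypoint, self.miss_per_keypoint
                )
            },
        }
        if self.change_rate is not None:
            d["change_rate"] = self.change_rate
            d["change_alpha"] = self.change_alpha
        return d


def drift_report(track: PoseTrack, skeleton: Skeleton, config) -> DriftReport:
    """Drift/miss fractions per bodypart, plus the identity change rate
    when the track carries more than one identity."""
    if track.n_slots == 1:
        traj = track.keypoints[:, 0]
        conf = track.confidences[:, 0]
        drift = drift_fraction(traj, config.drift_alpha)
        miss = miss_fraction(conf, config.conf_cutoff)
        cr = None
    else:
        drifts, misses = [], []
        for s in range(track.n_slots):
            drifts.append(drift_fraction(track.keypoints[:, s], config.drift_alpha))
            misses.append(miss_fraction(track.confidences[:, s], config.conf_cutoff))
        drift = np.mean(drifts, axis=0)
        miss = np.mean(misses, axis=0)
        centers = centers_by_identity(track, config.n_identities)
        cr, _ = change_rate(centers, config.change_alpha)
    return DriftReport(
        drift_alpha=config.drift_alpha,
        conf_cutoff=config.conf_cutoff,
        keypoint_names=list(skeleton.names),
        drift_per_keypoint=np.asarray(drift),
        miss_per_keypoint=np.asarray(miss),
        overall_drift=float(np.mean(drift)),
        overall_miss=float(np.mean(miss)),
        change_rate=cr,
        change_alpha=config.change_alpha if cr is not None else None,
    )
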
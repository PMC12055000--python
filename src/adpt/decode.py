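"""Decoding head tensors into keypoints, identities and corrected tracks.

Single-animal decoding takes the global argmax of each heatmap channel and
refines it with the location offset stored at that cell. Social decoding
is bidirectional: bottom-up, every body pixel votes for its instance
center through the body affinity field and inherits the identity that the
LRSS map assigns to that center (the *identity map*); top-down, heatmap
peaks are matched against the identity map to attach an identity to every
keypoint. A temporal pass finally relabels identities that contradict
motion continuity and majority-smooths the labels over a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import linear_sum_assignment

from .config import Config
from .frames import Detection, PoseTrack

__all__ = [
    "decode_single",
    "identity_of_frame",
    "IdentityMap",
    "build_identity_map",
    "decode_social",
    "temporal_identity_correction",
    "heads_to_px",
]


def heads_to_px(heads: dict, stride: int) -> dict:
    """Rescale a trained model's stride-unit locref head to pixel offsets."""
    out = dict(heads)
    out["locref"] = heads["locref"] * stride
    return out


def _squeeze_heads(heads: dict) -> dict:
    """Accept (C, h, w) or batch-of-one (1, C, h, w) head tensors."""
    out = {}
    for k, v in heads.items():
        v = np.asarray(v)
        if v.ndim == 4:
            if v.shape[0] != 1:
                raise ValueError("decoding expects a single frame")
            v = v[0]
        out[k] = v
    return out


def decode_single(heads: dict, config: Config) -> list[Detection]:
    """Decode one instance: global argmax + location refinement per channel.

    ``heads`` must contain "heatmap" (K, h, w) and "locref" (2K, h, w) with
    offsets in image pixels (use :func:`heads_to_px` on raw model output).
    Coordinates are returned at full resolution (rescaled by
    1 / global_scale).
    """
    heads = _squeeze_heads(heads)
    heat = heads["heatmap"]
    locref = heads["locref"]
    K = heat.shape[0]
    stride, gs = config.stride, config.global_scale
    detections = []
    for k in range(K):
        ch = heat[k]
        r, c = np.unravel_index(np.argmax(ch), ch.shape)
        conf = float(np.clip(ch[r, c], 0.0, 1.0))
        valid = bool(np.any(ch != 0))
        x = (c * stride + locref[2 * k, r, c]) / gs
        y = (r * stride + locref[2 * k + 1, r, c]) / gs
        detections.append(
            Detection(
                keypoint_index=k,
                x=float(x),
                y=float(y),
                confidence=conf,
                detected=valid and conf > config.conf_cutoff,
                valid=valid,
            )
        )
    return detections


def identity_of_frame(lrss_probabilities: np.ndarray, config: Config):
    """Whole-frame identity: argmax over identities of per-channel pixel sums.

    ``lrss_probabilities`` has ``n_identities + 1`` channels (background
    first). Returns None ("unknown") when every identity channel sums to
    zero; exact ties go to the lowest label.
    """
    p = np.asarray(lrss_probabilities)
    if p.ndim == 4:
        p = p[0]
    sums = p.reshape(p.shape[0], -1).sum(axis=1)
    identity_sums = sums[1:]
    if identity_sums.size == 0 or np.all(identity_sums <= 0):
        return None
    return int(np.argmax(identity_sums)) + 1


@dataclass
class IdentityMap:
    """Per-pixel identity labels at head resolution (0 = background)."""

    labels: np.ndarray
    n_clamped: int = 0
    n_fallback: int = 0


def build_identity_map(lrss_labels: np.ndarray, baf: np.ndarray, config: Config) -> IdentityMap:
    """Assign each body pixel the LRSS identity of the center its BAF points to.

    For a body pixel p the center estimate is ``c = p - baf(p)`` rounded to
    the nearest cell (clamped to the map, counted); if the LRSS label at c
    is background, the majority non-background LRSS label within radius rho
    of c is used instead.
    """
    lrss = np.asarray(lrss_labels)
    baf = np.asarray(baf)
    if baf.ndim == 4:
        baf = baf[0]
    h, w = lrss.shape
    out = np.zeros_like(lrss)
    rho = config.identity_radius
    n_clamped = n_fallback = 0
    body = np.argwhere(lrss != 0)
    for r, c in body:
        cx = c - baf[0, r, c]
        cy = r - baf[1, r, c]
        cr, cc = int(round(cy)), int(round(cx))
        if not (0 <= cr < h and 0 <= cc < w):
            n_clamped += 1
            cr, cc = min(max(cr, 0), h - 1), min(max(cc, 0), w - 1)
        label = lrss[cr, cc]
        if label == 0:
            n_fallback += 1
            r0, r1 = max(cr - rho, 0), min(cr + rho + 1, h)
            c0, c1 = max(cc - rho, 0), min(cc + rho + 1, w)
            window = lrss[r0:r1, c0:c1]
            vals = window[window != 0]
            label = np.bincount(vals).argmax() if vals.size else 0
        out[r, c] = label
    return IdentityMap(out, n_clamped, n_fallback)


def _local_peaks(channel: np.ndarray, cutoff: float, radius: int, max_peaks: int):
    """Non-maximum-suppressed peaks above cutoff, strongest first."""
    footprint = 2 * radius + 1
    localmax = channel == maximum_filter(channel, size=footprint, mode="constant")
    candidates = np.argwhere(localmax & (channel > cutoff))
    if len(candidates) == 0:
        return []
    order = np.argsort(-channel[candidates[:, 0], candidates[:, 1]], kind="stable")
    peaks, taken = [], []
    for idx in order:
        r, c = candidates[idx]
        if any((r - tr) ** 2 + (c - tc) ** 2 <= radius**2 for tr, tc in taken):
            continue
        taken.append((r, c))
        peaks.append((int(r), int(c)))
        if len(peaks) >= max_peaks:
            break
    return peaks


def decode_social(heads: dict, identity_map: IdentityMap, config: Config):
    """Decode up to n_identities instances with identities from the identity map.

    Returns ``{identity: [Detection, ...]}`` plus a diagnostics dict under
    key 0 is avoided; unmatched peaks (background-only window) are counted
    in the returned diagnostics.
    """
    heads = _squeeze_heads(heads)
    heat = heads["heatmap"]
    locref = heads["locref"]
    K = heat.shape[0]
    stride, gs = config.stride, config.global_scale
    rho = config.identity_radius
    labels = identity_map.labels
    h, w = labels.shape
    per_identity: dict[int, list[Detection]] = {}
    diagnostics = {"unmatched_peaks": 0, "identity_conflicts": 0}
    for k in range(K):
        peaks = _local_peaks(heat[k], config.conf_cutoff, config.nms_radius, config.n_identities)
        best: dict[int, Detection] = {}
        for r, c in peaks:
            r0, r1 = max(r - rho, 0), min(r + rho + 1, h)
            c0, c1 = max(c - rho, 0), min(c + rho + 1, w)
            window = labels[r0:r1, c0:c1]
            vals = window[window != 0]
            if vals.size == 0:
                diagnostics["unmatched_peaks"] += 1
                continue
            identity = int(np.bincount(vals).argmax())
            conf = float(np.clip(heat[k, r, c], 0.0, 1.0))
            det = Detection(
                keypoint_index=k,
                x=float((c * stride + locref[2 * k, r, c]) / gs),
                y=float((r * stride + locref[2 * k + 1, r, c]) / gs),
                confidence=conf,
                detected=conf > config.conf_cutoff,
                identity=identity,
            )
            prev = best.get(identity)
            if prev is None or det.confidence > prev.confidence:
                if prev is not None:
                    diagnostics["identity_conflicts"] += 1
                best[identity] = det
            elif prev is not None and det.confidence == prev.confidence:
                diagnostics["identity_conflicts"] += 1  # keep first in scan order
        for identity, det in best.items():
            per_identity.setdefault(identity, []).append(det)
    return per_identity, diagnostics


# ---------------------------------------------------------------------------
# temporal identity correction
# ---------------------------------------------------------------------------

def _majority_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window majority vote over a 1-D integer label sequence."""
    F = len(labels)
    half = window // 2
    out = labels.copy()
    for i in range(F):
        if labels[i] == 0:  # absent instance: nothing to relabel
            continue
        lo, hi = max(0, i - half), min(F, i + half + 1)
        seg = labels[lo:hi]
        seg = seg[seg > 0]
        if seg.size:
            counts = np.bincount(seg)
            best = counts.max()
            out[i] = int(np.flatnonzero(counts == best)[0])
    return out


def temporal_identity_correction(track: PoseTrack, config: Config) -> PoseTrack:
    """Relabel identities with motion continuity; coordinates never change.

    Frame-by-frame, instances are assigned to previous-frame instances by
    minimizing summed center displacement (optimal assignment). When the
    raw identity labels contradict that assignment and keeping the raw
    labels would cost more than ``config.hysteresis`` extra pixels of
    center displacement, the motion-propagated labels win. A sliding
    majority vote (``config.smoothing_window`` frames) then removes
    isolated flips. Idempotent: a consistent track is returned unchanged.
    """
    out = track.copy()
    F, I = out.identities.shape
    prev_centers = None
    prev_labels = None
    for f in range(F):
        present = np.flatnonzero(np.isfinite(out.centers[f]).all(axis=1))
        if present.size == 0:
            continue
        centers = out.centers[f, present]
        raw = out.identities[f, present]
        if prev_centers is not None and len(prev_centers):
            cost = np.linalg.norm(
                centers[:, None, :] - prev_centers[None, :, :], axis=-1
            )
            rows, cols = linear_sum_assignment(cost)
            propagated = raw.copy()
            motion_cost = 0.0
            for r, c in zip(rows, cols):
                propagated[r] = prev_labels[c]
                motion_cost += cost[r, c]
            if not np.array_equal(propagated, raw):
                # cost of linking by raw labels instead of by motion
                raw_cost = 0.0
                feasible = True
                for r in range(len(present)):
                    match = np.flatnonzero(prev_labels == raw[r])
                    if match.size == 0:
                        feasible = False
                        break
                    raw_cost += cost[r, match[0]]
                if not feasible or raw_cost - motion_cost > config.hysteresis:
                    out.identities[f, present] = propagated
        prev_centers = centers
        prev_labels = out.identities[f, present]
    # sliding-window majority smoothing along motion-consistent slots
    for s in range(I):
        seq = out.identities[:, s]
        out.identities[:, s] = _majority_smooth(seq, config.smoothing_window)
    return out
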
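"""Independent brute-force reference implementations used only by tests.

Every function here is written as plainly as possible (explicit Python
loops, no shared code with the package) so it can serve as an oracle for
the vectorized implementations.
"""

import math

import numpy as np


def oracle_drift(traj, alpha):
    """traj: (F, K, 2). Fraction of frames with displacement > alpha, per kp."""
    F, K, _ = traj.shape
    out = []
    for k in range(K):
        count = 0
        for i in range(1, F):
            dx = traj[i, k, 0] - traj[i - 1, k, 0]
            dy = traj[i, k, 1] - traj[i - 1, k, 1]
            if math.sqrt(dx * dx + dy * dy) > alpha:
                count += 1
        out.append(count / F)
    return np.array(out)


def oracle_miss(conf, cutoff):
    """conf: (F, K). Fraction of frames with confidence <= cutoff, per kp."""
    F, K = conf.shape
    return np.array(
        [sum(1 for i in range(F) if conf[i, k] <= cutoff) / F for k in range(K)]
    )


def oracle_change_rate(centers, alpha):
    """centers: (F, I, 2), NaN = absent. Mean per-identity rate of jumps > alpha."""
    F, I, _ = centers.shape
    rates = []
    for s in range(I):
        count = 0
        for i in range(1, F):
            a, b = centers[i, s], centers[i - 1, s]
            if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
                if math.hypot(a[0] - b[0], a[1] - b[1]) > alpha:
                    count += 1
        rates.append(count / F)
    return float(np.mean(rates)), np.array(rates)


def oracle_pck(pred, gt, vis, L, tau):
    """pred/gt: (N, K, 2); L: (N,) reference lengths."""
    total = ok = 0
    for n in range(pred.shape[0]):
        for k in range(pred.shape[1]):
            if not vis[n, k]:
                continue
            total += 1
            d = math.hypot(pred[n, k, 0] - gt[n, k, 0], pred[n, k, 1] - gt[n, k, 1])
            if d <= tau * L[n]:
                ok += 1
    return ok / total if total else float("nan")


def oracle_oks(pred, gt, vis, area, s):
    num = den = 0.0
    for i in range(pred.shape[0]):
        if vis[i]:
            d2 = (pred[i, 0] - gt[i, 0]) ** 2 + (pred[i, 1] - gt[i, 1]) ** 2
            num += math.exp(-d2 / (2.0 * area * (2.0 * s) ** 2))
            den += 1
    return num / den


def oracle_map(oks_values):
    thresholds = [0.5 + 0.05 * i for i in range(10)]
    aps = {}
    for t in thresholds:
        aps[round(t, 2)] = sum(1 for v in oks_values if v > t) / len(oks_values)
    return sum(aps.values()) / len(aps), aps


def oracle_rmse(pred, gt, conf=None, cutoff=None):
    total, n = 0.0, 0
    for i in range(pred.shape[0]):
        if cutoff is not None and not conf[i] > cutoff:
            continue
        total += (pred[i, 0] - gt[i, 0]) ** 2 + (pred[i, 1] - gt[i, 1]) ** 2
        n += 1
    return math.sqrt(total / n) if n else float("nan")


def oracle_segment_cells(shape, a, b, half_thickness):
    """Set of (row, col) cells within half_thickness of segment a-b."""
    cells = set()
    ax, ay = a
    bx, by = b
    for r in range(shape[0]):
        for c in range(shape[1]):
            dx, dy = bx - ax, by - ay
            seg2 = dx * dx + dy * dy
            if seg2 == 0:
                t = 0.0
            else:
                t = ((c - ax) * dx + (r - ay) * dy) / seg2
                t = min(max(t, 0.0), 1.0)
            px, py = ax + t * dx, ay + t * dy
            if (c - px) ** 2 + (r - py) ** 2 <= half_thickness**2:
                cells.add((r, c))
    return cells


def oracle_mixup(frame1, frame2, background, delta):
    """Per-pixel hard composite with animal-1 precedence, inclusive >= delta."""
    h, w = background.shape[:2]
    out = np.zeros_like(background)
    m1 = np.zeros((h, w), dtype=bool)
    m2 = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            d1 = max(
                abs(float(frame1[r, c, ch]) - float(background[r, c, ch]))
                for ch in range(background.shape[2])
            )
            d2 = max(
                abs(float(frame2[r, c, ch]) - float(background[r, c, ch]))
                for ch in range(background.shape[2])
            )
            if d1 >= delta:
                out[r, c] = frame1[r, c]
                m1[r, c] = True
            elif d2 >= delta:
                out[r, c] = frame2[r, c]
                m2[r, c] = True
            else:
                out[r, c] = background[r, c]
    return out, m1, m2
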
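"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the shortcuts used by the implementation
(distance transforms, cumulative threshold sweeps): boundary distances are
all-pairs Euclidean, AUC is the exhaustive pair-ordering statistic, pixel
scores are direct counting.
"""

import numpy as np


def boundary_set(mask: np.ndarray) -> np.ndarray:
    """(n, 2) array of (row, col) of foreground pixels with a background
    4-neighbor (image border counts as background)."""
    fg = np.asarray(mask) > 0
    h, w = fg.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not fg[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not fg[rr, cc]:
                    pts.append((r, c))
                    break
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def bf_bruteforce(pred, truth, theta_px: float) -> float:
    """BF score via all-pairs Euclidean distances, strict < theta."""
    bp = boundary_set(pred)
    bg = boundary_set(truth)
    if bp.size == 0 and bg.size == 0:
        return 1.0
    if bp.size == 0 or bg.size == 0:
        return 0.0
    d = np.sqrt(((bp[:, None, :] - bg[None, :, :]) ** 2).sum(-1))
    precision = float(np.mean(d.min(axis=1) < theta_px))
    recall = float(np.mean(d.min(axis=0) < theta_px))
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def recall_bruteforce(pred, truth, cls: int) -> float:
    p = np.asarray(pred) == cls
    t = np.asarray(truth) == cls
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    return tp / (tp + fn) if tp + fn else 1.0


def iou_bruteforce(pred, truth, cls: int) -> float:
    p = np.asarray(pred) == cls
    t = np.asarray(truth) == cls
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    return tp / (tp + fp + fn) if tp + fp + fn else 1.0


def auc_pairs(scores, positives) -> float:
    """AUC as the normalized count of correctly ordered positive-negative
    pairs, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    pos = scores[positives]
    neg = scores[~positives]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)
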
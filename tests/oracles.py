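"""Literal brute-force oracle implementations used by the tests.

Everything here is written as explicit Python loops over pixels/voxels,
independent of the package's vectorized code paths, so the two can be
compared on small inputs.
"""

from __future__ import annotations

import math


def mask_counts(x, y):
    """(|X|, |Y|, |X∩Y|, |X∪Y|) by double-loop pixel counting.

    Sums the actual pixel values, so soft predictions count fractionally
    (on binary masks this is exactly set counting; union uses
    inclusion–exclusion, which equals the boolean union on {0,1}).
    """
    nx = ny = inter = union = 0.0
    h = len(x)
    w = len(x[0])
    for i in range(h):
        for j in range(w):
            xi = float(x[i][j])
            yi = float(y[i][j])
            nx += xi
            ny += yi
            inter += xi * yi
            union += xi + yi - xi * yi
    return nx, ny, inter, union


def tversky_oracle(x, y, beta, epsilon):
    nx, ny, inter, _ = mask_counts(x, y)
    return (inter + epsilon) / (beta * nx + (1.0 - beta) * ny + epsilon)


def dice_oracle(x, y):
    nx, ny, inter, _ = mask_counts(x, y)
    if nx + ny == 0:
        return 1.0
    return 2.0 * inter / (nx + ny)


def iou_oracle(x, y):
    _, _, inter, union = mask_counts(x, y)
    if union == 0:
        return 1.0
    return inter / union


def focal_tversky_oracle(x, y, beta, gamma, alpha, epsilon):
    return (1.0 - tversky_oracle(x, y, beta, epsilon)) ** gamma * alpha


def gradient_magnitude_oracle(img):
    """Forward differences, zero past the last row/column; |.| Euclidean."""
    h = len(img)
    w = len(img[0])
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            dy = img[i + 1][j] - img[i][j] if i + 1 < h else 0.0
            dx = img[i][j + 1] - img[i][j] if j + 1 < w else 0.0
            out[i][j] = math.sqrt(dx * dx + dy * dy)
    return out


def boundary_loss_oracle(pred, true, lam):
    gp = gradient_magnitude_oracle(pred)
    gt = gradient_magnitude_oracle(true)
    total = 0.0
    for i in range(len(pred)):
        for j in range(len(pred[0])):
            total += (gp[i][j] - gt[i][j]) ** 2
    return lam * total


def voxel_count_oracle(mask):
    """Triple-loop voxel count of a 3D binary mask."""
    count = 0
    for z in range(len(mask)):
        for y in range(len(mask[0])):
            for x in range(len(mask[0][0])):
                if mask[z][y][x]:
                    count += 1
    return count


def spatial_mean_oracle(fmap):
    """Per-channel mean of a (C, H, W) array by explicit loops."""
    c, h, w = len(fmap), len(fmap[0]), len(fmap[0][0])
    out = []
    for ci in range(c):
        s = 0.0
        for i in range(h):
            for j in range(w):
                s += fmap[ci][i][j]
        out.append(s / (h * w))
    return out


def spatial_max_oracle(fmap):
    """Per-channel max of a (C, H, W) array by explicit loops."""
    out = []
    for ch in fmap:
        m = ch[0][0]
        for row in ch:
            for v in row:
                m = max(m, v)
        out.append(m)
    return out


def channelwise_mean_max_oracle(fmap):
    """Per-position mean and max over channels of a (C, H, W) array."""
    c, h, w = len(fmap), len(fmap[0]), len(fmap[0][0])
    mean = [[0.0] * w for _ in range(h)]
    mx = [[-float("inf")] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            s = 0.0
            for ci in range(c):
                v = fmap[ci][i][j]
                s += v
                mx[i][j] = max(mx[i][j], v)
            mean[i][j] = s / c
    return mean, mx
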
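"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written in the most direct way possible —
per-pixel Python loops, explicit histograms, dense distance scans — sharing
no code with the package so that agreement between the two is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def global_histogram_equalization(img: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Plain global histogram equalization: v -> cdf(bin(v))."""
    bins = np.minimum((img * nbins).astype(int), nbins - 1)
    hist = np.bincount(bins.ravel(), minlength=nbins)
    cdf = np.cumsum(hist) / img.size
    return cdf[bins]


def _clip_redistribute(hist: list[float], clip: float, nbins: int) -> list[float]:
    excess = sum(max(h - clip, 0.0) for h in hist)
    hist = [min(h, clip) for h in hist]
    for _ in range(100):
        if excess < 1.0:
            break
        hist = [h + excess / nbins for h in hist]
        new_excess = sum(max(h - clip, 0.0) for h in hist)
        hist = [min(h, clip) for h in hist]
        if new_excess >= excess:
            excess = new_excess
            break
        excess = new_excess
    return [h + excess / nbins for h in hist]


def clahe_bruteforce(
    img: np.ndarray,
    num_tiles: tuple[int, int] = (8, 8),
    clip_limit: float = 0.01,
    nbins: int = 256,
) -> np.ndarray:
    """Per-pixel CLAHE: clipped per-tile histograms, scaled CDF mappings,
    bilinear interpolation between tile centers with clamped replication."""
    H, W = img.shape
    tr, tc = num_tiles

    def edges(n: int, t: int) -> list[int]:
        base = n // t
        return [i * base for i in range(t)] + [n]

    re_, ce = edges(H, tr), edges(W, tc)
    mappings = {}
    for r in range(tr):
        for c in range(tc):
            tile = img[re_[r] : re_[r + 1], ce[c] : ce[c + 1]]
            hist = [0.0] * nbins
            for v in tile.ravel():
                hist[min(int(v * nbins), nbins - 1)] += 1.0
            clip = math.ceil(clip_limit * tile.size)
            hist = _clip_redistribute(hist, clip, nbins)
            cdf, s = [], 0.0
            for h in hist:
                s += h
                cdf.append(min(max(s / tile.size, 0.0), 1.0))
            mappings[(r, c)] = cdf
    cr = [(re_[i] + re_[i + 1] - 1) / 2 for i in range(tr)]
    cc = [(ce[i] + ce[i + 1] - 1) / 2 for i in range(tc)]

    def axis_interp(pos: float, centers: list[float]):
        if pos <= centers[0]:
            return 0, 0, 0.0
        if pos >= centers[-1]:
            return len(centers) - 1, len(centers) - 1, 0.0
        hi = next(i for i, c in enumerate(centers) if c >= pos)
        lo = hi - 1
        return lo, hi, (pos - centers[lo]) / (centers[hi] - centers[lo])

    out = np.empty_like(img)
    for y in range(H):
        rl, rh, wy = axis_interp(float(y), cr)
        for x in range(W):
            cl, ch, wx = axis_interp(float(x), cc)
            b = min(int(img[y, x] * nbins), nbins - 1)
            out[y, x] = (
                (1 - wy) * (1 - wx) * mappings[(rl, cl)][b]
                + (1 - wy) * wx * mappings[(rl, ch)][b]
                + wy * (1 - wx) * mappings[(rh, cl)][b]
                + wy * wx * mappings[(rh, ch)][b]
            )
    return out


def nl_means_bruteforce(
    img: np.ndarray, kernel_radius: int = 4, window_radius: int = 4, h: float = 0.05
) -> np.ndarray:
    """Triple-loop non-local means with Gaussian-weighted patch distances,
    mirror boundary for patches, window clipped at the image border, and
    self-weight equal to the maximum of the other window weights."""
    H, W = img.shape
    R, Wr = kernel_radius, window_radius
    u = np.pad(img, R, mode="symmetric")
    off = np.arange(-R, R + 1)
    g1 = np.exp(-(off**2) / (2.0 * (R / 2.0) ** 2))
    g2 = np.outer(g1, g1)
    g2 /= g2.sum()

    def patch(y: int, x: int) -> np.ndarray:
        return u[y : y + 2 * R + 1, x : x + 2 * R + 1]

    out = np.empty_like(img)
    for y in range(H):
        for x in range(W):
            weights, values = [], []
            for dy in range(-Wr, Wr + 1):
                for dx in range(-Wr, Wr + 1):
                    if dy == 0 and dx == 0:
                        continue
                    jy, jx = y + dy, x + dx
                    if not (0 <= jy < H and 0 <= jx < W):
                        continue
                    d2 = float((g2 * (patch(y, x) - patch(jy, jx)) ** 2).sum())
                    weights.append(math.exp(-d2 / (h * h)))
                    values.append(img[jy, jx])
            self_w = max(weights) if weights else 1.0
            weights.append(self_w)
            values.append(img[y, x])
            out[y, x] = float(np.dot(weights, values) / np.sum(weights))
    return out


def nearest_center_bruteforce(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Dense nearest-neighbour scan; ties resolved to the lowest index."""
    labels = np.empty(len(X), dtype=int)
    for i, x in enumerate(X):
        best, best_d = 0, float("inf")
        for j, c in enumerate(centers):
            d = float(((x - c) ** 2).sum())
            if d < best_d:
                best, best_d = j, d
        labels[i] = best
    return labels
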
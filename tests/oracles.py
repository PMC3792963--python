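"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library routines the implementation uses
(scipy EDT / labelling, skimage Otsu): distances by all-pairs
minimization, components by flood fill, thresholds by exhaustive
between-class-variance maximization, window scores by exhaustive scans.
"""

from __future__ import annotations

import numpy as np


def brute_force_distance_map(mask: np.ndarray, pitch_um: float) -> np.ndarray:
    """Per-pixel min Euclidean distance to any True pixel, all-pairs."""
    h, w = mask.shape
    vr, vc = np.nonzero(mask)
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    vessels = np.stack([vr, vc], axis=1).astype(float)
    d2 = (
        (pts[:, None, 0] - vessels[None, :, 0]) ** 2
        + (pts[:, None, 1] - vessels[None, :, 1]) ** 2
    )
    return np.sqrt(d2.min(axis=1)).reshape(h, w) * pitch_um


def flood_fill_components(mask: np.ndarray, min_size: int = 1) -> int:
    """Number of 8-connected components with area >= min_size (pure BFS)."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            size = 0
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            if size >= min_size:
                count += 1
    return count


def exhaustive_otsu(raster: np.ndarray) -> float:
    """Otsu threshold by exhaustive between-class-variance maximization.

    Evaluates every one of 256 histogram-bin candidate thresholds over the
    raster's range and returns the bin center maximizing sigma_b^2.
    """
    vals = raster.ravel().astype(float)
    lo, hi = vals.min(), vals.max()
    hist, edges = np.histogram(vals, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    total = vals.size
    best_t, best_var = centers[0], -1.0
    for k in range(1, 256):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return float(best_t)


def exhaustive_window_counts(
    mask: np.ndarray, side: int, origins_r: list[int], origins_c: list[int], min_size: int
) -> dict[tuple[int, int], int]:
    """Component count per window by cropping + flood fill."""
    return {
        (r, c): flood_fill_components(mask[r : r + side, c : c + side], min_size)
        for r in origins_r
        for c in origins_c
    }


def exhaustive_window_sums(
    raster: np.ndarray, side: int, origins_r: list[int], origins_c: list[int]
) -> dict[tuple[int, int], float]:
    """Summed intensity per window by direct slicing."""
    return {
        (r, c): float(raster[r : r + side, c : c + side].sum())
        for r in origins_r
        for c in origins_c
    }


def two_pass_mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Textbook two-pass mean / n-1 SD."""
    n = values.size
    mean = float(sum(values) / n)
    ss = float(sum((v - mean) ** 2 for v in values))
    return mean, (ss / (n - 1)) ** 0.5
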
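"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive (queue-based flood fill, explicit loops) and
share no code with the package internals they check.
"""

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for sy in range(H):
        for sx in range(W):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp: set[tuple[int, int]] = set()
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < H
                            and 0 <= nx < W
                            and mask[ny, nx]
                            and not seen[ny, nx]
                        ):
                            seen[ny, nx] = True
                            q.append((ny, nx))
            comps.append(comp)
    return comps


def loop_mip(planes: np.ndarray) -> np.ndarray:
    """Elementwise max over the leading axis by explicit iteration."""
    planes = np.asarray(planes)
    out = planes[0].copy()
    for z in range(1, planes.shape[0]):
        for y in range(planes.shape[1]):
            for x in range(planes.shape[2]):
                if planes[z, y, x] > out[y, x]:
                    out[y, x] = planes[z, y, x]
    return out


def enumerate_region_stats(
    pixels: np.ndarray, regions: list[tuple[int, int, int, int]]
) -> tuple[float, float]:
    """Pooled mean/population SD over (y0, x0, h, w) regions, pixel by pixel,
    counting pixels covered by several regions once."""
    chosen: set[tuple[int, int]] = set()
    for y0, x0, h, w in regions:
        for y in range(y0, y0 + h):
            for x in range(x0, x0 + w):
                chosen.add((y, x))
    vals = [float(pixels[y, x]) for y, x in sorted(chosen)]
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    return mean, var**0.5
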
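"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the library code paths they verify: flood fill
by explicit stack traversal, bilinear interpolation point by point, OLS
from the normal equations, quantiles from a sorted array.
"""

from __future__ import annotations

import numpy as np


def flood_fill_labels(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Stack-based connected-component labeling of a boolean image."""
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, dtype=int)
    if connectivity == 4:
        nbrs = ((1, 0), (-1, 0), (0, 1), (0, -1))
    else:
        nbrs = tuple((dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if (dy, dx) != (0, 0))
    current = 0
    ny, nx = binary.shape
    for sy in range(ny):
        for sx in range(nx):
            if not binary[sy, sx] or labels[sy, sx]:
                continue
            current += 1
            stack = [(sy, sx)]
            labels[sy, sx] = current
            while stack:
                y, x = stack.pop()
                for dy, dx in nbrs:
                    py, px = y + dy, x + dx
                    if (0 <= py < ny and 0 <= px < nx and binary[py, px]
                            and not labels[py, px]):
                        labels[py, px] = current
                        stack.append((py, px))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label images agree up to relabeling."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return (len(pairs) == len({p[0] for p in pairs})
            and len(pairs) == len({p[1] for p in pairs}))


def bilinear_point(values: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                   y: float, x: float) -> float:
    """Bilinear interpolation of one point from center coordinates,
    clamping outside the outermost centers."""
    y = min(max(y, ys[0]), ys[-1])
    x = min(max(x, xs[0]), xs[-1])
    iy = int(np.clip(np.searchsorted(ys, y) - 1, 0, len(ys) - 2))
    ix = int(np.clip(np.searchsorted(xs, x) - 1, 0, len(xs) - 2))
    fy = (y - ys[iy]) / (ys[iy + 1] - ys[iy])
    fx = (x - xs[ix]) / (xs[ix + 1] - xs[ix])
    return ((1 - fy) * (1 - fx) * values[iy, ix]
            + (1 - fy) * fx * values[iy, ix + 1]
            + fy * (1 - fx) * values[iy + 1, ix]
            + fy * fx * values[iy + 1, ix + 1])


def ols_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal-equations least squares: slope and intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb


def sorted_quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile computed from an explicit sort."""
    v = np.sort(np.asarray(values, float))
    pos = (v.size - 1) * q
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
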
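"""Independent brute-force oracles used across the test suite.

These are deliberately naive (loops, BFS) and share no code with the
package implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(grid: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """BFS connected components of a boolean grid; returns pixel sets."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        raise ValueError(connectivity)
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    components = []
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if grid[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if (0 <= nr < grid.shape[0] and 0 <= nc < grid.shape[1]
                                and grid[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                components.append(comp)
    return components


def sliding_median(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel neighbourhood median with edge replication."""
    img = np.asarray(img, dtype=float)
    out = np.empty_like(img)
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            window = []
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    window.append(img[rr, cc])
            out[r, c] = float(np.median(window))
    return out


def trimmed_mean_sorted(values, trim_fraction: float) -> float:
    """Sort, drop floor(frac*n) from each end, average the rest."""
    xs = sorted(float(v) for v in values)
    k = int(np.floor(trim_fraction * len(xs)))
    kept = xs[k: len(xs) - k] if k else xs
    return sum(kept) / len(kept)


def groupby_mean_loop(rows: list[dict], key_fields: tuple[str, ...],
                      value_field: str) -> dict[tuple, float]:
    """Plain-loop group-by mean."""
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for row in rows:
        key = tuple(row[f] for f in key_fields)
        sums[key] = sums.get(key, 0.0) + row[value_field]
        counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}
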
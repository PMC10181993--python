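"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the grid search
never calls the optimiser, the flood fill never calls scipy.ndimage, and
the Ward oracle re-derives the merge sequence from the ESS criterion.
"""

from __future__ import annotations

import numpy as np


def grid_search_sse(
    psi: np.ndarray,
    plc: np.ndarray,
    psi50_grid: np.ndarray | None = None,
    slope_grid: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Exhaustive SSE minimum of the Pammenter sigmoid over a parameter grid.

    Returns (best_sse, psi50, slope) for a 200x200 grid over
    psi50 in [-8, 0], S in [1, 300] by default.
    """
    if psi50_grid is None:
        psi50_grid = np.linspace(-8.0, 0.0, 200)
    if slope_grid is None:
        slope_grid = np.linspace(1.0, 300.0, 200)
    p50 = psi50_grid[:, None, None]
    s = slope_grid[None, :, None]
    model = 100.0 / (1.0 + np.exp(s / 25.0 * (psi[None, None, :] - p50)))
    sse = ((model - plc[None, None, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(sse[i, j]), float(psi50_grid[i]), float(slope_grid[j])


def flood_fill_components(mask: np.ndarray, min_area: int, connectivity: int = 8):
    """Count connected components of a boolean mask by explicit BFS.

    Returns (n_components_kept, total_kept_pixels) after discarding
    components smaller than ``min_area``.
    """
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n_kept, px_kept = 0, 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            queue = [(r, c)]
            seen[r, c] = True
            size = 0
            while queue:
                rr, cc = queue.pop()
                size += 1
                for dr, dc in nbrs:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            if size >= min_area:
                n_kept += 1
                px_kept += size
    return n_kept, px_kept


def ward_merge_order(points: np.ndarray) -> list[frozenset[int]]:
    """Agglomerative Ward merge sequence by direct ESS minimisation.

    At each step the pair of clusters whose merge least increases the total
    within-cluster sum of squares, dESS = n_i*n_j/(n_i+n_j)*||c_i - c_j||^2,
    is joined.  Returns the sequence of merged member sets (each merge as a
    frozenset of original point indices).
    """
    clusters: list[set[int]] = [{i} for i in range(len(points))]
    merges: list[frozenset[int]] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = points[list(clusters[a])].mean(axis=0)
                cb = points[list(clusters[b])].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d_ess = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or d_ess < best[0]:
                    best = (d_ess, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(frozenset(merged))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def scipy_merge_order(linkage: np.ndarray, n: int) -> list[frozenset[int]]:
    """Translate a scipy linkage matrix into the same merge-set sequence."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append(merged)
    return merges
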
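"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and scipy's labeling)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_components(member: np.ndarray, connectivity: int) -> list[set[tuple]]:
    """Flood-fill connected components of a 3D boolean array.

    Returns a list of voxel-index sets; order is unspecified (compare as a
    partition).
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    shape = member.shape
    seen = np.zeros(shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(member)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[a] < shape[a] for a in range(3)) \
                        and member[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(comp)
    return components


def brute_force_sphere(grid_shape, affine, center_mm, radius_mm) -> set[tuple]:
    """Every voxel whose world centre is within the radius, by full scan."""
    affine = np.asarray(affine)
    inside = set()
    for idx in np.ndindex(*grid_shape):
        world = affine[:3, :3] @ np.asarray(idx, float) + affine[:3, 3]
        if np.linalg.norm(world - np.asarray(center_mm, float)) <= radius_mm + 1e-12:
            inside.add(idx)
    return inside


def pearson(x, y) -> float:
    """Textbook Pearson correlation, written out long-hand."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def sort_and_count_threshold(values, flat_indices, percent, direction) -> set[int]:
    """Nearest-rank percentile retention by explicit sort."""
    import math

    pairs = sorted(zip(values, flat_indices),
                   key=lambda p: (p[0] if direction == "lowest" else -p[0], p[1]))
    k = math.ceil(percent / 100.0 * len(pairs))
    return {idx for _, idx in pairs[:k]}
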
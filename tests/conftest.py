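"""Shared fixtures and independent oracles.

Oracles are deliberately naive (scalar loops, breadth-first search) so they
stay independent of the vectorized implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

import trunkcomp as tc


@pytest.fixture(scope="session")
def clean_phantom():
    """Well-separated compartments: muscle N(45,5), fat N(-100,15)."""
    spec = tc.chest_phantom_spec(noise_seed=42)
    volume, truth = tc.generate_phantom(spec)
    return spec, volume, truth


def brute_force_point_in_polygon(point_xy, vertices):
    """Scalar even-odd crossing test for one point."""
    x, y = point_xy
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_at = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x < x_at:
                inside = not inside
    return inside


def brute_force_rasterize(vertices, slice_shape):
    mask = np.zeros(slice_shape, dtype=bool)
    for r in range(slice_shape[0]):
        for c in range(slice_shape[1]):
            mask[r, c] = brute_force_point_in_polygon((c + 0.5, r + 0.5), vertices)
    return mask


def bfs_region_grow(hu, roi, seeds, lower_threshold):
    """Breadth-first 26-connected region growing on a small 3-D grid."""
    hu = np.asarray(hu, dtype=float)
    admissible = np.asarray(roi, dtype=bool) & (hu >= lower_threshold)
    out = np.zeros_like(admissible)
    queue = deque(zip(*np.nonzero(np.asarray(seeds, dtype=bool) & admissible)))
    for v in queue:
        out[v] = True
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            w = (z + dz, y + dy, x + dx)
            if all(0 <= w[i] < hu.shape[i] for i in range(3)) \
                    and admissible[w] and not out[w]:
                out[w] = True
                queue.append(w)
    return out
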
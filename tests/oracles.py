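"""Independent reference implementations used to cross-check the package.

These are deliberately written with different algorithms from the library
code they validate: a winding-number point-in-polygon test, hinge-depth
quartiles, and a brute-force run scanner.
"""

from __future__ import annotations

import math

import numpy as np


def winding_number_inside(px: float, py: float, ring) -> bool:
    """Nonzero-winding containment test (signed angle accumulation).

    ``ring`` is a closed list of (x, y) vertices. Boundary points are
    ambiguous under this formulation and should not be fed to it when
    comparing against a boundary-inclusive implementation.
    """
    total = 0.0
    n = len(ring)
    for i in range(n - 1):
        ax, ay = ring[i][0] - px, ring[i][1] - py
        bx, by = ring[i + 1][0] - px, ring[i + 1][1] - py
        cross = ax * by - ay * bx
        dot = ax * bx + ay * by
        total += math.atan2(cross, dot)
    return abs(total) > math.pi  # ~2*pi inside, ~0 outside


def hinge_quartiles(values) -> tuple[float, float, float]:
    """Tukey hinges via the hinge-depth formula d = (floor((n+1)/2) + 1) / 2.

    Returns (lower hinge, median, upper hinge). One-indexed positions; a
    half-integer depth averages the two neighboring order statistics.
    """
    x = sorted(float(v) for v in values)
    n = len(x)

    def at_depth(d: float, from_top: bool) -> float:
        lo = int(math.floor(d))
        hi = int(math.ceil(d))
        if from_top:
            a, b = x[n - lo], x[n - hi]
        else:
            a, b = x[lo - 1], x[hi - 1]
        return (a + b) / 2.0

    med_depth = (n + 1) / 2.0
    hinge_depth = (math.floor(med_depth) + 1) / 2.0
    return (
        at_depth(hinge_depth, from_top=False),
        at_depth(med_depth, from_top=False),
        at_depth(hinge_depth, from_top=True),
    )


def brute_force_runs(values, min_len: int) -> list[tuple[int, int]]:
    """All maximal (start, length) runs of identical non-missing values."""
    runs = []
    i = 0
    n = len(values)
    while i < n:
        v = values[i]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            i += 1
            continue
        j = i
        while j < n and values[j] == v:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def random_star_polygon(rng: np.random.Generator, n_vertices: int, center=(0.0, 0.0), scale=1.0):
    """A random simple (star-shaped) closed polygon around ``center``.

    Vertices at sorted angles with random radii; simple by construction, so
    even–odd and nonzero-winding containment agree everywhere off-boundary.
    """
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(0.3 * scale, scale, size=n_vertices)
    cx, cy = center
    pts = [
        (cx + r * np.cos(a), cy + r * np.sin(a)) for a, r in zip(angles, radii)
    ]
    return pts + [pts[0]]
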
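"""Independent brute-force oracles used to validate the fast estimators.

Deliberately naive O(N²) Python loops — kept free of any code path from the
package under test.
"""

from __future__ import annotations

import math

import numpy as np


def ordered_pair_ring_counts(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Ordered pair counts per half-open ring [edges[k], edges[k+1])."""
    n = len(points)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.hypot(
                points[i][0] - points[j][0], points[i][1] - points[j][1]
            )
            for k in range(len(edges) - 1):
                if edges[k] <= d < edges[k + 1]:
                    counts[k] += 1
                    break
    return counts


def ordered_pair_cumulative_counts(points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Ordered pair counts with distance <= r for each r in radii."""
    n = len(points)
    counts = np.zeros(len(radii), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.hypot(
                points[i][0] - points[j][0], points[i][1] - points[j][1]
            )
            for k, r in enumerate(radii):
                if d <= r:
                    counts[k] += 1
    return counts


def rdf_from_counts(
    counts: np.ndarray, edges: np.ndarray, area: float, n: int
) -> np.ndarray:
    """Evaluate the ring-density formula from ordered pair counts."""
    r = edges[:-1]
    dr = edges[1] - edges[0]
    ring_area = np.pi * (2 * r * dr + dr**2)
    return (area / (n - 1)) / ring_area * (counts / n)


def k_from_counts(counts: np.ndarray, area: float, n: int) -> np.ndarray:
    return area / (n * (n - 1)) * counts
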
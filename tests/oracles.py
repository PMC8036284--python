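"""Independent brute-force oracles the implementation is checked against.

These deliberately use literal loops and exhaustive search, not the
vectorised code paths of the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def gdm2_brute(X, w, i: int, k: int) -> float:
    """Literal triple-loop evaluation of the ordinal GDM2 distance."""
    n = len(X)
    m = len(w)
    num = 0.0
    for j in range(m):
        num += w[j] * _sign(X[i][j] - X[k][j]) * _sign(X[k][j] - X[i][j])
    for j in range(m):
        for l in range(n):
            if l == i or l == k:
                continue
            num += w[j] * _sign(X[i][j] - X[l][j]) * _sign(X[k][j] - X[l][j])
    di = 0.0
    dk = 0.0
    for j in range(m):
        for l in range(n):
            if l != i:
                di += w[j] * _sign(X[i][j] - X[l][j]) ** 2
            if l != k:
                dk += w[j] * _sign(X[k][j] - X[l][j]) ** 2
    den = 2.0 * math.sqrt(di * dk)
    if den == 0.0:
        if all(X[i][j] == X[k][j] for j in range(m)):
            return 0.0
        raise ZeroDivisionError("degenerate context with non-identical profiles")
    return 0.5 - num / den


def best_gap_triple(d_sorted) -> tuple[float, tuple[int, int, int]]:
    """Exhaustive search over all boundary triples: maximal total gap,
    ties resolved toward the lexicographically smallest triple."""
    n = len(d_sorted)
    best_sum = -math.inf
    best = None
    for triple in combinations(range(n - 1), 3):
        s = sum(d_sorted[i + 1] - d_sorted[i] for i in triple)
        if s > best_sum + 1e-15:
            best_sum = s
            best = triple
    return best_sum, best


def component_bbox(mask3d, seed) -> tuple[int, int, int, int, int, int]:
    """Flood-fill (26-neighbourhood) bounding box of the component holding
    ``seed`` in a boolean volume."""
    from collections import deque

    ns, nr, nc = mask3d.shape
    seen = {seed}
    queue = deque([seed])
    lo = list(seed)
    hi = list(seed)
    while queue:
        s, r, c = queue.popleft()
        for ds in (-1, 0, 1):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if ds == dr == dc == 0:
                        continue
                    p = (s + ds, r + dr, c + dc)
                    if (
                        0 <= p[0] < ns and 0 <= p[1] < nr and 0 <= p[2] < nc
                        and p not in seen and mask3d[p]
                    ):
                        seen.add(p)
                        queue.append(p)
                        for ax in range(3):
                            lo[ax] = min(lo[ax], p[ax])
                            hi[ax] = max(hi[ax], p[ax])
    return (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def superlevel_component_count(values2d, threshold) -> int:
    """Count 8-connected components of {v >= threshold} by flood fill."""
    mask = values2d >= threshold
    nr, nc = mask.shape
    seen = set()
    count = 0
    for r0 in range(nr):
        for c0 in range(nc):
            if not mask[r0, c0] or (r0, c0) in seen:
                continue
            count += 1
            stack = [(r0, c0)]
            seen.add((r0, c0))
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        p = (r + dr, c + dc)
                        if (
                            0 <= p[0] < nr and 0 <= p[1] < nc
                            and p not in seen and mask[p]
                        ):
                            seen.add(p)
                            stack.append(p)
    return count
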
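"""Independent straight-from-the-equations reference implementations.

Deliberately naive pure-Python loops (pixel census, pairwise distance
matrix, flood fill) kept free of the package's vectorized code paths, so
they can serve as oracles for it.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Set, Tuple


def census(grid: Sequence[Sequence[int]]) -> Tuple[int, List[int]]:
    """(A0, [A_1..A_alpha]) by explicit double loop."""
    rows = len(grid)
    cols = len(grid[0])
    alpha = max(max(row) for row in grid)
    A = []
    for k in range(1, alpha + 1):
        count = 0
        for m in range(rows):
            for n in range(cols):
                if grid[m][n] >= k:
                    count += 1
        A.append(count)
    return rows * cols, A


def indices_reference(grid, spots, conversion_ratio: float) -> dict:
    """All four indices straight from their defining equations."""
    A0, A = census(grid)
    A1 = A[0] if A else 0
    d0 = (A0 - A1) / A0 * 100.0
    dz = sum(A[1:]) / A0 * 100.0

    beta = len(spots)
    dc = [math.dist(spots[i], spots[i + 1]) for i in range(beta - 1)]
    dn = [
        min(math.dist(si, sj) for j, sj in enumerate(spots) if j != i)
        for i, si in enumerate(spots)
    ]
    mu = sum(dc) / len(dc) * conversion_ratio
    mean_dn = sum(dn) / len(dn)
    var = sum((y - mean_dn) ** 2 for y in dn) / (len(dn) - 1)
    ratio = math.sqrt(var) / mean_dn
    return {
        "delta0": d0,
        "deltaz": dz,
        "mu": mu,
        "upsilon_pct": 100.0 * ratio,
        "upsilon_ratio": ratio,
        "alpha": len(A),
        "beta": beta,
        "dc": dc,
        "dn": dn,
        "A0": A0,
        "A": A,
    }


def components_8(mask) -> List[Set[Tuple[int, int]]]:
    """8-connected components by flood fill over a boolean 2-D mask."""
    rows = len(mask)
    cols = len(mask[0])
    seen: Set[Tuple[int, int]] = set()
    comps: List[Set[Tuple[int, int]]] = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r][c] or (r, c) in seen:
                continue
            comp = set()
            queue = [(r, c)]
            seen.add((r, c))
            while queue:
                cr, cc = queue.pop()
                comp.add((cr, cc))
                for dr in (-1, 0, 1):
                    for dcol in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dcol
                        if (
                            0 <= nr < rows
                            and 0 <= nc < cols
                            and mask[nr][nc]
                            and (nr, nc) not in seen
                        ):
                            seen.add((nr, nc))
                            queue.append((nr, nc))
            comps.append(comp)
    return comps


def paired_t_reference(pre, post):
    """Textbook paired t statistic (not the p-value) on post - pre."""
    diffs = [b - a for a, b in zip(pre, post)]
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, mean / (sd / math.sqrt(n))
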
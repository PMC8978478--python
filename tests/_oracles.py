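"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: connected
components by breadth-first flood fill over explicit neighbor offsets,
Benjamini-Hochberg by its textbook definition, and OLS by the normal
equations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy import stats as sps


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(v) for v in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offsets.append(d)
    return offsets


def bfs_components(binary: np.ndarray, connectivity: int) -> list[frozenset]:
    """All connected components of a boolean grid as frozensets of coords."""
    offsets = neighbor_offsets(connectivity)
    shape = binary.shape
    seen = np.zeros(shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        members = {start}
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if (
                    all(0 <= nb[i] < shape[i] for i in range(3))
                    and binary[nb]
                    and not seen[nb]
                ):
                    seen[nb] = True
                    members.add(nb)
                    queue.append(nb)
        components.append(frozenset(members))
    return components


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by definition: sort, p*m/rank, cumulative minimum
    from the largest rank down, cap at 1, restore input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adjusted[i] = min(adjusted[i], adjusted[i + 1])
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """(beta, se, p, r2) for X including an intercept column, via the normal
    equations and the exact t reference distribution."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df=n - k)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - (resid @ resid) / tss if tss > 0 else np.nan
    return beta, se, p, r2
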
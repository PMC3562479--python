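"""Independent oracles used by the test suite.

These deliberately avoid the package's own numerical paths: superposition
is solved with the quaternion (Davenport) eigenvalue method rather than
SVD, GDT by exhaustive subset enumeration, DIANA's first split by
breadth-first search over every legal splinter-move order, and average
linkage by the textbook recursive definition.
"""

from __future__ import annotations

import itertools

import numpy as np


def quat_kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal rotation/translation of P onto Q via the quaternion method."""
    Pc = P - P.mean(0)
    Qc = Q - Q.mean(0)
    M = Pc.T @ Qc
    K = np.array(
        [
            [M[0, 0] + M[1, 1] + M[2, 2], M[1, 2] - M[2, 1], M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]],
            [M[1, 2] - M[2, 1], M[0, 0] - M[1, 1] - M[2, 2], M[0, 1] + M[1, 0], M[2, 0] + M[0, 2]],
            [M[2, 0] - M[0, 2], M[0, 1] + M[1, 0], -M[0, 0] + M[1, 1] - M[2, 2], M[1, 2] + M[2, 1]],
            [M[0, 1] - M[1, 0], M[2, 0] + M[0, 2], M[1, 2] + M[2, 1], -M[0, 0] - M[1, 1] + M[2, 2]],
        ]
    )
    _, V = np.linalg.eigh(K)
    a, b, c, d = V[:, -1]
    R = np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )
    t = Q.mean(0) - R @ P.mean(0)
    return R, t


def quat_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    R, t = quat_kabsch(P, Q)
    return float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))


def subset_gdt_counts(P: np.ndarray, Q: np.ndarray, thresholds) -> dict[float, int]:
    """Exhaustive GDT oracle: best inlier count over Kabsch fits on every
    subset of size >= 3 (feasible up to ~12 points)."""
    n = len(P)
    best = {t: 0 for t in thresholds}
    for r in range(3, n + 1):
        for sub in itertools.combinations(range(n), r):
            idx = list(sub)
            R, t = quat_kabsch(P[idx], Q[idx])
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            for thr in thresholds:
                c = int((d <= thr).sum())
                if c > best[thr]:
                    best[thr] = c
    return best


def structured_gdt_instance(rng: np.random.Generator):
    """A rigid-consistent core with small jitter plus outliers displaced far
    beyond every GDT cut-off — the regime the search is designed for."""
    from scipy.spatial.transform import Rotation

    n = int(rng.integers(6, 11))
    P = rng.normal(size=(n, 3)) * 4
    Rm = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    sigma = rng.choice([0.02, 0.05, 0.08])
    Q = P @ Rm.T + rng.normal(size=3) * 5 + rng.normal(size=(n, 3)) * sigma
    k = int(rng.integers(0, 4))
    if k:
        idx = rng.choice(n, k, replace=False)
        disp = rng.normal(size=(k, 3))
        disp = disp / np.linalg.norm(disp, axis=1, keepdims=True) * rng.uniform(25, 40, size=(k, 1))
        Q[idx] += disp
    return P, Q


def diana_terminal_partitions(d: np.ndarray) -> tuple[int, set[frozenset]]:
    """All terminal splinter sets reachable from the max-average-dissimilarity
    seed by ANY order of legal moves (move while the object's average
    dissimilarity to its own group exceeds that to the splinter)."""
    n = len(d)
    seed = int(np.argmax(d.sum(axis=1) / (n - 1)))
    terminals: set[frozenset] = set()
    seen: set[frozenset] = set()
    stack = [frozenset([seed])]
    while stack:
        S = stack.pop()
        if S in seen:
            continue
        seen.add(S)
        T = [i for i in range(n) if i not in S]
        movers = []
        for j in T:
            others = [t for t in T if t != j]
            gain = (d[j, others].mean() if others else 0.0) - d[j, list(S)].mean()
            if gain > 0:
                movers.append(j)
        if not movers:
            terminals.add(S)
        else:
            for j in movers:
                stack.append(S | {j})
    return seed, terminals


def naive_average_linkage_heights(d: np.ndarray) -> np.ndarray:
    """Average-linkage merge heights from the direct recursive definition."""
    clusters = [[i] for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = d[np.ix_(clusters[a], clusters[b])].mean()
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return np.array(heights)
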
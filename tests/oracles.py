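"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately avoids the code path it checks: DTW by explicit
enumeration of all monotone continuous warping paths, DBSCAN by direct
density-reachability construction, the silhouette by naive double loops.
"""

from __future__ import annotations

import numpy as np


def dtw_brute_force(x: np.ndarray, y: np.ndarray,
                    window: int | None = None) -> float:
    """Minimum path-ordered cost over every monotone continuous warping
    path from (0, 0) to (nx−1, ny−1); exponential enumeration, tiny inputs
    only."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx, ny = x.shape[0], y.shape[0]

    def cost(s: int, u: int) -> float:
        return float(np.sqrt(np.sum((x[s] - y[u]) ** 2)))

    def in_band(s: int, u: int) -> bool:
        return window is None or abs(s - u) <= window

    best = [np.inf]

    def walk(s: int, u: int, acc: float) -> None:
        if s == nx - 1 and u == ny - 1:
            best[0] = min(best[0], acc)
            return
        for ds, du in ((1, 1), (1, 0), (0, 1)):
            ns, nu = s + ds, u + du
            if ns < nx and nu < ny and in_band(ns, nu):
                walk(ns, nu, acc + cost(ns, nu))

    if in_band(0, 0):
        walk(0, 0, cost(0, 0))
    return best[0]


def dbscan_brute_force(
    dist: np.ndarray, eps: float, min_pts: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Direct density-reachability DBSCAN.

    Core points have >= min_pts neighbours (self included) within the
    closed eps-ball; clusters are connected components of the core–core
    eps-graph; each non-core point within eps of a core joins that core's
    component.  Returns (labels, is_core, ambiguous) where ``ambiguous``
    flags a border point eps-reachable from cores of two different
    components (the one case where label assignment is order dependent).
    """
    n = dist.shape[0]
    within = dist <= eps
    is_core = within.sum(axis=1) >= min_pts
    core_idx = np.flatnonzero(is_core)

    # connected components of the core-core graph
    comp = {int(i): -1 for i in core_idx}
    cid = 0
    for i in core_idx:
        if comp[int(i)] != -1:
            continue
        stack = [int(i)]
        comp[int(i)] = cid
        while stack:
            p = stack.pop()
            for q in core_idx:
                q = int(q)
                if within[p, q] and comp[q] == -1:
                    comp[q] = cid
                    stack.append(q)
        cid += 1

    labels = np.full(n, -1, dtype=int)
    ambiguous = False
    for i in range(n):
        if is_core[i]:
            labels[i] = comp[i]
            continue
        owners = {comp[int(c)] for c in core_idx if within[i, c]}
        if len(owners) > 1:
            ambiguous = True
        if owners:
            labels[i] = min(owners)  # arbitrary; only used when unambiguous
    return labels, is_core, ambiguous


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Partition equality up to label permutation, with identical noise."""
    a = np.asarray(a)
    b = np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    grp_a = {frozenset(np.flatnonzero(a == c)) for c in set(a) if c != -1}
    grp_b = {frozenset(np.flatnonzero(b == c)) for c in set(b) if c != -1}
    return grp_a == grp_b


def silhouette_brute_force(
    dist: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Naive silhouette: double loops over all pairs; noise (−1) excluded.

    a_i divides by |C_I| − 1 (self excluded); singleton clusters get 0.
    """
    n = dist.shape[0]
    cids = sorted(c for c in set(labels.tolist()) if c != -1)
    s = np.full(n, np.nan)
    for i in range(n):
        if labels[i] == -1:
            continue
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s[i] = 0.0
            continue
        a = np.mean(np.array([dist[i, j] for j in own]))
        b = np.inf
        for c in cids:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean(np.array([dist[i, j] for j in members])))
        s[i] = (b - a) / max(a, b)
    clustered = labels != -1
    return s, float(np.mean(s[clustered]))


def random_blob_instance(rng: np.random.Generator, n_max: int = 40):
    """Planted Gaussian blobs plus uniform noise; Euclidean distances."""
    n_blobs = int(rng.integers(1, 4))
    pts = []
    for _ in range(n_blobs):
        center = rng.uniform(-10, 10, size=2)
        k = int(rng.integers(3, 10))
        pts.append(center + rng.normal(0, 0.5, size=(k, 2)))
    n_noise = int(rng.integers(0, 6))
    if n_noise:
        pts.append(rng.uniform(-12, 12, size=(n_noise, 2)))
    x = np.vstack(pts)[:n_max]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return d
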
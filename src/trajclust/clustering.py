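"""DBSCAN on a precomputed trajectory distance matrix, and parameter scans.

The classic DBSCAN algorithm is implemented directly on the pairwise
distance matrix: a trajectory is a *core* point when at least ``min_pts``
trajectories (itself included) lie within radius ``eps`` (closed ball,
≤ ε); clusters are the maximal density-connected sets grown from core
points; non-core points within ε of some core point become *border* points
of that core's cluster; everything else is *noise* (label −1).

Because border-point assignment in DBSCAN is order dependent, a canonical
processing order — ascending trajectory index, cluster ids in order of
first core point encountered — makes every run bit-reproducible.

``scan_parameters`` repeats the clustering over a grid of (ε, MinPts)
pairs, recording the cluster count N_C, the noise count N_noise, and the
average silhouette coefficient S_avg per cell; cells with fewer than two
clusters carry NaN for S_avg (the silhouette needs a nearest *other*
cluster).  ``best_cells`` ranks cells by S_avg, preferring low noise on
ties — mirroring how the best (ε, MinPts) combinations are picked from the
scan heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .similarity import DistanceMatrix

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass
class ClusterLabels:
    """Per-trajectory DBSCAN assignment.

    ``labels[i]`` is the cluster id of trajectory ``i`` (consecutive
    integers 0..N_C−1) or −1 for noise; ``is_core`` flags core points.
    """

    labels: np.ndarray
    is_core: np.ndarray
    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.is_core = np.asarray(self.is_core, dtype=bool)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if np.any(self.labels >= 0) else 0

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def cluster_members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)

    def sizes(self) -> list[int]:
        return [int(np.sum(self.labels == c)) for c in range(self.n_clusters)]


def region_query(dm: DistanceMatrix, i: int, eps: float) -> np.ndarray:
    """Indices within the closed ε-ball of trajectory ``i`` (``i`` included)."""
    if eps <= 0:
        raise ParameterError(f"eps must be positive, got {eps}")
    return np.flatnonzero(dm.values[i] <= eps)


def dbscan(dm: DistanceMatrix, eps: float, min_pts: int) -> ClusterLabels:
    """Classic DBSCAN on a precomputed distance matrix.

    ``min_pts`` counts the point itself (the original convention).  Seeds
    are processed in ascending trajectory index, which also fixes how a
    border point reachable from cores of two clusters is assigned: to the
    cluster discovered first.
    """
    if min_pts < 1:
        raise ParameterError(f"min_pts must be >= 1, got {min_pts}")
    if eps <= 0:
        raise ParameterError(f"eps must be positive, got {eps}")
    v = dm.values
    if not np.array_equal(v, v.T) or np.any(v < 0):
        raise ContractError("dbscan needs a symmetric nonnegative matrix")

    n = dm.n_traj
    within = v <= eps
    neighbor_counts = within.sum(axis=1)
    is_core = neighbor_counts >= min_pts

    labels = np.full(n, NOISE, dtype=int)
    cid = 0
    for seed in range(n):
        if not is_core[seed] or labels[seed] != NOISE:
            continue
        # Grow one density-connected cluster from this unassigned core.
        labels[seed] = cid
        frontier = [seed]
        while frontier:
            p = frontier.pop(0)
            if not is_core[p]:
                continue  # border points do not propagate density
            for q in np.flatnonzero(within[p]):
                if labels[q] == NOISE:
                    labels[q] = cid
                    if is_core[q]:
                        frontier.append(int(q))
        cid += 1
    return ClusterLabels(labels=labels, is_core=is_core,
                         eps=float(eps), min_pts=int(min_pts))


# ---------------------------------------------------------------------------
# Parameter scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Grid of clustering outcomes over (ε, MinPts).

    ``s_avg`` holds NaN where fewer than two clusters were found (silhouette
    undefined); all grids share shape (len(eps_grid), len(minpts_grid)).
    """

    eps_grid: np.ndarray
    minpts_grid: np.ndarray
    n_clusters: np.ndarray
    n_noise: np.ndarray
    s_avg: np.ndarray
    labels_per_cell: list[list[ClusterLabels]] = field(repr=False, default=None)

    def to_tidy(self) -> pd.DataFrame:
        """Long-form table: eps, min_pts, n_clusters, n_noise, s_avg."""
        recs = []
        for a, eps in enumerate(self.eps_grid):
            for b, mp in enumerate(self.minpts_grid):
                recs.append(
                    {
                        "eps": float(eps),
                        "min_pts": int(mp),
                        "n_clusters": int(self.n_clusters[a, b]),
                        "n_noise": int(self.n_noise[a, b]),
                        "s_avg": float(self.s_avg[a, b]),
                    }
                )
        return pd.DataFrame(recs)


def scan_parameters(
    dm: DistanceMatrix,
    eps_grid: np.ndarray,
    minpts_grid: np.ndarray,
) -> ScanResult:
    """Run DBSCAN + silhouette on every (ε, MinPts) grid cell.

    The distance matrix is computed once and reused across the whole scan —
    the expensive stage is the matrix, not the clustering.
    """
    from .diagnostics import silhouette  # deferred: diagnostics uses this module's types

    eps_grid = np.asarray(eps_grid, dtype=float)
    minpts_grid = np.asarray(minpts_grid, dtype=int)
    if eps_grid.size == 0 or minpts_grid.size == 0:
        raise ParameterError("scan grids must be nonempty")

    shape = (eps_grid.size, minpts_grid.size)
    n_clusters = np.zeros(shape, dtype=int)
    n_noise = np.zeros(shape, dtype=int)
    s_avg = np.full(shape, np.nan)
    labels_grid: list[list[ClusterLabels]] = []
    for a, eps in enumerate(eps_grid):
        row = []
        for b, mp in enumerate(minpts_grid):
            try:
                cl = dbscan(dm, float(eps), int(mp))
            except (ParameterError, ContractError) as exc:
                raise type(exc)(
                    f"scan cell (eps={eps}, min_pts={mp}): {exc}"
                ) from exc
            n_clusters[a, b] = cl.n_clusters
            n_noise[a, b] = cl.n_noise
            if cl.n_clusters >= 2:
                s_avg[a, b] = silhouette(dm, cl).s_avg
            row.append(cl)
        labels_grid.append(row)
    return ScanResult(
        eps_grid=eps_grid,
        minpts_grid=minpts_grid,
        n_clusters=n_clusters,
        n_noise=n_noise,
        s_avg=s_avg,
        labels_per_cell=labels_grid,
    )


def best_cells(
    scan: ScanResult,
    max_noise: int | None = None,
    n_clusters: int | None = None,
) -> list[dict]:
    """Rank scan cells by S_avg (descending), ties by lower N_noise, then
    lower ε; cells violating the optional constraints are excluded, and
    cells with undefined S_avg never rank."""
    cells = []
    for a, eps in enumerate(scan.eps_grid):
        for b, mp in enumerate(scan.minpts_grid):
            s = scan.s_avg[a, b]
            if np.isnan(s):
                continue
            if max_noise is not None and scan.n_noise[a, b] > max_noise:
                continue
            if n_clusters is not None and scan.n_clusters[a, b] != n_clusters:
                continue
            cells.append(
                {
                    "eps": float(eps),
                    "min_pts": int(mp),
                    "n_clusters": int(scan.n_clusters[a, b]),
                    "n_noise": int(scan.n_noise[a, b]),
                    "s_avg": float(s),
                    "labels": (
                        scan.labels_per_cell[a][b]
                        if scan.labels_per_cell is not None
                        else None
                    ),
                }
            )
    if not cells:
        logger.warning("best_cells: no cell satisfies the constraints")
        return []
    cells.sort(key=lambda c: (-c["s_avg"], c["n_noise"], c["eps"]))
    return cells


def suggest_eps_grid(
    dm: DistanceMatrix,
    min_pts: int,
    n: int = 20,
    quantile: float = 95.0,
    span: float = 2.5,
) -> np.ndarray:
    """Data-driven ε scan range from the k-distance heuristic.

    For each trajectory the distance to its ``min_pts``-th nearest neighbour
    (self excluded) is computed; the scan runs from the ``quantile``-th
    percentile of that k-distance distribution (the top of the bulk — below
    it clusters shred into cores and noise) up to ``span`` times that value
    (above the merge scale little changes until clusters fuse).
    """
    if min_pts < 1:
        raise ParameterError(f"min_pts must be >= 1, got {min_pts}")
    if n < 1:
        raise ParameterError(f"grid size must be >= 1, got {n}")
    d_k = np.sort(dm.values, axis=1)[:, min(min_pts, dm.n_traj - 1)]
    lo = float(np.percentile(d_k, quantile))
    if lo <= 0:
        lo = float(np.max(d_k)) or 1.0
    return np.linspace(lo, span * lo, n)


# ---------------------------------------------------------------------------
# Grid parsing and I/O helpers
# ---------------------------------------------------------------------------

def parse_grid(spec: str, integer: bool = False) -> np.ndarray:
    """Parse a CLI grid triple ``start:stop:step`` (stop inclusive up to
    floating-point slack); a bare number gives a single-value grid."""
    parts = spec.split(":")
    try:
        if len(parts) == 1:
            vals = np.array([float(parts[0])])
        elif len(parts) == 3:
            start, stop, step = (float(p) for p in parts)
            if step <= 0 or stop < start:
                raise ValueError
            n = int(np.floor((stop - start) / step + 1e-9)) + 1
            vals = start + step * np.arange(n)
        else:
            raise ValueError
    except ValueError:
        raise ParameterError(
            f"malformed grid {spec!r}; expected 'start:stop:step' or a number"
        ) from None
    return vals.astype(int) if integer else vals


def save_labels_csv(path: str | Path, labels: ClusterLabels,
                    traj_ids: list[str]) -> None:
    pd.DataFrame(
        {
            "traj_id": traj_ids,
            "label": labels.labels,
            "is_core": labels.is_core,
        }
    ).to_csv(path, index=False)


def load_labels_csv(path: str | Path) -> tuple[ClusterLabels, list[str]]:
    df = pd.read_csv(path)
    cl = ClusterLabels(
        labels=df["label"].to_numpy(dtype=int),
        is_core=df["is_core"].to_numpy(dtype=bool),
        eps=float("nan"),
        min_pts=0,
    )
    return cl, [str(t) for t in df["traj_id"]]


def plot_scan_heatmaps(scan: ScanResult, out_path: str | Path) -> None:
    """Heatmap triptych (S_avg, N_C, N_noise) over the (ε, MinPts) grid."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6), constrained_layout=True)
    panels = [
        (scan.s_avg, "S_avg", "viridis"),
        (scan.n_clusters.astype(float), "N_C", "magma"),
        (scan.n_noise.astype(float), "N_noise", "cividis"),
    ]
    for ax, (grid, title, cmap) in zip(axes, panels):
        im = ax.imshow(
            grid.T, origin="lower", aspect="auto", cmap=cmap,
            extent=(
                scan.eps_grid[0], scan.eps_grid[-1],
                scan.minpts_grid[0], scan.minpts_grid[-1],
            ),
        )
        ax.set_xlabel("eps")
        ax.set_ylabel("MinPts")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
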
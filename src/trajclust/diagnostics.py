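"""Cluster validation and interpretation.

Silhouette statistics quantify how well each trajectory sits in its cluster:
a_i is the mean distance from trajectory i to the other members of its
cluster, b_i the smallest mean distance to any other cluster, and
s_i = (b_i − a_i) / max(a_i, b_i) ∈ [−1, 1].  Noise trajectories are
excluded from every mean and from the ensemble average S_avg, which is
taken over clustered trajectories only.  The same distance matrix used for
clustering (L2 or DTW) is reused — silhouettes are never recomputed under a
different metric.

Interpretation aids: per-cluster mean time series of the (unnormalized,
physical-unit) features with a standard-deviation envelope, medoid-based
representative trajectories, and the final-time electronic-state population
split per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import NOISE, ClusterLabels
from .errors import ContractError, FeatureUnavailableError, ValidationError
from .features import FeatureMatrix
from .similarity import DistanceMatrix
from .trajectory_io import TrajectoryEnsemble

logger = logging.getLogger(__name__)


@dataclass
class SilhouetteReport:
    """Per-trajectory silhouette coefficients and cluster summaries.

    ``s_i``, ``a_i`` and ``b_i`` are NaN for noise trajectories; ``s_avg``
    is the mean of the defined ``s_i``.
    """

    s_i: np.ndarray
    a_i: np.ndarray
    b_i: np.ndarray
    s_avg: float
    per_cluster: pd.DataFrame


def silhouette(
    dm: DistanceMatrix,
    labels: ClusterLabels,
    intra_denominator: str = "exclude_self",
) -> SilhouetteReport:
    """Silhouette coefficients from a precomputed distance matrix.

    ``intra_denominator`` selects the a_i convention: ``"exclude_self"``
    (the standard — mean over the |C_I| − 1 *other* members) or
    ``"literal"`` (divide the same sum by |C_I|, for sensitivity checks).
    Singleton clusters get s_i = 0 by convention.  Requires at least two
    clusters; noise trajectories carry NaN and are excluded from s_avg.
    """
    if intra_denominator not in ("exclude_self", "literal"):
        raise ValidationError(
            f"unknown intra_denominator {intra_denominator!r}"
        )
    lab = labels.labels
    if lab.shape[0] != dm.n_traj:
        raise ContractError(
            f"labels cover {lab.shape[0]} trajectories but the matrix has "
            f"{dm.n_traj}"
        )
    ncl = labels.n_clusters
    if ncl < 2:
        raise ValidationError(
            f"silhouette needs >= 2 clusters, got {ncl}"
        )
    n = dm.n_traj
    v = dm.values
    members = [np.flatnonzero(lab == c) for c in range(ncl)]

    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    s = np.full(n, np.nan)
    for i in range(n):
        ci = lab[i]
        if ci == NOISE:
            continue
        own = members[ci]
        if own.size == 1:
            s[i] = 0.0
            a[i] = 0.0
            # b_i still reported for completeness
            b[i] = min(
                v[i, members[cj]].mean() for cj in range(ncl) if cj != ci
            )
            continue
        others = own[own != i]
        if intra_denominator == "exclude_self":
            a[i] = v[i, others].mean()
        else:
            a[i] = v[i, others].sum() / own.size
        b[i] = min(
            v[i, members[cj]].mean() for cj in range(ncl) if cj != ci
        )
        s[i] = (b[i] - a[i]) / max(a[i], b[i])

    clustered = lab != NOISE
    s_avg = float(np.mean(s[clustered]))

    rows = []
    for c in range(ncl):
        sc = s[members[c]]
        rows.append(
            {
                "cluster": c,
                "size": members[c].size,
                "mean_s": float(np.mean(sc)),
                "min_s": float(np.min(sc)),
                "n_negative": int(np.sum(sc < 0)),
            }
        )
    return SilhouetteReport(
        s_i=s, a_i=a, b_i=b, s_avg=s_avg, per_cluster=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# Cluster centers and spreads
# ---------------------------------------------------------------------------

@dataclass
class ClusterCenters:
    """Per-cluster mean time series and spread envelope, physical units."""

    centers: np.ndarray  # (n_clusters, n_time, n_feat)
    spreads: np.ndarray  # same shape; std (default) or half the band
    cluster_ids: list[int]
    feature_labels: list[str]
    times: np.ndarray
    band: str = "std"


def cluster_center_timeseries(
    fm: FeatureMatrix,
    labels: ClusterLabels,
    band: str = "std",
    percentile: float = 90.0,
) -> ClusterCenters:
    """Member-mean time series per cluster and feature, with an envelope.

    Expects the *unnormalized* feature matrix so curves carry physical units
    (Å, degrees).  ``band`` is ``"std"`` (member standard deviation, the
    default), ``"percentile"`` (half the central-percentile width) or
    ``"minmax"`` (half the full range).  Noise trajectories are excluded;
    empty clusters are skipped with a warning.
    """
    if band not in ("std", "percentile", "minmax"):
        raise ValidationError(f"unknown band type {band!r}")
    ncl = labels.n_clusters
    kept: list[int] = []
    centers, spreads = [], []
    for c in range(ncl):
        m = labels.cluster_members(c)
        if m.size == 0:
            logger.warning("cluster %d has no members; skipped", c)
            continue
        vals = fm.values[m]  # (size, n_time, n_feat)
        centers.append(vals.mean(axis=0))
        if band == "std":
            spreads.append(vals.std(axis=0, ddof=0))
        elif band == "percentile":
            lo = np.percentile(vals, 50 - percentile / 2, axis=0)
            hi = np.percentile(vals, 50 + percentile / 2, axis=0)
            spreads.append((hi - lo) / 2)
        else:
            spreads.append((vals.max(axis=0) - vals.min(axis=0)) / 2)
        kept.append(c)
    return ClusterCenters(
        centers=np.array(centers),
        spreads=np.array(spreads),
        cluster_ids=kept,
        feature_labels=fm.labels,
        times=fm.times,
        band=band,
    )


# ---------------------------------------------------------------------------
# Representatives (medoids)
# ---------------------------------------------------------------------------

def select_representatives(
    dm: DistanceMatrix, labels: ClusterLabels, k: int = 1
) -> dict[int, list[int]]:
    """Per cluster, the ``k`` medoids: members with the smallest total
    intra-cluster distance, ties broken by ascending trajectory index.
    ``k`` larger than a cluster is truncated with a warning."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    out: dict[int, list[int]] = {}
    for c in range(labels.n_clusters):
        m = labels.cluster_members(c)
        totals = dm.values[np.ix_(m, m)].sum(axis=1)
        kk = k
        if kk > m.size:
            logger.warning(
                "cluster %d has %d members < k=%d; truncating", c, m.size, k
            )
            kk = m.size
        order = np.lexsort((m, totals))  # total distance, then index
        out[c] = [int(m[o]) for o in order[:kk]]
    return out


# ---------------------------------------------------------------------------
# Electronic-population breakdown
# ---------------------------------------------------------------------------

def population_split(
    ensemble: TrajectoryEnsemble,
    labels: ClusterLabels,
    t: float,
    states: tuple[int, int] = (0, 1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Electronic-state populations at time ``t`` per trajectory and cluster.

    Returns a scatter table (traj_id, P_a, P_b, cluster) and a per-cluster
    summary with the fraction of members whose P_a strictly exceeds P_b —
    the dominant-state classification by the x = y line; a member exactly on
    the line counts as not dominant-a.  ``t`` is matched to the nearest
    frame, with the offset logged when not exact.
    """
    if ensemble.populations is None:
        raise FeatureUnavailableError(
            "population_split needs state populations attached to the ensemble"
        )
    sa, sb = states
    n_states = ensemble.populations.shape[2]
    if not (0 <= sa < n_states and 0 <= sb < n_states):
        raise ValidationError(
            f"state indices {states} outside [0, {n_states - 1}]"
        )
    ti = int(np.argmin(np.abs(ensemble.times - t)))
    if ensemble.times[ti] != t:
        logger.info(
            "time %.3f fs matched to nearest frame at %.3f fs", t,
            ensemble.times[ti],
        )
    pa = ensemble.populations[:, ti, sa]
    pb = ensemble.populations[:, ti, sb]
    scatter = pd.DataFrame(
        {
            "traj_id": ensemble.traj_ids,
            "P_a": pa,
            "P_b": pb,
            "cluster": labels.labels,
        }
    )
    rows = []
    for c in range(labels.n_clusters):
        m = labels.cluster_members(c)
        frac = float(np.mean(pa[m] > pb[m]))
        rows.append(
            {
                "cluster": c,
                "size": m.size,
                "dominant_a_fraction": frac,
                "mean_P_a": float(pa[m].mean()),
                "mean_P_b": float(pb[m].mean()),
            }
        )
    return scatter, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_silhouettes(report: SilhouetteReport, labels: ClusterLabels,
                     out_path) -> None:
    """Sorted per-cluster silhouette bars with a dashed S_avg line."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.2))
    y = 0
    for c in range(labels.n_clusters):
        sc = np.sort(report.s_i[labels.cluster_members(c)])[::-1]
        ax.barh(
            np.arange(y, y + sc.size), sc, height=1.0,
            label=f"cluster {c} (n={sc.size})",
        )
        y += sc.size + 2
    ax.axvline(report.s_avg, ls="--", color="red",
               label=f"S_avg = {report.s_avg:.3f}")
    ax.set_xlabel("silhouette coefficient S_i")
    ax.set_yticks([])
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_cluster_centers(cc: ClusterCenters, out_path) -> None:
    """One panel per feature: cluster-center curves with shaded envelopes."""
    import matplotlib.pyplot as plt

    n_feat = len(cc.feature_labels)
    ncols = 2
    nrows = (n_feat + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(9, 3.2 * nrows), squeeze=False,
        constrained_layout=True,
    )
    for f, lab in enumerate(cc.feature_labels):
        ax = axes[f // ncols][f % ncols]
        for idx, c in enumerate(cc.cluster_ids):
            mid = cc.centers[idx, :, f]
            half = cc.spreads[idx, :, f]
            ax.plot(cc.times, mid, label=f"cluster {c}")
            ax.fill_between(cc.times, mid - half, mid + half, alpha=0.25)
        ax.set_xlabel("time / fs")
        ax.set_ylabel(lab)
        if f == 0:
            ax.legend(fontsize=8)
    for f in range(n_feat, nrows * ncols):
        axes[f // ncols][f % ncols].set_axis_off()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_population_scatter(scatter: pd.DataFrame, out_path,
                            state_names: tuple[str, str] = ("S0", "S1")) -> None:
    """Final-time population scatter with the x = y guide line."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for c in sorted(scatter["cluster"].unique()):
        sub = scatter[scatter["cluster"] == c]
        name = "noise" if c == NOISE else f"cluster {c}"
        ax.scatter(sub["P_a"], sub["P_b"], s=18, label=name,
                   marker="x" if c == NOISE else "o")
    lim = max(1.0, scatter[["P_a", "P_b"]].to_numpy().max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel(f"P({state_names[0]})")
    ax.set_ylabel(f"P({state_names[1]})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
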
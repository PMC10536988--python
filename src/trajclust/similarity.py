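"""Pairwise trajectory distances: multidimensional Lp norm and MD-DTW.

Two similarity measures operate on the (time × feature) series of a pair of
trajectories:

* the multidimensional Lp norm (p = 2 by default),
  d = (Σ_t Σ_f |x_tf − y_tf|^p)^(1/p), a strict 1:1 mapping of time points
  requiring equal lengths;
* dependent multidimensional dynamic time warping (MD-DTW): one shared
  monotone warping path over all features, local cost the Euclidean distance
  across features at a pair of time points, accumulated by dynamic
  programming with the symmetric step pattern {(−1,0), (0,−1), (−1,−1)} and
  unit weights.  A Sakoe–Chiba band of width ``window`` limits how far the
  path may leave the diagonal, i.e. how much frequency invariance is
  allowed; the DTW cost is NOT normalized by path length, so DTW and L2
  distances live on different scales.

Either measure fills a symmetric :class:`DistanceMatrix` that downstream
DBSCAN consumes as precomputed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from numba import njit

from .errors import ContractError, ParameterError, ValidationError
from .features import FeatureMatrix

DEFAULT_WINDOW_FRACTION = 0.05  # default band half-width as fraction of N_t


@dataclass
class WarpingPath:
    """An optimal DTW alignment: monotone, continuous index pairs."""

    steps: list[tuple[int, int]]  # zero-based (s, u) pairs
    total_cost: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise trajectory distances tagged with their metric."""

    values: np.ndarray  # (n_traj, n_traj)
    metric: str  # "l2" | "md_dtw"
    traj_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(self.traj_ids) != v.shape[0]:
            raise ValidationError("traj_ids length must match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix has non-finite entries")
        if np.any(v < 0):
            raise ValidationError("distances must be nonnegative")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.array_equal(v, v.T):
            raise ValidationError("distance matrix must be symmetric")

    @property
    def n_traj(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Lp norm
# ---------------------------------------------------------------------------

def l2_distance(x: np.ndarray, y: np.ndarray, p: float = 2.0) -> float:
    """Multidimensional Lp distance between two equal-length series.

    ``x`` and ``y`` are (N_t, N_f); the sum runs over all time steps and
    features before the 1/p power is taken.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ContractError(
            f"Lp norm requires equal shapes, got {x.shape} vs {y.shape}"
        )
    if p < 1:
        raise ParameterError(f"norm order p must be >= 1, got {p}")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

def dtw_local_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Local cost between two time points: Euclidean distance over features
    (dependent MD-DTW: one shared warping over all features)."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ContractError(
            f"local cost requires equal feature counts, got {a.shape} vs {b.shape}"
        )
    return float(np.linalg.norm(a - b))


@njit(cache=True)
def _dtw_dp(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Accumulated-cost matrix with a Sakoe–Chiba band; inf outside band."""
    nx, ny = x.shape[0], y.shape[0]
    nf = x.shape[1]
    D = np.full((nx, ny), np.inf)
    for s in range(nx):
        lo = 0 if window < 0 else max(0, s - window)
        hi = ny if window < 0 else min(ny, s + window + 1)
        for u in range(lo, hi):
            c = 0.0
            for f in range(nf):
                d = x[s, f] - y[u, f]
                c += d * d
            c = np.sqrt(c)
            if s == 0 and u == 0:
                D[s, u] = c
            else:
                best = np.inf
                if s > 0 and u > 0 and D[s - 1, u - 1] < best:
                    best = D[s - 1, u - 1]
                if s > 0 and D[s - 1, u] < best:
                    best = D[s - 1, u]
                if u > 0 and D[s, u - 1] < best:
                    best = D[s, u - 1]
                D[s, u] = c + best
    return D


def dtw_distance(
    x: np.ndarray,
    y: np.ndarray,
    window: int | None = None,
) -> tuple[float, WarpingPath]:
    """Banded MD-DTW distance and one optimal warping path.

    ``window`` is the Sakoe–Chiba band half-width in time steps (``None``
    for unconstrained).  The path starts at the first index pair, ends at
    the last, and each step advances one or both indices by exactly 1.
    Back-tracing ties are broken deterministically: diagonal first, then the
    step that advances ``x`` only, then the step that advances ``y`` only
    (the distance itself is unaffected).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.ndim != 2 or y.ndim != 2:
        raise ContractError("DTW inputs must be (N_t, N_f) arrays")
    if x.shape[1] != y.shape[1]:
        raise ContractError(
            f"DTW requires equal feature counts, got {x.shape[1]} vs {y.shape[1]}"
        )
    nx, ny = x.shape[0], y.shape[0]
    if window is not None:
        if window < 0:
            raise ParameterError(f"window must be nonnegative, got {window}")
        if abs(nx - ny) > window:
            raise ParameterError(
                f"band of width {window} cannot align lengths {nx} and {ny}"
            )
    w = -1 if window is None else int(window)
    D = _dtw_dp(x, y, w)
    dist = float(D[nx - 1, ny - 1])
    if not np.isfinite(dist):
        raise ParameterError("no feasible warping path within the band")

    # Back-trace one optimal path (diagonal > advance-x > advance-y on ties).
    s, u = nx - 1, ny - 1
    rev = [(s, u)]
    while (s, u) != (0, 0):
        cands: list[tuple[float, int, int]] = []
        if s > 0 and u > 0:
            cands.append((D[s - 1, u - 1], s - 1, u - 1))
        if s > 0:
            cands.append((D[s - 1, u], s - 1, u))
        if u > 0:
            cands.append((D[s, u - 1], s, u - 1))
        best = min(c[0] for c in cands)
        for cost, ps, pu in cands:  # first match respects the tie order
            if cost == best:
                s, u = ps, pu
                break
        rev.append((s, u))
    rev.reverse()
    return dist, WarpingPath(steps=rev, total_cost=dist)


def default_dtw_window(n_time: int) -> int:
    """Default band half-width: 5% of the series length, at least 1 step."""
    return max(1, round(DEFAULT_WINDOW_FRACTION * n_time))


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pairwise_l2(values: np.ndarray, p: float) -> np.ndarray:
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            acc = 0.0
            for s in range(values.shape[1]):
                for f in range(values.shape[2]):
                    acc += np.abs(values[i, s, f] - values[j, s, f]) ** p
            d = acc ** (1.0 / p)
            out[i, j] = d
            out[j, i] = d
    return out


@njit(cache=True)
def _pairwise_dtw(values: np.ndarray, window: int) -> np.ndarray:
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D = _dtw_dp(values[i], values[j], window)
            d = D[values.shape[1] - 1, values.shape[1] - 1]
            out[i, j] = d
            out[j, i] = d
    return out


def pairwise_distance_matrix(
    fm: FeatureMatrix,
    metric: str = "l2",
    p: float = 2.0,
    window: int | None = None,
    allow_unnormalized: bool = False,
) -> DistanceMatrix:
    """Compute all unordered-pair distances for an ensemble's feature matrix.

    Features are expected min–max normalized (normalization precedes
    distance computation); pass ``allow_unnormalized=True`` to override.
    For ``metric="md_dtw"`` the band half-width defaults to 5% of the
    series length; the window actually used is recorded in ``params``.
    """
    if not fm.normalized and not allow_unnormalized:
        raise ContractError(
            "pairwise distances expect a normalized feature matrix "
            "(pass allow_unnormalized=True to override)"
        )
    if metric == "l2":
        if p < 1:
            raise ParameterError(f"norm order p must be >= 1, got {p}")
        values = _pairwise_l2(np.ascontiguousarray(fm.values), float(p))
        params = {"p": float(p)}
    elif metric == "md_dtw":
        if window is None:
            window = default_dtw_window(fm.n_time)
        if window < 0:
            raise ParameterError(f"window must be nonnegative, got {window}")
        values = _pairwise_dtw(np.ascontiguousarray(fm.values), int(window))
        params = {"window": int(window)}
    else:
        raise ParameterError(
            f"unknown metric {metric!r}; expected 'l2' or 'md_dtw'"
        )
    return DistanceMatrix(
        values=values, metric=metric, traj_ids=list(fm.traj_ids), params=params
    )


def pairwise_dtw_ragged(
    series: Sequence[np.ndarray],
    traj_ids: Sequence[str],
    window: int | None = None,
) -> DistanceMatrix:
    """MD-DTW distance matrix for per-trajectory series of unequal length.

    Accepts a list of (N_t_i, N_f) arrays; DTW is the only metric that can
    compare different lengths, so no L2 variant exists here.
    """
    n = len(series)
    if n == 0:
        raise ValidationError("no series given")
    arrs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in series]
    nf = arrs[0].shape[1]
    if any(a.shape[1] != nf for a in arrs):
        raise ContractError("all series must share the feature count")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = dtw_distance(arrs[i], arrs[j], window=window)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(
        values=out,
        metric="md_dtw",
        traj_ids=list(traj_ids),
        params={"window": window, "ragged": True},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_distance_matrix_csv(path: str | Path, dm: DistanceMatrix) -> None:
    """Square CSV with traj_id header row/column; metric metadata in a
    sidecar comment line would not survive CSV round-trips, so it is stored
    in the first column name as ``metric=...;params=...``."""
    meta = f"metric={dm.metric};params={_params_str(dm.params)}"
    df = pd.DataFrame(dm.values, index=dm.traj_ids, columns=dm.traj_ids)
    df.index.name = meta
    df.to_csv(path)


def load_distance_matrix_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    meta = df.index.name or ""
    metric, params = _parse_meta(meta)
    return DistanceMatrix(
        values=df.to_numpy(dtype=float),
        metric=metric,
        traj_ids=[str(c) for c in df.columns],
        params=params,
    )


def save_distance_matrix_h5(path: str | Path, dm: DistanceMatrix) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=dm.values)
        h5.create_dataset("traj_ids", data=np.array(dm.traj_ids, dtype="S64"))
        h5.attrs["metric"] = dm.metric
        h5.attrs["params"] = _params_str(dm.params)


def load_distance_matrix_h5(path: str | Path) -> DistanceMatrix:
    with h5py.File(path, "r") as h5:
        metric = str(h5.attrs["metric"])
        _, params = _parse_meta(f"metric={metric};params={h5.attrs['params']}")
        return DistanceMatrix(
            values=h5["values"][()],
            metric=metric,
            traj_ids=[s.decode() for s in h5["traj_ids"][()]],
            params=params,
        )


def _params_str(params: dict) -> str:
    return ",".join(f"{k}:{v}" for k, v in sorted(params.items()))


def _parse_meta(meta: str) -> tuple[str, dict]:
    metric = "unknown"
    params: dict = {}
    for part in meta.split(";"):
        if part.startswith("metric="):
            metric = part[len("metric="):]
        elif part.startswith("params="):
            body = part[len("params="):]
            for kv in body.split(","):
                if ":" in kv:
                    k, v = kv.split(":", 1)
                    try:
                        params[k] = float(v) if "." in v else int(v)
                    except ValueError:
                        params[k] = v
    return metric, params
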
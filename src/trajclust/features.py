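"""Internal-coordinate features: extraction, normalization, variance ranking.

Each trajectory becomes a multivariate time series of internal coordinates
(bond lengths in Å, bend and dihedral angles in degrees).  Dihedral series
are unwrapped per trajectory by default so torsions tracked past ±180° stay
continuous — wrap-around jumps would corrupt both the L2 and the DTW
distance.  Features are min–max normalized to [0, 1] using global extrema
over all trajectories and times, and ranked by population variance on the
normalized values; clustering then uses a small number of top-variance
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import GeometryError, ParameterError, ValidationError
from .trajectory_io import TrajectoryEnsemble

logger = logging.getLogger(__name__)

_ARITY = {"bond": 2, "angle": 3, "dihedral": 4}


@dataclass(frozen=True)
class FeatureDefinition:
    """One internal coordinate: a bond, bend angle or dihedral.

    Atom indices are one-based, following chemical numbering (C1–C6 etc.);
    they are converted to zero-based indices only at evaluation time.
    ``unwrap`` applies to dihedrals only and is on by default there.
    """

    kind: str
    atom_indices: tuple[int, ...]
    label: str = ""
    unwrap: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _ARITY:
            raise ValidationError(
                f"unknown feature kind {self.kind!r}; "
                f"expected one of {sorted(_ARITY)}"
            )
        idx = tuple(int(i) for i in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        if len(idx) != _ARITY[self.kind]:
            raise ValidationError(
                f"{self.kind} feature needs {_ARITY[self.kind]} atoms, "
                f"got {len(idx)}"
            )
        if len(set(idx)) != len(idx):
            raise ValidationError(f"atom indices must be distinct, got {idx}")
        if min(idx) < 1:
            raise ValidationError(f"atom indices are one-based, got {idx}")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.kind}({','.join(map(str, idx))})"
            )


@dataclass
class FeatureMatrix:
    """trajectory × time × feature array of internal-coordinate values.

    ``feature_min``/``feature_max`` hold the pre-normalization global extrema
    per feature once :func:`minmax_normalize` has run, so normalized values
    can be mapped back to physical units.
    """

    values: np.ndarray  # (n_traj, n_time, n_feat)
    definitions: list[FeatureDefinition]
    traj_ids: list[str]
    times: np.ndarray
    normalized: bool = False
    feature_min: np.ndarray | None = None
    feature_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(
                f"feature values must be 3-D (traj, time, feature), "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[2] != len(self.definitions):
            raise ValidationError(
                "number of feature definitions must match the value array"
            )

    @property
    def n_traj(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def n_feat(self) -> int:
        return self.values.shape[2]

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.definitions]


# ---------------------------------------------------------------------------
# Geometry primitives (single frame)
# ---------------------------------------------------------------------------

def bond_length(frame: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance in Å between atoms ``i`` and ``j`` (one-based)."""
    if i == j:
        raise ValidationError("bond_length: atom indices must differ")
    frame = np.asarray(frame, dtype=float)
    return float(np.linalg.norm(frame[i - 1] - frame[j - 1]))


def bend_angle(frame: np.ndarray, i: int, j: int, k: int) -> float:
    """Bend angle i–j–k in degrees, apex at ``j``, in [0, 180]."""
    frame = np.asarray(frame, dtype=float)
    v1 = frame[i - 1] - frame[j - 1]
    v2 = frame[k - 1] - frame[j - 1]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("bend_angle: zero-length bond vector")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(frame: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i–j–k–l in degrees, principal range (−180, 180].

    Sign convention: looking from j towards k, a clockwise rotation of the
    far bond is positive.  Computed with the two-argument arctangent, which
    is numerically stable near 0° and 180°.
    """
    frame = np.asarray(frame, dtype=float)
    series = _dihedral_series(
        frame[None, :, :], i - 1, j - 1, k - 1, l - 1
    )
    return float(series[0])


def _dihedral_series(
    coords: np.ndarray, i: int, j: int, k: int, l: int
) -> np.ndarray:
    """Vectorized dihedral over frames; zero-based indices; (n_frames,)."""
    b1 = coords[:, j] - coords[:, i]
    b2 = coords[:, k] - coords[:, j]
    b3 = coords[:, l] - coords[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=1)
    n2n = np.linalg.norm(n2, axis=1)
    if np.any(n1n < 1e-10):
        raise GeometryError("dihedral undefined: atoms i, j, k are collinear")
    if np.any(n2n < 1e-10):
        raise GeometryError("dihedral undefined: atoms j, k, l are collinear")
    b2n = np.linalg.norm(b2, axis=1)
    if np.any(b2n < 1e-10):
        raise GeometryError("dihedral undefined: central bond has zero length")
    m1 = np.cross(n1, b2 / b2n[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # Negated atan2 realizes the clockwise-positive (from j to k) convention.
    ang = -np.degrees(np.arctan2(y, x))
    # Principal range (−180, 180]: fold an exact −180 onto +180.
    ang = np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)
    return ang


def unwrap_dihedral_series(series: np.ndarray) -> np.ndarray:
    """Remove ±360° jumps so consecutive steps satisfy \\|Δ\\| ≤ 180°.

    The first value is unchanged; each later value is shifted by a multiple
    of 360° to continue minimally from its predecessor.
    """
    series = np.asarray(series, dtype=float)
    return np.unwrap(series, period=360.0)


# ---------------------------------------------------------------------------
# Feature-matrix construction
# ---------------------------------------------------------------------------

def _evaluate_feature(
    coords: np.ndarray, d: FeatureDefinition
) -> np.ndarray:
    """Evaluate one feature over all frames of one trajectory; (n_time,)."""
    idx = tuple(a - 1 for a in d.atom_indices)
    if d.kind == "bond":
        i, j = idx
        return np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
    if d.kind == "angle":
        i, j, k = idx
        v1 = coords[:, i] - coords[:, j]
        v2 = coords[:, k] - coords[:, j]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        if np.any(n1 < 1e-10) or np.any(n2 < 1e-10):
            raise GeometryError("bend angle undefined: zero-length vector")
        cosang = np.clip(
            np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0
        )
        return np.degrees(np.arccos(cosang))
    i, j, k, l = idx
    series = _dihedral_series(coords, i, j, k, l)
    if d.unwrap:
        series = unwrap_dihedral_series(series)
    return series


def build_feature_matrix(
    ensemble: TrajectoryEnsemble,
    definitions: Sequence[FeatureDefinition],
) -> FeatureMatrix:
    """Evaluate every feature on every trajectory and frame (unnormalized).

    Dihedral features with ``unwrap=True`` are unwrapped per trajectory.
    Geometry errors are re-raised with (trajectory, feature) context.
    """
    definitions = list(definitions)
    if not definitions:
        raise ValidationError("build_feature_matrix: empty definition list")
    for d in definitions:
        if max(d.atom_indices) > ensemble.n_atoms:
            raise ValidationError(
                f"feature {d.label!r} references atom "
                f"{max(d.atom_indices)} but the ensemble has "
                f"{ensemble.n_atoms} atoms"
            )
    values = np.empty((ensemble.n_traj, ensemble.n_time, len(definitions)))
    for t in range(ensemble.n_traj):
        for f, d in enumerate(definitions):
            try:
                values[t, :, f] = _evaluate_feature(ensemble.coords[t], d)
            except GeometryError as exc:
                raise GeometryError(
                    f"trajectory {ensemble.traj_ids[t]!r}, "
                    f"feature {d.label!r}: {exc}"
                ) from exc
    return FeatureMatrix(
        values=values,
        definitions=definitions,
        traj_ids=list(ensemble.traj_ids),
        times=np.asarray(ensemble.times, dtype=float),
    )


# ---------------------------------------------------------------------------
# Normalization and variance ranking
# ---------------------------------------------------------------------------

def minmax_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Map every feature onto [0, 1] using its global extrema.

    The extrema are taken over all trajectories and all time steps of one
    feature, so one affine map applies ensemble-wide per feature.  Constant
    features map to 0 everywhere (logged); the extrema are stored on the
    result so values can be mapped back to physical units.
    """
    if fm.normalized:
        raise ValidationError("feature matrix is already normalized")
    fmin = fm.values.min(axis=(0, 1))
    fmax = fm.values.max(axis=(0, 1))
    span = fmax - fmin
    out = np.zeros_like(fm.values)
    for f in range(fm.n_feat):
        if span[f] == 0.0:
            logger.warning(
                "feature %r is constant; normalized to 0 everywhere",
                fm.definitions[f].label,
            )
        else:
            out[..., f] = (fm.values[..., f] - fmin[f]) / span[f]
    return FeatureMatrix(
        values=out,
        definitions=list(fm.definitions),
        traj_ids=list(fm.traj_ids),
        times=fm.times.copy(),
        normalized=True,
        feature_min=fmin,
        feature_max=fmax,
    )


def rank_features_by_variance(
    fm: FeatureMatrix, allow_unnormalized: bool = False
) -> list[tuple[FeatureDefinition, float]]:
    """Rank features by population variance, pooled over trajectories and
    times, in descending order; ties keep definition order.

    Ranking is defined on normalized data; ``allow_unnormalized=True``
    permits ranking raw values for diagnostics.
    """
    if not fm.normalized and not allow_unnormalized:
        raise ValidationError(
            "variance ranking expects a normalized feature matrix "
            "(pass allow_unnormalized=True to override)"
        )
    variances = fm.values.reshape(-1, fm.n_feat).var(axis=0, ddof=0)
    order = np.argsort(-variances, kind="stable")
    return [(fm.definitions[f], float(variances[f])) for f in order]


def select_features(
    ranked: Sequence[tuple[FeatureDefinition, float]], k: int
) -> list[FeatureDefinition]:
    """Return the top-``k`` features from a variance ranking."""
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k > len(ranked):
        raise ParameterError(
            f"k={k} exceeds the {len(ranked)} available features"
        )
    return [d for d, _ in ranked[:k]]


def subset_features(
    fm: FeatureMatrix, definitions: Sequence[FeatureDefinition]
) -> FeatureMatrix:
    """Restrict a feature matrix to the given definitions (in their order)."""
    pos = {d.label: f for f, d in enumerate(fm.definitions)}
    try:
        cols = [pos[d.label] for d in definitions]
    except KeyError as exc:
        raise ValidationError(f"feature {exc.args[0]!r} not in matrix") from None
    return FeatureMatrix(
        values=fm.values[..., cols],
        definitions=list(definitions),
        traj_ids=list(fm.traj_ids),
        times=fm.times.copy(),
        normalized=fm.normalized,
        feature_min=None if fm.feature_min is None else fm.feature_min[cols],
        feature_max=None if fm.feature_max is None else fm.feature_max[cols],
    )


# ---------------------------------------------------------------------------
# Configuration and serialization
# ---------------------------------------------------------------------------

def load_feature_definitions(path: str | Path) -> list[FeatureDefinition]:
    """Load feature definitions from a YAML list.

    Each entry looks like
    ``- {kind: dihedral, atoms: [3, 2, 1, 6], label: phi_b, unwrap: true}``
    with one-based atom indices.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: expected a non-empty YAML list")
    defs = []
    for entry in raw:
        defs.append(
            FeatureDefinition(
                kind=entry["kind"],
                atom_indices=tuple(entry["atoms"]),
                label=entry.get("label", ""),
                unwrap=bool(entry.get("unwrap", True)),
            )
        )
    return defs


def feature_matrix_to_tidy(fm: FeatureMatrix) -> pd.DataFrame:
    """Tidy long-form view: columns traj_id, time_fs, feature, value."""
    n_traj, n_time, n_feat = fm.values.shape
    return pd.DataFrame(
        {
            "traj_id": np.repeat(fm.traj_ids, n_time * n_feat),
            "time_fs": np.tile(np.repeat(fm.times, n_feat), n_traj),
            "feature": np.tile(fm.labels, n_traj * n_time),
            "value": fm.values.ravel(),
        }
    )


def save_feature_matrix(path: str | Path, fm: FeatureMatrix) -> None:
    """Persist a feature matrix (values + definitions + metadata) as HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=fm.values)
        h5.create_dataset("times", data=fm.times)
        h5.create_dataset(
            "traj_ids", data=np.array(fm.traj_ids, dtype="S64")
        )
        h5.attrs["normalized"] = fm.normalized
        if fm.feature_min is not None:
            h5.create_dataset("feature_min", data=fm.feature_min)
            h5.create_dataset("feature_max", data=fm.feature_max)
        grp = h5.create_group("definitions")
        for f, d in enumerate(fm.definitions):
            g = grp.create_group(f"{f:03d}")
            g.attrs["kind"] = d.kind
            g.attrs["atoms"] = list(d.atom_indices)
            g.attrs["label"] = d.label
            g.attrs["unwrap"] = d.unwrap


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Load a feature matrix written by :func:`save_feature_matrix`."""
    with h5py.File(path, "r") as h5:
        defs = []
        grp = h5["definitions"]
        for key in sorted(grp.keys()):
            g = grp[key]
            defs.append(
                FeatureDefinition(
                    kind=g.attrs["kind"],
                    atom_indices=tuple(int(a) for a in g.attrs["atoms"]),
                    label=str(g.attrs["label"]),
                    unwrap=bool(g.attrs["unwrap"]),
                )
            )
        return FeatureMatrix(
            values=h5["values"][()],
            definitions=defs,
            traj_ids=[s.decode() for s in h5["traj_ids"][()]],
            times=h5["times"][()],
            normalized=bool(h5.attrs["normalized"]),
            feature_min=h5["feature_min"][()] if "feature_min" in h5 else None,
            feature_max=h5["feature_max"][()] if "feature_max" in h5 else None,
        )
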
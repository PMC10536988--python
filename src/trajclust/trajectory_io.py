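"""Reading, writing and assembling trajectory ensembles.

The data backbone of the package is :class:`TrajectoryEnsemble`: an ensemble
of molecular-dynamics trajectories stored as Cartesian geometries on a shared
uniform time grid, optionally carrying per-trajectory electronic-state
populations.  Trajectories enter as standard multi-frame XYZ files (one file
per trajectory), populations as delimited text; an HDF5 cache round-trips the
assembled ensemble at full precision.

Units are fixed package-wide: coordinates in Å, time in fs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ParseError,
    ReferenceError_,
    StructureError,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryBlock:
    """One trajectory as read from a single multi-frame XYZ file."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    atom_symbols: list[str]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class TrajectoryEnsemble:
    """An ensemble of trajectories on one shared, uniform time grid.

    Attributes
    ----------
    times : (n_time,) strictly increasing times in fs.
    coords : (n_traj, n_time, n_atoms, 3) Cartesian positions in Å.
    atom_symbols : element symbols, identical across all trajectories.
    traj_ids : per-trajectory identifiers, in input order.
    populations : optional (n_traj, n_time, n_states) state populations;
        each entry validated to lie in [0, 1].  Per-trajectory sums are not
        required to equal 1 (semiclassical weights may deviate).
    """

    times: np.ndarray
    coords: np.ndarray
    atom_symbols: list[str]
    traj_ids: list[str]
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[3] != 3:
            raise StructureError(
                f"coords must have shape (n_traj, n_time, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if self.times.ndim != 1 or self.times.shape[0] != self.coords.shape[1]:
            raise StructureError("times length must equal the frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite values")
        if len(self.atom_symbols) != self.coords.shape[2]:
            raise StructureError("atom_symbols length must equal n_atoms")
        if len(self.traj_ids) != self.coords.shape[0]:
            raise StructureError("traj_ids length must equal n_traj")
        if self.populations is not None:
            self.populations = _validate_populations(
                np.asarray(self.populations, dtype=float),
                self.coords.shape[0],
                self.coords.shape[1],
            )

    @property
    def n_traj(self) -> int:
        return self.coords.shape[0]

    @property
    def n_time(self) -> int:
        return self.coords.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[2]


def _validate_populations(pop: np.ndarray, n_traj: int, n_time: int) -> np.ndarray:
    if pop.ndim != 3 or pop.shape[0] != n_traj or pop.shape[1] != n_time:
        raise StructureError(
            f"populations must have shape (n_traj, n_time, n_states), "
            f"got {pop.shape} for n_traj={n_traj}, n_time={n_time}"
        )
    if not np.all(np.isfinite(pop)):
        raise ValidationError("populations contain non-finite values")
    if pop.min() < 0.0 or pop.max() > 1.0:
        bad = pop[(pop < 0.0) | (pop > 1.0)].flat[0]
        raise ValidationError(f"population value {bad} outside [0, 1]")
    return pop


# ---------------------------------------------------------------------------
# XYZ reading / writing
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path: str | Path) -> TrajectoryBlock:
    """Read one multi-frame XYZ file into a :class:`TrajectoryBlock`.

    The standard dialect is expected: repeating blocks of an atom-count
    line, a comment line (ignored), and ``n_atoms`` lines of
    ``symbol x y z``.  Element symbols are taken from the first frame;
    later frames must agree in atom count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # Trailing blank lines are tolerated; internal blanks are not.
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")

    frames: list[np.ndarray] = []
    symbols: list[str] | None = None
    pos = 0
    while pos < len(lines):
        header = lines[pos].strip()
        try:
            n_atoms = int(header)
        except ValueError:
            raise ParseError(
                f"{path}:{pos + 1}: expected an atom-count line, got {header!r}"
            ) from None
        if n_atoms <= 0:
            raise ParseError(f"{path}:{pos + 1}: non-positive atom count {n_atoms}")
        if pos + 2 + n_atoms > len(lines):
            raise ParseError(
                f"{path}:{pos + 1}: truncated frame "
                f"(need {n_atoms} atom lines)"
            )
        frame_syms: list[str] = []
        xyz = np.empty((n_atoms, 3), dtype=float)
        for a in range(n_atoms):
            ln = pos + 2 + a
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln + 1}: expected 'symbol x y z'")
            frame_syms.append(parts[0])
            try:
                xyz[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(
                    f"{path}:{ln + 1}: non-numeric coordinate"
                ) from None
        if symbols is None:
            symbols = frame_syms
        elif n_atoms != len(symbols):
            raise StructureError(
                f"{path}:{pos + 1}: frame has {n_atoms} atoms, "
                f"first frame had {len(symbols)}"
            )
        frames.append(xyz)
        pos += 2 + n_atoms

    assert symbols is not None
    return TrajectoryBlock(coords=np.stack(frames), atom_symbols=symbols)


def write_xyz_trajectory(
    path: str | Path,
    coords: np.ndarray,
    atom_symbols: Sequence[str],
    comment: str = "",
) -> None:
    """Write a (n_frames, n_atoms, 3) array as a multi-frame XYZ file."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    out: list[str] = []
    for frame in coords:
        out.append(str(n_atoms))
        out.append(comment)
        for sym, (x, y, z) in zip(atom_symbols, frame):
            out.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Ensemble assembly
# ---------------------------------------------------------------------------

def assemble_ensemble(
    blocks: Sequence[TrajectoryBlock],
    dt: float,
    traj_ids: Sequence[str] | None = None,
    on_length_mismatch: str = "truncate",
) -> TrajectoryEnsemble:
    """Assemble single-trajectory blocks into a :class:`TrajectoryEnsemble`.

    All blocks must share atom count and symbols.  Trajectories of unequal
    length are truncated to the shortest common frame count (with a logged
    warning) so the shared-time-grid invariant holds; pass
    ``on_length_mismatch="error"`` to refuse instead.  The time grid is
    ``0, dt, 2·dt, ...`` in fs.  Trajectory order is preserved.
    """
    if not blocks:
        raise ValidationError("assemble_ensemble: no trajectory blocks given")
    if dt <= 0:
        raise ValidationError(f"time step dt must be positive, got {dt}")
    if on_length_mismatch not in ("truncate", "error"):
        raise ValidationError(
            f"on_length_mismatch must be 'truncate' or 'error', "
            f"got {on_length_mismatch!r}"
        )
    ref = blocks[0]
    for b_i, blk in enumerate(blocks):
        if blk.atom_symbols != ref.atom_symbols:
            raise StructureError(
                f"block {b_i}: atom symbols {blk.atom_symbols} differ from "
                f"block 0 symbols {ref.atom_symbols}"
            )
    lengths = [b.n_frames for b in blocks]
    n_time = min(lengths)
    if len(set(lengths)) > 1:
        if on_length_mismatch == "error":
            raise StructureError(
                f"trajectory lengths differ ({sorted(set(lengths))}); "
                "re-run with on_length_mismatch='truncate' or use the "
                "ragged DTW path"
            )
        logger.warning(
            "trajectory lengths differ (%d to %d frames); truncating all to %d",
            min(lengths), max(lengths), n_time,
        )
    if traj_ids is None:
        traj_ids = [f"traj_{i:04d}" for i in range(len(blocks))]
    coords = np.stack([b.coords[:n_time] for b in blocks])
    times = np.arange(n_time, dtype=float) * dt
    return TrajectoryEnsemble(
        times=times,
        coords=coords,
        atom_symbols=list(ref.atom_symbols),
        traj_ids=list(traj_ids),
    )


def read_ensemble_dir(
    directory: str | Path,
    dt: float,
    pattern: str = "*.xyz",
    on_length_mismatch: str = "truncate",
) -> TrajectoryEnsemble:
    """Read every XYZ file matching ``pattern`` (sorted) into an ensemble."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise ValidationError(f"no files matching {pattern!r} in {directory}")
    blocks = [read_xyz_trajectory(p) for p in paths]
    return assemble_ensemble(
        blocks, dt, traj_ids=[p.stem for p in paths],
        on_length_mismatch=on_length_mismatch,
    )


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def read_populations(
    path: str | Path, ensemble: TrajectoryEnsemble
) -> TrajectoryEnsemble:
    """Attach a populations table to an ensemble.

    Expects comma-delimited text with a header of the form
    ``traj_id,time_index,state_0,state_1,...``.  Every (trajectory, time
    index) pair of the ensemble must be covered exactly.  Returns a new
    ensemble; the input is not modified.
    """
    df = pd.read_csv(path)
    required = {"traj_id", "time_index"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: populations table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    state_cols = [c for c in df.columns if c not in required]
    if not state_cols:
        raise ParseError(f"{path}: no state columns found")
    n_states = len(state_cols)

    known = set(ensemble.traj_ids)
    unknown = set(df["traj_id"].astype(str)) - known
    if unknown:
        raise ReferenceError_(
            f"{path}: unknown trajectory id(s): {sorted(unknown)[:5]}"
        )

    pop = np.full((ensemble.n_traj, ensemble.n_time, n_states), np.nan)
    idx_of = {tid: i for i, tid in enumerate(ensemble.traj_ids)}
    ti = df["time_index"].to_numpy(dtype=int)
    if ti.min() < 0 or ti.max() >= ensemble.n_time:
        raise ReferenceError_(
            f"{path}: time_index outside [0, {ensemble.n_time - 1}]"
        )
    rows = np.array([idx_of[t] for t in df["traj_id"].astype(str)])
    pop[rows, ti] = df[state_cols].to_numpy(dtype=float)
    if np.any(np.isnan(pop)):
        miss_traj, miss_t = np.argwhere(np.isnan(pop[..., 0]))[0]
        raise ReferenceError_(
            f"{path}: missing populations for trajectory "
            f"{ensemble.traj_ids[miss_traj]!r} at time index {miss_t}"
        )
    return TrajectoryEnsemble(
        times=ensemble.times,
        coords=ensemble.coords,
        atom_symbols=list(ensemble.atom_symbols),
        traj_ids=list(ensemble.traj_ids),
        populations=pop,
    )


def write_populations(
    path: str | Path, ensemble: TrajectoryEnsemble
) -> None:
    """Write the ensemble's populations as the delimited table read back by
    :func:`read_populations`."""
    if ensemble.populations is None:
        raise ValidationError("ensemble carries no populations")
    n_traj, n_time, n_states = ensemble.populations.shape
    recs = []
    for i, tid in enumerate(ensemble.traj_ids):
        for s in range(n_time):
            recs.append(
                [tid, s, *ensemble.populations[i, s].tolist()]
            )
    cols = ["traj_id", "time_index"] + [f"state_{k}" for k in range(n_states)]
    pd.DataFrame(recs, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HDF5 cache
# ---------------------------------------------------------------------------

def save_ensemble(path: str | Path, ensemble: TrajectoryEnsemble) -> None:
    """Cache an ensemble as HDF5 (datasets /coords, /times, /populations,
    /atom_symbols, /traj_ids)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("coords", data=ensemble.coords)
        h5.create_dataset("times", data=ensemble.times)
        h5.create_dataset(
            "atom_symbols",
            data=np.array(ensemble.atom_symbols, dtype="S8"),
        )
        h5.create_dataset(
            "traj_ids", data=np.array(ensemble.traj_ids, dtype="S64")
        )
        if ensemble.populations is not None:
            h5.create_dataset("populations", data=ensemble.populations)


def load_ensemble(path: str | Path) -> TrajectoryEnsemble:
    """Load an ensemble previously written by :func:`save_ensemble`."""
    with h5py.File(path, "r") as h5:
        pop = h5["populations"][()] if "populations" in h5 else None
        return TrajectoryEnsemble(
            times=h5["times"][()],
            coords=h5["coords"][()],
            atom_symbols=[s.decode() for s in h5["atom_symbols"][()]],
            traj_ids=[s.decode() for s in h5["traj_ids"][()]],
            populations=pop,
        )
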
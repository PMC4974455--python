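"""Core data types for sparsely sampled (NUS) NMR time-domain data.

A non-uniform sampling experiment records the indirect-dimension time
domain only at a subset of the Nyquist grid.  This module holds the
containers for that situation:

* :class:`SamplingSchedule` -- the list of sampled grid positions;
* :class:`SparseDataset` -- hypercomplex measurements keyed to a schedule;
* :class:`SplitDataset` -- the working/free cross-validation partition.

It also provides plain-text I/O for schedules and datasets and the seeded
working/free split used by the cross-validated quality factors.

File formats
------------
Schedule files are plain text, one sample per line, ``D`` 0-based integer
grid indices per line, with a header line ``# grid N1 [N2]`` and ``#``
comments allowed.

Dataset files are plain text with header lines recording dimensionality,
grid, dwell time(s) and role, followed by ``D`` index columns and ``2**D``
real component columns (re/im for 1-D; RR RI IR II for 2-D planes).
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Role",
    "SamplingSchedule",
    "SparseDataset",
    "SplitDataset",
    "ScheduleFormatError",
    "DatasetFormatError",
    "load_schedule",
    "write_schedule",
    "read_dataset",
    "write_dataset",
    "split_measurements",
    "SPLIT_GENERATOR",
]

#: Name and version of the pseudo-random generator used for working/free
#: splits, recorded so splits stay reproducible across releases.
SPLIT_GENERATOR = "numpy.random.Generator(PCG64)"


class ScheduleFormatError(ValueError):
    """Raised when a schedule file is malformed or violates grid bounds."""


class DatasetFormatError(ValueError):
    """Raised when a dataset file is malformed or internally inconsistent."""


class Role(str, enum.Enum):
    """What a dataset is used for in the cross-validation protocol."""

    FULL = "full"
    WORKING = "working"
    FREE = "free"
    NOISE_REFERENCE = "noise_reference"


@dataclasses.dataclass(frozen=True)
class SamplingSchedule:
    """An ordered set of sampled positions on an indirect-dimension grid.

    Parameters
    ----------
    grid_shape
        Points per indirect dimension (e.g. ``(1024,)`` or ``(64, 96)``).
    positions
        Integer array of shape ``(n, D)``; file/generation order is
        preserved and is the single source of ordering truth for any
        dataset attached to this schedule.
    """

    grid_shape: tuple[int, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.grid_shape)
        if not shape or any(n <= 0 for n in shape):
            raise ValueError(f"grid_shape must be positive integers, got {shape}")
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.ndim == 1:
            pos = pos[:, None]
        if pos.ndim != 2 or pos.shape[1] != len(shape):
            raise ValueError(
                f"positions must have shape (n, {len(shape)}), got {pos.shape}"
            )
        if pos.shape[0] < 1:
            raise ValueError("a schedule must contain at least one position")
        if np.any(pos < 0) or np.any(pos >= np.asarray(shape)[None, :]):
            raise ScheduleFormatError("position outside the sampling grid")
        flat = np.ravel_multi_index(pos.T, shape)
        if np.unique(flat).size != flat.size:
            raise ScheduleFormatError("duplicate positions in schedule")
        pos.setflags(write=False)
        object.__setattr__(self, "grid_shape", shape)
        object.__setattr__(self, "positions", pos)

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)

    @property
    def n_points(self) -> int:
        return int(self.positions.shape[0])

    @property
    def grid_size(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def density(self) -> float:
        """Sampling density, ``n_points / grid_size``."""
        return self.n_points / self.grid_size

    def flat_indices(self) -> np.ndarray:
        """Row-major flat grid indices, in schedule order."""
        return np.ravel_multi_index(self.positions.T, self.grid_shape)

    def subset(self, indices: Sequence[int]) -> "SamplingSchedule":
        """Schedule restricted to the given row indices (order preserved)."""
        return SamplingSchedule(self.grid_shape, self.positions[np.asarray(indices)])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


@dataclasses.dataclass
class SparseDataset:
    """Hypercomplex time-domain measurements on a sampling schedule.

    ``values`` has shape ``(n_points, 2**D)`` of real quadrature
    components per sample: (re, im) for D=1 and (RR, RI, IR, II) for D=2.
    ``dwell`` is the time increment per indirect dimension, in seconds.
    """

    schedule: SamplingSchedule
    values: np.ndarray
    role: Role = Role.FULL
    dwell: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        d = self.schedule.ndim
        if vals.shape != (self.schedule.n_points, 2**d):
            raise ValueError(
                f"values must have shape ({self.schedule.n_points}, {2**d}), "
                f"got {vals.shape}"
            )
        self.role = Role(self.role)
        dwell = tuple(float(x) for x in np.atleast_1d(self.dwell))
        if len(dwell) != d or any(x <= 0 for x in dwell):
            raise ValueError(f"dwell must be {d} positive values, got {dwell}")
        self.values = vals
        self.dwell = dwell

    @property
    def n_points(self) -> int:
        return self.schedule.n_points

    @property
    def n_components(self) -> int:
        return int(self.values.shape[1])

    def as_complex(self) -> np.ndarray:
        """1-D data as a complex vector (re + i*im), in schedule order."""
        if self.schedule.ndim != 1:
            raise ValueError("as_complex is defined for 1-D datasets only")
        return self.values[:, 0] + 1j * self.values[:, 1]

    @classmethod
    def from_complex(
        cls,
        schedule: SamplingSchedule,
        z: np.ndarray,
        role: Role = Role.FULL,
        dwell: tuple[float, ...] = (1.0,),
    ) -> "SparseDataset":
        z = np.asarray(z, dtype=np.complex128)
        return cls(schedule, np.column_stack([z.real, z.imag]), role, dwell)

    def subset(self, indices: Sequence[int], role: Role) -> "SparseDataset":
        idx = np.asarray(indices)
        return SparseDataset(self.schedule.subset(idx), self.values[idx], role, self.dwell)


@dataclasses.dataclass
class SplitDataset:
    """A working/free cross-validation partition of one sparse dataset."""

    working: SparseDataset
    free: SparseDataset
    seed: int | None = None
    generator: str = SPLIT_GENERATOR

    def __post_init__(self) -> None:
        if self.working.schedule.grid_shape != self.free.schedule.grid_shape and (
            self.free.n_points > 0
        ):
            raise ValueError("working and free sets live on different grids")
        if self.free.n_points:
            w = set(self.working.schedule.flat_indices().tolist())
            f = set(self.free.schedule.flat_indices().tolist())
            if w & f:
                raise ValueError("working and free position sets overlap")

    @property
    def n_total(self) -> int:
        return self.working.n_points + self.free.n_points

    @property
    def free_fraction(self) -> float:
        return self.free.n_points / self.n_total


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_measurements(
    dataset: SparseDataset, free_fraction: float, seed: int
) -> SplitDataset:
    """Partition a full dataset into working and free (cross-validation) sets.

    The free set holds ``round(free_fraction * n)`` positions (half rounds
    away from zero), chosen uniformly at random without replacement from a
    seeded PCG64 generator; the remainder is the working set.  Both halves
    keep schedule order.  Deterministic for a fixed seed.
    """
    if dataset.role is not Role.FULL:
        raise ValueError(f"can only split a dataset with role 'full', got {dataset.role.value!r}")
    if not 0 <= free_fraction < 1:
        raise ValueError(f"free_fraction must be in [0, 1), got {free_fraction}")
    n = dataset.n_points
    n_free = _round_half_away(free_fraction * n)
    rng = np.random.default_rng(seed)
    free_idx = np.sort(rng.choice(n, size=n_free, replace=False))
    mask = np.ones(n, dtype=bool)
    mask[free_idx] = False
    work_idx = np.nonzero(mask)[0]
    if n_free == 0:
        # degenerate free set: keep an empty dataset on a 1-position slice is
        # not representable (schedules are non-empty), so model it explicitly
        free = _empty_like(dataset)
    else:
        free = dataset.subset(free_idx, Role.FREE)
    return SplitDataset(dataset.subset(work_idx, Role.WORKING), free, seed=seed)


class _EmptySchedule(SamplingSchedule):
    """Internal zero-length schedule used only for an empty free set."""

    def __post_init__(self) -> None:  # relax the >=1 invariant
        shape = tuple(int(n) for n in self.grid_shape)
        pos = np.asarray(self.positions, dtype=np.int64).reshape(0, len(shape))
        pos.setflags(write=False)
        object.__setattr__(self, "grid_shape", shape)
        object.__setattr__(self, "positions", pos)


def _empty_like(dataset: SparseDataset) -> SparseDataset:
    sched = _EmptySchedule(
        dataset.schedule.grid_shape,
        np.empty((0, dataset.schedule.ndim), dtype=np.int64),
    )
    ds = SparseDataset.__new__(SparseDataset)
    ds.schedule = sched
    ds.values = np.empty((0, dataset.n_components))
    ds.role = Role.FREE
    ds.dwell = dataset.dwell
    return ds


# ---------------------------------------------------------------------------
# plain-text I/O


def load_schedule(path: str | Path, grid_shape: tuple[int, ...] | None = None) -> SamplingSchedule:
    """Read a schedule file (``# grid ...`` header, D integers per line)."""
    path = Path(path)
    rows: list[list[int]] = []
    header_grid: tuple[int, ...] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].split()
                if body and body[0] == "grid":
                    try:
                        header_grid = tuple(int(x) for x in body[1:])
                    except ValueError as exc:
                        raise ScheduleFormatError(
                            f"{path}:{lineno}: malformed grid header {line!r}"
                        ) from exc
                continue
            try:
                rows.append([int(tok) for tok in line.split()])
            except ValueError as exc:
                raise ScheduleFormatError(
                    f"{path}:{lineno}: malformed schedule line {line!r}"
                ) from exc
    grid = grid_shape or header_grid
    if grid is None:
        raise ScheduleFormatError(f"{path}: no '# grid' header and no grid_shape given")
    if not rows:
        raise ScheduleFormatError(f"{path}: schedule file contains no positions")
    widths = {len(r) for r in rows}
    if widths != {len(grid)}:
        raise ScheduleFormatError(
            f"{path}: expected {len(grid)} indices per line, found widths {sorted(widths)}"
        )
    return SamplingSchedule(tuple(grid), np.asarray(rows, dtype=np.int64))


def write_schedule(schedule: SamplingSchedule, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# grid " + " ".join(str(n) for n in schedule.grid_shape) + "\n")
        for row in schedule.positions:
            fh.write(" ".join(str(int(i)) for i in row) + "\n")


_FLOAT_FMT = "%.17g"  # full float64 round-trip precision


def write_dataset(dataset: SparseDataset, path: str | Path) -> None:
    """Write a dataset as columnar text; ``read_dataset`` restores it exactly."""
    path = Path(path)
    d = dataset.schedule.ndim
    comp_names = ["re", "im"] if d == 1 else ["RR", "RI", "IR", "II"]
    with path.open("w") as fh:
        fh.write("# rnoise-dataset v1\n")
        fh.write(f"# dims {d}\n")
        fh.write("# grid " + " ".join(str(n) for n in dataset.schedule.grid_shape) + "\n")
        fh.write("# dwell " + " ".join(_FLOAT_FMT % x for x in dataset.dwell) + "\n")
        fh.write(f"# role {dataset.role.value}\n")
        fh.write("# columns " + " ".join(["i", "j"][:d] + comp_names) + "\n")
        for pos, vals in zip(dataset.schedule.positions, dataset.values):
            cols = [str(int(i)) for i in pos] + [_FLOAT_FMT % v for v in vals]
            fh.write(" ".join(cols) + "\n")


def read_dataset(path: str | Path) -> SparseDataset:
    """Read a columnar text dataset written by :func:`write_dataset`."""
    path = Path(path)
    meta: dict[str, list[str]] = {}
    data_rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].split()
                if body:
                    meta[body[0]] = body[1:]
                continue
            data_rows.append(line.split())
    for key in ("dims", "grid", "dwell", "role"):
        if key not in meta:
            raise DatasetFormatError(f"{path}: missing '# {key}' header")
    d = int(meta["dims"][0])
    grid = tuple(int(x) for x in meta["grid"])
    if len(grid) != d:
        raise DatasetFormatError(f"{path}: grid header inconsistent with dims={d}")
    dwell = tuple(float(x) for x in meta["dwell"])
    role = Role(meta["role"][0])
    ncols = d + 2**d
    positions, values = [], []
    for row in data_rows:
        if len(row) != ncols:
            raise DatasetFormatError(
                f"{path}: expected {ncols} columns for dims={d}, got {len(row)}"
            )
        positions.append([int(x) for x in row[:d]])
        values.append([float(x) for x in row[d:]])
    schedule = SamplingSchedule(grid, np.asarray(positions, dtype=np.int64))
    return SparseDataset(schedule, np.asarray(values), role, dwell)
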
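"""Classic and noise-normalized cross-validation quality factors.

The agreement between a model spectrum and sparse time-domain measurements
is scored crystallography-style:

* ``R = sum ||obs - calc|| / sum ||obs||`` over the hypercomplex vector
  lengths of the measured (obs) and back-calculated (calc) time-domain
  points.  Computed separately for the working set used in reconstruction
  (R_work) and the held-out free set (R_free).

* ``R_noise`` replaces the signal-dependent denominator with the mean
  magnitude of a pure-noise reference, so an ideal reconstruction scores
  about 1 regardless of how much signal the plane contains, and a plane of
  pure noise no longer pins R at 100%.  Numerator and denominator are both
  per-point means, which keeps the ratio well-defined when the working,
  free and noise sets differ in size.

Overfitting shows up as divergence: R_noise_work keeps falling as noise is
absorbed into the model while R_noise_free passes through a minimum and
rises.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .datamodel import SparseDataset, SplitDataset
from .transforms import Spectrum, back_calculate, hyper_magnitude

__all__ = [
    "RFactorReport",
    "QualitySummary",
    "Trajectory",
    "r_factor",
    "r_noise",
    "score_split",
    "score_arrays",
    "aggregate_quality",
    "spectrum_rmsd",
]

_FACTORS = ("r_work", "r_free", "rnoise_work", "rnoise_free")

#: CSV column order for trajectory exports.
TRAJECTORY_COLUMNS = [
    "control_name",
    "control_value",
    "r_work",
    "r_free",
    "rnoise_work",
    "rnoise_free",
    "score_total",
    "rmsd_to_reference",
    "n_work",
    "n_free",
]


@dataclasses.dataclass
class RFactorReport:
    """All four quality factors for one reconstruction snapshot."""

    r_work: float
    r_free: float
    rnoise_work: float
    rnoise_free: float
    control_name: str
    control_value: float
    n_work: int
    n_free: int
    score_total: float | None = None
    rmsd_to_reference: float | None = None
    algorithm: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in _FACTORS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in TRAJECTORY_COLUMNS}


@dataclasses.dataclass
class QualitySummary:
    """Mean and sample standard deviation of each factor over a set of
    reconstructions (e.g. the planes of a 3-D spectrum)."""

    r_work_mean: float
    r_work_sd: float
    r_free_mean: float
    r_free_sd: float
    rnoise_work_mean: float
    rnoise_work_sd: float
    rnoise_free_mean: float
    rnoise_free_sd: float
    n: int


@dataclasses.dataclass
class Trajectory:
    """Ordered snapshots of the quality factors along a control parameter
    (CLEAN stopping threshold, Lagrangian multiplier, or IST iteration)."""

    reports: list[RFactorReport]

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[RFactorReport]:
        return iter(self.reports)

    def __getitem__(self, i: int) -> RFactorReport:
        return self.reports[i]

    @property
    def control_name(self) -> str:
        return self.reports[0].control_name

    def array(self, field: str) -> np.ndarray:
        vals = [getattr(r, field) for r in self.reports]
        return np.asarray([np.nan if v is None else v for v in vals], dtype=float)

    @property
    def control_values(self) -> np.ndarray:
        return self.array("control_value")

    def index_min(self, field: str = "rnoise_free") -> int:
        """Index of the snapshot minimizing the given factor."""
        return int(np.nanargmin(self.array(field)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.reports], columns=TRAJECTORY_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        payload = [r.as_dict() for r in self.reports]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def r_factor(obs: np.ndarray, calc: np.ndarray) -> float:
    """Classic R-factor: sum ||obs_i - calc_i|| / sum ||obs_i||.

    Magnitudes are hypercomplex vector lengths; inputs may be real
    component arrays ``(n, 2**D)`` or complex vectors.
    """
    obs = np.asarray(obs)
    calc = np.asarray(calc)
    if obs.shape != calc.shape:
        raise ValueError(f"obs shape {obs.shape} != calc shape {calc.shape}")
    denom = float(np.sum(hyper_magnitude(obs)))
    if denom == 0.0:
        raise ValueError("R-factor undefined: observations are all zero")
    num = float(np.sum(hyper_magnitude(obs - calc)))
    return num / denom


def r_noise(obs: np.ndarray, calc: np.ndarray, noise_ref: np.ndarray) -> float:
    """Noise-normalized R-factor.

    Mean residual magnitude over the scored points, divided by the mean
    magnitude of the pure-noise reference points.  Per-point means keep the
    ratio well-defined when the two sets differ in size; an ideal model of
    noisy data scores about 1.
    """
    obs = np.asarray(obs)
    calc = np.asarray(calc)
    if obs.shape != calc.shape:
        raise ValueError(f"obs shape {obs.shape} != calc shape {calc.shape}")
    noise_mag = hyper_magnitude(np.asarray(noise_ref))
    if noise_mag.size == 0 or float(np.sum(noise_mag)) == 0.0:
        raise ValueError("R-noise undefined: noise reference has zero magnitude")
    num = float(np.mean(hyper_magnitude(obs - calc)))
    return num / float(np.mean(noise_mag))


def _noise_values_for(noise_ref: SparseDataset, schedule_flat: np.ndarray) -> np.ndarray:
    """Noise values restricted to the given positions when the reference is
    position-matched; otherwise the whole reference set."""
    ref_flat = noise_ref.schedule.flat_indices()
    lookup = {int(f): i for i, f in enumerate(ref_flat)}
    idx = [lookup.get(int(f), -1) for f in schedule_flat]
    if len(idx) > 0 and min(idx) >= 0:
        return noise_ref.values[np.asarray(idx)]
    return noise_ref.values


def score_arrays(
    obs_work: np.ndarray,
    calc_work: np.ndarray,
    obs_free: np.ndarray,
    calc_free: np.ndarray,
    noise_ref: SparseDataset,
    work_flat: np.ndarray,
    free_flat: np.ndarray,
    control: tuple[str, float],
    **meta,
) -> RFactorReport:
    """Assemble a report from already back-calculated time-domain arrays.

    Used by :func:`score_split` and by engines (IST) that carry the
    time-domain reconstruction explicitly.
    """
    def _rnoise_or_nan(obs, calc, noise_vals):
        # a silent reference (e.g. a noiseless simulation) leaves the
        # noise-normalized factors undefined; record NaN in trajectories
        if float(np.sum(hyper_magnitude(noise_vals))) == 0.0:
            return float("nan")
        return r_noise(obs, calc, noise_vals)

    noise_w = _noise_values_for(noise_ref, work_flat)
    name, value = control
    r_w = r_factor(obs_work, calc_work)
    rn_w = _rnoise_or_nan(obs_work, calc_work, noise_w)
    if len(obs_free):
        noise_f = _noise_values_for(noise_ref, free_flat)
        r_f = r_factor(obs_free, calc_free)
        rn_f = _rnoise_or_nan(obs_free, calc_free, noise_f)
    else:
        r_f = rn_f = float("nan")
    return RFactorReport(
        r_work=r_w,
        r_free=r_f,
        rnoise_work=rn_w,
        rnoise_free=rn_f,
        control_name=name,
        control_value=float(value),
        n_work=len(obs_work),
        n_free=len(obs_free),
        **meta,
    )


def score_split(
    model: Spectrum,
    split: SplitDataset,
    noise_ref: SparseDataset,
    control: tuple[str, float] = ("none", 0.0),
    **meta,
) -> RFactorReport:
    """Score a model spectrum against a working/free split.

    Back-calculates the model at the working and free positions and fills
    all four factors.  The noise reference is restricted to the matching
    positions when it shares the parent schedule, otherwise the full noise
    set is used (both paths are mean-normalized and agree in expectation).
    """
    calc_w = back_calculate(model, split.working.schedule.positions)
    if split.free.n_points:
        calc_f = back_calculate(model, split.free.schedule.positions)
        free_flat = split.free.schedule.flat_indices()
    else:
        calc_f = np.empty((0, split.working.n_components))
        free_flat = np.empty(0, dtype=np.int64)
    return score_arrays(
        split.working.values,
        calc_w,
        split.free.values,
        calc_f,
        noise_ref,
        split.working.schedule.flat_indices(),
        free_flat,
        control,
        **meta,
    )


def aggregate_quality(reports: Sequence[RFactorReport]) -> QualitySummary:
    """Overall quality of a multi-plane reconstruction: per-factor mean and
    sample standard deviation (n-1 denominator; sd = 0 for a single plane)."""
    if len(reports) == 0:
        raise ValueError("cannot aggregate an empty list of reports")
    out: dict[str, float] = {}
    for name in _FACTORS:
        vals = np.asarray([getattr(r, name) for r in reports], dtype=float)
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return QualitySummary(n=len(reports), **out)


def spectrum_rmsd(a: Spectrum, b: Spectrum) -> float:
    """Root-mean-square magnitude of the point-wise difference of two
    spectra on the same grid."""
    if a.grid_shape != b.grid_shape or a.is_hyper != b.is_hyper:
        raise ValueError("spectra live on different grids")
    diff = a.data - b.data
    if a.is_hyper:
        axes = tuple(range(a.ndim, diff.ndim))
        mag2 = np.sum(diff**2, axis=axes)
    else:
        mag2 = np.abs(diff) ** 2
    return float(np.sqrt(np.mean(mag2)))
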
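"""Synthetic NUS data generation.

The 1-D benchmark emulates a sparsely detected indirect dimension: nine
exponentially decaying complex sinusoids with amplitudes descending from
64 to 1 and frequencies spanning -4,000 to 4,000 Hz in white noise, on a
1,024-point grid, sampled at 30% density, with a 20% free fraction held
out for cross-validation and a pure-noise dataset of the same amplitude
on the same schedule serving as the R_noise reference.

Defaults the underlying study leaves open (spectral width, decay rates,
the exact amplitude/frequency ladders, noise amplitude) are fixed once
here and documented in docs/methods.md; all quality-factor behaviour tied
to them is shape/property based, not value based.

All randomness flows from a single master seed split into named streams
(signal-phase, noise, schedule, split) so the components can be varied
independently.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datamodel import (
    Role,
    SamplingSchedule,
    SparseDataset,
    SplitDataset,
    split_measurements,
    _round_half_away,
)
from .transforms import Spectrum, _hyper_fft

__all__ = [
    "SimulationParams",
    "PlaneParams",
    "Simulation1D",
    "Benchmark1D",
    "simulate_1d",
    "simulate_plane",
    "simulate_benchmark",
    "make_schedule",
]

_STREAMS = ("signal-phase", "noise", "schedule", "split")


def _child_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


def _int_seed(ss: np.random.SeedSequence) -> int:
    # keep derived integer seeds below 2**31 for portability
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _geometric_ladder(top: float, bottom: float, n: int) -> np.ndarray:
    return np.geomspace(top, bottom, n)


@dataclasses.dataclass
class SimulationParams:
    """Parameters of the 1-D simulated experiment (defaults = benchmark)."""

    grid_points: int = 1024
    n_signals: int = 9
    amplitudes: tuple[float, ...] | None = None  # default: geometric 64 -> 1
    frequencies_hz: tuple[float, ...] | None = None  # default: -4000 .. 4000 evenly
    decay_rate_hz: float | tuple[float, ...] = 100.0
    noise_sigma: float = 0.5
    spectral_width_hz: float = 10_000.0
    sampling_density: float = 0.30
    free_fraction: float = 0.20
    seed: int = 0
    random_phase: bool = False

    def __post_init__(self) -> None:
        if self.amplitudes is None:
            self.amplitudes = tuple(_geometric_ladder(64.0, 1.0, self.n_signals)) if self.n_signals else ()
        if self.frequencies_hz is None:
            self.frequencies_hz = (
                tuple(np.linspace(-4000.0, 4000.0, self.n_signals)) if self.n_signals else ()
            )
        self.amplitudes = tuple(float(a) for a in self.amplitudes)
        self.frequencies_hz = tuple(float(f) for f in self.frequencies_hz)
        if len(self.amplitudes) != self.n_signals or len(self.frequencies_hz) != self.n_signals:
            raise ValueError("amplitudes and frequencies must both have n_signals entries")
        if np.isscalar(self.decay_rate_hz):
            self.decay_rate_hz = tuple([float(self.decay_rate_hz)] * self.n_signals)
        else:
            self.decay_rate_hz = tuple(float(r) for r in self.decay_rate_hz)
            if len(self.decay_rate_hz) != self.n_signals:
                raise ValueError("decay_rate_hz must be scalar or one value per signal")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral_width_hz must be positive")
        if self.n_signals and max(abs(f) for f in self.frequencies_hz) >= self.spectral_width_hz / 2:
            raise ValueError("signal frequency outside the spectral band (would alias)")
        if not 0 < self.sampling_density <= 1:
            raise ValueError("sampling_density must be in (0, 1]")

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_width_hz


@dataclasses.dataclass
class Simulation1D:
    """Output of :func:`simulate_1d`."""

    full: SparseDataset
    sparse: SparseDataset
    noise_ref: SparseDataset
    reference_spectrum: Spectrum  # transform of the fully sampled noisy data
    truth: Spectrum  # transform of the noiseless signals
    split_seed: int  # derived seed for the working/free split stream


@dataclasses.dataclass
class Benchmark1D:
    """A simulation plus its working/free split, ready for reconstruction."""

    sim: Simulation1D
    split: SplitDataset

    @property
    def noise_ref(self) -> SparseDataset:
        return self.sim.noise_ref

    @property
    def reference(self) -> Spectrum:
        return self.sim.reference_spectrum


def make_schedule(grid_shape: tuple[int, ...] | int, density: float, seed: int) -> SamplingSchedule:
    """Uniform-random NUS schedule: ``round(density * grid_size)`` distinct
    positions drawn without replacement, sorted in grid order."""
    if np.isscalar(grid_shape):
        grid_shape = (int(grid_shape),)
    grid_shape = tuple(int(n) for n in grid_shape)
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    size = int(np.prod(grid_shape))
    count = max(1, _round_half_away(density * size))
    rng = np.random.default_rng(seed)
    flat = np.sort(rng.choice(size, size=count, replace=False))
    positions = np.column_stack(np.unravel_index(flat, grid_shape))
    return SamplingSchedule(grid_shape, positions)


def _signal_fid(params: SimulationParams, phases: np.ndarray) -> np.ndarray:
    n = params.grid_points
    t = np.arange(n) * params.dwell
    fid = np.zeros(n, dtype=np.complex128)
    for amp, f, r, ph in zip(
        params.amplitudes, params.frequencies_hz, params.decay_rate_hz, phases
    ):
        fid += amp * np.exp((2j * np.pi * f - r) * t + 1j * ph)
    return fid


def simulate_1d(params: SimulationParams) -> Simulation1D:
    """Simulate the 1-D experiment.

    Returns the fully sampled noisy dataset, its restriction to a seeded
    random schedule, a pure-noise dataset of the same amplitude on the same
    schedule, the reference spectrum (transform of the full noisy data) and
    the noiseless truth spectrum.  Bit-identical for a fixed seed.
    """
    seeds = _child_seeds(params.seed)
    n = params.grid_points
    phase_rng = np.random.default_rng(seeds["signal-phase"])
    phases = (
        phase_rng.uniform(0, 2 * np.pi, params.n_signals)
        if params.random_phase
        else np.zeros(params.n_signals)
    )
    clean_fid = _signal_fid(params, phases)

    noise_rng = np.random.default_rng(seeds["noise"])
    noise = noise_rng.normal(0.0, params.noise_sigma, n) + 1j * noise_rng.normal(
        0.0, params.noise_sigma, n
    )
    full_fid = clean_fid + noise if params.noise_sigma > 0 else clean_fid

    full_sched = SamplingSchedule((n,), np.arange(n))
    dwell = (params.dwell,)
    full = SparseDataset.from_complex(full_sched, full_fid, Role.FULL, dwell)

    schedule = make_schedule((n,), params.sampling_density, _int_seed(seeds["schedule"]))
    sel = schedule.flat_indices()
    sparse = SparseDataset.from_complex(schedule, full_fid[sel], Role.FULL, dwell)

    ref_noise = noise_rng.normal(0.0, params.noise_sigma, schedule.n_points) + 1j * (
        noise_rng.normal(0.0, params.noise_sigma, schedule.n_points)
    )
    noise_ref = SparseDataset.from_complex(schedule, ref_noise, Role.NOISE_REFERENCE, dwell)

    reference = Spectrum((n,), np.fft.fft(full_fid, norm="ortho"), dwell)
    truth = Spectrum((n,), np.fft.fft(clean_fid, norm="ortho"), dwell)
    return Simulation1D(full, sparse, noise_ref, reference, truth, _int_seed(seeds["split"]))


def simulate_benchmark(params: SimulationParams | None = None) -> Benchmark1D:
    """Simulate and split in one step, using the named split stream."""
    params = params or SimulationParams()
    sim = simulate_1d(params)
    split = split_measurements(sim.sparse, params.free_fraction, sim.split_seed)
    return Benchmark1D(sim, split)


# ---------------------------------------------------------------------------
# 2-D hypercomplex planes


@dataclasses.dataclass
class PlaneParams:
    """Parameters for a simulated 2-D hypercomplex plane."""

    grid_shape: tuple[int, int] = (32, 32)
    n_signals: int = 4
    amplitudes: tuple[float, ...] | None = None  # default: geometric 100 -> 25
    frequencies_hz: tuple[tuple[float, float], ...] | None = None
    decay_rate_hz: float = 60.0
    noise_sigma: float = 0.5
    spectral_width_hz: tuple[float, float] = (2000.0, 2000.0)
    sampling_density: float = 0.30
    seed: int = 0
    weak_scale: float | None = None  # default: peak amplitude == 5 * noise_sigma

    def __post_init__(self) -> None:
        if self.amplitudes is None:
            self.amplitudes = tuple(_geometric_ladder(100.0, 25.0, self.n_signals))
        if self.frequencies_hz is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xF0]))
            f1 = rng.uniform(-0.35, 0.35, self.n_signals) * self.spectral_width_hz[0]
            f2 = rng.uniform(-0.35, 0.35, self.n_signals) * self.spectral_width_hz[1]
            self.frequencies_hz = tuple(zip(f1.tolist(), f2.tolist()))
        if len(self.amplitudes) != self.n_signals or len(self.frequencies_hz) != self.n_signals:
            raise ValueError("amplitudes and frequencies must both have n_signals entries")
        for f1, f2 in self.frequencies_hz:
            if abs(f1) >= self.spectral_width_hz[0] / 2 or abs(f2) >= self.spectral_width_hz[1] / 2:
                raise ValueError("signal frequency outside the spectral band (would alias)")
        if not 0 < self.sampling_density <= 1:
            raise ValueError("sampling_density must be in (0, 1]")

    @property
    def dwell(self) -> tuple[float, float]:
        return (1.0 / self.spectral_width_hz[0], 1.0 / self.spectral_width_hz[1])


def _plane_components(params: PlaneParams, scale: float) -> np.ndarray:
    """Noiseless hypercomplex plane on the full grid, shape (N1, N2, 2, 2)."""
    n1, n2 = params.grid_shape
    t1 = np.arange(n1) * params.dwell[0]
    t2 = np.arange(n2) * params.dwell[1]
    grid = np.zeros((n1, n2, 2, 2))
    for amp, (f1, f2) in zip(params.amplitudes, params.frequencies_hz):
        a = scale * amp
        w1 = 2 * np.pi * f1 * t1
        w2 = 2 * np.pi * f2 * t2
        env = np.exp(-params.decay_rate_hz * t1)[:, None] * np.exp(
            -params.decay_rate_hz * t2
        )[None, :]
        grid[:, :, 0, 0] += a * env * np.outer(np.cos(w1), np.cos(w2))
        grid[:, :, 0, 1] += a * env * np.outer(np.cos(w1), np.sin(w2))
        grid[:, :, 1, 0] += a * env * np.outer(np.sin(w1), np.cos(w2))
        grid[:, :, 1, 1] += a * env * np.outer(np.sin(w1), np.sin(w2))
    return grid


def simulate_plane(params: PlaneParams, kind: str = "strong") -> tuple[SparseDataset, Spectrum]:
    """Simulate a sparsely sampled hypercomplex plane.

    ``kind`` selects the signal content: ``strong`` (full amplitudes),
    ``weak`` (same layout scaled so the largest amplitude is 5x the noise
    sigma, mimicking leakage from a neighbouring plane) or ``noise`` (no
    signals at all).  The sampling schedule and noise realization depend
    only on the seed, so strong/weak planes from one seed share peak
    positions and differ purely by the amplitude scale.

    Returns the sparse dataset and the noiseless truth spectrum.
    """
    if kind not in {"strong", "weak", "noise"}:
        raise ValueError(f"kind must be strong, weak or noise, got {kind!r}")
    seeds = _child_seeds(params.seed)
    if kind == "noise":
        scale = 0.0
    elif kind == "weak":
        scale = (
            params.weak_scale
            if params.weak_scale is not None
            else 5.0 * params.noise_sigma / max(params.amplitudes)
        )
    else:
        scale = 1.0
    clean = _plane_components(params, scale)
    schedule = make_schedule(params.grid_shape, params.sampling_density, _int_seed(seeds["schedule"]))
    vals = clean[tuple(schedule.positions.T)].reshape(schedule.n_points, 4)
    if params.noise_sigma > 0:
        noise_rng = np.random.default_rng(seeds["noise"])
        vals = vals + noise_rng.normal(0.0, params.noise_sigma, vals.shape)
    dataset = SparseDataset(schedule, vals, Role.FULL, params.dwell)
    truth = Spectrum(params.grid_shape, _hyper_fft(clean), params.dwell)
    return dataset, truth
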
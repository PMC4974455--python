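"""Benchmark orchestration and algorithm-independent external scoring.

``run_benchmark`` reproduces the full 1-D simulation study: simulate the
nine-signal sparse dataset, split it 80/20 into working and free sets, run
the l1 and MaxEnt lambda-scans and the IST iteration scan, and write every
trajectory (four quality factors, composite score, RMSD to the reference
spectrum) as CSV/JSON, with optional plots.

``score_external`` scores any externally produced model spectrum against
held-out data -- the algorithm-independent use of R_noise_free as a gauge
of reconstruction fidelity when no reference spectrum exists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .datamodel import (
    Role,
    SparseDataset,
    SplitDataset,
    read_dataset,
    write_dataset,
    write_schedule,
)
from .ist import IstConfig, IstResult, ist_reconstruct
from .rfactor import RFactorReport, Trajectory, score_split
from .synth import Benchmark1D, SimulationParams, simulate_benchmark
from .transforms import (
    Spectrum,
    noise_floor,
    read_spectrum,
    write_spectrum,
    zero_fill_transform,
)
from .variational import DEFAULT_LAMBDAS, VariationalConfig, lambda_scan

__all__ = ["BenchmarkReport", "run_benchmark", "score_external", "score_datasets"]


@dataclasses.dataclass
class BenchmarkReport:
    bench: Benchmark1D
    l1_scan: Trajectory
    maxent_scan: Trajectory
    ist: IstResult
    manifest: dict
    output_dir: Path | None


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def suggest_maxent_scale(working: SparseDataset) -> float:
    """Entropy scale anchored to the dirty-spectrum baseline (a tenth of
    the median magnitude), so the entropy default image stays well below
    the noise floor."""
    return 0.1 * noise_floor(zero_fill_transform(working))


def run_benchmark(
    seed: int,
    output_dir: str | Path | None = None,
    params: SimulationParams | None = None,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
    ist_config: IstConfig | None = None,
    variational_config: VariationalConfig | None = None,
    plots: bool = False,
) -> BenchmarkReport:
    """Run the 1-D benchmark end to end; deterministic for a fixed seed."""
    params = params or SimulationParams(seed=seed)
    bench = simulate_benchmark(params)
    split, noise_ref, reference = bench.split, bench.noise_ref, bench.reference

    base_cfg = variational_config or VariationalConfig()
    l1_traj = lambda_scan(split, noise_ref, reference, lambdas, base_cfg.replace(regularizer="l1"))
    me_cfg = base_cfg.replace(
        regularizer="maxent", maxent_scale=suggest_maxent_scale(split.working)
    )
    me_traj = lambda_scan(split, noise_ref, reference, lambdas, me_cfg)
    ist_result = ist_reconstruct(split, noise_ref, ist_config or IstConfig(), reference=reference)

    manifest: dict = {
        "command": "benchmark",
        "package": "rnoise",
        "version": __version__,
        "seed": seed,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(params).items()
        },
        "lambdas": list(lambdas),
        "split_seed": bench.sim.split_seed,
        "split_generator": split.generator,
        "maxent_scale": me_cfg.maxent_scale,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {},
    }

    out = None
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(bench.sim.sparse, out / "sparse.txt")
        write_dataset(noise_ref, out / "noise_reference.txt")
        write_schedule(bench.sim.sparse.schedule, out / "schedule.txt")
        write_spectrum(reference, out / "reference_spectrum.txt")
        write_spectrum(bench.sim.truth, out / "truth_spectrum.txt")
        l1_traj.write_csv(out / "l1_scan.csv")
        l1_traj.write_json(out / "l1_scan.json")
        me_traj.write_csv(out / "maxent_scan.csv")
        me_traj.write_json(out / "maxent_scan.json")
        ist_result.model_trajectory.write_csv(out / "ist_model.csv")
        ist_result.recon_trajectory.write_csv(out / "ist_reconstruction.csv")
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["outputs"][f.name] = _digest(f)
        if plots:
            _plot_benchmark(out, l1_traj, me_traj, ist_result)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    return BenchmarkReport(bench, l1_traj, me_traj, ist_result, manifest, out)


def _plot_benchmark(out: Path, l1, me, ist: IstResult) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, traj, xlab, logx in (
        ("l1_scan", l1, "lambda", True),
        ("maxent_scan", me, "lambda", True),
        ("ist_model", ist.model_trajectory, "iteration", False),
    ):
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        x = traj.control_values
        axes[0].plot(x, traj.array("score_total"))
        axes[0].set_ylabel("composite score")
        axes[1].plot(x, traj.array("rnoise_work"), label="$R^{noise}_{work}$")
        axes[1].plot(x, traj.array("rnoise_free"), label="$R^{noise}_{free}$")
        axes[1].legend()
        axes[2].plot(x, traj.array("rmsd_to_reference"))
        axes[2].set_ylabel("RMSD to reference")
        for ax in axes:
            ax.set_xlabel(xlab)
            if logx:
                ax.set_xscale("log")
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)


def score_datasets(
    model: Spectrum,
    working: SparseDataset,
    free: SparseDataset,
    noise_ref: SparseDataset,
    control: tuple[str, float] = ("external", 0.0),
) -> RFactorReport:
    """Score a model against explicit working/free/noise datasets."""
    for name, ds in (("working", working), ("free", free), ("noise", noise_ref)):
        if ds.schedule.grid_shape != model.grid_shape:
            raise ValueError(f"{name} dataset grid does not match the model grid")
    split = SplitDataset(working, free, seed=None)
    return score_split(model, split, noise_ref, control=control, algorithm="external")


def score_external(
    model_file: str | Path,
    working_file: str | Path,
    free_file: str | Path,
    noise_file: str | Path,
) -> RFactorReport:
    """File-based variant of :func:`score_datasets`."""
    model = read_spectrum(model_file)
    working = read_dataset(working_file)
    free = read_dataset(free_file)
    noise = read_dataset(noise_file)
    working.role = Role.WORKING
    free.role = Role.FREE
    return score_datasets(model, working, free, noise)
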
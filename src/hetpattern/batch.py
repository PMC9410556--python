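"""Seeded batch orchestration and run manifests.

Replicate simulations are organized as ``n_batches`` x ``runs_per_batch``
(default 15 x 10, the convention used for all ensemble statistics).  Each
run's seed is derived deterministically from (base_seed, batch, run) through
numpy's SeedSequence, so a batch is reproducible from its base seed alone and
runs are statistically independent without a shared stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .model_core import ModelParameters
from .observables import BatchResult, batch_statistics, summary_dataframe
from .simulate import (
    MutantSpec,
    NoiseSettings,
    SimulationConfig,
    Trajectory,
    run_simulation,
)

__all__ = ["RunManifest", "BatchRun", "derive_seed", "run_batch"]


def derive_seed(base_seed: int, batch: int, run: int) -> int:
    """Deterministic, well-separated per-run seed (always < 2**31)."""
    return int(
        np.random.SeedSequence((base_seed, batch, run)).generate_state(1)[0] % (2**31)
    )


@dataclass
class RunManifest:
    """Everything needed to regenerate a batch bit-for-bit."""

    config_hash: str
    config: dict
    parameters: dict
    mutant: dict
    noise: dict
    base_seed: int
    seeds: List[List[int]]  # [batch][run]
    version: str = __version__
    files: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class BatchRun:
    """Trajectories grouped into batches plus per-time ensemble statistics."""

    batches: List[List[Trajectory]]
    results: Dict[float, BatchResult]
    manifest: RunManifest


def _config_hash(doc: dict) -> str:
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def run_batch(
    config: SimulationConfig,
    params: ModelParameters,
    mutant: Optional[MutantSpec] = None,
    n_batches: int = 15,
    runs_per_batch: int = 10,
    base_seed: int = 0,
    noise: Optional[NoiseSettings] = None,
    times: Optional[Sequence[float]] = None,
    out_dir=None,
    condition: str = "WT",
    write_trajectories: bool = False,
) -> BatchRun:
    """Run a seeded batch ensemble and aggregate its pattern statistics.

    ``times`` defaults to the final time only.  With ``out_dir`` set, writes
    a summary CSV per time point, the manifest JSON, and (optionally) one
    trajectory CSV per run.
    """
    if n_batches < 1 or runs_per_batch < 1:
        raise ValueError("n_batches and runs_per_batch must be >= 1")
    noise = noise if noise is not None else NoiseSettings()
    mut = mutant if mutant is not None else MutantSpec()
    seeds = [
        [derive_seed(base_seed, b, r) for r in range(runs_per_batch)]
        for b in range(n_batches)
    ]
    batches: List[List[Trajectory]] = []
    for b in range(n_batches):
        batches.append(
            [
                run_simulation(
                    config,
                    params,
                    mut,
                    NoiseSettings(noise.omega_phi, noise.omega_lambda, seed=s),
                )
                for s in seeds[b]
            ]
        )
    tlist = list(times) if times is not None else [config.t_end]
    results = {
        t: batch_statistics([[tr.at_time(t) for tr in b] for b in batches])
        for t in tlist
    }
    doc = {
        "config": config.to_dict(),
        "parameters": params.to_dict(),
        "mutant": mut.to_dict(),
        "noise": {"omega_phi": noise.omega_phi, "omega_lambda": noise.omega_lambda},
        "n_batches": n_batches,
        "runs_per_batch": runs_per_batch,
        "base_seed": base_seed,
    }
    manifest = RunManifest(
        config_hash=_config_hash(doc),
        config=config.to_dict(),
        parameters=params.to_dict(),
        mutant=mut.to_dict(),
        noise=doc["noise"],
        base_seed=base_seed,
        seeds=seeds,
    )
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            for t, res in results.items():
                f = out / f"summary_{condition}_{t:g}h.csv"
                summary_dataframe(res, condition, t).to_csv(f, index=False)
                manifest.files.append(f.name)
            if write_trajectories:
                for b, batch in enumerate(batches):
                    for r, tr in enumerate(batch):
                        f = out / f"trajectory_{condition}_b{b:02d}_r{r:02d}.csv"
                        tr.to_dataframe().to_csv(f, index=False)
                        manifest.files.append(f.name)
            (out / "manifest.json").write_text(manifest.to_json())
        except OSError as exc:
            raise OSError(f"failed writing batch output under {out}: {exc}") from exc
    return BatchRun(batches=batches, results=results, manifest=manifest)
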
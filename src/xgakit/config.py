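"""Run configuration: validated, echoed verbatim into output manifests."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimulateSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_strains: int = Field(default=300, ge=1)
    n_loci: int = Field(default=16, ge=1)
    n_drugs: int = Field(default=4, ge=1)
    n_influences: int = 2
    n_effluxes: int = 6
    linkage: list[tuple[int, int, float]] = []
    mating_split: float = 0.5
    depth: int = 200_000
    timepoints: list[float] = [0, 5, 10, 15, 20]
    noise_sd: float = 0.03
    write_fastq: bool = False


class FitnessSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    solvent: str = "DMSO"
    min_t0_count: float = 30.0
    baseline_fraction: float = 0.7


class EpistasisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_order: int = 5
    alpha: float = 0.05
    expand_alpha: float = 0.05
    family: str = "gaussian_log"


class NetfitSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float = 0.05
    epochs: int = 600
    batch_fraction: float = 0.30
    validation_fraction: float = 0.10
    n_runs: int = 10
    z_cut: float = 4.0
    prune_alpha: float = 0.05
    prune_tolerance: float = 1e-4
    merge_mode: str = "mean_with_z"
    lam: float = 5e-4


class RunConfig(BaseModel):
    """Complete pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    outdir: str = "xga_run"
    seed: int = 0
    simulate: SimulateSettings = SimulateSettings()
    fitness: FitnessSettings = FitnessSettings()
    epistasis: EpistasisSettings = EpistasisSettings()
    netfit: NetfitSettings = NetfitSettings()

    @model_validator(mode="after")
    def _check(self):
        if self.simulate.n_influences > self.simulate.n_loci * (self.simulate.n_loci - 1):
            raise ValueError("n_influences exceeds available off-diagonal links")
        return self


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    return RunConfig(**data)


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(outdir: str | Path, stage: str, config: RunConfig, inputs: dict) -> Path:
    """Stage manifest: full config echo, seed, input-file hashes."""
    payload = {
        "stage": stage,
        "seed": config.seed,
        "config": config.model_dump(),
        "inputs": {k: file_hash(v) for k, v in inputs.items() if Path(v).exists()},
    }
    path = Path(outdir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
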
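"""Run configuration: schema-validated nested sections, one per stage.

A single global seed fans out to per-stage seeds by hashing the stage
name (see :func:`uqmlaa.io.stage_seed`), so stages are independently
reproducible.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PhantomSection", "TrainSection", "MCSection", "PriorSection",
           "GeometrySection", "ReconSection", "EvalSection", "RunConfig",
           "load_run_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LesionEntry(_Section):
    center: tuple[float, float, float]   # fractional grid coordinates
    radius_mm: float = 7.5
    contrast: float = 4.0
    klass: str = "soft"


class ImplantEntry(_Section):
    center: tuple[float, float, float] = (0.5, 0.48, 0.27)
    radius_mm: float = 10.0
    implant_hu: float = 3000.0
    halo_radius_mm: float = 25.0


class PhantomSection(_Section):
    n_train_cases: int = 10
    grid_shape: tuple[int, int, int] = (1, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    noise: float = 0.02
    split_fraction: float = 0.8
    train_with_implants: bool = False    # guarded: must stay False
    test_implant: ImplantEntry = Field(default_factory=ImplantEntry)
    test_lesions: tuple[LesionEntry, ...] = (
        LesionEntry(center=(0.5, 0.45, 0.62), radius_mm=7.5, contrast=4.0,
                    klass="soft"),
    )


class TrainSection(_Section):
    iterations: int = 1500
    learning_rate: float = 1e-3
    batch_size: int = 4
    lambda_gdl: float = 0.01
    lambda_ldl: float = 0.01
    weight_decay: float = 1e-5
    depth: int = 3
    base_channels: int = 16
    dropout: float = 0.2
    patch_size: tuple[int, int] = (64, 64)


class MCSection(_Section):
    n_samples: int = 32


class PriorSection(_Section):
    beta_min: float = 1e3
    beta_max: float = 5e6
    scaling: str = "minmax"


class GeometrySection(_Section):
    n_angles: int = 64
    n_radial: int = 96
    n_tof: int = 9
    tof_fwhm_mm: float = 60.0
    psf_fwhm_mm: float = 0.0
    n_subsets: int = 8
    total_counts: float = 2e6
    background: float = 0.0


class ReconSection(_Section):
    outer_iterations: int = 5
    osem_passes_per_outer: int = 1
    ostr_passes_per_outer: int = 5
    beta_smooth: float = 2e4
    mu_max: float = 0.5
    step_clamp: float = 0.02
    osem_iterations: int = 2
    uniform_betas: tuple[float, ...] = (1e3, 7e5, 5e6)


class EvalSection(_Section):
    suv_scale: float = 1.0
    hu_threshold: float = -950.0
    mu_threshold: float = 0.01


class RunConfig(_Section):
    seed: int = 0
    out_root: str = "runs"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    train: TrainSection = Field(default_factory=TrainSection)
    mc: MCSection = Field(default_factory=MCSection)
    prior: PriorSection = Field(default_factory=PriorSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    recon: ReconSection = Field(default_factory=ReconSection)
    eval: EvalSection = Field(default_factory=EvalSection)


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def config_hash(cfg: BaseModel) -> str:
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
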
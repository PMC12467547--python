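"""Run configuration: a validated, serializable description of an analysis."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class EnsembleConfig(BaseModel):
    """Dipole ensemble: shells at radius_start..radius_stop (step) x per_shell."""

    radius_start_mm: float = 0.0
    radius_stop_mm: float = 76.0
    radius_step_mm: float = 1.0
    per_shell: int = Field(100, ge=1)
    seed: int = 0


class SpectrumConfig(BaseModel):
    """Dense-layout SH/Sphara spectral comparison stage."""

    enabled: bool = True
    layout_n: int = Field(4000, ge=16)
    l_max: int = Field(15, ge=1)
    n_center_reference: int = Field(100, ge=1)
    subset_shells_mm: list[float] = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 76.0]
    sources_per_shell: int = Field(12, ge=1)


class RunConfig(BaseModel):
    """Top-level configuration of the spherical validation pipeline."""

    layout_sizes: list[int] = [34, 104, 232, 462, 938]
    layout_radius_mm: float = Field(92.0, gt=0)
    layout_seed: int = 7
    shell_radii_mm: tuple[float, float, float, float] = (80.0, 81.0, 86.0, 92.0)
    conductivities_S_per_m: tuple[float, float, float, float] = (0.33, 1.79, 0.0066, 0.33)
    series_tol: float = Field(1e-10, gt=0)
    l_max_cap: int = Field(600, ge=1)
    ensemble: EnsembleConfig = EnsembleConfig()
    spectrum: SpectrumConfig = SpectrumConfig()
    depth_groups: int = Field(6, ge=1)
    make_plots: bool = False

    @field_validator("layout_sizes")
    @classmethod
    def _sizes_ok(cls, v):
        if not v or any(n < 4 for n in v):
            raise ValueError("layout sizes must all be >= 4")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.layout_radius_mm != self.shell_radii_mm[3]:
            raise ValueError("layout radius must equal the outer shell radius R4")
        if self.ensemble.radius_stop_mm >= self.shell_radii_mm[0]:
            raise ValueError("ensemble shells must stay inside the innermost radius R1")
        return self


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: str) -> None:
    """Write the resolved configuration next to the results."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
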
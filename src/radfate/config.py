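"""Validated run configuration: one structured file drives a whole run.

Every module's tunables appear as a section; unknown keys are rejected
so a typo cannot silently fall back to a default.  Command-line flags
only override values coming from the file.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["SimConfig", "load_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DamageConfig(_Section):
    dose_gy: float = Field(2.0, ge=0)
    dsb_yield_per_gy: float = Field(40.0, ge=0)
    complex_fraction: float = Field(0.1, ge=0, le=1)
    hc_fraction: float = Field(0.2, ge=0, le=1)
    nucleus_radius_nm: float = Field(5000.0, gt=0)


class CompartmentConfig(_Section):
    slope: float = 0.8268
    intercept: float = 0.0705
    forced_f_slow: float | None = Field(None, ge=0, le=1)


class RepairConfig(_Section):
    dt_s: float = Field(0.01, gt=0)
    t_max_s: float = Field(259200.0, gt=0)  # 72 h
    synapsis_distance_nm: float = Field(100.0, gt=0)
    d_pre_nm2_s: float = Field(1.0, ge=0)
    d_post_nm2_s: float = Field(100.0, ge=0)
    artemis_active: bool = True
    adaptive_dt: bool = True


class P53Config(_Section):
    param_file: str | None = None  # packaged defaults when None
    m_gy: float = Field(0.14, gt=0)
    t_max_h: float = Field(72.0, gt=0)


class FateConfig(_Section):
    apoptosis_species: str = "Bax"
    apoptosis_multiple: float = Field(5.0, gt=0)
    arrest_species: str = "cyclin_E"
    arrest_fraction: float = Field(0.1, gt=0)
    n_cells: int = Field(100, ge=1)
    doses_gy: list[float] = [2.0, 4.0, 8.0]
    f_slows: list[float] = [0.2, 0.4, 0.6, 0.8]
    m_values_gy: list[float] = [0.14, 0.5]


class SimConfig(_Section):
    """Top-level configuration mirroring the module layout."""

    master_seed: int = 0
    output_dir: str = "radfate_out"
    engine: str = Field("stochastic", pattern="^(deterministic|stochastic|both)$")
    damage: DamageConfig = DamageConfig()
    compartments: CompartmentConfig = CompartmentConfig()
    repair: RepairConfig = RepairConfig()
    p53: P53Config = P53Config()
    fate: FateConfig = FateConfig()

    def repair_params(self):
        from .repair import RepairParams

        return RepairParams(
            dt=self.repair.dt_s,
            t_max=self.repair.t_max_s,
            synapsis_distance=self.repair.synapsis_distance_nm,
            d_pre=self.repair.d_pre_nm2_s,
            d_post=self.repair.d_post_nm2_s,
            artemis_active=self.repair.artemis_active,
            adaptive_dt=self.repair.adaptive_dt,
        )

    def fate_thresholds(self):
        from .fate import FateThresholds

        return FateThresholds(
            apoptosis_species=self.fate.apoptosis_species,
            apoptosis_multiple=self.fate.apoptosis_multiple,
            arrest_species=self.fate.arrest_species,
            arrest_fraction=self.fate.arrest_fraction,
        )


def load_config(path: str | Path | None = None) -> SimConfig:
    """Load and validate a YAML configuration; defaults when path is None."""
    if path is None:
        return SimConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return SimConfig.model_validate(raw)
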
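"""Scenario configuration: validated, serializable, with base-case defaults.

A scenario file is a human-editable YAML document; omitted physics keys fall
back to the base-case parameter set, unknown keys are rejected by name, and
``load -> save -> load`` round-trips losslessly.  One master seed
deterministically derives every sub-seed (percolation, heterogeneity) through
a counter-based splitting scheme so partial re-runs stay reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .properties import FlowProperties

__all__ = ["ScenarioConfig", "load_config", "save_config", "derive_seeds"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HeterogeneityConfig(_Strict):
    distribution: str = Field("lognormal", pattern="^(lognormal|uniform)$")
    cv: float = Field(0.0, ge=0.0)


class LatticeConfig(_Strict):
    dims: tuple[int, int, int] = (50, 50, 50)
    master_seed: int = Field(0, ge=0)
    percolation_fraction: float = Field(1.0, gt=0.0, le=1.0)
    heterogeneity: HeterogeneityConfig = HeterogeneityConfig()


class PhysicsConfig(_Strict):
    """Unit-cell physical properties; defaults are the base-case set."""

    sinusoid_radius_um: float = Field(3.0, gt=0.0)
    tissue_edge_um: float = Field(24.0, gt=0.0)
    tissue_porosity: float = Field(0.2, gt=0.0, lt=1.0)
    tissue_permeability_um2: float = Field(1.736e-7, gt=0.0)
    sinusoid_diffusion_m2_s: float = Field(4.2e-10, gt=0.0)
    tissue_diffusion_m2_s: float = Field(4.2e-11, gt=0.0)
    blood_viscosity_pa_s: float = Field(3.5e-3, gt=0.0)

    def flow_properties(self) -> FlowProperties:
        from .properties import poiseuille_sinusoid

        porosity, perm = poiseuille_sinusoid(self.sinusoid_radius_um)
        return FlowProperties(
            sinusoid_radius=self.sinusoid_radius_um,
            sinusoid_porosity=porosity,
            sinusoid_permeability=perm,
            tissue_porosity=self.tissue_porosity,
            tissue_permeability=self.tissue_permeability_um2,
            sinusoid_diffusion=self.sinusoid_diffusion_m2_s,
            tissue_diffusion=self.tissue_diffusion_m2_s,
            blood_viscosity=self.blood_viscosity_pa_s,
        )


class FlowConfig(_Strict):
    delta_p_pa: float = Field(100.0, ge=0.0)
    tol: float = Field(1e-10, gt=0.0)


class O2Config(_Strict):
    inlet_uM: float = Field(60.0, ge=0.0)
    v_max_uM_min: float = Field(1000.0, gt=0.0)
    K_m_uM: float = Field(6.0, gt=0.0)


class PacConfig(_Strict):
    injection_uM: float = Field(1.0, ge=0.0)
    duration_min: float = Field(1.0, gt=0.0)
    t_end_min: float = Field(1.0, gt=0.0)
    dt_min: float = Field(1e-3, gt=0.0)
    v_max_uM_min: float = Field(0.06, gt=0.0)
    K_m_uM: float = Field(10.0, gt=0.0)
    snapshot_times_min: tuple[float, ...] = (0.2, 0.4, 1.0)


class ZonationConfig(_Strict):
    rule: str = Field("linear", pattern="^(linear|threshold|hill)$")
    params: dict = Field(default_factory=dict)


class ProtocolConfig(_Strict):
    strain: float = Field(0.05, gt=0.0, lt=1.0)
    ramp_s: float = Field(0.1, gt=0.0)
    hold_s: float = Field(60.0, gt=0.0)
    n_ramp: int = Field(20, ge=1)
    hold_growth: float = Field(1.3, ge=1.0)


class ScenarioFactors(_Strict):
    stiffness_factor: float = Field(5.0, gt=0.0)
    permeability_factor: float = Field(0.2, gt=0.0)


class MechanicsConfig(_Strict):
    youngs_modulus_pa: float = Field(5.0e3, gt=0.0)
    poissons_ratio: float = Field(0.35, ge=0.0, lt=0.5)
    biot_alpha: float = Field(1.0, gt=0.0, le=1.0)
    skempton: float = Field(1.0, gt=0.0, le=1.0)
    protocol: ProtocolConfig = ProtocolConfig()
    scenario: ScenarioFactors = ScenarioFactors()

    def biot_params(self, viscosity: float = 3.5e-3):
        from .mechanics import BiotParams

        return BiotParams(
            youngs_modulus=self.youngs_modulus_pa,
            poissons_ratio=self.poissons_ratio,
            biot_alpha=self.biot_alpha,
            skempton=self.skempton,
            fluid_viscosity=viscosity,
        )


class OutputConfig(_Strict):
    directory: str = "runs"
    log_level: str = "INFO"


class ScenarioConfig(_Strict):
    """Full simulation scenario; every block is optional in the file."""

    lattice: LatticeConfig = LatticeConfig()
    physics: PhysicsConfig = PhysicsConfig()
    flow: FlowConfig = FlowConfig()
    o2: O2Config = O2Config()
    pac: PacConfig = PacConfig()
    zonation: ZonationConfig = ZonationConfig()
    mechanics: MechanicsConfig = MechanicsConfig()
    output: OutputConfig = OutputConfig()


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ScenarioConfig.model_validate(raw)


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Derive all sub-seeds from the master seed (stable, counter-based)."""
    state = np.random.SeedSequence(master_seed).generate_state(4)
    names = ("percolation", "heterogeneity", "replicates", "reserved")
    return {name: int(s % 2**31) for name, s in zip(names, state)}
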
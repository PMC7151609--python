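"""Physics-law property estimators and unit conversions.

The base-case parameter set of the idealized lobule is not measured but
*derived* from first principles: Poiseuille flow in a circular sinusoid tube
inscribed in a square channel, a Carman-Kozeny correlation for the fibrous
space-of-Disse tissue, Stokes-Einstein free diffusion in blood plasma with a
fixed hindrance ratio in tissue, and Michaelis-Menten elimination kinetics.
This module regenerates every such entry and provides the dual-unit
conversions (um^2 <-> Darcy, uM <-> mole fraction) used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "BOLTZMANN",
    "DARCY_UM2",
    "WATER_MOLARITY",
    "FlowProperties",
    "KineticParameters",
    "poiseuille_sinusoid",
    "carman_kozeny",
    "stokes_einstein",
    "micromolar_to_molefrac",
    "molefrac_to_micromolar",
    "um2_to_darcy",
    "darcy_to_um2",
    "m2s_to_cm2min",
    "michaelis_menten_rate",
    "load_parameter_set",
    "base_case_parameters",
]

BOLTZMANN = 1.380649e-23
"""Boltzmann constant, J/K (exact, 2019 SI)."""

DARCY_UM2 = 0.9869
"""One Darcy expressed in um^2 (engineering permeability convention)."""

WATER_MOLARITY = 55.56
"""Molar density of pure water, mol/L; fixes the uM -> mole-fraction factor."""


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class FlowProperties:
    """Per-compartment flow and diffusion properties of the unit cell.

    Lengths in um (fibers in nm), permeabilities in um^2, diffusivities in
    m^2/s, viscosity in Pa*s.  Porosities are dimensionless fractions.
    """

    sinusoid_radius: float = 3.0
    sinusoid_porosity: float = math.pi / 4.0
    sinusoid_permeability: float = 1.125
    tissue_porosity: float = 0.2
    tissue_permeability: float = 1.736e-7
    sinusoid_diffusion: float = 4.2e-10
    tissue_diffusion: float = 4.2e-11
    blood_viscosity: float = 3.5e-3
    fiber_diameter: float = 50.0
    fiber_length: float = 300.0

    def __post_init__(self) -> None:
        for name in ("sinusoid_porosity", "tissue_porosity"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "sinusoid_radius",
            "sinusoid_permeability",
            "tissue_permeability",
            "sinusoid_diffusion",
            "tissue_diffusion",
            "blood_viscosity",
            "fiber_diameter",
            "fiber_length",
        ):
            v = getattr(self, name)
            if not v > 0.0:
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if not self.tissue_diffusion < self.sinusoid_diffusion:
            raise InvalidParameterError(
                "tissue diffusion must be below free sinusoid diffusion "
                "(restricted motion around collagen fibers)"
            )


@dataclass(frozen=True)
class KineticParameters:
    """Michaelis-Menten elimination parameters in dual units.

    ``v_max`` in uM/min, ``K_m`` in uM; the mole-fraction twins and the
    low-concentration linear rate v_max/K_m (1/min) are derived.
    """

    v_max: float = 0.06
    K_m: float = 10.0

    def __post_init__(self) -> None:
        if not (self.v_max > 0.0 and self.K_m > 0.0):
            raise InvalidParameterError("v_max and K_m must be strictly positive")

    @property
    def v_max_molefrac(self) -> float:
        return micromolar_to_molefrac(self.v_max)

    @property
    def K_m_molefrac(self) -> float:
        return micromolar_to_molefrac(self.K_m)

    @property
    def linear_rate(self) -> float:
        """First-order rate v_max/K_m (1/min), unit-system invariant."""
        return self.v_max / self.K_m


def poiseuille_sinusoid(radius: float) -> tuple[float, float]:
    """Porosity and permeability of a circular tube in a square channel.

    A sinusoid of radius ``R`` (um) runs inside a square cross-section of
    side 2R.  The open-area fraction is pi/4 independent of R, and the
    Poiseuille-equivalent Darcy permeability of the tube is R^2/8 (um^2),
    which reproduces the base case 1.125 um^2 at R = 3 um.
    """
    if radius <= 0.0:
        raise InvalidParameterError(f"sinusoid radius must be positive, got {radius}")
    return math.pi / 4.0, radius**2 / 8.0


def carman_kozeny(porosity: float, grain_scale: float = 0.05) -> float:
    """Carman-Kozeny permeability (um^2) of a granular/fibrous bed.

    K = phi^3 d^2 / (180 (1 - phi)^2) with the classic packed-bed constant
    180; ``grain_scale`` d defaults to the 50 nm collagen fiber diameter
    expressed in um.
    """
    if not 0.0 < porosity < 1.0:
        raise InvalidParameterError(f"porosity must lie in (0, 1), got {porosity}")
    if grain_scale <= 0.0:
        raise InvalidParameterError(f"grain scale must be positive, got {grain_scale}")
    return porosity**3 * grain_scale**2 / (180.0 * (1.0 - porosity) ** 2)


def stokes_einstein(particle_radius: float, temperature: float, viscosity: float) -> float:
    """Free diffusivity D = k_B T / (6 pi mu r) in m^2/s (SI inputs)."""
    if particle_radius <= 0.0 or temperature <= 0.0 or viscosity <= 0.0:
        raise InvalidParameterError("Stokes-Einstein arguments must be strictly positive")
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * particle_radius)


def micromolar_to_molefrac(conc: float) -> float:
    """Convert uM to mole fraction in dilute aqueous solution.

    Uses the pure-water molar density 55.56 mol/L, i.e. 1 uM = 1.8e-8
    mole fraction.
    """
    if conc < 0.0:
        raise InvalidParameterError(f"concentration must be non-negative, got {conc}")
    return conc * 1e-6 / WATER_MOLARITY


def molefrac_to_micromolar(x: float) -> float:
    if x < 0.0:
        raise InvalidParameterError(f"mole fraction must be non-negative, got {x}")
    return x * WATER_MOLARITY * 1e6


def um2_to_darcy(k: float) -> float:
    """Permeability um^2 -> Darcy (1 Darcy = 0.9869 um^2)."""
    if k < 0.0:
        raise InvalidParameterError(f"permeability must be non-negative, got {k}")
    return k / DARCY_UM2


def darcy_to_um2(k: float) -> float:
    if k < 0.0:
        raise InvalidParameterError(f"permeability must be non-negative, got {k}")
    return k * DARCY_UM2


def m2s_to_cm2min(d: float) -> float:
    """Diffusivity m^2/s -> cm^2/min (factor 6e5)."""
    return d * 6.0e5


def michaelis_menten_rate(conc, v_max: float, K_m: float):
    """Michaelis-Menten rate v = v_max C / (K_m + C); accepts array C.

    Saturates at v_max and reduces to the linear rate (v_max/K_m) C for
    C << K_m.  Units follow the inputs (uM and uM/min, or mole fraction and
    molefrac/min).
    """
    import numpy as np

    if v_max <= 0.0 or K_m <= 0.0:
        raise InvalidParameterError("v_max and K_m must be strictly positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0.0):
        raise InvalidParameterError("concentration must be non-negative")
    out = v_max * c / (K_m + c)
    return float(out) if out.ndim == 0 else out


def load_parameter_set(name: str = "table1_base_case") -> dict:
    """Load a named parameter file shipped with the package."""
    ref = resources.files("lobulesim.data").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise FileNotFoundError(f"unknown parameter set {name!r}")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def base_case_parameters() -> dict:
    """Regenerate the base-case dual-unit parameter table from first principles.

    Returns a dict keyed by parameter name with (characteristic-unit value,
    engineering-unit value) pairs, recomputed by the estimators above rather
    than read from the shipped file.
    """
    porosity, k_sin = poiseuille_sinusoid(3.0)
    raw = load_parameter_set("table1_base_case")
    d_sin = raw["diffusion"]["sinusoid_diffusion_m2_s"]
    d_tis = raw["diffusion"]["tissue_diffusion_m2_s"]
    kin = KineticParameters(v_max=raw["kinetics"]["v_max_uM_min"], K_m=raw["kinetics"]["K_m_uM"])
    return {
        "sinusoid_porosity": (porosity, porosity),
        "sinusoid_permeability": (k_sin, um2_to_darcy(k_sin)),  # um^2, Darcy
        "sinusoid_diffusion": (d_sin, m2s_to_cm2min(d_sin)),  # m^2/s, cm^2/min
        "tissue_diffusion": (d_tis, m2s_to_cm2min(d_tis)),
        "v_max": (kin.v_max, kin.v_max_molefrac),  # uM/min, molefrac/min
        "K_m": (kin.K_m, kin.K_m_molefrac),  # uM, molefrac
        "linear_rate": (kin.linear_rate, kin.linear_rate),  # 1/min both
        "blood_viscosity": (raw["flow"]["blood_viscosity_pa_s"], raw["flow"]["blood_viscosity_pa_s"] * 1e3),
        "youngs_modulus": (raw["mechanics"]["youngs_modulus_pa"], raw["mechanics"]["youngs_modulus_pa"] / 1e3),
        "poissons_ratio": (raw["mechanics"]["poissons_ratio"],) * 2,
        "biot_alpha": (raw["mechanics"]["biot_alpha"],) * 2,
        "skempton": (raw["mechanics"]["skempton"],) * 2,
    }
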
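"""Force calibration for centrifuge force microscopy (CFM).

In a CFM a video microscope spins inside a centrifuge bucket, so every
tethered microsphere experiences a constant centrifugal force

    F = m_eff * omega**2 * r,

where ``m_eff`` is the buoyancy-corrected bead mass, ``omega`` the angular
velocity set by the rotor speed (RPM) and ``r`` the distance from the rotor
axis to the sample chamber.  This module owns that conversion, its inverse
(for experiment planning), the relative centrifugal field (RCF, in multiples
of standard gravity) and the thermal energy scale k_B*T used to turn
Bell-Evans force scales into transition-state distances.

Units contract: SI internally (kg, m, s, K); piconewtons, nanometres and
kcal/mol at the interface.  The unit factors live here and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "AcquisitionConfig",
    "rpm_to_force",
    "rpm_to_rcf",
    "force_to_rpm",
    "thermal_energy",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants, read-only for all modules.

    Attributes
    ----------
    gas_constant : float
        R in kcal mol^-1 K^-1.
    boltzmann : float
        k_B in pN nm K^-1.
    standard_gravity : float
        g0 in m s^-2.
    """

    gas_constant: float = 1.9872e-3
    boltzmann: float = 1.38065e-2
    standard_gravity: float = 9.80665


#: Module-wide read-only constants instance.
CONSTANTS = PhysicalConstants()

# 1 N = 1e12 pN
_PN_PER_N = 1e12


@dataclass(frozen=True)
class AcquisitionConfig:
    """Spin and acquisition parameters of one constant-force run.

    Parameters
    ----------
    rpm : float
        Rotor speed in revolutions per minute at the force plateau.
    rotor_radius : float
        Distance from rotor centre to the sample chamber, metres.
    bead_mass_eff : float
        Buoyancy-corrected bead mass in kilograms (actual mass minus the
        mass of displaced buffer).  Default is the Dynabeads M-270 value.
    temperature : float
        Absolute temperature, kelvin.  Default 294.15 K (21 degC room
        temperature).
    frame_interval : float
        Seconds between *saved* frames (acquisition at 1 fps with every
        fifth frame kept gives 5 s).
    """

    rpm: float
    rotor_radius: float = 0.133
    bead_mass_eff: float = 6.9e-15
    temperature: float = 294.15
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.rpm) or self.rpm < 0:
            raise ValueError(f"rpm must be finite and >= 0, got {self.rpm}")
        for name in ("rotor_radius", "bead_mass_eff", "temperature", "frame_interval"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def force_pN(self) -> float:
        """Tether force at this config's spin rate, piconewtons."""
        return rpm_to_force(self.rpm, self)


def _angular_velocity(rpm: float) -> float:
    """rad/s from rev/min."""
    return 2.0 * math.pi * rpm / 60.0


def _check_rpm(rpm: float) -> None:
    if not math.isfinite(rpm) or rpm < 0:
        raise ValueError(f"rpm must be finite and >= 0, got {rpm}")


def rpm_to_force(rpm: float, cfg: AcquisitionConfig) -> float:
    """Centrifugal force on a tethered bead.

    Implements F = m_eff * omega**2 * r with omega = 2*pi*rpm/60, returned
    in piconewtons.  Quadratic and monotone increasing in ``rpm``.
    """
    _check_rpm(rpm)
    omega = _angular_velocity(rpm)
    return cfg.bead_mass_eff * omega**2 * cfg.rotor_radius * _PN_PER_N


def rpm_to_rcf(rpm: float, cfg: AcquisitionConfig) -> float:
    """Relative centrifugal field omega**2 * r / g0, in multiples of g."""
    _check_rpm(rpm)
    omega = _angular_velocity(rpm)
    return omega**2 * cfg.rotor_radius / CONSTANTS.standard_gravity


def force_to_rpm(force_pN: float, cfg: AcquisitionConfig) -> float:
    """Spin rate producing a given tether force (inverse of rpm_to_force)."""
    if not math.isfinite(force_pN) or force_pN < 0:
        raise ValueError(f"force must be finite and >= 0, got {force_pN}")
    omega = math.sqrt(force_pN / _PN_PER_N / (cfg.bead_mass_eff * cfg.rotor_radius))
    return omega * 60.0 / (2.0 * math.pi)


def thermal_energy(temperature: float) -> float:
    """k_B * T in pN nm.

    Temperatures below 1 K are rejected: they are outside any meaningful
    operating range and would make downstream transition-distance ratios
    numerically meaningless.
    """
    if not math.isfinite(temperature) or temperature < 1.0:
        raise ValueError(f"temperature must be finite and >= 1 K, got {temperature}")
    return CONSTANTS.boltzmann * temperature
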
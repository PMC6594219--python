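"""Analytical correction terms for simulated ion solvation free energies.

Three standard terms bridge the raw alchemical estimate and the
experimental reference state:

1. finite-size — leading-order self-interaction of a charged solute with
   its periodic images on a cubic lattice;
2. compression — the standard-state change from a 1 atm ideal gas to a
   1 mol/L ideal solution;
3. interface — the electrostatic work of carrying the charge across the
   vacuum/liquid surface potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    COULOMB,
    FARADAY,
    KB,
    R_L_ATM,
    XI_EWALD_CUBIC,
    ConfigError,
    InvalidSpecError,
    ThermoState,
)


@dataclass(frozen=True)
class CorrectionSet:
    """The three per-term corrections (kJ/mol) with provenance notes."""

    finite_size: float = 0.0
    compression: float = 0.0
    interface: float = 0.0
    notes: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        """Exact sum of the three terms."""
        return self.finite_size + self.compression + self.interface

    def to_dict(self) -> dict:
        return {
            "finite_size_kJ_per_mol": self.finite_size,
            "compression_kJ_per_mol": self.compression,
            "interface_kJ_per_mol": self.interface,
            "total_kJ_per_mol": self.total,
            "notes": dict(self.notes),
        }


def compression_correction(
    thermo: Optional[ThermoState] = None,
    gas_pressure: float = 1.0,
    solution_conc: float = 1.0,
) -> float:
    """Standard-state compression term, kJ/mol.

    Free energy of compressing one mole of ideal gas at ``gas_pressure``
    (atm) into an ideal solution at ``solution_conc`` (mol/L):
    RT ln(c2/c1) with c1 = P/(RT) the gas-phase molar concentration.
    Evaluated at 298.15 K unless a thermodynamic state is given.
    """
    temperature = 298.15 if thermo is None else thermo.temperature
    if gas_pressure <= 0 or solution_conc <= 0:
        raise InvalidSpecError("pressure and concentration must be positive")
    c_gas = gas_pressure / (R_L_ATM * temperature)  # mol/L
    return KB * temperature * float(np.log(solution_conc / c_gas))


def finite_size_correction(charge: float, box_edge: float, dielectric: float) -> float:
    """Leading-order periodic-image self-interaction term, kJ/mol.

    xi_EW * q^2 / (8 pi eps0 eps_r L) per mole, with the cubic-lattice
    constant xi_EW = -2.837297.  Higher-order (quadrupole, solvent
    response) terms are omitted.
    """
    if box_edge <= 0:
        raise InvalidSpecError("box edge must be > 0")
    if dielectric < 1:
        raise InvalidSpecError("relative dielectric must be >= 1")
    # COULOMB = e^2/(4 pi eps0) in kJ nm/mol, so /(8 pi eps0) = COULOMB/2
    return XI_EWALD_CUBIC * (COULOMB / 2.0) * charge**2 / (dielectric * box_edge)


def interface_correction(charge: float, surface_potential: Optional[float]) -> float:
    """Work of crossing the vacuum -> liquid surface potential, kJ/mol.

    q * F * chi per mole, with chi the potential change on entering the
    liquid (V).  chi is a per-solvent-model configuration input.
    """
    if surface_potential is None:
        raise ConfigError("no surface potential configured for the requested solvent")
    return charge * FARADAY * surface_potential


def apply_corrections(raw_delta_g: float, corrections: CorrectionSet) -> float:
    """Corrected solvation free energy: raw + sum of the three terms."""
    return raw_delta_g + corrections.total
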
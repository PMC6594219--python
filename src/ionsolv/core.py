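"""Shared physical constants, thermodynamic state, and alchemical coupling.

Units are fixed package-wide: energies in kJ/mol, lengths in nm,
temperatures in K, charges in elementary charge units. Reduced potentials
(u = beta*U) are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Boltzmann constant, kJ/(mol K)
KB = 0.0083144621
# Gas constant in L atm / (mol K), for ideal-gas molar volumes
R_L_ATM = 0.0820573661
# Coulomb prefactor e^2/(4 pi eps0), kJ nm / mol  (per pair of unit charges)
COULOMB = 138.935458
# Faraday constant expressed as kJ/(mol V) per elementary charge
FARADAY = 96.4853321
# Cubic-lattice (Wigner) self-interaction constant for periodic point charges
XI_EWALD_CUBIC = -2.837297


class IonsolvError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(IonsolvError):
    pass


class GeometryError(IonsolvError):
    pass


class ConfigError(IonsolvError):
    pass


@dataclass(frozen=True)
class ThermoState:
    """Temperature and the derived inverse thermal energy beta = 1/(kB T)."""

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise InvalidSpecError(f"temperature must be > 0, got {self.temperature}")

    @property
    def beta(self) -> float:
        """Inverse thermal energy in (kJ/mol)^-1."""
        return 1.0 / (KB * self.temperature)

    @property
    def kt(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return KB * self.temperature


@dataclass(frozen=True)
class LambdaState:
    """One alchemical window: coupling strengths for LJ and electrostatics."""

    lambda_lj: float
    lambda_elec: float

    def __post_init__(self) -> None:
        for name in ("lambda_lj", "lambda_elec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0,1], got {v}")

    @property
    def label(self) -> str:
        return f"LJ{self.lambda_lj:g}_Q{self.lambda_elec:g}"


# LJ coupling ladder (12 interior Gaussian-sequence points plus endpoints).
LAMBDA_LJ_LADDER = (
    0.0, 0.00922, 0.04794, 0.11505, 0.260634, 0.31608, 0.43738,
    0.56262, 0.68392, 0.79366, 0.88495, 0.95206, 0.99078, 1.0,
)
LAMBDA_ELEC_LADDER = (0.25, 0.75, 1.0)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered sequence of alchemical windows from fully decoupled to coupled.

    The default 17-window schedule grows the Lennard-Jones interaction at
    zero charge over 14 windows, then turns on electrostatics at full LJ
    over 3 more.
    """

    states: tuple[LambdaState, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise InvalidSpecError("schedule needs at least 2 states")
        first, last = self.states[0], self.states[-1]
        if (first.lambda_lj, first.lambda_elec) != (0.0, 0.0):
            raise InvalidSpecError("schedule must start at the decoupled state (0,0)")
        if (last.lambda_lj, last.lambda_elec) != (1.0, 1.0):
            raise InvalidSpecError("schedule must end at the coupled state (1,1)")
        seen = set()
        for s in self.states:
            key = (s.lambda_lj, s.lambda_elec)
            if key in seen:
                raise InvalidSpecError(f"duplicate lambda state {key}")
            seen.add(key)
            if s.lambda_elec > 0 and s.lambda_lj != 1.0:
                raise InvalidSpecError(
                    "electrostatics may only be coupled at full LJ (lambda_lj = 1)"
                )

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    @classmethod
    def default(cls) -> "LambdaSchedule":
        """The 17-window schedule used for all ion solvation free energies."""
        states = [LambdaState(lj, 0.0) for lj in LAMBDA_LJ_LADDER]
        states += [LambdaState(1.0, q) for q in LAMBDA_ELEC_LADDER]
        return cls(tuple(states))


@dataclass(frozen=True)
class SoftCorePotentialSpec:
    """Parameters of the coupled solute-solvent pair potential.

    The LJ part uses the Beutler soft-core form, which removes the r -> 0
    singularity at intermediate coupling and reduces exactly to the plain
    12-6 potential at lambda_lj = 1.  The electrostatic part is a
    truncated-and-shifted Coulomb interaction scaled linearly by
    lambda_elec.

    For monatomic (point) solutes the intramolecular bonded/non-bonded
    terms of the full coupled potential are configuration-independent
    constants; they cancel in any free-energy difference and are therefore
    not simulated.
    """

    epsilon: float = 0.65       # kJ/mol
    sigma: float = 0.32         # nm
    alpha_sc: float = 0.5       # soft-core alpha (dimensionless)
    p_sc: int = 1               # soft-core lambda exponent
    charge_solute: float = 0.0  # e
    charge_solvent: float = 0.0  # e
    cutoff: float = 1.2         # nm

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise InvalidSpecError("epsilon must be >= 0")
        if not self.sigma > 0:
            raise InvalidSpecError("sigma must be > 0")
        if self.alpha_sc < 0:
            raise InvalidSpecError("alpha_sc must be >= 0")
        if not self.cutoff > 0:
            raise InvalidSpecError("cutoff must be > 0")

    def lj_energy(self, r, lambda_lj: float):
        """Soft-core LJ pair energy at coupling lambda_lj (vectorized in r).

        U_sc(r; lam) = lam * 4 eps [ (s6/(a s6 (1-lam)^p + r^6))^2
                                     - s6/(a s6 (1-lam)^p + r^6) ]

        Zero beyond the cutoff and identically zero at lam = 0.
        """
        r = np.asarray(r, dtype=float)
        if lambda_lj == 0.0:
            return np.zeros_like(r)
        s6 = self.sigma ** 6
        denom = self.alpha_sc * s6 * (1.0 - lambda_lj) ** self.p_sc + r ** 6
        x = s6 / denom
        u = lambda_lj * 4.0 * self.epsilon * (x * x - x)
        return np.where(r < self.cutoff, u, 0.0)

    def elec_energy(self, r, lambda_elec: float):
        """Linearly scaled truncated-and-shifted Coulomb pair energy."""
        r = np.asarray(r, dtype=float)
        if lambda_elec == 0.0 or self.charge_solute == 0.0 or self.charge_solvent == 0.0:
            return np.zeros_like(r)
        qq = COULOMB * self.charge_solute * self.charge_solvent
        with np.errstate(divide="ignore"):
            u = qq * (1.0 / r - 1.0 / self.cutoff)
        return lambda_elec * np.where(r < self.cutoff, u, 0.0)

    def pair_energy(self, r, state: LambdaState):
        """Total coupled solute-solvent pair energy at one lambda window."""
        return self.lj_energy(r, state.lambda_lj) + self.elec_energy(r, state.lambda_elec)


def minimum_image(dx: np.ndarray, box: float) -> np.ndarray:
    """Apply the cubic minimum-image convention to displacement vectors."""
    return dx - box * np.round(dx / box)
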
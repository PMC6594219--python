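"""Water -> organic-solvent transfer free energies and electroneutral sums.

A solvation free energy computed in solvent system k and one computed in
pure water combine, through a thermodynamic cycle, into the transfer free
energy dG(H2O->k) = dG_k - dG_H2O.  The electroneutral sum over the
hydronium/chloride pair proxies the solvent's effect on acid dissociation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .core import InvalidSpecError, IonsolvError
from .corrections import CorrectionSet

IONS = ("hydronium", "chloride")

STABILIZING = "stabilizing"
DESTABILIZING = "destabilizing"


@dataclass(frozen=True)
class SolvationRecord:
    """Per-ion, per-solvent-system solvation free energy with provenance."""

    ion: str
    solvent: str
    delta_g: float                     # corrected solvation free energy, kJ/mol
    wt_pct_organic: float = 0.0
    trials: Optional[tuple[float, float]] = None
    uncertainty: float = 0.0
    corrections: Optional[CorrectionSet] = None
    raw_delta_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ion not in IONS:
            raise InvalidSpecError(f"ion must be one of {IONS}, got {self.ion!r}")
        if not 0.0 <= self.wt_pct_organic <= 100.0:
            raise InvalidSpecError("organic wt% must lie in [0, 100]")
        if self.uncertainty < 0:
            raise InvalidSpecError("uncertainty must be >= 0")


@dataclass(frozen=True)
class TransferResult:
    """A transfer free energy with quadrature-combined uncertainty."""

    value: float        # kJ/mol
    uncertainty: float  # kJ/mol

    def __float__(self) -> float:
        return self.value


def transfer_free_energy(
    record_k: SolvationRecord, record_water: SolvationRecord
) -> TransferResult:
    """Free energy of moving an ion from pure water into solvent system k.

    dG(H2O->k) = dG_k - dG_H2O; the two trial-based uncertainties combine
    in quadrature (the trials are independent).
    """
    if record_k.ion != record_water.ion:
        raise InvalidSpecError(
            f"ion mismatch: {record_k.ion!r} vs {record_water.ion!r}"
        )
    value = record_k.delta_g - record_water.delta_g
    unc = math.hypot(record_k.uncertainty, record_water.uncertainty)
    return TransferResult(value=value, uncertainty=unc)


def electroneutral_sum(g1: float, g2: float) -> float:
    """Exact sum of two free energies (hydronium + chloride pair)."""
    return g1 + g2


def classify_solvent(hydronium_transfer: float) -> str:
    """Classify a solvent by the sign of the hydronium transfer free energy.

    Negative transfer (ion lower in free energy than in water) is
    stabilizing; positive is destabilizing.  Zero — the water baseline —
    is destabilizing by convention (no driving force).
    """
    if not math.isfinite(hydronium_transfer):
        raise InvalidSpecError("transfer free energy must be finite")
    return STABILIZING if hydronium_transfer < 0 else DESTABILIZING


@dataclass
class TransferTable:
    """Per-solvent transfer free energies, their sum, and classification."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: list[SolvationRecord]) -> "TransferTable":
        """Assemble the transfer table from solvation records.

        Requires hydronium and chloride records in pure water; every other
        (solvent, wt%) system needs both ions as well.  The water row is
        identically zero and the sum column is the exact sum of the two ion
        columns.
        """
        by_key: dict[tuple[str, float, str], SolvationRecord] = {}
        for r in records:
            by_key[(r.solvent, r.wt_pct_organic, r.ion)] = r
        water = {}
        for ion in IONS:
            key = [k for k in by_key if k[2] == ion and k[1] == 0.0]
            water_keys = [k for k in key if k[0].lower() == "water"]
            if not water_keys:
                raise InvalidSpecError(f"missing pure-water record for {ion}")
            water[ion] = by_key[water_keys[0]]
        systems = sorted({(s, w) for (s, w, _) in by_key})
        rows = []
        for solvent, wt in systems:
            try:
                rec_h = by_key[(solvent, wt, "hydronium")]
                rec_cl = by_key[(solvent, wt, "chloride")]
            except KeyError as exc:
                raise InvalidSpecError(
                    f"system ({solvent}, {wt} wt%) is missing an ion record"
                ) from exc
            t_h = transfer_free_energy(rec_h, water["hydronium"])
            t_cl = transfer_free_energy(rec_cl, water["chloride"])
            if solvent.lower() == "water":
                t_h = TransferResult(0.0, 0.0)
                t_cl = TransferResult(0.0, 0.0)
            total = electroneutral_sum(t_h.value, t_cl.value)
            rows.append(
                {
                    "solvent": solvent,
                    "wt_pct_organic": wt,
                    "dG_transfer_hydronium_kJ_per_mol": t_h.value,
                    "dG_transfer_hydronium_unc_kJ_per_mol": t_h.uncertainty,
                    "dG_transfer_chloride_kJ_per_mol": t_cl.value,
                    "dG_transfer_chloride_unc_kJ_per_mol": t_cl.uncertainty,
                    "sum_dG_kJ_per_mol": total,
                    "sum_dG_unc_kJ_per_mol": math.hypot(
                        t_h.uncertainty, t_cl.uncertainty
                    ),
                    "classification": classify_solvent(t_h.value),
                }
            )
        return cls(pd.DataFrame(rows))
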
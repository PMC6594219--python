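"""Solvent-structure descriptors: RDFs, domain cutoffs, and Gamma.

The preferential exclusion coefficient Gamma measures the excess of
cosolvent in the local solvent domain around a solute relative to the
bulk-composition expectation,

    Gamma = -< n_C^L - n_W^L * (n_C^B / n_W^B) >,

averaged over frames.  Positive Gamma means the local domain is depleted
of cosolvent (water-enriched).  The local/bulk boundary is the radius at
which the solute-water RDF settles back to unity after its main peak.
Gamma' multiplies Gamma by the sign of the hydronium water -> pure-organic
transfer free energy, so that it tracks enrichment of whichever solvent
stabilizes the acid catalyst.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import GeometryError, InvalidSpecError, IonsolvError, minimum_image
from .synthetic import COSOLVENT, WATER, TrajectoryFrames


class NoCutoffError(IonsolvError):
    """Raised when the RDF never settles into the unity band."""


class UndefinedGammaError(IonsolvError):
    """Raised when every frame has an empty bulk water domain."""


class UndefinedSignError(IonsolvError):
    """Raised when the transfer free energy used for the sign is zero."""


@dataclass
class RDFResult:
    """Radial distribution function g(r) on uniform bins."""

    r: np.ndarray              # bin centers, nm
    g: np.ndarray              # dimensionless
    bin_width: float
    n_frames: int
    center_label: str = "solute"
    target_label: str = "water"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.bin_width <= 0:
            raise InvalidSpecError("bin width must be positive")
        if (np.diff(self.r) <= 0).any():
            raise InvalidSpecError("bin centers must strictly increase")
        if (self.g < 0).any():
            raise InvalidSpecError("g(r) must be non-negative")


@dataclass
class DomainCounts:
    """Per-frame local/bulk molecule counts at a fixed cutoff."""

    n_c_local: np.ndarray
    n_w_local: np.ndarray
    n_c_bulk: np.ndarray
    n_w_bulk: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        for name in ("n_c_local", "n_w_local", "n_c_bulk", "n_w_bulk"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))


@dataclass
class GammaResult:
    """Preferential exclusion coefficient with block-averaged uncertainty."""

    gamma: float
    cutoff: float
    n_frames_used: int
    n_frames_skipped: int
    uncertainty: float
    gamma_prime: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "gamma_prime": self.gamma_prime,
            "cutoff_nm": self.cutoff,
            "frames_used": self.n_frames_used,
            "frames_skipped": self.n_frames_skipped,
            "block_standard_error": self.uncertainty,
        }


def _species_positions(frame, species: int) -> np.ndarray:
    return frame.solvent_pos[frame.solvent_species == species]


def compute_rdf(
    frames: TrajectoryFrames,
    target: str = "water",
    bin_width: float = 0.02,
    r_max: Optional[float] = None,
) -> RDFResult:
    """RDF between the solute center of mass and a solvent species.

    Minimum-image distances in a cubic box; normalization uses each
    frame's own bulk number density (n_target / V), so fluctuating boxes
    are handled per frame.  Default bin width 0.02 nm.
    """
    if len(frames) < 1:
        raise InvalidSpecError("need at least one frame")
    code = {"water": WATER, "cosolvent": COSOLVENT}[target]
    min_box = min(f.box for f in frames)
    if r_max is None:
        r_max = min_box / 2.0
    if r_max > min_box / 2.0 + 1e-12:
        raise GeometryError(
            f"r_max {r_max} nm exceeds half the smallest box edge {min_box/2:.3f} nm"
        )
    n_bins = int(np.floor(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g_acc = np.zeros(n_bins)
    for f in frames:
        pos = _species_positions(f, code)
        counts = np.zeros(n_bins)
        if pos.shape[0]:
            d = minimum_image(pos - f.solute_com[None, :], f.box)
            r = np.sqrt((d * d).sum(axis=1))
            counts, _ = np.histogram(r, bins=edges)
        density = pos.shape[0] / f.box**3
        if density > 0:
            g_acc += counts / (shell_vol * density)
    g = g_acc / len(frames)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(
        r=centers, g=g, bin_width=bin_width, n_frames=len(frames),
        target_label=target,
    )


def find_domain_cutoff(
    rdf: RDFResult, tol: float = 0.05, smooth_window: int = 5
) -> float:
    """Radius where the smoothed RDF first settles back to unity.

    The RDF is smoothed with a centered moving average, then scanned past
    its global maximum for the first entry into [1 - tol, 1 + tol] that
    persists for at least 5 consecutive bins.
    """
    g = uniform_filter1d(rdf.g, size=max(1, smooth_window), mode="nearest")
    peak = int(np.argmax(g))
    if g[peak] <= 1.0 + tol:
        raise NoCutoffError(
            f"no RDF peak above {1 + tol:.3f} (max smoothed g = {g[peak]:.3f})"
        )
    in_band = np.abs(g - 1.0) <= tol
    run = 0
    for i in range(peak + 1, len(g)):
        run = run + 1 if in_band[i] else 0
        if run >= 5:
            return float(rdf.r[i - 4])
    raise NoCutoffError(
        "smoothed RDF never stays within the unity band for 5 consecutive bins"
    )


def count_domains(frames: TrajectoryFrames, cutoff: float) -> DomainCounts:
    """Assign every solvent molecule to the local or bulk domain per frame.

    A molecule is local iff its center of mass lies within ``cutoff`` of
    the solute center of mass under the minimum-image convention.
    """
    ncl, nwl, ncb, nwb = [], [], [], []
    for f in frames:
        if cutoff >= f.box / 2.0:
            raise GeometryError(
                f"cutoff {cutoff} nm must be < half the box edge ({f.box/2:.3f} nm)"
            )
        d = minimum_image(f.solvent_pos - f.solute_com[None, :], f.box)
        r = np.sqrt((d * d).sum(axis=1))
        local = r < cutoff
        water = f.solvent_species == WATER
        nwl.append(int((local & water).sum()))
        ncl.append(int((local & ~water).sum()))
        nwb.append(int((~local & water).sum()))
        ncb.append(int((~local & ~water).sum()))
    return DomainCounts(
        n_c_local=np.array(ncl), n_w_local=np.array(nwl),
        n_c_bulk=np.array(ncb), n_w_bulk=np.array(nwb), cutoff=cutoff,
    )


def gamma(counts: DomainCounts, n_blocks: int = 10) -> GammaResult:
    """Frame-averaged preferential exclusion coefficient.

    Frames with an empty bulk water domain are skipped (the ratio is
    undefined there) and reported.  The uncertainty is the standard error
    over ``n_blocks`` contiguous blocks of the per-frame values.
    """
    ok = counts.n_w_bulk > 0
    n_skip = int((~ok).sum())
    if not ok.any():
        raise UndefinedGammaError("all frames have an empty bulk water domain")
    per_frame = -(
        counts.n_c_local[ok]
        - counts.n_w_local[ok] * (counts.n_c_bulk[ok] / counts.n_w_bulk[ok])
    )
    value = float(per_frame.mean())
    n_used = int(ok.sum())
    nb = min(n_blocks, n_used)
    if nb >= 2:
        blocks = np.array_split(per_frame, nb)
        means = np.array([b.mean() for b in blocks])
        se = float(means.std(ddof=1) / np.sqrt(nb))
    else:
        se = float("nan")
    return GammaResult(
        gamma=value, cutoff=counts.cutoff, n_frames_used=n_used,
        n_frames_skipped=n_skip, uncertainty=se,
    )


def gamma_prime(gamma_value: float, hydronium_transfer_pure_org: float) -> float:
    """Sign-corrected exclusion coefficient Gamma' = Gamma * sign(dG).

    The sign is that of the hydronium water -> pure-organic transfer free
    energy, so Gamma' measures enrichment of whichever solvent species
    preferentially stabilizes the catalyst.
    """
    if hydronium_transfer_pure_org == 0:
        raise UndefinedSignError("transfer free energy of exactly zero has no sign")
    sign = 1.0 if hydronium_transfer_pure_org > 0 else -1.0
    return gamma_value * sign


def gamma_with_sign(result: GammaResult, hydronium_transfer_pure_org: float) -> GammaResult:
    """Return a copy of ``result`` with gamma_prime filled in."""
    return GammaResult(
        gamma=result.gamma,
        cutoff=result.cutoff,
        n_frames_used=result.n_frames_used,
        n_frames_skipped=result.n_frames_skipped,
        uncertainty=result.uncertainty,
        gamma_prime=gamma_prime(result.gamma, hydronium_transfer_pure_org),
    )
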
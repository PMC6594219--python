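"""Synthetic-data generators with analytically known ground truth.

Every input the pipeline consumes can be generated here:

* harmonic alchemical ensembles — exact Gaussian sampling with a
  closed-form reduced free energy, the primary oracle for the estimators;
* a Metropolis Monte Carlo Lennard-Jones fluid sampled over a soft-core
  coupling schedule — a desk-scale stand-in for the alchemical MD windows;
* mixture trajectories with a prescribed radial water-enrichment profile
  around a fixed solute — ground truth for the preferential-exclusion
  coefficient;
* kinetic datasets drawn from the standardized two-descriptor linear
  model plus Gaussian noise — ground truth for the correlative fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    InvalidSpecError,
    IonsolvError,
    GeometryError,
    LambdaSchedule,
    LambdaState,
    SoftCorePotentialSpec,
    ThermoState,
    minimum_image,
)
from .estimators import ReducedEnergyMatrix

logger = logging.getLogger("ionsolv.synthetic")

WATER = 0
COSOLVENT = 1
SPECIES_NAMES = {WATER: "water", COSOLVENT: "cosolvent"}


class InvalidProfileError(IonsolvError):
    """Raised when an enrichment profile cannot be realized with the counts."""


class DegenerateDesignError(IonsolvError):
    """Raised when a regression design has a zero-variance descriptor."""


# ---------------------------------------------------------------------------
# harmonic alchemical ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicAlchemySpec:
    """A ladder of 1-D harmonic states with exact relative free energies.

    State i has reduced potential u_i(x) = beta k_i (x - x0_i)^2 / 2, so the
    reduced free energy relative to state 0 is f_i = (1/2) ln(k_i/k_0)
    (the beta and x0 dependence cancels in the Gaussian normalization).
    """

    k: tuple[float, ...]                 # spring constants, kJ/(mol nm^2)
    x0: Optional[tuple[float, ...]] = None  # centers, nm (default all 0)
    n_samples: int | tuple[int, ...] = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(ki <= 0 for ki in self.k):
            raise InvalidSpecError("spring constants must be positive")
        if self.x0 is not None and len(self.x0) != len(self.k):
            raise InvalidSpecError("x0 length must match k")
        n = self.per_state_samples
        if any(ni < 1 for ni in n):
            raise InvalidSpecError("need at least one sample per state")

    @property
    def centers(self) -> tuple[float, ...]:
        return self.x0 if self.x0 is not None else (0.0,) * len(self.k)

    @property
    def per_state_samples(self) -> tuple[int, ...]:
        if isinstance(self.n_samples, int):
            return (self.n_samples,) * len(self.k)
        return tuple(self.n_samples)

    @property
    def analytic_f(self) -> np.ndarray:
        k = np.asarray(self.k, dtype=float)
        return 0.5 * np.log(k / k[0])


def gen_harmonic_alchemy(
    spec: HarmonicAlchemySpec, thermo: ThermoState
) -> tuple[ReducedEnergyMatrix, np.ndarray]:
    """Sample the harmonic ladder exactly and build the reduced-energy matrix.

    Returns the samples-by-states matrix u[n, k] = beta k_k (x_n - x0_k)^2/2
    and the analytic reduced free-energy vector f_i = (1/2) ln(k_i/k_0).
    """
    rng = np.random.default_rng(spec.seed)
    beta = thermo.beta
    k = np.asarray(spec.k, dtype=float)
    x0 = np.asarray(spec.centers, dtype=float)
    n = spec.per_state_samples
    xs = []
    for i in range(len(k)):
        sd = 1.0 / np.sqrt(beta * k[i])
        xs.append(rng.normal(x0[i], sd, size=n[i]))
    x = np.concatenate(xs)
    u = 0.5 * beta * k[None, :] * (x[:, None] - x0[None, :]) ** 2
    labels = [f"k{ki:g}" for ki in spec.k]
    return ReducedEnergyMatrix(u, np.array(n), labels), spec.analytic_f


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo LJ fluid over a coupling schedule
# ---------------------------------------------------------------------------

def _pair_distances(pos: np.ndarray, ref: np.ndarray, box: float) -> np.ndarray:
    d = minimum_image(pos - ref[None, :], box)
    return np.sqrt((d * d).sum(axis=1))


def _plain_lj(r: np.ndarray, eps: float, sig: float, cutoff: float) -> np.ndarray:
    x6 = (sig / r) ** 6
    return np.where(r < cutoff, 4.0 * eps * (x6 * x6 - x6), 0.0)


def gen_lj_alchemy(
    spec: SoftCorePotentialSpec,
    schedule: LambdaSchedule,
    n_solvent: int,
    n_steps: int,
    thermo: ThermoState,
    seed: int,
    box_edge: float = 2.6,
    equilibration_fraction: float = 0.2,
    sample_every: int = 10,
) -> ReducedEnergyMatrix:
    """Sample each coupling window with Metropolis MC and cross-evaluate.

    A point solute sits fixed at the box center; ``n_solvent`` LJ particles
    move by single-particle displacements accepted with the full coupled
    potential at the window's lambda (solvent-solvent plain LJ plus
    solute-solvent soft-core LJ and scaled Coulomb).  After discarding the
    equilibration fraction, every retained configuration's solute-solvent
    energy is re-evaluated at every window of the schedule, producing the
    reduced-energy matrix the multistate estimators need.
    """
    if n_solvent > 100:
        raise InvalidSpecError("desk-scale sampler supports at most 100 particles")
    if n_solvent < 1 or n_steps < 10:
        raise InvalidSpecError("need n_solvent >= 1 and n_steps >= 10")
    if box_edge <= 0:
        raise GeometryError("box edge must be positive (cubic box only)")
    rng = np.random.default_rng(seed)
    beta = thermo.beta
    states = list(schedule)
    center = np.full(3, box_edge / 2.0)

    def solute_energy(r: np.ndarray, lam: LambdaState) -> float:
        return float(spec.pair_energy(r, lam).sum())

    def solvent_particle_energy(pos: np.ndarray, i: int, xi: np.ndarray) -> float:
        d = minimum_image(np.delete(pos, i, axis=0) - xi[None, :], box_edge)
        r = np.sqrt((d * d).sum(axis=1))
        r = np.maximum(r, 1e-6)
        return float(_plain_lj(r, spec.epsilon, spec.sigma, spec.cutoff).sum())

    n_equil = int(equilibration_fraction * n_steps)
    blocks = []
    for window in states:
        pos = rng.uniform(0.0, box_edge, size=(n_solvent, 3))
        step = 0.25 * spec.sigma
        accepted = 0
        attempted = 0
        samples = []
        for t in range(n_steps):
            i = int(rng.integers(n_solvent))
            old = pos[i].copy()
            r_old_sol = float(np.linalg.norm(minimum_image(old - center, box_edge)))
            e_old = solvent_particle_energy(pos, i, old) + solute_energy(
                np.array([r_old_sol]), window
            )
            new = (old + rng.uniform(-step, step, size=3)) % box_edge
            r_new_sol = float(np.linalg.norm(minimum_image(new - center, box_edge)))
            e_new = solvent_particle_energy(pos, i, new) + solute_energy(
                np.array([r_new_sol]), window
            )
            attempted += 1
            if e_new <= e_old or rng.random() < np.exp(-beta * (e_new - e_old)):
                pos[i] = new
                accepted += 1
            if t < n_equil:
                # tune the step size toward ~40% acceptance during burn-in
                if attempted % 200 == 0:
                    rate = accepted / attempted
                    step *= 1.1 if rate > 0.45 else (0.9 if rate < 0.35 else 1.0)
                    step = min(step, box_edge / 4)
                continue
            if (t - n_equil) % sample_every == 0:
                r_sol = _pair_distances(pos, center, box_edge)
                row = [beta * solute_energy(r_sol, s) for s in states]
                samples.append(row)
        rate = accepted / max(attempted, 1)
        if not 0.05 <= rate <= 0.95:
            logger.warning(
                "window %s acceptance rate %.3f outside [0.05, 0.95]",
                window.label, rate,
            )
        blocks.append(np.asarray(samples, dtype=float))
    n_k = np.array([b.shape[0] for b in blocks])
    u = np.vstack(blocks)
    return ReducedEnergyMatrix(u, n_k, [s.label for s in states])


# ---------------------------------------------------------------------------
# mixture trajectories with prescribed radial enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentProfile:
    """Piecewise-constant local water mole fraction x_W(r) around the solute.

    ``edges`` are shell boundaries starting at 0 (nm); shell i spans
    [edges[i], edges[i+1]) with water mole fraction ``x_w[i]``.  Beyond the
    last edge the composition is the bulk mole fraction ``x_w_bulk``.
    """

    edges: tuple[float, ...]
    x_w: tuple[float, ...]
    x_w_bulk: float

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e[0] != 0.0 or (np.diff(e) <= 0).any():
            raise InvalidSpecError("edges must start at 0 and strictly increase")
        if len(self.x_w) != len(self.edges) - 1:
            raise InvalidSpecError("need one x_w value per shell")
        for v in (*self.x_w, self.x_w_bulk):
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError("mole fractions must lie in [0,1]")

    @classmethod
    def flat(cls, x_w_bulk: float, radius: float = 1.0) -> "EnrichmentProfile":
        return cls(edges=(0.0, radius), x_w=(x_w_bulk,), x_w_bulk=x_w_bulk)

    def fraction_at(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.full(r.shape, self.x_w_bulk)
        for i in range(len(self.x_w)):
            mask = (r >= self.edges[i]) & (r < self.edges[i + 1])
            out[mask] = self.x_w[i]
        return out


@dataclass
class Frame:
    """One trajectory frame: cubic box, solute sites, solvent molecule COMs."""

    box: float
    solute_pos: np.ndarray        # (n_sites, 3), nm
    solute_masses: np.ndarray     # (n_sites,)
    solvent_pos: np.ndarray       # (n_molecules, 3) molecule centers of mass
    solvent_species: np.ndarray   # (n_molecules,) int: 0 water, 1 cosolvent

    def __post_init__(self) -> None:
        self.solute_pos = np.atleast_2d(np.asarray(self.solute_pos, dtype=float))
        self.solute_masses = np.atleast_1d(np.asarray(self.solute_masses, dtype=float))
        self.solvent_pos = np.asarray(self.solvent_pos, dtype=float).reshape(-1, 3)
        self.solvent_species = np.asarray(self.solvent_species, dtype=np.int8)

    @property
    def solute_com(self) -> np.ndarray:
        m = self.solute_masses
        return (self.solute_pos * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class TrajectoryFrames:
    """A sequence of frames sharing species conventions."""

    frames: list[Frame]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def _systematic_round(targets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomized rounding with exact totals and exact expectations.

    Requires the fractional parts to sum to an integer; each region is
    rounded up with probability equal to its fractional part (systematic
    sampling over a random region order), so E[result] = targets and
    sum(result) = sum(targets) in every draw.
    """
    base = np.floor(targets).astype(int)
    frac = targets - base
    d = int(round(frac.sum()))
    if d == 0:
        return base
    order = rng.permutation(len(targets))
    c = np.cumsum(frac[order])
    points = rng.random() + np.arange(d)
    idx = np.searchsorted(c, points, side="right")
    idx = np.clip(idx, 0, len(targets) - 1)
    base[order[idx]] += 1
    return base


def _region_volumes(profile: EnrichmentProfile, box: float) -> tuple[np.ndarray, float]:
    edges = np.asarray(profile.edges)
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    outer = box**3 - 4.0 / 3.0 * np.pi * edges[-1] ** 3
    if outer < 0:
        raise InvalidProfileError("profile radius exceeds the box")
    return shells, outer


def _region_targets(
    profile: EnrichmentProfile, n_water: int, n_cosolvent: int, box: float
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous per-region (shells + outer) molecule and water targets.

    Region totals follow the uniform number density; water targets follow
    the profile, rescaled by the (necessarily small) mismatch between the
    profile-implied water count and the supplied one.
    """
    shells, outer = _region_volumes(profile, box)
    vols = np.append(shells, outer)
    n_total = n_water + n_cosolvent
    density = n_total / box**3
    totals = density * vols
    x = np.append(np.asarray(profile.x_w), profile.x_w_bulk)
    water_targets = totals * x
    implied = water_targets.sum()
    # feasibility: the stated composition must be achievable within one
    # molecule per shell given the fixed totals
    if abs(implied - n_water) > len(vols):
        raise InvalidProfileError(
            f"profile implies {implied:.1f} water molecules but "
            f"{n_water} supplied; adjust counts or profile"
        )
    if n_water > 0 and implied > 0:
        water_targets = water_targets * (n_water / implied)
    elif n_water == 0:
        water_targets = np.zeros_like(water_targets)
    if (water_targets - totals > 1e-9).any():
        raise InvalidProfileError("rescaled water target exceeds a region total")
    return totals, water_targets


def consistent_counts(
    profile: EnrichmentProfile, box: float, n_total: int
) -> tuple[int, int]:
    """Water/cosolvent totals that realize the profile at uniform density.

    Integrates the profile's water mole fraction over the box at the
    uniform number density n_total / V and rounds, so the generator's
    feasibility precondition is satisfied by construction.
    """
    shells, outer = _region_volumes(profile, box)
    vols = np.append(shells, outer)
    x = np.append(np.asarray(profile.x_w), profile.x_w_bulk)
    density = n_total / box**3
    n_water = int(round(float((density * vols * x).sum())))
    return n_water, n_total - n_water


def gen_mixture_trajectory(
    profile: EnrichmentProfile,
    n_water: int,
    n_cosolvent: int,
    box: float,
    n_frames: int,
    seed: int,
    solute_mass: float = 18.0,
) -> TrajectoryFrames:
    """Independent frames realizing the prescribed enrichment profile.

    The solute is a single site fixed at the box center.  Each frame
    allocates the fixed molecule totals across radial regions by
    randomized systematic rounding against the uniform number density
    (totals are conserved exactly; per-region expectations match the
    continuous targets exactly), draws positions uniformly within each
    region, and randomizes which molecules within a region are water.
    Frames are i.i.d. and the expected local water mole fraction matches
    the profile within one molecule per shell.
    """
    if n_water < 0 or n_cosolvent < 0 or n_frames < 1:
        raise InvalidSpecError("counts must be non-negative and n_frames >= 1")
    t_targets, w_targets = _region_targets(profile, n_water, n_cosolvent, box)
    edges = np.asarray(profile.edges)
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    frames = []
    for _ in range(n_frames):
        totals = _systematic_round(t_targets, rng)
        waters = _systematic_round(w_targets, rng)
        # repair the rare draw where a region gets more water than slots
        excess_regions = np.flatnonzero(waters > totals)
        for s in excess_regions:
            excess = int(waters[s] - totals[s])
            waters[s] = totals[s]
            room = np.flatnonzero(waters < totals)
            for r in rng.permutation(room)[:excess]:
                waters[r] += 1
        pos_list, spec_list = [], []
        for s in range(len(totals)):
            n_s = int(totals[s])
            if n_s == 0:
                continue
            if s < len(edges) - 1:
                r3 = rng.uniform(edges[s] ** 3, edges[s + 1] ** 3, size=n_s)
                r = r3 ** (1.0 / 3.0)
                v = rng.normal(size=(n_s, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                pts = center + r[:, None] * v
            else:
                # outer region: uniform in the box, rejecting the sphere
                pts = np.empty((0, 3))
                while pts.shape[0] < n_s:
                    cand = rng.uniform(0.0, box, size=(2 * n_s + 8, 3))
                    d = np.linalg.norm(cand - center, axis=1)
                    pts = np.vstack([pts, cand[d >= edges[-1]]])
                pts = pts[:n_s]
            species = np.full(n_s, COSOLVENT, dtype=np.int8)
            species[: int(waters[s])] = WATER
            rng.shuffle(species)
            pos_list.append(pts % box)
            spec_list.append(species)
        frames.append(
            Frame(
                box=box,
                solute_pos=center.copy(),
                solute_masses=np.array([solute_mass]),
                solvent_pos=np.vstack(pos_list),
                solvent_species=np.concatenate(spec_list),
            )
        )
    return TrajectoryFrames(frames)


def expected_gamma(
    profile: EnrichmentProfile,
    n_water: int,
    n_cosolvent: int,
    box: float,
    cutoff: float,
) -> float:
    """Numeric-integration expectation of the exclusion coefficient.

    Uses the same deterministic region allocation as the generator and
    uniform-within-region position statistics; expected counts inside the
    cutoff follow from region/sphere overlap volumes.  The frame-average
    ratio is approximated by the ratio of expectations, accurate at the
    molecule counts the generator targets.
    """
    totals, waters = _region_targets(profile, n_water, n_cosolvent, box)
    cosolv = totals - waters
    edges = np.asarray(profile.edges)
    shells, outer_v = _region_volumes(profile, box)
    vols = np.append(shells, outer_v)
    # overlap volume of each region with the cutoff sphere
    overlaps = np.empty(len(vols))
    for s in range(len(shells)):
        lo, hi = edges[s], edges[s + 1]
        a, b = min(lo, cutoff), min(hi, cutoff)
        overlaps[s] = 4.0 / 3.0 * np.pi * (b**3 - a**3)
    overlaps[-1] = max(0.0, 4.0 / 3.0 * np.pi * (cutoff**3 - edges[-1] ** 3))
    frac = overlaps / vols
    e_w_local = float((waters * frac).sum())
    e_c_local = float((cosolv * frac).sum())
    e_w_bulk = n_water - e_w_local
    e_c_bulk = n_cosolvent - e_c_local
    if e_w_bulk <= 0:
        raise InvalidProfileError("expected bulk water count is zero")
    return -(e_c_local - e_w_local * (e_c_bulk / e_w_bulk))


# ---------------------------------------------------------------------------
# kinetic datasets from the correlative model
# ---------------------------------------------------------------------------

def gen_kinetic_dataset(
    coefficients: tuple[float, float, float],
    design: Sequence[tuple[float, float]],
    noise_sd: float,
    seed: int,
    solvent: str = "synthetic",
):
    """Kinetic solvent parameters from the standardized two-descriptor model.

    sigma = A * z(Gamma') + B * z(dG_ratio) + C + Normal(0, noise_sd), with
    z-scores computed from the design points themselves (sample SD,
    divisor n-1) — the same convention the fitting routines use, so a
    zero-noise dataset is recovered exactly.
    """
    from .kinetics import KineticDataset, standardize

    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    if len(design) < 3:
        raise InvalidSpecError("need at least 3 design points for identifiability")
    a, b, c = coefficients
    gp = np.array([d[0] for d in design], dtype=float)
    dg = np.array([d[1] for d in design], dtype=float)
    if np.std(gp, ddof=1) == 0 or np.std(dg, ddof=1) == 0:
        raise DegenerateDesignError("a descriptor has zero variance in the design")
    z_gp, _, _ = standardize(gp)
    z_dg, _, _ = standardize(dg)
    rng = np.random.default_rng(seed)
    sigma = a * z_gp + b * z_dg + c + rng.normal(0.0, noise_sd, size=len(design))
    # back out self-consistent rate constants (k_water = 1 by convention)
    k_water = np.ones(len(design))
    k_org = np.exp(sigma)
    return KineticDataset(
        solvent=[solvent] * len(design),
        wt_pct=np.linspace(25, 90, len(design)),
        k_org=k_org,
        k_water=k_water,
        sigma=sigma,
        gamma_prime=gp,
        dg_ratio=dg,
    )
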
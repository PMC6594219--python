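"""File formats and run configuration.

Formats are plain text throughout: TSV for reduced-energy matrices, XYZ
(with a box record in the comment line and a trailing molecule-id /
species column) or GRO for trajectories, CSV for tables, JSON for
results, YAML for configuration.  Units are fixed package-wide: kJ/mol,
nm, K; reduced potentials are dimensionless and marked so in headers.

Converting MD-engine output into the TSV dialect is a one-liner per
engine: write one row per stored configuration holding beta*U re-evaluated
at every window, tagged with the window the configuration came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import ConfigError, InvalidSpecError, IonsolvError
from .estimators import FreeEnergyResult, ReducedEnergyMatrix
from .synthetic import COSOLVENT, WATER, Frame, TrajectoryFrames


class ParseError(IonsolvError):
    """A file-format error carrying the offending line number."""

    def __init__(self, path, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


HEADER_COMMENT = "# reduced potentials u = beta*U (dimensionless); first column = origin state"


def write_energy_matrix(path, matrix: ReducedEnergyMatrix) -> None:
    """Write the samples-by-states matrix as TSV (bit-exact round trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        fh.write("origin_state\t" + "\t".join(matrix.labels) + "\n")
        row_idx = 0
        for k in range(matrix.n_states):
            block = matrix.rows_from(k)
            label = matrix.labels[k]
            for row in block:
                fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
                row_idx += 1


def read_energy_matrix(path) -> ReducedEnergyMatrix:
    """Read the TSV dialect back, validating shape, labels, and finiteness."""
    path = Path(path)
    labels: Optional[list[str]] = None
    rows: list[list[float]] = []
    origins: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if labels is None:
                if parts[0] != "origin_state":
                    raise ParseError(path, lineno, "missing origin_state header")
                labels = parts[1:]
                if len(labels) < 2:
                    raise ParseError(path, lineno, "need at least 2 state columns")
                continue
            if len(parts) != len(labels) + 1:
                raise ParseError(
                    path, lineno,
                    f"expected {len(labels) + 1} fields, got {len(parts)}",
                )
            if parts[0] not in labels:
                raise ParseError(path, lineno, f"unknown origin state {parts[0]!r}")
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad number: {exc}") from None
            if not all(np.isfinite(values)):
                raise ParseError(path, lineno, "non-finite reduced energy")
            origins.append(parts[0])
            rows.append(values)
    if labels is None or not rows:
        raise ParseError(path, 0, "no data rows")
    # rows must be grouped by origin state in label order
    order = {lab: i for i, lab in enumerate(labels)}
    codes = [order[o] for o in origins]
    if any(b < a for a, b in zip(codes, codes[1:])):
        idx = np.argsort(codes, kind="stable")
        rows = [rows[i] for i in idx]
        codes = sorted(codes)
    n_k = np.bincount(codes, minlength=len(labels))
    return ReducedEnergyMatrix(np.asarray(rows, dtype=float), n_k, list(labels))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

SOLUTE = "solute"
DEFAULT_SPECIES_MAP = {"SOL": "water", "COS": "cosolvent", "ION": SOLUTE}


def _role_of(name: str, species_map: dict) -> str:
    if name not in species_map:
        raise ParseError("<species_map>", 0, f"unmapped residue name {name!r}")
    role = species_map[name]
    if role not in ("water", "cosolvent", SOLUTE):
        raise ConfigError(f"species role must be water/cosolvent/solute, got {role!r}")
    return role


def write_xyz(path, frames: TrajectoryFrames, species_map: Optional[dict] = None) -> None:
    """Write the XYZ dialect: box in the comment line, molecule-id column."""
    species_map = species_map or DEFAULT_SPECIES_MAP
    inverse = {v: k for k, v in species_map.items()}
    path = Path(path)
    with path.open("w") as fh:
        for f in frames:
            n_atoms = f.solute_pos.shape[0] + f.solvent_pos.shape[0]
            fh.write(f"{n_atoms}\n")
            fh.write(f"box {f.box:.6f} {f.box:.6f} {f.box:.6f}\n")
            mol = 0
            for site in f.solute_pos:
                fh.write(
                    f"{inverse[SOLUTE]} {site[0]:.6f} {site[1]:.6f} {site[2]:.6f} {mol}\n"
                )
            mol += 1
            for pos, sp in zip(f.solvent_pos, f.solvent_species):
                name = inverse["water"] if sp == WATER else inverse["cosolvent"]
                fh.write(f"{name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} {mol}\n")
                mol += 1


def read_xyz(path, species_map: Optional[dict] = None) -> TrajectoryFrames:
    """Read the XYZ dialect (coordinates in nm, wrapped into the box)."""
    species_map = species_map or DEFAULT_SPECIES_MAP
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(path, i + 1, "expected atom count") from None
        if i + 1 >= len(lines):
            raise ParseError(path, i + 2, "missing comment/box line")
        comment = lines[i + 1].split()
        if len(comment) < 4 or comment[0] != "box":
            raise ParseError(path, i + 2, "missing box record ('box Lx Ly Lz')")
        lx, ly, lz = (float(v) for v in comment[1:4])
        if not (lx == ly == lz):
            raise ParseError(path, i + 2, "only cubic boxes are supported")
        solute_pos, solvent_pos, species = [], [], []
        for j in range(n_atoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ParseError(path, lineno + 1, "truncated frame")
            parts = lines[lineno].split()
            if len(parts) < 5:
                raise ParseError(path, lineno + 1, "expected: name x y z molid")
            role = _role_of(parts[0], species_map)
            xyz = np.array([float(v) for v in parts[1:4]]) % lx
            if role == SOLUTE:
                solute_pos.append(xyz)
            else:
                solvent_pos.append(xyz)
                species.append(WATER if role == "water" else COSOLVENT)
        if not solute_pos:
            raise ParseError(path, i + 1, "frame has no solute site")
        frames.append(
            Frame(
                box=lx,
                solute_pos=np.array(solute_pos),
                solute_masses=np.ones(len(solute_pos)),
                solvent_pos=np.array(solvent_pos).reshape(-1, 3),
                solvent_species=np.array(species, dtype=np.int8),
            )
        )
        i += 2 + n_atoms
    if not frames:
        raise ParseError(path, 1, "no frames")
    return TrajectoryFrames(frames)


def write_gro(path, frames: TrajectoryFrames, species_map: Optional[dict] = None) -> None:
    """Write frames in GRO format (one atom per molecule, nm)."""
    species_map = species_map or DEFAULT_SPECIES_MAP
    inverse = {v: k for k, v in species_map.items()}
    path = Path(path)
    with path.open("w") as fh:
        for fi, f in enumerate(frames):
            n_atoms = f.solute_pos.shape[0] + f.solvent_pos.shape[0]
            fh.write(f"ionsolv frame {fi}\n{n_atoms}\n")
            atom = 1
            res = 1
            for site in f.solute_pos:
                fh.write(
                    f"{res:5d}{inverse[SOLUTE]:<5s}{'X':>5s}{atom:5d}"
                    f"{site[0]:8.3f}{site[1]:8.3f}{site[2]:8.3f}\n"
                )
                atom += 1
            res += 1
            for pos, sp in zip(f.solvent_pos, f.solvent_species):
                name = inverse["water"] if sp == WATER else inverse["cosolvent"]
                fh.write(
                    f"{res:5d}{name:<5s}{'X':>5s}{atom % 100000:5d}"
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}\n"
                )
                atom += 1
                res += 1
            fh.write(f"{f.box:10.5f}{f.box:10.5f}{f.box:10.5f}\n")


def read_gro(path, species_map: Optional[dict] = None) -> TrajectoryFrames:
    """Read GRO frames; molecules grouped by contiguous residue index.

    Multi-atom molecules are reduced to equal-mass centers of geometry
    (synthetic trajectories are single-site; for real data supply
    per-site masses upstream).
    """
    species_map = species_map or DEFAULT_SPECIES_MAP
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ParseError(path, i + 2, "missing atom count")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise ParseError(path, i + 2, "bad atom count") from None
        box_line = i + 2 + n_atoms
        if box_line >= len(lines):
            raise ParseError(path, box_line + 1, "missing box line")
        box_fields = lines[box_line].split()
        if len(box_fields) < 3:
            raise ParseError(path, box_line + 1, "box line needs 3 edge lengths")
        lx, ly, lz = (float(v) for v in box_fields[:3])
        if not (abs(lx - ly) < 1e-9 and abs(lx - lz) < 1e-9):
            raise ParseError(path, box_line + 1, "only cubic boxes are supported")
        mol_atoms: dict[tuple[int, str], list[np.ndarray]] = {}
        order: list[tuple[int, str]] = []
        for j in range(n_atoms):
            ln = lines[i + 2 + j]
            lineno = i + 3 + j
            try:
                resid = int(ln[0:5])
                resname = ln[5:10].strip()
                x, y, z = float(ln[20:28]), float(ln[28:36]), float(ln[36:44])
            except (ValueError, IndexError):
                raise ParseError(path, lineno, "malformed GRO atom line") from None
            key = (resid, resname)
            if key not in mol_atoms:
                mol_atoms[key] = []
                order.append(key)
            mol_atoms[key].append(np.array([x, y, z]) % lx)
        solute_pos, solvent_pos, species = [], [], []
        for key in order:
            resname = key[1]
            role = _role_of(resname, species_map)
            com = np.mean(mol_atoms[key], axis=0)
            if role == SOLUTE:
                solute_pos.extend(mol_atoms[key])
            else:
                solvent_pos.append(com)
                species.append(WATER if role == "water" else COSOLVENT)
        if not solute_pos:
            raise ParseError(path, i + 1, "frame has no solute residue")
        frames.append(
            Frame(
                box=lx,
                solute_pos=np.array(solute_pos),
                solute_masses=np.ones(len(solute_pos)),
                solvent_pos=np.array(solvent_pos).reshape(-1, 3),
                solvent_species=np.array(species, dtype=np.int8),
            )
        )
        i = box_line + 1
    if not frames:
        raise ParseError(path, 1, "no frames")
    return TrajectoryFrames(frames)


def read_trajectory(path, species_map: Optional[dict] = None) -> TrajectoryFrames:
    """Dispatch on extension: .xyz or .gro."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path, species_map)
    if suffix == ".gro":
        return read_gro(path, species_map)
    raise ConfigError(f"unsupported trajectory format {suffix!r}")


# ---------------------------------------------------------------------------
# results and tables
# ---------------------------------------------------------------------------

def write_result_json(path, result) -> None:
    obj = result.to_dict() if hasattr(result, "to_dict") else result
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_window_table(path, result: FreeEnergyResult) -> None:
    """Human-readable per-window reduced free energies as CSV."""
    df = pd.DataFrame(
        {
            "state": result.labels or list(range(len(result.f))),
            "f_reduced": result.f,
        }
    )
    df.to_csv(path, index=False)


def read_kinetic_csv(path, gamma_prime=None, dg_ratio=None):
    """Kinetic table CSV: solvent, wt_pct, and either sigma or k_org/k_water.

    Descriptor columns (gamma_prime, dg_ratio) may live in the file or be
    supplied as arrays.
    """
    from .kinetics import KineticDataset, sigma as sigma_fn

    df = pd.read_csv(path)
    required = {"solvent", "wt_pct"}
    if not required <= set(df.columns):
        raise ParseError(path, 1, f"missing required columns {required - set(df.columns)}")
    if "sigma" in df.columns:
        sig = df["sigma"].to_numpy(dtype=float)
        k_org = k_water = None
    elif {"k_org", "k_water"} <= set(df.columns):
        k_org = df["k_org"].to_numpy(dtype=float)
        k_water = df["k_water"].to_numpy(dtype=float)
        sig = np.array([sigma_fn(o, w) for o, w in zip(k_org, k_water)])
    else:
        raise ParseError(path, 1, "need either a sigma column or k_org + k_water")
    gp = df["gamma_prime"].to_numpy(dtype=float) if "gamma_prime" in df.columns \
        else np.asarray(gamma_prime, dtype=float)
    dg = df["dg_ratio"].to_numpy(dtype=float) if "dg_ratio" in df.columns \
        else np.asarray(dg_ratio, dtype=float)
    return KineticDataset(
        solvent=list(df["solvent"]), wt_pct=df["wt_pct"].to_numpy(dtype=float),
        sigma=sig, gamma_prime=gp, dg_ratio=dg, k_org=k_org, k_water=k_water,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "thermo": {"temperature"},
    "schedule": {"lambda_lj", "lambda_elec"},
    "corrections": {"surface_potentials", "dielectric", "box_edge",
                    "gas_pressure", "solution_conc"},
    "species_map": None,  # free-form residue-name -> role mapping
    "descriptors": {"bin_width", "tol", "smooth_window", "cutoff_override",
                    "r_max"},
    "model": {"kind"},
    "seed": None,
    "outdir": None,
}


@dataclass
class RunConfig:
    """Resolved run configuration; unknown keys are rejected on load."""

    temperature: float = 300.0
    lambda_lj: Optional[list[float]] = None
    lambda_elec: Optional[list[float]] = None
    surface_potentials: dict[str, float] = field(default_factory=dict)
    dielectric: float = 78.5
    box_edge: float = 6.0
    gas_pressure: float = 1.0
    solution_conc: float = 1.0
    species_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SPECIES_MAP))
    bin_width: float = 0.02
    tol: float = 0.05
    smooth_window: int = 5
    cutoff_override: Optional[float] = None
    r_max: Optional[float] = None
    model_kind: str = "multilinear"
    seed: int = 0
    outdir: str = "ionsolv_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_KNOWN_SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls()
        for section, keys in _KNOWN_SECTIONS.items():
            if section not in raw:
                continue
            value = raw[section]
            if section == "seed":
                cfg.seed = int(value)
            elif section == "outdir":
                cfg.outdir = str(value)
            elif section == "species_map":
                cfg.species_map = dict(value)
            else:
                extra = set(value) - keys
                if extra:
                    raise ConfigError(
                        f"unknown keys in {section!r}: {sorted(extra)}"
                    )
                for k, v in value.items():
                    attr = "model_kind" if (section, k) == ("model", "kind") else k
                    setattr(cfg, attr, v)
        return cfg

    def to_dict(self) -> dict:
        return {
            "thermo": {"temperature": self.temperature},
            "schedule": {"lambda_lj": self.lambda_lj, "lambda_elec": self.lambda_elec},
            "corrections": {
                "surface_potentials": dict(self.surface_potentials),
                "dielectric": self.dielectric,
                "box_edge": self.box_edge,
                "gas_pressure": self.gas_pressure,
                "solution_conc": self.solution_conc,
            },
            "species_map": dict(self.species_map),
            "descriptors": {
                "bin_width": self.bin_width,
                "tol": self.tol,
                "smooth_window": self.smooth_window,
                "cutoff_override": self.cutoff_override,
                "r_max": self.r_max,
            },
            "model": {"kind": self.model_kind},
            "seed": self.seed,
            "outdir": self.outdir,
        }

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
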
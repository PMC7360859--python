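"""Structures, trajectories, and region selections.

Coordinates are Å everywhere; times are ns everywhere. PDB author residue
numbering is authoritative — no renumbering scheme (IMGT/Kabat) is applied,
so CDR and domain definitions are always explicit chain + residue ranges
supplied by the user.

Two trajectory containers are supported:

* multi-model PDB (MODEL/ENDMDL blocks), portable;
* a frame-major binary container with a one-line JSON text header
  (atom count, frame count, frame interval, float32 payload), compact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "RegionSelection",
    "BACKBONE_ATOMS",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Standard atomic masses (u); fallback for elements not listed is carbon.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
}


def element_mass(element: str) -> float:
    return _ELEMENT_MASSES.get(element.upper().strip(), 12.011)


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].upper() in _ELEMENT_MASSES and not name[0].isdigit():
        # two-letter elements only when unambiguous (e.g. FE, ZN)
        if name[:2].upper() in ("FE", "ZN", "MG", "SE"):
            return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Structure:
    """A single conformation: parallel per-atom arrays plus coordinates (Å)."""

    atom_names: list[str]
    residue_numbers: np.ndarray          # author numbering, int
    chain_ids: list[str]
    elements: list[str]
    masses: np.ndarray                   # atomic mass units
    coordinates: np.ndarray              # (n_atoms, 3), Å
    residue_names: list[str] = field(default=None)  # type: ignore[assignment]
    insertion_codes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.residue_names is None:
            self.residue_names = ["ALA"] * n
        if self.insertion_codes is None:
            self.insertion_codes = [""] * n
        for arr, label in (
            (self.residue_numbers, "residue_numbers"),
            (self.chain_ids, "chain_ids"),
            (self.elements, "elements"),
            (self.masses, "masses"),
            (self.residue_names, "residue_names"),
            (self.insertion_codes, "insertion_codes"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if self.coordinates.shape != (n, 3):
            raise ValueError(f"coordinates shape {self.coordinates.shape} != ({n}, 3)")
        if not np.all(self.masses > 0):
            raise ValueError("all masses must be > 0")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class Trajectory:
    """Ordered frames over one topology, with a fixed time per saved frame (ns)."""

    topology: Structure
    frames: np.ndarray                   # (n_frames, n_atoms, 3), Å
    frame_interval: float                # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs >= 1 frame")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


_KNOWN_REGIONS = (
    "CDR3_alpha", "CDR3_beta", "V_alpha", "V_beta",
    "CDR_loops_alpha", "CDR_loops_beta", "custom",
)


@dataclass(frozen=True)
class RegionSelection:
    """A named chain + inclusive residue range, e.g. the CDR3α loop."""

    name: str
    chain_id: str
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.name not in _KNOWN_REGIONS:
            raise ValueError(f"unknown region name {self.name!r}; use one of {_KNOWN_REGIONS}")
        if self.residue_range[0] > self.residue_range[1]:
            raise ValueError("residue_range start must be <= end")


# ---------------------------------------------------------------------------
# PDB

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise ValueError(f"unparseable ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    return name, altloc, resname, chain, resnum, icode, (x, y, z), element


def read_pdb_models(path) -> list[Structure]:
    """Parse every model in a PDB file into a Structure (first altloc kept)."""
    models: list[Structure] = []
    names: list[str] = []
    resnums: list[int] = []
    chains: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    icodes: list[str] = []
    coords: list[tuple] = []
    seen_altloc: set = set()

    def flush():
        nonlocal names, resnums, chains, elements, resnames, icodes, coords, seen_altloc
        if names:
            masses = np.array([element_mass(e) for e in elements])
            models.append(Structure(
                atom_names=names, residue_numbers=np.array(resnums),
                chain_ids=chains, elements=elements, masses=masses,
                coordinates=np.array(coords), residue_names=resnames,
                insertion_codes=icodes,
            ))
        names, resnums, chains = [], [], []
        elements, resnames, icodes, coords = [], [], [], []
        seen_altloc = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                name, altloc, resname, chain, resnum, icode, xyz, element = \
                    _parse_atom_line(line, lineno)
                key = (chain, resnum, icode, name)
                if altloc and key in seen_altloc:
                    continue  # first altloc wins
                seen_altloc.add(key)
                if not element:
                    element = _infer_element(name)
                names.append(name)
                resnums.append(resnum)
                chains.append(chain)
                elements.append(element)
                resnames.append(resname)
                icodes.append(icode)
                coords.append(xyz)
            elif rec.startswith("ENDMDL"):
                flush()
    flush()
    if not models:
        raise ValueError(f"{path}: no ATOM records found")
    return models


def read_pdb(path) -> Structure:
    """Read the first (or only) model of a PDB file."""
    return read_pdb_models(path)[0]


def write_pdb(obj: Structure | Trajectory, path) -> None:
    """Write a Structure, or a Trajectory as a multi-model PDB."""
    if isinstance(obj, Trajectory):
        top, frames = obj.topology, obj.frames
    else:
        top, frames = obj, obj.coordinates[None]
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(top.n_atoms):
                name = top.atom_names[i]
                pad = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i + 1:5d} {pad:<4s} {top.residue_names[i]:<3s} "
                    f"{top.chain_ids[i]:1s}{top.residue_numbers[i]:4d}"
                    f"{(top.insertion_codes[i] or ' '):1s}   "
                    f"{frame[i, 0]:8.3f}{frame[i, 1]:8.3f}{frame[i, 2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {top.elements[i]:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Binary trajectory container

_MAGIC = "tcrmsm-traj"


def write_trajectory(traj: Trajectory, path) -> None:
    """Frame-major binary container: one JSON header line + float32 frames."""
    header = {
        "format": _MAGIC, "version": 1,
        "n_atoms": traj.topology.n_atoms, "n_frames": traj.n_frames,
        "frame_interval_ns": traj.frame_interval, "dtype": "float32",
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        fh.write(np.ascontiguousarray(traj.frames, dtype="<f4").tobytes())


def read_trajectory(path, topology: Structure,
                    frame_interval: float | None = None) -> Trajectory:
    """Read the binary container or a multi-model PDB into a Trajectory.

    ``frame_interval`` overrides the header (required for the PDB path, which
    carries no timing; default 1.0 ns there).
    """
    with open(path, "rb") as fh:
        first = fh.readline()
        if first.lstrip().startswith(b"{"):
            header = json.loads(first)
            if header.get("format") != _MAGIC:
                raise ValueError(f"{path}: unrecognised container header")
            n_atoms, n_frames = header["n_atoms"], header["n_frames"]
            if n_atoms != topology.n_atoms:
                raise ValueError(
                    f"{path}: header atom count {n_atoms} != topology {topology.n_atoms}"
                )
            payload = fh.read()
            expected = n_frames * n_atoms * 3 * 4
            if len(payload) < expected:
                bad = len(payload) // (n_atoms * 3 * 4)
                raise ValueError(f"{path}: truncated at frame {bad} of {n_frames}")
            frames = np.frombuffer(payload[:expected], dtype="<f4").astype(float)
            frames = frames.reshape(n_frames, n_atoms, 3)
            dt = frame_interval or header["frame_interval_ns"]
            return Trajectory(topology, frames, dt)
    # multi-model PDB path
    models = read_pdb_models(path)
    for k, m in enumerate(models):
        if m.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: model {k} has {m.n_atoms} atoms, topology {topology.n_atoms}"
            )
    frames = np.stack([m.coordinates for m in models])
    return Trajectory(topology, frames, frame_interval or 1.0)


# ---------------------------------------------------------------------------
# Selections

def resolve_selection(selection: RegionSelection, topology: Structure,
                      backbone_only: bool = False) -> np.ndarray:
    """Resolve a region to a sorted array of atom indices.

    Raises on a missing chain or an empty resolution — silently empty
    selections are forbidden.
    """
    chains = np.array(topology.chain_ids)
    if selection.chain_id not in chains:
        raise ValueError(
            f"chain {selection.chain_id!r} not in topology "
            f"(have {sorted(set(topology.chain_ids))})"
        )
    lo, hi = selection.residue_range
    mask = (
        (chains == selection.chain_id)
        & (topology.residue_numbers >= lo)
        & (topology.residue_numbers <= hi)
    )
    if backbone_only:
        bb = np.array([n in BACKBONE_ATOMS for n in topology.atom_names])
        mask &= bb
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"selection {selection.name} ({selection.chain_id} {lo}-{hi}) "
            "resolves to no atoms"
        )
    return np.sort(idx)
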
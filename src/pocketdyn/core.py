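"""Trajectory and structure data model with PDB/XYZ readers and writers.

Coordinates are always in Å, time in ps, energies in kJ/mol. Structures hold
an ordered atom list plus an N×3 coordinate array; trajectories stack F frames
over a shared topology. A small selector mini-language (`select_atoms`)
expresses the atom groups the downstream analyses need, e.g. the substrate
lysine Nε ("resid 36 and name NZ") or a residue's heavy atoms
("resid 1150 and heavy").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Atomic masses (Da) for the elements that occur in the toy systems and
#: fixtures. Unknown elements fall back to 12.0 with a warning.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

DEFAULT_MASS = 12.0


def element_mass(element: str) -> float:
    """Mass in Da for an element symbol; unknown symbols get 12.0 + warning."""
    try:
        return ELEMENT_MASSES[element.capitalize()]
    except KeyError:
        warnings.warn(
            f"unknown element {element!r}: using default mass {DEFAULT_MASS} Da",
            stacklevel=2,
        )
        return DEFAULT_MASS


@dataclass(frozen=True)
class Atom:
    """A single atom: identity only, no coordinates."""

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain: str = "A"
    element: str = "C"
    mass: float | None = None

    def __post_init__(self):
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.mass is None:
            object.__setattr__(self, "mass", element_mass(self.element))

    @property
    def is_heavy(self) -> bool:
        return self.element.capitalize() != "H"


@dataclass(frozen=True)
class AtomGroup:
    """Strictly increasing atom indices into a topology, with a label."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ValueError(f"atom group {self.label!r} is empty")
        if any(i < 0 for i in idx):
            raise ValueError(f"atom group {self.label!r} has negative indices")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"atom group {self.label!r} indices must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, n_atoms: int) -> None:
        if self.indices[-1] >= n_atoms:
            raise IndexError(
                f"atom group {self.label!r} index {self.indices[-1]} out of "
                f"range for topology of {n_atoms} atoms"
            )


@dataclass
class Structure:
    """Ordered atoms plus one N×3 Å coordinate frame."""

    atoms: list[Atom]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("structure coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """F frames of N×3 Å coordinates over a shared topology.

    ``frame_interval_ps`` is the time between recorded frames (the production
    protocol the package emulates recorded every 20 ps).
    """

    topology: list[Atom]
    frames: np.ndarray
    frame_interval_ps: float = 20.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty F×N×3 array")
        if self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match "
                f"{len(self.topology)} atoms"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory coordinates must be finite")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def structure(self, i: int = 0) -> Structure:
        return Structure(list(self.topology), self.frames[i].copy())

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology], dtype=float)


def structure_to_trajectory(structure: Structure, frame_interval_ps: float = 20.0) -> Trajectory:
    return Trajectory(
        list(structure.atoms), structure.coords[None, :, :], frame_interval_ps
    )


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column, MODEL/ENDMDL multi-frame)
# ---------------------------------------------------------------------------

_PDB_NAME_ELEMENTS = ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA")


def _element_from_name(name: str) -> str:
    """Fallback element inference from the atom-name convention."""
    stripped = name.strip()
    if not stripped:
        return "C"
    # standard PDB convention: a leading digit means a hydrogen like "1HB"
    if stripped[0].isdigit():
        return "H"
    return stripped[0].upper()


def read_pdb(stream) -> Trajectory:
    """Parse a (possibly multi-MODEL) PDB text stream into a Trajectory.

    One frame per MODEL block; a file without MODEL records yields a single
    frame. Elements come from columns 77–78 when present, else from the atom
    name. Alternate locations other than '' / 'A' are skipped with a warning.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    atoms: list[Atom] = []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    model_number = 0
    in_model = False
    first_frame_done = False
    skipped_altloc = 0

    def _close_frame():
        nonlocal current, first_frame_done
        if current is None:
            return
        if first_frame_done and len(current) != len(atoms):
            raise ValueError(
                f"MODEL {model_number} has {len(current)} atoms; "
                f"expected {len(atoms)} from the first frame"
            )
        frames.append(current)
        first_frame_done = True
        current = None

    for lineno, line in enumerate(lines, start=1):
        record = line[:6].strip()
        if record == "MODEL":
            _close_frame()
            in_model = True
            try:
                model_number = int(line[6:].strip() or 0)
            except ValueError:
                model_number += 1
            current = []
        elif record == "ENDMDL":
            _close_frame()
        elif record in ("ATOM", "HETATM"):
            altloc = line[16:17]
            if altloc not in (" ", "", "A"):
                skipped_altloc += 1
                continue
            if current is None:
                current = []
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"unparsable coordinate field on line {lineno}: {line!r}"
                ) from exc
            if not first_frame_done:
                name = line[12:16].strip()
                elem = line[76:78].strip() if len(line) >= 77 else ""
                element = elem.capitalize() if elem else _element_from_name(name)
                try:
                    serial = int(line[6:11])
                except ValueError:
                    serial = len(atoms) + 1
                try:
                    resseq = int(line[22:26])
                except ValueError as exc:
                    raise ValueError(
                        f"unparsable residue number on line {lineno}: {line!r}"
                    ) from exc
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        residue_name=line[17:20].strip() or "UNK",
                        residue_seq=resseq,
                        chain=line[21:22].strip() or "A",
                        element=element,
                    )
                )
            current.append((x, y, z))
        elif record == "END":
            _close_frame()

    _close_frame()

    if skipped_altloc:
        logger.warning("skipped %d altloc records (kept ''/'A' only)", skipped_altloc)
    if not atoms or not frames:
        raise ValueError("PDB stream contains no ATOM/HETATM records")
    arr = np.array(frames, dtype=float)
    if arr.shape[1] != len(atoms):
        raise ValueError("inconsistent atom count across frames")
    return Trajectory(atoms, arr)


def write_pdb(trajectory: Trajectory, stream) -> None:
    """Write a Trajectory as a multi-MODEL PDB (one MODEL per frame)."""
    if np.any(np.abs(trajectory.frames) >= 1e5):
        raise ValueError("coordinate magnitude ≥ 1e5 Å overflows PDB columns")
    out = []
    for f in range(trajectory.n_frames):
        out.append(f"MODEL     {f + 1:4d}\n")
        for atom, (x, y, z) in zip(trajectory.topology, trajectory.frames[f]):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            out.append(
                f"ATOM  {atom.serial % 100000:5d} {name:<4.4s} "
                f"{atom.residue_name:<3.3s} {atom.chain:1.1s}"
                f"{atom.residue_seq % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2.2s}\n"
            )
        out.append("ENDMDL\n")
    out.append("END\n")
    stream.write("".join(out))


# ---------------------------------------------------------------------------
# XYZ I/O (multi-frame)
# ---------------------------------------------------------------------------

def read_xyz(stream) -> Trajectory:
    """Parse a standard multi-frame XYZ stream (count / comment / atom lines)."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    lines = [ln for ln in lines]

    atoms: list[Atom] = []
    frames = []
    i = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"expected atom count on line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(
                f"frame starting at line {i + 1} declares {n} atoms but only "
                f"{len(block)} atom lines follow"
            )
        coords = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"malformed XYZ atom line {i + 3 + j}: {ln!r}")
            elem = parts[0].capitalize()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            if first:
                atoms.append(
                    Atom(
                        serial=j + 1,
                        name=parts[0],
                        residue_name="UNK",
                        residue_seq=1,
                        element=elem,
                    )
                )
        if not first and n != len(atoms):
            raise ValueError(
                f"frame {len(frames) + 1} has {n} atoms, expected {len(atoms)}"
            )
        frames.append(coords)
        first = False
        i += 2 + n
    if not frames:
        raise ValueError("XYZ stream contains no frames")
    return Trajectory(atoms, np.array(frames, dtype=float))


def write_xyz(trajectory: Trajectory, stream, comment: str = "") -> None:
    out = []
    for f in range(trajectory.n_frames):
        out.append(f"{trajectory.n_atoms}\n")
        out.append(f"{comment or f'frame {f}'}\n")
        for atom, (x, y, z) in zip(trajectory.topology, trajectory.frames[f]):
            out.append(f"{atom.element:<2s} {x:.6f} {y:.6f} {z:.6f}\n")
    stream.write("".join(out))


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(topology, selector: str, label: str | None = None) -> AtomGroup:
    """Select atoms with a conjunctive mini-language.

    Clauses are joined by ``and``; each clause is one of:

    - ``resid 36`` or ``resid 36,37`` — residue sequence number(s)
    - ``resname LYS`` — residue name(s)
    - ``name NZ`` or ``name N,CA,C`` — atom name(s)
    - ``chain A`` — chain id(s)
    - ``heavy`` — element ≠ H
    - ``all`` — no-op clause

    The result preserves topology order. An empty result is an error (silent
    empties hide typos in residue numbers and atom names).
    """
    if isinstance(topology, (Structure, Trajectory)):
        atoms = topology.atoms if isinstance(topology, Structure) else topology.topology
    else:
        atoms = list(topology)

    keep = np.ones(len(atoms), dtype=bool)
    for clause in selector.split(" and "):
        clause = clause.strip()
        if not clause or clause == "all":
            continue
        if clause == "heavy":
            keep &= np.array([a.is_heavy for a in atoms])
            continue
        try:
            keyword, arg = clause.split(None, 1)
        except ValueError:
            raise ValueError(f"cannot parse selector clause {clause!r}")
        values = [v.strip() for v in arg.split(",")]
        if keyword == "resid":
            wanted = {int(v) for v in values}
            keep &= np.array([a.residue_seq in wanted for a in atoms])
        elif keyword == "resname":
            wanted = {v.upper() for v in values}
            keep &= np.array([a.residue_name.upper() in wanted for a in atoms])
        elif keyword == "name":
            wanted = {v.upper() for v in values}
            keep &= np.array([a.name.upper() in wanted for a in atoms])
        elif keyword == "chain":
            wanted = {v.upper() for v in values}
            keep &= np.array([a.chain.upper() in wanted for a in atoms])
        else:
            raise ValueError(f"unknown selector keyword {keyword!r} in {clause!r}")
    indices = tuple(int(i) for i in np.flatnonzero(keep))
    if not indices:
        raise ValueError(f"selector {selector!r} matched no atoms")
    return AtomGroup(indices, label if label is not None else selector)


def center_of_mass(
    frame_coords: np.ndarray,
    group: AtomGroup,
    masses: np.ndarray | None = None,
    weighting: str = "mass",
) -> np.ndarray:
    """COM of a group in one frame: mass-weighted by default, or geometric.

    ``masses`` must cover the full topology when ``weighting='mass'``.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    idx = np.asarray(group.indices)
    pts = frame_coords[idx]
    if weighting == "geometric":
        return pts.mean(axis=0)
    if weighting != "mass":
        raise ValueError(f"weighting must be 'mass' or 'geometric', got {weighting!r}")
    if masses is None:
        raise ValueError("mass weighting requires per-atom masses")
    w = np.asarray(masses, dtype=float)[idx]
    return (pts * w[:, None]).sum(axis=0) / w.sum()
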
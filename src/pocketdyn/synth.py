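"""Synthetic fixtures with known ground truth for every pipeline stage.

Everything here is generated programmatically — four-atom S_N_2 geometries
with prescribed internal coordinates, hollow atom shells enclosing cavities of
analytic volume, two-residue trajectories with prescribed contact fractions,
scaled-shell trajectories populating prescribed volume bands, and coarse
receptor–ligand systems with open vs. occluded pockets for the steered
association simulator. No real structures, no downloads, no MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Atom, AtomGroup, Structure, Trajectory
from .steering import SteeringForce, ToySystem
from .tsdetect import TsAtomMap
from .volume import DEFAULT_VDW_RADII, DEFAULT_VDW_FALLBACK, GridConfig, InclusionSphere


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


# ---------------------------------------------------------------------------
# S_N_2 four-atom geometry
# ---------------------------------------------------------------------------

#: Canonical bond lengths used only to realize internal coordinates (Å).
CD_NE_BOND = 1.5
C_S_BOND = 1.8


@dataclass(frozen=True)
class Sn2GeometrySpec:
    """Prescribed internal coordinates for the four catalytic atoms."""

    d: float  # Nε–methyl C distance, Å
    attack_angle: float  # ∠(Cδ, Nε, C), degrees
    linearity_angle: float  # ∠(Nε, C, S), degrees
    rigid_seed: int = 0

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("Nε–C distance must be positive")
        for name, a in (("attack", self.attack_angle), ("linearity", self.linearity_angle)):
            if not 0 < a <= 180:
                raise ValueError(f"{name} angle must lie in (0, 180], got {a}")


def make_sn2_geometry(spec: Sn2GeometrySpec) -> Structure:
    """Four atoms (Cδ, Nε, methyl C, S) realizing the prescribed internals.

    Construction: Cδ at the origin, Nε at (1.5, 0, 0); the methyl carbon at
    distance d from Nε making the requested attack angle; S placed 1.8 Å from
    the carbon so that ∠(Nε, C, S) equals the linearity angle. A seeded random
    rigid transform is then applied, so measuring the three internal
    coordinates recovers the spec (to ~1e-9) regardless of pose.
    """
    t1 = math.radians(spec.attack_angle)
    t2 = math.radians(spec.linearity_angle)
    cd = np.array([0.0, 0.0, 0.0])
    ne = np.array([CD_NE_BOND, 0.0, 0.0])
    # direction Nε→Cδ is (−1, 0, 0); rotate it by the attack angle in the xy-plane
    c = ne + spec.d * np.array([-math.cos(t1), math.sin(t1), 0.0])
    u = (ne - c) / np.linalg.norm(ne - c)  # C→Nε
    # rotate u about z by the linearity angle to get C→S
    cz, sz = math.cos(t2), math.sin(t2)
    v = np.array([cz * u[0] - sz * u[1], sz * u[0] + cz * u[1], 0.0])
    s = c + C_S_BOND * v

    coords = np.vstack([cd, ne, c, s])
    rng = np.random.default_rng(spec.rigid_seed)
    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)
    coords = coords @ rot.T + trans

    atoms = [
        Atom(1, "CD", "LYS", 36, "A", "C"),
        Atom(2, "NZ", "LYS", 36, "A", "N"),
        Atom(3, "CE", "SAM", 500, "B", "C"),
        Atom(4, "SD", "SAM", 500, "B", "S"),
    ]
    return Structure(atoms, coords)


SN2_ATOM_MAP = TsAtomMap(n_epsilon=1, c_delta=0, methyl_c=2, sulfur=3)


# ---------------------------------------------------------------------------
# Hollow pocket shell (analytic volume oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketShellSpec:
    """Hollow-shell fixture: atoms on a cubic lattice filling the radial band
    [cavity_radius, cavity_radius + shell_thickness].

    ``atom_spacing`` controls how well the discrete shell approximates a
    continuous wall; the default 0.25 Å keeps the lattice gaps well under the
    0.4 Å distance cut so the measured cavity tracks the analytic ball.
    """

    cavity_radius: float = 3.0
    shell_thickness: float = 1.0
    atom_spacing: float = 0.25
    element: str = "C"

    def __post_init__(self):
        if min(self.cavity_radius, self.shell_thickness, self.atom_spacing) <= 0:
            raise ValueError("shell parameters must be positive")
        if self.atom_spacing >= self.shell_thickness:
            raise ValueError("atom_spacing must be smaller than shell_thickness")


def _shell_coords(spec: PocketShellSpec, center: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Cubic-lattice atom positions with radius in [r_cav, r_cav+thickness]."""
    r_in = spec.cavity_radius
    r_out = spec.cavity_radius + spec.shell_thickness
    n = int(math.ceil(r_out / spec.atom_spacing))
    ax = np.arange(-n, n + 1) * spec.atom_spacing
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    r = np.linalg.norm(pts, axis=1)
    pts = pts[(r >= r_in) & (r <= r_out)]
    return center + scale * pts


def shell_analytic_volume(
    spec: PocketShellSpec,
    distance_cut: float = 0.4,
    proximity_mode: str = "center",
    vdw_radii: dict | None = None,
) -> float:
    """Analytic accessible cavity volume after radius inflation (Å³).

    The grid stage removes points within ``inflation`` of shell atoms at
    radius ≥ cavity_radius, leaving a ball of radius cavity_radius − inflation
    where inflation is the distance cut (center mode) or vdW radius + distance
    cut (vdw mode).
    """
    if proximity_mode == "center":
        inflation = distance_cut
    elif proximity_mode == "vdw":
        radii = vdw_radii or DEFAULT_VDW_RADII
        inflation = radii.get(spec.element.capitalize(), DEFAULT_VDW_FALLBACK) + distance_cut
    else:
        raise ValueError("proximity_mode must be 'center' or 'vdw'")
    r = max(spec.cavity_radius - inflation, 0.0)
    return 4.0 / 3.0 * math.pi * r**3


def make_pocket_shell(
    spec: PocketShellSpec,
    inclusion_center=(0.0, 0.0, 0.0),
    distance_cut: float = 0.4,
    proximity_mode: str = "center",
) -> tuple[Structure, float]:
    """Hollow atom shell around a cavity, plus its analytic accessible volume."""
    center = np.asarray(inclusion_center, dtype=float)
    coords = _shell_coords(spec, center)
    atoms = [
        Atom(i + 1, spec.element, "SHL", 1 + i // 9999, "A", spec.element)
        for i in range(len(coords))
    ]
    return Structure(atoms, coords), shell_analytic_volume(spec, distance_cut, proximity_mode)


# ---------------------------------------------------------------------------
# Contact trajectory with prescribed occupancy
# ---------------------------------------------------------------------------

def make_contact_trajectory(
    n_frames: int,
    fraction: float,
    d_in: float = 3.0,
    d_out: float = 8.0,
    seed: int = 0,
) -> Trajectory:
    """Two single-atom residues separated by d_in in exactly
    round(n_frames·fraction) frames (shuffled by seed) and d_out otherwise."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if d_in >= d_out:
        raise ValueError("d_in must be smaller than d_out")
    n_in = round(n_frames * fraction)
    seps = np.full(n_frames, d_out)
    seps[:n_in] = d_in
    rng = np.random.default_rng(seed)
    rng.shuffle(seps)
    frames = np.zeros((n_frames, 2, 3))
    frames[:, 1, 0] = seps
    atoms = [
        Atom(1, "OG1", "THR", 1150, "A", "O"),
        Atom(2, "N", "TYR", 1092, "A", "N"),
    ]
    return Trajectory(atoms, frames)


# ---------------------------------------------------------------------------
# Volume trajectory populating prescribed volume bands
# ---------------------------------------------------------------------------

#: Shell geometries whose accessible cavity volumes land in the ≥70 Å³ band
#: (open) and the 0–25 Å³ band (collapsed) under the companion grid config.
VOLUME_SHELL_SPEC = PocketShellSpec(cavity_radius=3.2, shell_thickness=1.0, atom_spacing=0.5)
COLLAPSED_SCALE = 1.8 / 3.2  # collapsed cavity radius 1.8 Å


def volume_grid_config() -> GridConfig:
    """Grid config matched to make_volume_trajectory fixtures: center-mode
    proximity, hull exclusion off (the shell itself bounds the cavity)."""
    return GridConfig(
        spacing=0.4,
        distance_cut=0.4,
        contiguity_criterion=3,
        convex_hull_exclusion=False,
        proximity_mode="center",
        inclusion=(InclusionSphere((0.0, 0.0, 0.0), 3.0),),
    )


def make_volume_trajectory(open_frames: int, collapsed_frames: int, seed: int = 0) -> Trajectory:
    """Interleaves (seeded order) shell frames with a large cavity and frames
    with the same shell radially shrunk so the cavity falls in the low band."""
    if open_frames < 0 or collapsed_frames < 0:
        raise ValueError("frame counts must be non-negative")
    if open_frames + collapsed_frames == 0:
        raise ValueError("need at least one frame")
    base = _shell_coords(VOLUME_SHELL_SPEC, np.zeros(3))
    flags = np.array([True] * open_frames + [False] * collapsed_frames)
    rng = np.random.default_rng(seed)
    rng.shuffle(flags)
    frames = np.array([base if f else base * COLLAPSED_SCALE for f in flags])
    atoms = [Atom(i + 1, "C", "SHL", 1 + i // 9999, "A", "C") for i in range(len(base))]
    return Trajectory(atoms, frames)


# ---------------------------------------------------------------------------
# Toy receptor–ligand association system
# ---------------------------------------------------------------------------

ATTACK_ANGLE_DEG = 109.0
_POCKET_RADIUS = 5.0  # inner wall radius around the lysine Nε, Å
_WALL_THICKNESS = 1.0
_WALL_SPACING = 1.2
_MOUTH_HALF_ANGLE = 55.0  # degrees around +z; wide enough that a thermally
# wandering bead (lateral spread ≈ √(kBT/k₁) ≈ 3.5 Å) can find the entrance
_WALL_EXCLUSION = 1.2
_BEAD_RADIUS = 1.0
_BEAD_MASS = 30.0  # coarse beads lump hydrogens and ring atoms
_BOND_K = 50.0  # kJ·mol⁻¹·Å⁻²


def make_toy_association_system(
    pocket: str = "open", start_distance: float = 27.0
) -> tuple[ToySystem, list[SteeringForce]]:
    """Coarse receptor pocket plus an 8-bead cofactor ligand, wired for the
    three steering forces (k = 0.2, 0.1, 0.05 kJ·mol⁻¹·Å⁻²).

    The receptor is a spherical atom shell around the substrate lysine Nε with
    a conical mouth opening along +z; the ``occluded`` variant caps the mouth
    with gate atoms so the ligand cannot reach the catalytic geometry. The
    ligand's center of mass starts ``start_distance`` Å above the Nε along the
    pocket axis. Returns ``(system, steering_forces)``.
    """
    if pocket not in ("open", "occluded"):
        raise ValueError("pocket must be 'open' or 'occluded'")
    if start_distance <= _POCKET_RADIUS + _WALL_THICKNESS:
        raise ValueError("start_distance must exceed the pocket size")

    t_attack = math.radians(ATTACK_ANGLE_DEG)
    mouth_cos = math.cos(math.radians(_MOUTH_HALF_ANGLE))

    rec_atoms: list[Atom] = []
    rec_coords: list[np.ndarray] = []
    rec_radii: list[float] = []

    def add(name, resname, resseq, element, xyz, radius):
        rec_atoms.append(Atom(len(rec_atoms) + 1, name, resname, resseq, "A", element))
        rec_coords.append(np.asarray(xyz, dtype=float))
        rec_radii.append(radius)

    # substrate lysine: Nε at the origin, Cδ at the canonical attack direction
    add("NZ", "LYS", 36, "N", (0.0, 0.0, 0.0), _BEAD_RADIUS)
    add(
        "CD", "LYS", 36, "C",
        (CD_NE_BOND * math.sin(t_attack), 0.0, CD_NE_BOND * math.cos(t_attack)),
        _BEAD_RADIUS,
    )

    # pocket wall: spherical shell lattice with the mouth cone removed
    n = int(math.ceil((_POCKET_RADIUS + _WALL_THICKNESS) / _WALL_SPACING))
    ax = np.arange(-n, n + 1) * _WALL_SPACING
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    r = np.linalg.norm(pts, axis=1)
    in_shell = (r >= _POCKET_RADIUS) & (r <= _POCKET_RADIUS + _WALL_THICKNESS)
    with np.errstate(invalid="ignore"):
        in_mouth = np.where(r > 0, pts[:, 2] / np.where(r > 0, r, 1.0), 0.0) > mouth_cos
    for p in pts[in_shell & ~in_mouth]:
        add("O", "WAL", 900, "O", p, _WALL_EXCLUSION)

    if pocket == "occluded":
        # gate cap closing the mouth just above the wall
        gate_r = _POCKET_RADIUS + 0.5
        for p in pts[in_shell & in_mouth]:
            add("O", "GAT", 901, "O", p / np.linalg.norm(p) * gate_r, _WALL_EXCLUSION)

    # anchor triads for the two weaker guiding forces, above the mouth rim and
    # clear of the entry path (beads keep ≥ σ from the axis)
    anchor1 = np.array([2.6, 0.0, 7.5])
    for name, off in (("N", (0, 0, 0)), ("CA", (0.9, 0, 0.5)), ("C", (1.8, 0, 0))):
        add(name, "LEU", 1202, "C" if name != "N" else "N", anchor1 + np.array(off), _WALL_EXCLUSION)
    anchor2 = np.array([-2.6, 0.0, 7.5])
    for name, off in (("CA", (0, 0, 0)), ("C", (-0.9, 0, 0.5)), ("O", (-1.8, 0, 0))):
        add(name, "PHE", 1149, "O" if name == "O" else "C", anchor2 + np.array(off), _WALL_EXCLUSION)

    receptor = Structure(rec_atoms, np.array(rec_coords))
    nr = receptor.n_atoms

    # 8-bead cofactor: methyl C and S on the pocket axis, adenine-like triad
    # (N1, C2, N3) and amino-acid-like triad (N0, CA, CB) above
    lig_template = {
        "CM": ("C", np.array([0.0, 0.0, 0.0])),
        "SD": ("S", np.array([0.0, 0.0, 1.8])),
        "N1": ("N", np.array([-1.1, 0.0, 2.6])),
        "C2": ("C", np.array([-2.0, 0.0, 3.4])),
        "N3": ("N", np.array([-1.1, 0.0, 4.2])),
        "CB": ("C", np.array([1.1, 0.0, 2.6])),
        "CA": ("C", np.array([2.0, 0.0, 3.4])),
        "N0": ("N", np.array([1.1, 0.0, 4.2])),
    }
    names = list(lig_template)
    lig_coords = np.array([lig_template[k][1] for k in names])
    lig_coords = lig_coords - lig_coords.mean(axis=0) + np.array([0.0, 0.0, start_distance])
    lig_atoms = [
        Atom(nr + i + 1, name, "SAM", 500, "B", lig_template[name][0], mass=_BEAD_MASS)
        for i, name in enumerate(names)
    ]
    ligand = Structure(lig_atoms, lig_coords)

    gi = {name: nr + i for i, name in enumerate(names)}
    # triads are closed into triangles for rigidity; the S bead keeps at most
    # three bonds so the stiffest mode stays stable under the overdamped
    # update at the default time step
    bond_pairs = [
        ("CM", "SD"),
        ("SD", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "N1"),
        ("SD", "CB"), ("CB", "CA"), ("CA", "N0"), ("N0", "CB"),
    ]
    bonds = []
    for a, b in bond_pairs:
        r0 = float(np.linalg.norm(lig_template[a][1] - lig_template[b][1]))
        bonds.append((gi[a], gi[b], r0, _BOND_K))

    rec_index = {(a.residue_name, a.name): i for i, a in enumerate(rec_atoms)}
    centroid_groups = {
        "lysine_n": AtomGroup((rec_index[("LYS", "NZ")],), "lysine_n"),
        "methyl": AtomGroup((gi["CM"],), "methyl"),
        "adenine": AtomGroup(tuple(sorted((gi["N1"], gi["C2"], gi["N3"]))), "adenine"),
        "anchor_adenine": AtomGroup(
            tuple(sorted(rec_index[("LEU", nm)] for nm in ("N", "CA", "C"))), "anchor_adenine"
        ),
        "amino": AtomGroup(tuple(sorted((gi["N0"], gi["CA"], gi["CB"]))), "amino"),
        "anchor_amino": AtomGroup(
            tuple(sorted(rec_index[("PHE", nm)] for nm in ("CA", "C", "O"))), "anchor_amino"
        ),
    }

    ts_map = TsAtomMap(
        n_epsilon=rec_index[("LYS", "NZ")],
        c_delta=rec_index[("LYS", "CD")],
        methyl_c=gi["CM"],
        sulfur=gi["SD"],
    )

    system = ToySystem(
        receptor=receptor,
        ligand=ligand,
        receptor_radii=np.array(rec_radii),
        ligand_radii=np.full(ligand.n_atoms, _BEAD_RADIUS),
        bonds=bonds,
        centroid_groups=centroid_groups,
        ts_atom_map=ts_map,
    )
    forces = [
        SteeringForce(0.2, centroid_groups["methyl"], centroid_groups["lysine_n"], "pull_methyl"),
        SteeringForce(0.1, centroid_groups["adenine"], centroid_groups["anchor_adenine"], "guide_adenine"),
        SteeringForce(0.05, centroid_groups["amino"], centroid_groups["anchor_amino"], "guide_amino"),
    ]
    return system, forces
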
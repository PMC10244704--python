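"""Desk-scale steered-association simulator.

A coarse ligand (a handful of bonded beads standing in for the cofactor) is
pulled into a rigid coarse receptor by distance-dependent centroid–centroid
forces — harmonic with zero rest length, U = ½·k·d², F = k·d — mirroring the
guiding-force setup of steered cofactor-association protocols (default force
constants 0.2 / 0.1 / 0.05 kJ·mol⁻¹·Å⁻²). Dynamics are overdamped Langevin
(Euler–Maruyama): receptor atoms never move, ligand beads feel steering,
harmonic bonds, a purely repulsive excluded-volume term against the receptor
spheres, and thermal noise at the configured temperature (default 300 K,
friction 1 ps⁻¹).

Internal unit system: Å, ps, Da, with energies in kJ/mol converted via
1 kJ/mol = 100 Da·Å²/ps², so the zero-temperature update is exactly
x ← x + F·dt/(m·γ) in internal units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import Atom, AtomGroup, Structure, Trajectory, center_of_mass
from .tsdetect import TsAtomMap

#: Boltzmann constant, kJ/(mol·K).
KB_KJ_PER_MOL_K = 0.00831446261815324
#: 1 kJ/mol expressed in internal Da·Å²/ps² units.
KJ_PER_MOL_INTERNAL = 100.0
#: Excluded-volume spring constant, kJ·mol⁻¹·Å⁻². Kept soft enough that the
#: overdamped update relaxes overlaps monotonically at the default dt.
K_REPULSION = 100.0


@dataclass(frozen=True)
class SteeringForce:
    """Zero-rest-length harmonic pull between two centroids."""

    k: float
    group_a: AtomGroup  # mobile (ligand) centroid
    group_b: AtomGroup  # target (receptor) centroid
    label: str = ""

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("steering force constant must be non-negative")


@dataclass
class ToySystem:
    """Rigid coarse receptor plus mobile bonded-bead ligand.

    The combined topology is receptor atoms followed by ligand beads; all
    groups and the TS atom map index that combined space. ``bonds`` are
    ``(i, j, rest_length, k)`` tuples over combined indices of ligand beads.
    """

    receptor: Structure
    ligand: Structure
    receptor_radii: np.ndarray  # exclusion radii, Å
    ligand_radii: np.ndarray  # bead radii, Å
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    centroid_groups: dict[str, AtomGroup] = field(default_factory=dict)
    ts_atom_map: TsAtomMap | None = None

    def __post_init__(self):
        self.receptor_radii = np.asarray(self.receptor_radii, dtype=float)
        self.ligand_radii = np.asarray(self.ligand_radii, dtype=float)
        if len(self.receptor_radii) != self.receptor.n_atoms:
            raise ValueError("need one exclusion radius per receptor atom")
        if len(self.ligand_radii) != self.ligand.n_atoms:
            raise ValueError("need one bead radius per ligand bead")
        if np.any(self.receptor_radii <= 0) or np.any(self.ligand_radii <= 0):
            raise ValueError("exclusion/bead radii must be positive")
        n = self.n_atoms
        for i, j, r0, kb in self.bonds:
            if not (self.n_receptor <= i < n and self.n_receptor <= j < n):
                raise ValueError("bonds may only connect ligand beads")
            if r0 <= 0 or kb < 0:
                raise ValueError("bond rest length must be positive, k non-negative")
        if self.ts_atom_map is not None:
            self.ts_atom_map.validate(n)
        # cached arrays for the integrator hot loop
        self._masses = np.concatenate([self.receptor.masses(), self.ligand.masses()])
        self._mobile = np.zeros(n, dtype=bool)
        self._mobile[self.n_receptor :] = True
        if self.bonds:
            b = np.array([(i, j, r0, kb) for i, j, r0, kb in self.bonds])
            self._bond_i = b[:, 0].astype(int)
            self._bond_j = b[:, 1].astype(int)
            self._bond_r0 = b[:, 2]
            self._bond_k = b[:, 3]
        else:
            self._bond_i = np.zeros(0, dtype=int)
            self._bond_j = np.zeros(0, dtype=int)
            self._bond_r0 = np.zeros(0)
            self._bond_k = np.zeros(0)
        self._sigma = self.ligand_radii[:, None] + self.receptor_radii[None, :]

    @property
    def n_receptor(self) -> int:
        return self.receptor.n_atoms

    @property
    def n_atoms(self) -> int:
        return self.receptor.n_atoms + self.ligand.n_atoms

    @property
    def topology(self) -> list[Atom]:
        return list(self.receptor.atoms) + list(self.ligand.atoms)

    def masses(self) -> np.ndarray:
        return self._masses

    def initial_frame(self) -> np.ndarray:
        return np.vstack([self.receptor.coords, self.ligand.coords])

    def mobile_mask(self) -> np.ndarray:
        return self._mobile.copy()


@dataclass(frozen=True)
class SimParams:
    """Integrator parameters (toy analogue of the production protocol)."""

    dt_ps: float = 0.001
    friction_per_ps: float = 1.0
    temperature_K: float = 300.0
    n_steps: int = 20000
    record_stride: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be ≥ 1")
        if self.temperature_K < 0:
            raise ValueError("temperature must be non-negative")
        if self.friction_per_ps <= 0:
            raise ValueError("friction must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be ≥ 1")


def steering_energy(frame: np.ndarray, force: SteeringForce, masses: np.ndarray) -> float:
    """U = ½·k·‖COM_a − COM_b‖² in kJ/mol."""
    com_a = center_of_mass(frame, force.group_a, masses)
    com_b = center_of_mass(frame, force.group_b, masses)
    d2 = float(((com_a - com_b) ** 2).sum())
    return 0.5 * force.k * d2


def _steering_cache(system: ToySystem, forces) -> list[tuple]:
    """Per-force index arrays and mass-fraction weights for the hot loop."""
    masses = system._masses
    cache = []
    for force in forces:
        ia = np.asarray(force.group_a.indices)
        ib = np.asarray(force.group_b.indices)
        wa = masses[ia] / masses[ia].sum()
        wb = masses[ib] / masses[ib].sum()
        mobile_a = ia >= system.n_receptor
        cache.append((force.k, ia, wa, ib, wb, ia[mobile_a], wa[mobile_a]))
    return cache


def total_forces(frame: np.ndarray, system: ToySystem, forces, _cache=None) -> np.ndarray:
    """Per-atom force vectors (kJ·mol⁻¹·Å⁻¹) on the combined topology.

    Sums (i) each steering pull −k·d·û spread over the mobile centroid atoms
    by mass fraction, with the reaction on the rigid receptor dropped;
    (ii) harmonic ligand bonds; (iii) a purely repulsive receptor–ligand pair
    force F = k_rep·(σ_ij − r)·û for r < σ_ij, where σ_ij is the receptor
    exclusion radius plus the ligand bead radius.
    """
    frame = np.asarray(frame, dtype=float)
    out = np.zeros_like(frame)
    nr = system.n_receptor
    if _cache is None:
        _cache = _steering_cache(system, forces)

    for k, ia, wa, ib, wb, ia_mobile, wa_mobile in _cache:
        com_a = wa @ frame[ia]
        com_b = wb @ frame[ib]
        # F on centroid a is −k·(COM_a − COM_b); distributed by mass fraction
        f_com = -k * (com_a - com_b)
        out[ia_mobile] += wa_mobile[:, None] * f_com[None, :]

    if len(system._bond_i):
        rij = frame[system._bond_i] - frame[system._bond_j]
        r = np.linalg.norm(rij, axis=1)
        if np.any(r == 0.0):
            raise FloatingPointError("bonded beads coincide")
        fb = (-system._bond_k * (r - system._bond_r0) / r)[:, None] * rij
        np.add.at(out, system._bond_i, fb)
        np.add.at(out, system._bond_j, -fb)

    if nr > 0 and system.ligand.n_atoms > 0:
        lig = frame[nr:]
        rec = frame[:nr]
        d = cdist(lig, rec)
        sigma = system._sigma
        overlap = d < sigma
        if overlap.any():
            li, ri = np.nonzero(overlap)
            r = d[li, ri]
            if np.any(r == 0.0):
                raise FloatingPointError(
                    "ligand bead exactly at a receptor atom center: repulsion "
                    "direction undefined"
                )
            u = (lig[li] - rec[ri]) / r[:, None]
            mag = K_REPULSION * (sigma[li, ri] - r)
            np.add.at(out, nr + li, mag[:, None] * u)

    return out


def step_overdamped(
    frame: np.ndarray,
    system: ToySystem,
    forces,
    params: SimParams,
    rng: np.random.Generator,
    _cache=None,
) -> np.ndarray:
    """One Euler–Maruyama step; receptor atoms never move.

    x ← x + (D/kBT)·F·dt + √(2·D·dt)·ξ with per-bead D = kBT/(m·γ). At T = 0
    the noise term is exactly zero. Raises if any bead would move farther in
    one step than the smallest receptor exclusion radius (tunnelling risk —
    reduce dt).
    """
    frame = np.asarray(frame, dtype=float)
    f = total_forces(frame, system, forces, _cache) * KJ_PER_MOL_INTERNAL
    masses = system._masses
    gamma = params.friction_per_ps
    mobile = system._mobile

    disp = np.zeros_like(frame)
    mg = (masses[mobile] * gamma)[:, None]
    disp[mobile] = f[mobile] * params.dt_ps / mg
    if params.temperature_K > 0:
        kbt = KB_KJ_PER_MOL_K * params.temperature_K * KJ_PER_MOL_INTERNAL
        d_coef = kbt / mg
        noise = rng.standard_normal((int(mobile.sum()), 3))
        disp[mobile] += np.sqrt(2.0 * d_coef * params.dt_ps) * noise

    max_disp = float(np.linalg.norm(disp[mobile], axis=1).max(initial=0.0))
    limit = float(system.receptor_radii.min(initial=np.inf))
    if max_disp >= limit:
        raise RuntimeError(
            f"step displacement {max_disp:.3f} Å ≥ smallest exclusion radius "
            f"{limit:.3f} Å: reduce dt_ps (currently {params.dt_ps} ps)"
        )
    return frame + disp


def run_replicate(system: ToySystem, forces, params: SimParams) -> Trajectory:
    """Integrate one seeded replicate; frames recorded every ``record_stride``
    steps (plus the initial frame) over the combined topology."""
    rng = np.random.default_rng(params.seed)
    frame = system.initial_frame()
    cache = _steering_cache(system, forces)
    recorded = [frame.copy()]
    for step in range(1, params.n_steps + 1):
        frame = step_overdamped(frame, system, forces, params, rng, cache)
        if step % params.record_stride == 0:
            recorded.append(frame.copy())
    return Trajectory(
        system.topology,
        np.array(recorded),
        frame_interval_ps=params.dt_ps * params.record_stride,
    )


def run_ensemble(
    system: ToySystem,
    forces,
    params: SimParams,
    n_replicates: int,
    base_seed: int,
) -> list[Trajectory]:
    """Independent replicates; replicate i runs with seed ``base_seed + i``."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    out = []
    for i in range(n_replicates):
        p = SimParams(
            dt_ps=params.dt_ps,
            friction_per_ps=params.friction_per_ps,
            temperature_K=params.temperature_K,
            n_steps=params.n_steps,
            record_stride=params.record_stride,
            seed=base_seed + i,
        )
        out.append(run_replicate(system, forces, p))
    return out
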
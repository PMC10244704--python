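"""S_N_2 transition-state-like docking detection and docked-pose RMSD.

A cofactor-association frame counts as a productive (TS-like) docking event
when the four catalytic atoms — substrate lysine Nε and Cδ, cofactor methyl
carbon and sulfur — satisfy the geometry of an S_N_2 methyl transfer:

1. d(Nε, methyl C) < 4 Å (strict),
2. attack angle ∠(Cδ, Nε, methyl C) within 109° ± 30° (inclusive),
3. near-linear donor axis ∠(Nε, methyl C, S) within 180° ± 30° (inclusive;
   since interior angles fold to ≤ 180°, this means angle ≥ 150°).

A replicate is successful when at least one recorded frame passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtomGroup, Structure, Trajectory


@dataclass(frozen=True)
class TsCriteria:
    """Geometric thresholds for a TS-like conformation."""

    d_max: float = 4.0
    attack_angle_center: float = 109.0
    attack_angle_tol: float = 30.0
    linearity_center: float = 180.0
    linearity_tol: float = 30.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        for tol in (self.attack_angle_tol, self.linearity_tol):
            if not (0 < tol < 90):
                raise ValueError("angle tolerances must lie in (0, 90) degrees")


@dataclass(frozen=True)
class TsAtomMap:
    """Indices of the four catalytic atoms in the topology."""

    n_epsilon: int
    c_delta: int
    methyl_c: int
    sulfur: int

    def __post_init__(self):
        idx = (self.n_epsilon, self.c_delta, self.methyl_c, self.sulfur)
        if len(set(idx)) != 4:
            raise ValueError("TS atom map requires four distinct atom indices")

    def validate(self, n_atoms: int) -> None:
        for i in (self.n_epsilon, self.c_delta, self.methyl_c, self.sulfur):
            if not 0 <= i < n_atoms:
                raise IndexError(f"TS atom index {i} out of range (N={n_atoms})")


@dataclass(frozen=True)
class TsFrameResult:
    frame_index: int
    distance: float
    attack_angle: float
    linearity_angle: float
    passed: bool


@dataclass(frozen=True)
class ReplicateOutcome:
    replicate_id: int
    successful: bool
    first_passing_frame: int | None
    n_passing_frames: int


def distance(frame: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance (Å) between atoms i and j in one frame."""
    frame = np.asarray(frame, dtype=float)
    return float(np.linalg.norm(frame[i] - frame[j]))


def angle_deg(frame: np.ndarray, a: int, b: int, c: int) -> float:
    """Interior angle at b (degrees, in [0, 180]) of the a–b–c triple.

    Computed as atan2(‖u×v‖, u·v), which is well conditioned near 0° and
    180° where the plain arccos formulation loses precision.
    """
    frame = np.asarray(frame, dtype=float)
    u = frame[a] - frame[b]
    v = frame[c] - frame[b]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError(f"zero-length arm in angle ({a},{b},{c})")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def classify_ts_frame(
    frame: np.ndarray,
    atom_map: TsAtomMap,
    criteria: TsCriteria = TsCriteria(),
    frame_index: int = 0,
) -> TsFrameResult:
    """Evaluate the three S_N_2 criteria on one frame.

    The distance bound is strict (< d_max); the angle windows are inclusive.
    """
    d = distance(frame, atom_map.n_epsilon, atom_map.methyl_c)
    attack = angle_deg(frame, atom_map.c_delta, atom_map.n_epsilon, atom_map.methyl_c)
    linearity = angle_deg(frame, atom_map.n_epsilon, atom_map.methyl_c, atom_map.sulfur)
    passed = (
        d < criteria.d_max
        and abs(attack - criteria.attack_angle_center) <= criteria.attack_angle_tol
        and abs(linearity - criteria.linearity_center) <= criteria.linearity_tol
    )
    return TsFrameResult(frame_index, d, attack, linearity, passed)


def scan_trajectory(
    trajectory: Trajectory,
    atom_map: TsAtomMap,
    criteria: TsCriteria = TsCriteria(),
    replicate_id: int = 0,
) -> tuple[list[TsFrameResult], ReplicateOutcome]:
    """Classify every recorded frame and aggregate the replicate outcome."""
    atom_map.validate(trajectory.n_atoms)
    results = [
        classify_ts_frame(trajectory.frames[f], atom_map, criteria, frame_index=f)
        for f in range(trajectory.n_frames)
    ]
    passing = [r.frame_index for r in results if r.passed]
    outcome = ReplicateOutcome(
        replicate_id=replicate_id,
        successful=bool(passing),
        first_passing_frame=passing[0] if passing else None,
        n_passing_frames=len(passing),
    )
    return results, outcome


def count_successes(outcomes) -> int:
    """Number of replicates with at least one passing frame."""
    return sum(1 for o in outcomes if o.successful)


def frame_results_table(results_by_replicate: dict[int, list[TsFrameResult]]) -> pd.DataFrame:
    rows = [
        {
            "replicate": rep,
            "frame": r.frame_index,
            "distance": r.distance,
            "attack_angle": r.attack_angle,
            "linearity_angle": r.linearity_angle,
            "passed": r.passed,
        }
        for rep, results in results_by_replicate.items()
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["replicate", "frame", "distance", "attack_angle", "linearity_angle", "passed"],
    )


def outcome_table(outcomes) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicate": o.replicate_id,
                "successful": o.successful,
                "first_passing_frame": -1 if o.first_passing_frame is None else o.first_passing_frame,
                "n_passing": o.n_passing_frames,
            }
            for o in outcomes
        ],
        columns=["replicate", "successful", "first_passing_frame", "n_passing"],
    )


# ---------------------------------------------------------------------------
# Superposition and docked-pose RMSD
# ---------------------------------------------------------------------------

def superpose_kabsch(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    fit_group: AtomGroup,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch) over a fit group.

    Returns ``(rotation, translation, fitted_coords)`` where
    ``fitted = mobile @ rotation.T + translation`` and the transform is the
    optimal proper rotation (det = +1) minimising the fit-group RMSD.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    reference = np.asarray(reference_coords, dtype=float)
    idx = np.asarray(fit_group.indices)
    if len(idx) < 3:
        raise ValueError("fit group must contain at least 3 atoms")
    x = mobile[idx]
    y = reference[idx]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    if np.linalg.matrix_rank(h) < 2:
        raise ValueError("fit group is degenerate (collinear or coincident atoms)")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    fitted = mobile @ rot.T + trans
    return rot, trans, fitted


def docking_rmsd(
    frame: np.ndarray,
    reference: Structure | np.ndarray,
    fit_group: AtomGroup,
    ligand_group: AtomGroup,
) -> float:
    """RMSD (Å) of the docked ligand after receptor superposition.

    The frame is superposed on the reference over ``fit_group`` (receptor
    atoms), then the RMSD is taken over ``ligand_group``. Both groups index
    the shared topology and must have equal size and order in frame and
    reference.
    """
    ref_coords = reference.coords if isinstance(reference, Structure) else np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if frame.shape != ref_coords.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match reference {ref_coords.shape}"
        )
    _, _, fitted = superpose_kabsch(frame, ref_coords, fit_group)
    idx = np.asarray(ligand_group.indices)
    diff = fitted[idx] - ref_coords[idx]
    return float(np.sqrt((diff**2).sum(axis=1).mean()))
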
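"""Heavy-atom residue contact detection and per-replicate occupancy.

A contact between two residues (or named atom subsets, e.g. a threonine
hydroxyl oxygen vs a tyrosine backbone nitrogen) is established in a frame
when any heavy-atom pair across the two groups is closer than the cutoff
(default 4.5 Å, strict). Occupancy is the fraction of frames in contact;
per-replicate occupancies — not pooled frames — are the statistical unit
handed to the t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import AtomGroup, Trajectory


@dataclass(frozen=True)
class ContactSpec:
    group_a: AtomGroup
    group_b: AtomGroup
    cutoff: float = 4.5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if set(self.group_a.indices) & set(self.group_b.indices):
            raise ValueError("contact groups must be disjoint")


@dataclass(frozen=True)
class ContactSeries:
    in_contact: tuple[bool, ...]
    spec: ContactSpec
    replicate_id: int = 0

    @property
    def fraction(self) -> float:
        return sum(self.in_contact) / len(self.in_contact)


@dataclass(frozen=True)
class ContactSummary:
    fractions: tuple[float, ...]
    mean: float
    n_replicates: int


def frame_in_contact(frame: np.ndarray, spec: ContactSpec) -> tuple[bool, float]:
    """Whether any cross-group atom pair is below the cutoff, plus the
    minimum pair distance (Å)."""
    frame = np.asarray(frame, dtype=float)
    d = cdist(frame[np.asarray(spec.group_a.indices)], frame[np.asarray(spec.group_b.indices)])
    dmin = float(d.min())
    return dmin < spec.cutoff, dmin


def contact_series(trajectory: Trajectory, spec: ContactSpec, replicate_id: int = 0) -> ContactSeries:
    spec.group_a.validate(trajectory.n_atoms)
    spec.group_b.validate(trajectory.n_atoms)
    flags = tuple(
        frame_in_contact(trajectory.frames[f], spec)[0] for f in range(trajectory.n_frames)
    )
    return ContactSeries(flags, spec, replicate_id)


def contact_fraction(trajectory: Trajectory, spec: ContactSpec) -> float:
    """Fraction of recorded frames in which the contact is established."""
    return contact_series(trajectory, spec).fraction


def summarize_replicates(series_list) -> ContactSummary:
    """Per-replicate occupancy fractions and their unweighted mean."""
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one contact series")
    fractions = tuple(s.fraction for s in series_list)
    return ContactSummary(fractions, float(np.mean(fractions)), len(fractions))


def contact_table(series_list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicate": s.replicate_id,
                "n_frames": len(s.in_contact),
                "n_contact": int(sum(s.in_contact)),
                "fraction": s.fraction,
            }
            for s in series_list
        ],
        columns=["replicate", "n_frames", "n_contact", "fraction"],
    )
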
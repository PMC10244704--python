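import numpy as np
import pytest

from pocketdyn.core import Atom, Structure, Trajectory


@pytest.fixture
def lysine_fragment() -> Structure:
    """Minimal lysine-like fragment with named side-chain atoms."""
    atoms = [
        Atom(1, "CD", "LYS", 36, "A", "C"),
        Atom(2, "CE", "LYS", 36, "A", "C"),
        Atom(3, "NZ", "LYS", 36, "A", "N"),
        Atom(4, "HZ1", "LYS", 36, "A", "H"),
        Atom(5, "HZ2", "LYS", 36, "A", "H"),
    ]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.4, 1.1, 0.0],
            [3.1, 1.0, 0.7],
            [2.9, 1.3, -0.9],
        ]
    )
    return Structure(atoms, coords)


@pytest.fixture
def two_frame_trajectory(lysine_fragment) -> Trajectory:
    frames = np.stack([lysine_fragment.coords, lysine_fragment.coords + 1.0])
    return Trajectory(list(lysine_fragment.atoms), frames)


def random_rigid_transform(rng: np.random.Generator):
    """Independent random proper rotation + translation for invariance tests."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    t = rng.uniform(-50, 50, size=3)
    return q, t
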
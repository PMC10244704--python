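"""Grid volumetrics: every pruning stage against an independent brute-force
oracle, plus the analytic-sphere and hollow-shell volume recoveries."""

import math
from collections import deque

import numpy as np
import pytest

from pocketdyn.core import AtomGroup
from pocketdyn.synth import PocketShellSpec, make_pocket_shell
from pocketdyn.volume import (
    GridConfig,
    InclusionSphere,
    contiguity_filter,
    generate_inclusion_grid,
    large_volume_fold,
    pocket_volume,
    prune_by_receptor_proximity,
    prune_outside_convex_hull,
    sample_frames,
    triplicate_large_volume_folds,
    volume_distribution,
)

BALL_VOLUME_R3 = 4.0 / 3.0 * math.pi * 27.0  # 113.097 Å³


def config(spacing=0.4, **kw):
    defaults = dict(
        spacing=spacing,
        convex_hull_exclusion=False,
        proximity_mode="center",
        inclusion=(InclusionSphere((0.0, 0.0, 0.0), 3.0),),
    )
    defaults.update(kw)
    return GridConfig(**defaults)


# --- independent oracles -----------------------------------------------------

def brute_proximity_prune(points, atoms, cut):
    keep = []
    for p in points:
        if all(np.linalg.norm(p - a) > cut for a in atoms):
            keep.append(p)
    return np.array(keep).reshape(-1, 3)


def brute_contiguity(points, spacing, criterion, seeds):
    """Independent BFS implementation of iterative deletion + seed components."""
    cells = {tuple(np.rint(p / spacing).astype(int)) for p in points}

    def neighbors(c):
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    out.append((c[0] + dx, c[1] + dy, c[2] + dz))
        return out

    changed = True
    while changed:
        drop = {c for c in cells if sum(n in cells for n in neighbors(c)) < criterion}
        changed = bool(drop) and criterion > 0
        cells -= drop if criterion > 0 else set()
        if criterion == 0:
            break

    if not cells:
        return cells
    seed_cells = set()
    for s in seeds:
        target = tuple(np.rint(np.asarray(s) / spacing).astype(int))
        if target in cells:
            seed_cells.add(target)
        else:
            seed_cells.add(
                min(cells, key=lambda c: sum((a - b) ** 2 for a, b in zip(c, target)))
            )
    keep = set()
    for s in seed_cells:
        if s in keep:
            continue
        queue = deque([s])
        while queue:
            c = queue.popleft()
            if c in keep or c not in cells:
                continue
            keep.add(c)
            queue.extend(n for n in neighbors(c) if n in cells)
    return keep


# --- grid generation ---------------------------------------------------------

class TestInclusionGrid:
    def test_single_sphere_volume_within_5_percent(self):
        pts = generate_inclusion_grid(config())
        vol = len(pts) * 0.4**3
        assert vol == pytest.approx(BALL_VOLUME_R3, rel=0.05)

    def test_halved_spacing_grows_eightfold(self):
        coarse = generate_inclusion_grid(config(spacing=0.4))
        fine = generate_inclusion_grid(config(spacing=0.2))
        assert len(fine) / len(coarse) == pytest.approx(8.0, rel=0.1)

    def test_discretization_error_decreases_with_spacing(self):
        errors = []
        for s in (0.8, 0.4, 0.2):
            pts = generate_inclusion_grid(config(spacing=s))
            errors.append(abs(len(pts) * s**3 - BALL_VOLUME_R3) / BALL_VOLUME_R3)
        assert errors[0] > errors[1] > errors[2]

    def test_disjoint_spheres_are_additive(self):
        lone = generate_inclusion_grid(config())
        cfg2 = config(
            inclusion=(
                InclusionSphere((0.0, 0.0, 0.0), 3.0),
                InclusionSphere((100.0, 0.0, 0.0), 3.0),
            )
        )
        both = generate_inclusion_grid(cfg2)
        # the far sphere is offset by an exact lattice multiple of 0.4
        assert len(both) == 2 * len(lone)

    def test_all_points_inside_some_sphere(self):
        cfg = config(
            inclusion=(
                InclusionSphere((0.0, 0.0, 0.0), 3.0),
                InclusionSphere((2.0, 1.0, 0.5), 2.0),
            )
        )
        pts = generate_inclusion_grid(cfg)
        centers = np.array([s.center for s in cfg.inclusion])
        radii = np.array([s.radius for s in cfg.inclusion])
        d = np.linalg.norm(pts[:, None, :] - centers[None], axis=2)
        assert np.all((d <= radii[None] + 1e-9).any(axis=1))


# --- proximity pruning -------------------------------------------------------

class TestProximityPruning:
    def test_distant_receptor_leaves_points_unchanged(self):
        cfg = config()
        pts = generate_inclusion_grid(cfg)
        frame = np.array([[50.0, 0, 0]])
        out = prune_by_receptor_proximity(pts, frame, AtomGroup((0,)), cfg)
        assert len(out) == len(pts)

    def test_dense_receptor_saturates_in_vdw_mode(self):
        cfg = config(proximity_mode="vdw")
        pts = generate_inclusion_grid(cfg)
        ax = np.arange(-3, 3.5, 1.0)
        ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
        frame = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        group = AtomGroup(tuple(range(len(frame))))
        out = prune_by_receptor_proximity(
            pts, frame, group, cfg, elements=["C"] * len(frame)
        )
        assert len(out) == 0

    def test_center_mode_matches_brute_force(self):
        cfg = config()
        pts = generate_inclusion_grid(cfg)
        frame = np.array([[0.0, 0.0, 0.0], [1.0, 0.5, -0.5]])
        group = AtomGroup((0, 1))
        out = prune_by_receptor_proximity(pts, frame, group, cfg)
        brute = brute_proximity_prune(pts, frame, cfg.distance_cut)
        assert {tuple(np.round(p, 9)) for p in out} == {
            tuple(np.round(p, 9)) for p in brute
        }

    def test_vdw_mode_matches_brute_force_with_inflated_radii(self):
        cfg = config(proximity_mode="vdw")
        pts = generate_inclusion_grid(cfg)
        rng = np.random.default_rng(4)
        frame = rng.uniform(-2, 2, size=(5, 3))
        elements = ["C", "N", "O", "S", "C"]
        group = AtomGroup(tuple(range(5)))
        out = prune_by_receptor_proximity(pts, frame, group, cfg, elements=elements)
        keep = []
        for p in pts:
            ok = True
            for a, e in zip(frame, elements):
                r = cfg.vdw_radii[e] + cfg.distance_cut
                if np.linalg.norm(p - a) <= r:
                    ok = False
                    break
            if ok:
                keep.append(p)
        assert len(out) == len(keep)


# --- convex hull -------------------------------------------------------------

class TestConvexHull:
    def test_points_inside_tetrahedron_kept(self):
        frame = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
        pts = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        out = prune_outside_convex_hull(pts, frame, AtomGroup((0, 1, 2, 3)))
        assert len(out) == 2

    def test_all_outside_gives_empty(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        pts = np.array([[5.0, 5.0, 5.0], [-3.0, 0.0, 0.0]])
        out = prune_outside_convex_hull(pts, frame, AtomGroup((0, 1, 2, 3)))
        assert len(out) == 0

    def test_unit_cube_membership_matches_half_space_oracle(self):
        corners = np.array(
            [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
        )
        rng = np.random.default_rng(8)
        pts = rng.uniform(-0.5, 1.5, size=(1000, 3))
        out = prune_outside_convex_hull(pts, corners, AtomGroup(tuple(range(8))))
        inside = pts[
            np.all((pts >= -1e-9) & (pts <= 1 + 1e-9), axis=1)
        ]  # oracle: the cube's six half-spaces
        assert len(out) == len(inside)

    def test_degenerate_coplanar_hull_raises(self):
        frame = np.zeros((5, 3))
        frame[:, 0] = np.arange(5)
        frame[:, 1] = np.arange(5) * 2
        with pytest.raises(ValueError, match="degenerate"):
            prune_outside_convex_hull(np.zeros((1, 3)), frame, AtomGroup(tuple(range(5))))


# --- contiguity --------------------------------------------------------------

class TestContiguity:
    def lattice_block(self, n, spacing=0.4):
        ax = np.arange(n) * spacing
        ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)

    def test_full_block_unchanged(self):
        cfg = config(inclusion=(InclusionSphere((0.8, 0.8, 0.8), 0.1),))
        pts = self.lattice_block(5)
        out = contiguity_filter(pts, cfg)
        assert len(out) == len(pts)

    def test_single_isolated_point_removed(self):
        cfg = config()
        pts = np.vstack([self.lattice_block(5), [[10.0, 10.0, 10.0]]])
        out = contiguity_filter(pts, cfg)
        assert len(out) == len(pts) - 1

    def test_unseeded_component_removed_matches_bfs_oracle(self):
        cfg = config(inclusion=(InclusionSphere((0.8, 0.8, 0.8), 0.1),))
        far = self.lattice_block(4) + np.array([8.0, 0.0, 0.0])
        pts = np.vstack([self.lattice_block(5), far])
        out = contiguity_filter(pts, cfg)
        oracle = brute_contiguity(pts, 0.4, 3, [(0.8, 0.8, 0.8)])
        assert len(out) == len(oracle) == 125

    def test_matches_bfs_oracle_on_random_lattices(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            cells = rng.random((12, 12, 12)) < 0.45
            ijk = np.argwhere(cells)
            pts = ijk * 0.4
            seed_pt = tuple(pts[rng.integers(len(pts))])
            cfg = config(inclusion=(InclusionSphere(seed_pt, 0.1),))
            out = contiguity_filter(pts, cfg)
            oracle = brute_contiguity(pts, 0.4, 3, [seed_pt])
            assert len(out) == len(oracle), f"trial {trial}"

    def test_pipeline_stages_only_remove_points(self):
        shell, _ = make_pocket_shell(PocketShellSpec(atom_spacing=0.4))
        cfg = config()
        heavy = AtomGroup(tuple(range(shell.n_atoms)))
        pts0 = generate_inclusion_grid(cfg)
        pts1 = prune_by_receptor_proximity(pts0, shell.coords, heavy, cfg)
        pts2 = contiguity_filter(pts1, cfg)
        assert len(pts0) >= len(pts1) >= len(pts2)


# --- full pipeline -----------------------------------------------------------

class TestPocketVolume:
    def test_hollow_shell_recovers_analytic_cavity_within_10_percent(self):
        shell, analytic = make_pocket_shell(PocketShellSpec())
        cfg = config()
        heavy = AtomGroup(tuple(range(shell.n_atoms)))
        res = pocket_volume(shell.coords, heavy, cfg)
        assert res.volume == pytest.approx(analytic, rel=0.10)
        assert res.volume == res.n_points * 0.4**3

    def test_receptor_free_frame_attains_grid_volume(self):
        cfg = config()
        grid_vol = len(generate_inclusion_grid(cfg)) * 0.4**3
        res = pocket_volume(np.zeros((1, 3)), None, cfg)
        assert res.volume == pytest.approx(grid_vol)

    def test_volume_monotone_as_atoms_added(self):
        rng = np.random.default_rng(21)
        atoms = rng.uniform(-2.5, 2.5, size=(12, 3))
        cfg = config(distance_cut=0.8)
        prev = math.inf
        for n in range(1, 13):
            res = pocket_volume(atoms[:n], AtomGroup(tuple(range(n))), cfg)
            assert res.volume <= prev + 1e-9
            prev = res.volume

    def test_volume_never_exceeds_inclusion_region(self):
        cfg = config()
        upper = len(generate_inclusion_grid(cfg)) * cfg.spacing**3
        shell, _ = make_pocket_shell(PocketShellSpec())
        res = pocket_volume(shell.coords, AtomGroup(tuple(range(shell.n_atoms))), cfg)
        assert res.volume <= upper


# --- sampling, distributions, folds ------------------------------------------

class TestSamplingAndFolds:
    def test_ten_percent_of_5000(self):
        idx = sample_frames(5000, 0.1, seed=1)
        assert len(idx) == 500
        assert len(np.unique(idx)) == 500

    def test_fraction_one_returns_all(self):
        idx = sample_frames(37, 1.0, seed=0)
        np.testing.assert_array_equal(np.sort(idx), np.arange(37))

    def test_same_seed_same_subset(self):
        np.testing.assert_array_equal(
            sample_frames(1000, 0.1, seed=5), sample_frames(1000, 0.1, seed=5)
        )

    def test_distribution_bands(self):
        dist = volume_distribution([10.0, 30.0, 80.0], (0.0, 25.0, 70.0))
        assert dist.counts == (1, 1, 1)
        assert dist.n_frames == 3

    def test_all_zeros_land_in_first_bin(self):
        dist = volume_distribution([0.0] * 5)
        assert dist.counts == (5, 0, 0)

    def test_histogram_matches_numpy_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 100, 1000)
        dist = volume_distribution(v, (0.0, 25.0, 70.0))
        expected = np.histogram(v, bins=[0.0, 25.0, 70.0, np.inf])[0]
        assert dist.counts == tuple(expected)
        assert sum(dist.counts) == dist.n_frames

    def test_identical_distributions_give_unit_fold(self):
        v = [10.0] * 50 + [90.0] * 50
        assert large_volume_fold(v, list(v)) == pytest.approx(1.0)

    def test_constructed_eight_point_five_fold(self):
        alt = [90.0] * 17 + [10.0] * 983
        ref = [90.0] * 2 + [10.0] * 998
        assert large_volume_fold(alt, ref) == pytest.approx(8.5)

    def test_zero_reference_fraction_warns_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            fold = large_volume_fold([90.0, 10.0], [10.0, 10.0])
        assert math.isinf(fold)

    def test_triplicate_folds_are_seeded_and_reproducible(self):
        rng = np.random.default_rng(3)
        alt = np.where(rng.random(1000) < 0.017, 90.0, 10.0)
        ref = np.where(rng.random(1000) < 0.002, 90.0, 10.0)
        f1, fa1, fr1 = triplicate_large_volume_folds(alt, ref, seed=11)
        f2, fa2, fr2 = triplicate_large_volume_folds(alt, ref, seed=11)
        assert len(f1) == 3
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(fa1, fa2)
        assert all(len(x) == 3 for x in (fa1, fr1))
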
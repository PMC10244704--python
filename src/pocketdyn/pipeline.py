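"""Config-driven end-to-end runs: simulate → detect → volumes → contacts → stats.

A pipeline config names ≥1 conditions (e.g. an open vs. an occluded pocket),
each inheriting shared defaults. Per condition the pipeline runs the seeded
toy ensemble, scans every replicate for TS-like docking frames, measures
pocket volumes on triplicate random frame subsamples, and computes contact
occupancies; across the first two conditions it compares success counts with
the binomial construction and subsample large-volume fractions plus contact
occupancies with the equal-variance t-test. Every output TSV/JSON is listed
in a manifest with its SHA-256 checksum, the config hash and all seeds, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import ContactSpec, contact_series, contact_table, summarize_replicates
from .steering import SimParams, run_ensemble
from .stats import compare_success_counts, ttest_equal_var_two_tailed
from .synth import make_toy_association_system
from .tsdetect import TsCriteria, count_successes, outcome_table, scan_trajectory
from .volume import (
    GridConfig,
    InclusionSphere,
    large_volume_fraction,
    pocket_volume,
    sample_frames,
)
from .core import AtomGroup

_CONDITION_KEYS = {
    "pocket", "start_distance", "n_replicates", "n_steps", "dt_ps",
    "temperature_K", "friction_per_ps", "record_stride",
}
_TOP_KEYS = {"base_seed", "conditions", "defaults", "ts_criteria", "contact", "volume", "stats"}
_TS_KEYS = {"d_max", "attack_angle_center", "attack_angle_tol", "linearity_center", "linearity_tol"}
_CONTACT_KEYS = {"cutoff"}
_VOLUME_KEYS = {
    "spacing", "distance_cut", "contiguity", "hull", "proximity_mode",
    "spheres", "subsample_fraction", "n_subsamples", "threshold",
}
_STATS_KEYS = {"binomial_construction"}

_CONDITION_DEFAULTS = {
    "pocket": "open",
    "start_distance": 27.0,
    "n_replicates": 100,
    "n_steps": 20000,
    "dt_ps": 0.001,
    "temperature_K": 300.0,
    "friction_per_ps": 1.0,
    "record_stride": 200,
}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {', '.join(unknown)}")


@dataclass
class PipelineConfig:
    base_seed: int = 0
    conditions: dict[str, dict] = field(default_factory=dict)
    ts_criteria: TsCriteria = field(default_factory=TsCriteria)
    contact_cutoff: float = 4.5
    volume: dict = field(default_factory=dict)
    binomial_construction: str = "upper_tail_alt_at_ref_rate"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        _check_keys(data, _TOP_KEYS, "top level")
        conditions_in = data.get("conditions") or {}
        if not conditions_in:
            raise ValueError("config must define at least one condition")
        defaults = dict(_CONDITION_DEFAULTS)
        overrides = data.get("defaults") or {}
        _check_keys(overrides, _CONDITION_KEYS, "defaults")
        defaults.update(overrides)
        conditions = {}
        for name, block in conditions_in.items():
            block = block or {}
            _check_keys(block, _CONDITION_KEYS, f"condition {name!r}")
            merged = dict(defaults)
            merged.update(block)
            conditions[name] = merged

        ts_block = data.get("ts_criteria") or {}
        _check_keys(ts_block, _TS_KEYS, "ts_criteria")
        contact_block = data.get("contact") or {}
        _check_keys(contact_block, _CONTACT_KEYS, "contact")
        vol_block = dict(data.get("volume") or {})
        _check_keys(vol_block, _VOLUME_KEYS, "volume")
        stats_block = data.get("stats") or {}
        _check_keys(stats_block, _STATS_KEYS, "stats")

        return cls(
            base_seed=int(data.get("base_seed", 0)),
            conditions=conditions,
            ts_criteria=TsCriteria(**ts_block),
            contact_cutoff=float(contact_block.get("cutoff", 4.5)),
            volume=vol_block,
            binomial_construction=stats_block.get(
                "binomial_construction", "upper_tail_alt_at_ref_rate"
            ),
            raw=data,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def grid_config(self) -> GridConfig:
        v = self.volume
        spheres = tuple(
            InclusionSphere(tuple(s["center"]), float(s.get("radius", 3.0)))
            for s in v.get("spheres", [{"center": (0.0, 0.0, 0.0), "radius": 3.0}])
        )
        return GridConfig(
            spacing=float(v.get("spacing", 0.4)),
            distance_cut=float(v.get("distance_cut", 0.4)),
            contiguity_criterion=int(v.get("contiguity", 3)),
            convex_hull_exclusion=bool(v.get("hull", False)),
            proximity_mode=v.get("proximity_mode", "vdw"),
            inclusion=spheres,
        )

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all conditions and cross-condition statistics; returns the result
    bundle (also written as TSV/JSON under ``out_dir``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = config.grid_config()
    vfrac = float(config.volume.get("subsample_fraction", 0.1))
    n_sub = int(config.volume.get("n_subsamples", 3))
    threshold = float(config.volume.get("threshold", 70.0))

    bundle: dict = {
        "config_hash": config.config_hash(),
        "base_seed": config.base_seed,
        "version": __version__,
        "conditions": {},
    }
    files: list[Path] = []

    for ci, (name, cond) in enumerate(config.conditions.items()):
        try:
            system, forces = make_toy_association_system(
                pocket=cond["pocket"], start_distance=float(cond["start_distance"])
            )
            params = SimParams(
                dt_ps=float(cond["dt_ps"]),
                friction_per_ps=float(cond["friction_per_ps"]),
                temperature_K=float(cond["temperature_K"]),
                n_steps=int(cond["n_steps"]),
                record_stride=int(cond["record_stride"]),
            )
            seed = config.base_seed + 10000 * ci
            ensemble = run_ensemble(system, forces, params, int(cond["n_replicates"]), seed)
        except Exception as exc:
            raise RuntimeError(f"condition {name!r}, stage simulate: {exc}") from exc

        try:
            outcomes = []
            for rep, traj in enumerate(ensemble):
                _, outcome = scan_trajectory(
                    traj, system.ts_atom_map, config.ts_criteria, replicate_id=rep
                )
                outcomes.append(outcome)
            n_success = count_successes(outcomes)
        except Exception as exc:
            raise RuntimeError(f"condition {name!r}, stage ts-scan: {exc}") from exc

        try:
            heavy = AtomGroup(
                tuple(i for i, a in enumerate(system.topology) if a.is_heavy), "heavy"
            )
            pooled = np.concatenate([t.frames for t in ensemble], axis=0)
            n_pool = len(pooled)
            elements = [a.element for a in system.topology]
            sub_volumes = []
            for s in range(n_sub):
                idx = sample_frames(n_pool, vfrac, seed + 777 + s)
                results = [
                    pocket_volume(pooled[f], heavy, grid, elements, frame_index=int(f))
                    for f in idx
                ]
                sub_volumes.append(np.array([r.volume for r in results]))
            large_fracs = [large_volume_fraction(v, threshold) for v in sub_volumes]
        except Exception as exc:
            raise RuntimeError(f"condition {name!r}, stage volume: {exc}") from exc

        try:
            spec = ContactSpec(
                system.centroid_groups["methyl"],
                system.centroid_groups["lysine_n"],
                cutoff=config.contact_cutoff,
            )
            series = [
                contact_series(traj, spec, replicate_id=rep)
                for rep, traj in enumerate(ensemble)
            ]
            summary = summarize_replicates(series)
        except Exception as exc:
            raise RuntimeError(f"condition {name!r}, stage contacts: {exc}") from exc

        cdir = out_dir / name
        cdir.mkdir(exist_ok=True)
        p1 = cdir / "ts_replicates.tsv"
        _write_tsv(outcome_table(outcomes), p1)
        p2 = cdir / "volume_subsamples.tsv"
        _write_tsv(
            pd.DataFrame(
                {
                    "subsample": np.arange(n_sub),
                    "n_frames": [len(v) for v in sub_volumes],
                    "large_volume_fraction": large_fracs,
                    "mean_volume_A3": [float(v.mean()) for v in sub_volumes],
                }
            ),
            p2,
        )
        p3 = cdir / "contacts.tsv"
        _write_tsv(contact_table(series), p3)
        files += [p1, p2, p3]

        bundle["conditions"][name] = {
            "seed": seed,
            "n_replicates": int(cond["n_replicates"]),
            "n_success": n_success,
            "large_volume_fractions": [float(x) for x in large_fracs],
            "contact_fractions": [float(f) for f in summary.fractions],
            "contact_mean": summary.mean,
        }

    names = list(config.conditions)
    if len(names) >= 2:
        ref, alt = names[0], names[1]
        cref, calt = bundle["conditions"][ref], bundle["conditions"][alt]
        binom = compare_success_counts(
            cref["n_success"], cref["n_replicates"],
            calt["n_success"], calt["n_replicates"],
            construction=config.binomial_construction,
        )
        t_vol = ttest_equal_var_two_tailed(
            calt["large_volume_fractions"], cref["large_volume_fractions"]
        )
        t_contact = ttest_equal_var_two_tailed(
            calt["contact_fractions"], cref["contact_fractions"]
        )
        bundle["stats"] = {
            "reference": ref,
            "alternative": alt,
            "binomial": {
                "k": binom.k, "n": binom.n, "p0": binom.p0,
                "p_upper_tail": binom.p_upper_tail,
                "construction": binom.construction,
            },
            "ttest_large_volume": {
                "t": t_vol.t, "df": t_vol.df, "p_two_tailed": t_vol.p_two_tailed,
            },
            "ttest_contacts": {
                "t": t_contact.t, "df": t_contact.df, "p_two_tailed": t_contact.p_two_tailed,
            },
        }

    stats_path = out_dir / "stats.json"
    stats_path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    files.append(stats_path)

    manifest = {
        "config_hash": bundle["config_hash"],
        "base_seed": config.base_seed,
        "version": __version__,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return bundle
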
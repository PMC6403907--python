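"""End-to-end study orchestration: build -> embed -> simulate -> analyze.

A :class:`StudyConfig` describes a set of dendrimer recipes, the
temperatures, the replica count and the time spans; :func:`run_study`
produces per-dendrimer trajectories and the full set of analysis tables
(TSV), plus a manifest recording versions, seeds, parameters and output
hashes so a re-run with the same config is byte-reproducible.

The full study design (8 replicas x 30 ns production after 6 ns
equilibration at 600 K, temperatures 300 and 600 K) is expressible but
cluster-scale; :meth:`StudyConfig.desk` builds a desk-scale preset
(generation capped at 4, production capped at 2 ns) that exercises the
same code path in minutes.

Analysis outputs depend only on trajectory frames plus topology, never
on simulator internals: :func:`analyze_trajectories` is the single
analysis entry point used both after integration and in analysis-only
mode on externally supplied trajectory files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .dendrons import angle_correlations, dendron_angles, phase_labels
from .embedding import initial_coordinates
from .forcefield import ForceFieldParams
from .mobility import layer_table, mobility_series_set
from .relaxation import relaxation_table
from .simulate import SimulationConfig, integrate
from .topology import DendrimerRecipe, build_topology
from .torsion import frequency_profile, torsion_records
from .trajectory import Trajectory, read_trajectory, write_trajectory


@dataclass
class StudyConfig:
    """Study design: recipes x temperatures x replicas."""

    recipes: list
    temperatures: tuple = (300.0, 600.0)
    replicas: int = 8
    equilibration_ps: float = 6000.0
    production_ps: float = 30000.0
    coarse_save_ps: float = 10.0
    fine_save_ps: float | None = None
    collision_rate: float = 10.0
    seed: int = 0
    output_root: str = "study_output"

    def __post_init__(self):
        if self.replicas < 1:
            raise ValueError("need at least one replica")
        if self.equilibration_ps < 0 or self.production_ps <= 0:
            raise ValueError("spans must be positive")
        self.recipes = [
            r if isinstance(r, DendrimerRecipe) else DendrimerRecipe.from_dict(r)
            for r in self.recipes
        ]

    def replica_seed(self, recipe_idx: int, temp_idx: int, replica: int) -> int:
        """Distinct deterministic seed per (recipe, temperature, replica)."""
        return (int(self.seed) * 1000003 + recipe_idx * 10007 + temp_idx * 101 + replica) % (2**31)

    @classmethod
    def desk(cls, recipes, **kw) -> "StudyConfig":
        """Desk-scale preset: capped generation and spans, one temperature."""
        cfg = cls(
            recipes=recipes,
            temperatures=kw.pop("temperatures", (600.0,)),
            replicas=kw.pop("replicas", 1),
            equilibration_ps=kw.pop("equilibration_ps", 20.0),
            production_ps=kw.pop("production_ps", min(kw.pop("max_production_ps", 2000.0), 200.0)),
            coarse_save_ps=kw.pop("coarse_save_ps", 0.5),
            **kw,
        )
        for r in cfg.recipes:
            if r.generation > 4:
                raise ValueError("desk preset caps generation at 4")
        if cfg.production_ps > 2000.0:
            raise ValueError("desk preset caps production at 2 ns")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["temperatures"] = tuple(raw.get("temperatures", (300.0, 600.0)))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recipes"] = [
            {
                "family": r.family,
                "generation": r.generation,
                "representation": r.representation,
                "branch_multiplicity": r.branch_multiplicity,
                "seed": r.seed,
            }
            for r in self.recipes
        ]
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_trajectories(
    coarse: list[Trajectory],
    fine: list[Trajectory] | None,
    outdir,
    max_lag: int | None = None,
    dwell_threshold: float = 0.4,
) -> dict:
    """Run all analyses on replica trajectories; write TSVs, return paths.

    ``coarse`` carries positional statistics (mobility, relaxation,
    dendron angles); ``fine`` (optional) feeds the torsion counter.
    """
    os.makedirs(outdir, exist_ok=True)
    topo = coarse[0].topology
    paths = {}

    series_sets = [mobility_series_set(t) for t in coarse]
    flat = [s for ss in series_sets for s in ss]
    mob = layer_table(flat, topo)
    paths["mobility"] = os.path.join(outdir, "mobility.tsv")
    mob.to_csv(paths["mobility"], sep="\t", index=False)

    rel = relaxation_table(series_sets, spacing=coarse[0].spacing, max_lag=max_lag)
    paths["relaxation"] = os.path.join(outdir, "relaxation.tsv")
    rel.to_csv(paths["relaxation"], sep="\t", index=False)

    dend_rows = []
    corr_frames = []
    for rep, t in enumerate(coarse):
        aset = dendron_angles(t)
        summ = aset.summary()
        summ.insert(0, "replica", rep)
        dend_rows.append(summ)
        if t.n_frames >= 2 and np.all(aset.angles.std(axis=0) > 0):
            corr = angle_correlations(aset)
            lab = phase_labels(corr)
            lab.insert(0, "replica", rep)
            corr_frames.append(lab)
    paths["dendrons"] = os.path.join(outdir, "dendrons.tsv")
    pd.concat(dend_rows, ignore_index=True).to_csv(paths["dendrons"], sep="\t", index=False)
    if corr_frames:
        paths["dendron_correlations"] = os.path.join(outdir, "dendron_correlations.tsv")
        pd.concat(corr_frames, ignore_index=True).to_csv(
            paths["dendron_correlations"], sep="\t", index=False
        )

    if fine:
        records = []
        for t in fine:
            records.extend(torsion_records(t, dwell_threshold=dwell_threshold))
        if records:
            prof = frequency_profile(records)
            paths["torsions"] = os.path.join(outdir, "torsions.tsv")
            prof.to_csv(paths["torsions"], sep="\t", index=False)
    return paths


def run_study(config: StudyConfig, resume: bool = False) -> dict:
    """Run the full study; returns the manifest dict (also written to disk).

    Per (recipe, temperature): the topology is built and exported, every
    replica is embedded and integrated with its own seed, trajectories
    are written as XYZ, and the pooled analyses are emitted as TSVs.
    With ``resume=True`` existing trajectory files are loaded instead of
    re-simulated, so a partially failed run continues where it stopped.
    """
    from . import __version__ as pkg_version

    root = config.output_root
    os.makedirs(root, exist_ok=True)
    manifest = {"version": pkg_version, "config": config.to_dict(), "runs": []}

    for ri, recipe in enumerate(config.recipes):
        topo = build_topology(recipe)
        params = ForceFieldParams.for_family(recipe.family)
        for ti, temp in enumerate(config.temperatures):
            tag = f"{recipe.family}G{recipe.generation}_T{int(temp)}"
            rundir = os.path.join(root, tag)
            os.makedirs(rundir, exist_ok=True)
            run_entry = {"tag": tag, "seeds": [], "files": {}}
            topo.to_pdb(os.path.join(rundir, "topology.pdb"))
            topo.to_labels_json(os.path.join(rundir, "topology_labels.json"))

            coarse_trajs, fine_trajs = [], []
            for rep in range(config.replicas):
                seed = config.replica_seed(ri, ti, rep)
                run_entry["seeds"].append(seed)
                tpath = os.path.join(rundir, f"replica{rep}.xyz")
                fpath = os.path.join(rundir, f"replica{rep}_fine.xyz")
                if resume and os.path.exists(tpath):
                    coarse_trajs.append(
                        read_trajectory(tpath, topo, expected_spacing=config.coarse_save_ps)
                    )
                    if config.fine_save_ps and os.path.exists(fpath):
                        fine_trajs.append(
                            read_trajectory(fpath, topo, expected_spacing=config.fine_save_ps)
                        )
                    continue
                x0 = initial_coordinates(topo, seed=seed, params=params)
                sim = SimulationConfig(
                    temperature=temp,
                    equilibration_ps=config.equilibration_ps,
                    production_ps=config.production_ps,
                    coarse_save_ps=config.coarse_save_ps,
                    fine_save_ps=config.fine_save_ps,
                    collision_rate=config.collision_rate,
                    seed=seed,
                )
                result = integrate(topo, x0, sim, params=params)
                write_trajectory(result.coarse, tpath)
                coarse_trajs.append(result.coarse)
                if result.fine is not None:
                    write_trajectory(result.fine, fpath)
                    fine_trajs.append(result.fine)
                result.energies.to_csv(
                    os.path.join(rundir, f"replica{rep}_energies.tsv"), sep="\t", index=False
                )

            paths = analyze_trajectories(coarse_trajs, fine_trajs or None, rundir)
            for key, p in paths.items():
                run_entry["files"][key] = {"path": os.path.relpath(p, root), "sha256": _sha256(p)}
            for rep in range(config.replicas):
                p = os.path.join(rundir, f"replica{rep}.xyz")
                run_entry["files"][f"replica{rep}"] = {
                    "path": os.path.relpath(p, root),
                    "sha256": _sha256(p),
                }
            manifest["runs"].append(run_entry)

    with open(os.path.join(root, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
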
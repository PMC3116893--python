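"""End-to-end pipeline orchestration.

Stages run in dependency order on either user-supplied inputs or the
synthetic generators, every stage's randomness being derived from one
global seed. Each run writes per-stage TSV reports plus a ``manifest.json``
echoing the fully resolved configuration, the package version and a hash
of every output file, so a manifest suffices to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import energetics, ensemble_stats, interactions, nma, pockets as pk
from . import synthetic_data as synth
from .structio import (RegionMap, read_structure, select, write_structure)

logger = logging.getLogger(__name__)

ALL_STAGES = ("ensemble", "contacts", "energetics", "nma", "displace", "pockets")


@dataclass
class PipelineConfig:
    outdir: str = "modescope_run"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # inputs; None means "generate synthetically"
    trajectory: str | None = None
    structure: str | None = None
    energy_tables: dict[str, str] = field(default_factory=dict)
    region_config: str | None = None
    # synthetic-generation parameters
    n_residues: int = 60
    n_frames: int = 200
    ensemble_scale: float = 1.0
    # stage parameters
    enm_cutoff: float = 12.0
    n_modes: int = 97
    convergence_cutoff: float = 2.5
    convergence_seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    occupancy_threshold: float = 0.15
    contact_type: str = "hydrophobic"
    pocket_spacing: float = 0.8
    pocket_burial_min: int = 5
    pocket_min_points: int = 30
    displace_mode: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file."""
        cfg = cls()
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                parts = [p.strip() for p in value.split(",") if p.strip()]
                setattr(cfg, key, tuple(
                    int(p) if p.lstrip("-").isdigit() else p for p in parts))
            elif isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif isinstance(current, dict):
                label, _, p = value.partition(":")
                current[label.strip()] = p.strip()
            else:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; known: {ALL_STAGES}")
        if "pockets" in self.stages and self.structure is None \
                and "displace" not in self.stages and self.trajectory is not None:
            raise ValueError(
                "pockets stage needs a structure (give one, or enable the "
                "synthetic/displace path)"
            )


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region_map = (RegionMap.from_config(Path(config.region_config).read_text())
                  if config.region_config else None)

    # --- inputs -----------------------------------------------------------
    if config.trajectory is not None:
        traj = read_structure(config.trajectory, model_policy="all")
        structure = traj.frame(0)
    else:
        structure = synth.make_toy_chain(
            config.n_residues, seed=_stage_seed(config.seed, "chain"))
        modes0 = nma.compute_enm_modes(
            structure, cutoff=config.enm_cutoff, n_modes=None)
        traj = synth.sample_enm_ensemble(
            structure, modes0, scale=config.ensemble_scale,
            n_frames=config.n_frames,
            seed=_stage_seed(config.seed, "ensemble"))
    if config.structure is not None:
        pocket_structure = read_structure(config.structure)
    else:
        pocket_structure = synth.make_cavity_structure(
            seed=_stage_seed(config.seed, "cavity"))

    results: dict[str, str] = {}

    def _timed(stage):
        logger.info("stage %s ...", stage)
        return time.perf_counter()

    # --- ensemble statistics ---------------------------------------------
    if "ensemble" in config.stages:
        t0 = _timed("ensemble")
        series = ensemble_stats.rmsd_series(traj, reference="first")
        _write_tsv(pd.DataFrame({"time_ps": traj.times, "rmsd_A": series}),
                   outdir / "rmsd.tsv")
        report = ensemble_stats.convergence_analysis(
            traj, cutoff=config.convergence_cutoff,
            seeds=config.convergence_seeds)
        _write_tsv(pd.DataFrame({
            "seed": report.seeds,
            "n_references": report.n_references,
            "n_lone_references": report.n_lone_references,
        }), outdir / "convergence.tsv")
        pca_res = ensemble_stats.pca(traj)
        _write_tsv(pd.DataFrame({
            "mode": np.arange(1, len(pca_res.eigenvalues) + 1),
            "eigenvalue_A2": pca_res.eigenvalues,
            "cumulative_variance": pca_res.cumulative_variance,
        }), outdir / "pca_spectrum.tsv")
        tensors = ensemble_stats.fluctuation_tensors(traj)
        _write_tsv(pd.DataFrame({
            "atom_index": tensors.atom_indices,
            "msf_A2": tensors.msf,
        }), outdir / "fluctuations.tsv")
        results["ensemble_seconds"] = f"{time.perf_counter() - t0:.2f}"
        representative = report.representative_frames()
    else:
        representative = [0]

    # --- contacts ---------------------------------------------------------
    if "contacts" in config.stages:
        t0 = _timed("contacts")
        res_ids = traj.topology.res_ids
        mid = int(np.median(res_ids))
        try:
            region_a = select(traj.topology, (int(res_ids.min()), mid),
                              region_map=region_map)
            region_b = select(traj.topology, (mid + 1, int(res_ids.max())),
                              region_map=region_map)
            occ = interactions.occupancy_map(
                traj, region_a, region_b,
                contact_type=config.contact_type,
                threshold=config.occupancy_threshold)
            _write_tsv(occ.table, outdir / "occupancy.tsv")
        except ValueError as exc:
            raise RuntimeError(f"contacts stage failed: {exc}") from exc
        _, per_res = interactions.sasa(traj.topology, traj.frames[0])
        _write_tsv(per_res, outdir / "sasa.tsv")
        results["contacts_seconds"] = f"{time.perf_counter() - t0:.2f}"

    # --- energetics -------------------------------------------------------
    if "energetics" in config.stages:
        t0 = _timed("energetics")
        if config.energy_tables:
            tables = {label: energetics.parse_energy_table(p, label=label)
                      for label, p in config.energy_tables.items()}
        else:
            tables = {}
            for i, label in enumerate(("wt", "mut")):
                rng_seed = _stage_seed(config.seed, f"energy_{label}")
                comp = {}
                for j, col in enumerate(energetics.ENTHALPY_COLUMNS
                                        + energetics.ENTROPY_COLUMNS):
                    comp[col] = synth.make_ar1_series(
                        mean=(-100.0 + 10 * j + 5 * i), sigma=4.0, phi=0.6,
                        n=config.n_frames, seed=rng_seed + j)
                tables[label] = energetics.EnergySeries(
                    times=np.arange(1.0, config.n_frames + 1.0) * 20.0,
                    components=pd.DataFrame(comp), label=label)
        rows = []
        estimates = {}
        for label, series in tables.items():
            est = energetics.free_energy_estimate(series)
            estimates[label] = est
            for quantity in ("G", "H", "TS"):
                sc = getattr(est, quantity)
                rows.append({"system": label, "quantity": quantity,
                             "mean_kcal_mol": sc.mean, "error_kcal_mol": sc.error,
                             "tau_frames": sc.tau})
        _write_tsv(pd.DataFrame(rows), outdir / "free_energy.tsv")
        if {"wt", "mut"} <= set(estimates):
            change = energetics.stability_change(estimates["mut"], estimates["wt"])
            _write_tsv(pd.DataFrame([{
                "dG": change.dG.value, "dG_err": change.dG.error,
                "dH": change.dH.value, "dH_err": change.dH.error,
                "dTS": change.dTS.value, "dTS_err": change.dTS.error,
            }]), outdir / "stability_change.tsv")
        results["energetics_seconds"] = f"{time.perf_counter() - t0:.2f}"

    # --- NMA on representative conformations ------------------------------
    mode_sets = []
    if "nma" in config.stages:
        t0 = _timed("nma")
        conformers = [traj.frame(i) for i in representative[:4]] or [structure]
        labels = [f"frame{i}" for i in representative[:4]] or ["input"]
        mode_sets = [
            nma.compute_enm_modes(c, cutoff=config.enm_cutoff,
                                  n_modes=config.n_modes)
            for c in conformers
        ]
        n_res = len(np.unique(traj.topology.res_ids))
        subset = np.arange(traj.topology.n_atoms)
        frag_a = select(traj.topology,
                        (int(traj.topology.res_ids.min()),
                         int(np.percentile(traj.topology.res_ids, 30))))
        metrics = nma.pooled_mode_metrics(
            mode_sets, subset=subset, fragments={"nterm": frag_a},
            labels=labels)
        _write_tsv(metrics, outdir / "mode_metrics.tsv")
        results["n_pooled_modes"] = str(len(metrics))
        results["nma_seconds"] = f"{time.perf_counter() - t0:.2f}"

    # --- mode displacement -------------------------------------------------
    if "displace" in config.stages:
        t0 = _timed("displace")
        if not mode_sets:
            mode_sets = [nma.compute_enm_modes(
                traj.frame(representative[0]), cutoff=config.enm_cutoff,
                n_modes=min(config.n_modes, 3 * traj.topology.n_atoms - 6))]
        displaced = nma.displace_along_mode(
            traj.frame(representative[0]), mode_sets[0],
            mode_index=config.displace_mode)
        write_structure(displaced, outdir / "displaced_conformers.pdb")
        results["displace_seconds"] = f"{time.perf_counter() - t0:.2f}"

    # --- pockets ------------------------------------------------------------
    if "pockets" in config.stages:
        t0 = _timed("pockets")
        pocket_set = pk.detect_pockets(
            pocket_structure, spacing=config.pocket_spacing,
            burial_min=config.pocket_burial_min,
            min_points=config.pocket_min_points)
        rows = [{"pocket_id": p.id, "n_points": p.n_points,
                 "volume_A3": p.volume,
                 "centroid_x": p.centroid[0], "centroid_y": p.centroid[1],
                 "centroid_z": p.centroid[2]} for p in pocket_set.pockets]
        _write_tsv(pd.DataFrame(
            rows, columns=["pocket_id", "n_points", "volume_A3",
                           "centroid_x", "centroid_y", "centroid_z"]),
            outdir / "pockets.tsv")
        results["pockets_seconds"] = f"{time.perf_counter() - t0:.2f}"

    # --- manifest -----------------------------------------------------------
    manifest = {
        "package": "modescope",
        "version": __version__,
        "config": _jsonable(asdict(config)),
        "stage_info": results,
        "outputs": {},
    }
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
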
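"""Orchestration: run every analysis stage over one or many trajectories.

A :class:`RunManifest` names the input files per run (trajectory, topology
sidecar, optional per-frame energies, optional ground truth) plus a shared
:class:`~gagconf.core.AnalysisConfig`.  :func:`run_pipeline` executes the
six stages — torsions, H-bonds, pucker, RMSD, clustering, energy landscape
— for every run, isolates per-run failures, writes one report directory
per run, and aggregates a :class:`CrossRunSummary` with the
clusters-vs-sulfation regressions.
"""

from __future__ import annotations

import json
import sys
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .core import AnalysisConfig, Trajectory
from . import cluster as cl
from . import hbonds as hb
from . import landscape as ls
from . import pucker as pk
from . import torsions as ts
from .io import (
    read_dcd,
    read_energies_csv,
    read_multi_model_pdb,
    read_topology_json,
    write_report,
)

__all__ = [
    "ALL_STAGES",
    "RunEntry",
    "RunManifest",
    "CrossRunSummary",
    "linear_r2",
    "run_pipeline",
    "load_manifest",
    "analyze_trajectory",
]

ALL_STAGES = ("torsions", "hbonds", "pucker", "rmsd", "cluster", "landscape")

#: Frame budgets keeping desk-scale runs fast: clustering uses a sieve so
#: at most this many frames enter the exact pairwise-RMSD stage, and toy
#: quenching (only used when no energies file is supplied) is applied to a
#: strided subset of at most this many frames.
_MAX_EXACT_FRAMES = 1000
_MAX_QUENCH_FRAMES = 30
_QUENCH_CG_ITER = 200


@dataclass(frozen=True)
class RunEntry:
    """One trajectory to analyze."""

    run_id: str
    trajectory: str
    topology: str
    energies: Optional[str] = None
    ground_truth: Optional[str] = None


@dataclass
class RunManifest:
    """All runs plus shared analysis configuration and output directory."""

    runs: list
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "gagconf_out"
    stages: tuple = ALL_STAGES

    def __post_init__(self):
        if not self.runs:
            raise ValueError("empty manifest: no runs to analyze")
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate run ids {dup}")
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class CrossRunSummary:
    """Aggregated statistics plus clusters-vs-sulfates regressions.

    ``per_run`` maps run id to that run's key numbers (or its error
    message).  ``r2_overall`` and ``r2_per_linkage`` regress the number of
    conformational clusters on the number of sulfate groups — overall and
    within each linkage class — via ordinary least squares (``None`` where
    too few successful runs exist or the predictor is constant).
    """

    per_run: dict
    r2_overall: Optional[float]
    r2_per_linkage: dict
    failed_runs: list


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the OLS fit of y on x.

    Requires ≥3 points and non-constant x.  A constant y gives 0.0 (the
    fit explains none of a zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("linear_r2 needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx < 1e-300:
        raise ValueError("zero variance in x: regression undefined")
    syy = float(yc @ yc)
    if syy == 0.0:
        return 0.0
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    return 1.0 - float(resid @ resid) / syy


def _load_trajectory(entry: RunEntry) -> Trajectory:
    traj_path = Path(entry.trajectory)
    if traj_path.suffix.lower() == ".dcd":
        topology = read_topology_json(entry.topology)
        traj = read_dcd(topology, traj_path)
    else:
        traj = read_multi_model_pdb(traj_path, entry.topology)
    if entry.energies is not None:
        energies = read_energies_csv(entry.energies)
        if len(energies) != traj.n_frames:
            raise ValueError(
                f"energies file has {len(energies)} rows for "
                f"{traj.n_frames} frames"
            )
        traj.energies = np.asarray(energies, dtype=float)
    return traj


def _landscape_energies(traj: Trajectory) -> np.ndarray:
    """Per-frame energies for the landscape stage.

    Supplied energies are used verbatim.  Without them, the documented toy
    force field is built from frame 0 and a strided subset of frames is
    quenched (steepest descent then conjugate gradient); remaining frames
    take the energy of their nearest quenched neighbor in time.
    """
    if traj.energies is not None:
        return traj.energies
    ff = ls.ToyForceField.from_reference(traj.topology, traj.coords[0])
    stride = max(1, int(np.ceil(traj.n_frames / _MAX_QUENCH_FRAMES)))
    idx = np.arange(0, traj.n_frames, stride)
    quenched = np.array([
        ls.quench(traj.coords[f], traj.topology, ff,
                  max_cg_iter=_QUENCH_CG_ITER)[1] for f in idx
    ])
    nearest = np.clip(np.round(np.arange(traj.n_frames) / stride).astype(int),
                      0, len(idx) - 1)
    return quenched[nearest]


def analyze_trajectory(traj: Trajectory, config: AnalysisConfig = None,
                       stages: tuple = ALL_STAGES) -> dict:
    """Run the requested stages on one loaded trajectory.

    Returns the stage-results dict accepted by
    :func:`gagconf.io.write_report`.  Stages are independent: disabling one
    never changes another's output.
    """
    config = config or AnalysisConfig()
    results: dict = {}

    if "torsions" in stages:
        series = ts.extract_phi_psi(traj)
        grid = ts.density_grid(series, config.torsion_bin_width)
        results["torsions"] = {
            "series": series,
            "grid": grid,
            "summary": ts.summarize(grid, series),
        }

    if "hbonds" in stages:
        criteria = hb.HBondCriteria.from_config(config)
        records = hb.detect_hbonds_trajectory(traj, criteria)
        results["hbonds"] = {
            "occupancy": hb.occupancy(records, traj.n_frames),
            "bridging": hb.bridging_from_records(records, traj.topology),
            "coordination": hb.water_coordination(records, traj.topology,
                                                  traj.n_frames),
        }

    if "pucker" in stages:
        results["pucker"] = pk.pucker_series(traj)

    if "rmsd" in stages:
        results["rmsd"] = cl.rmsd_to_reference(
            traj, reference_frame="first",
            atom_subset=traj.topology.heavy_solute_ids())

    if "cluster" in stages:
        stride = max(1, int(np.ceil(traj.n_frames / _MAX_EXACT_FRAMES)))
        results["cluster"] = cl.cluster_trajectory(
            traj, epsilon=config.cluster_epsilon, stride=stride)

    if "landscape" in stages:
        model = ls.pca_frames(traj)
        energies = _landscape_energies(traj)
        results["landscape"] = {
            "pca": model,
            "landscape": ls.build_landscape(model, energies,
                                            config.landscape_grid),
        }
    return results


def _run_summary_row(traj: Trajectory, results: dict) -> dict:
    row: dict = {"status": "ok", "n_frames": traj.n_frames}
    row["n_sulfates"] = traj.topology.n_sulfate_groups()
    row["linkage_kind"] = (traj.topology.linkage.kind
                           if traj.topology.linkage else None)
    if "torsions" in results:
        tsum = results["torsions"]["summary"]
        row["preferred_phi_psi_deg"] = [list(p) for p in tsum.preferred]
        row["n_modes"] = tsum.n_modes
    if "hbonds" in results:
        row["mean_intra_hbond_count"] = \
            results["hbonds"]["occupancy"].mean_intra_count
    if "pucker" in results:
        row["pucker_proportions"] = [
            dict(sorted(p.items()))
            for p in results["pucker"].proportions
        ]
    if "cluster" in results:
        row["n_clusters"] = results["cluster"].n_clusters
    return row


def run_pipeline(manifest: RunManifest, log=None) -> CrossRunSummary:
    """Execute all configured stages for every run in the manifest.

    A failure in one run is logged and recorded; the remaining runs still
    complete.  Each run writes its report files under
    ``out_dir/<run_id>/``; the aggregated summary (with full provenance:
    analysis config, package and library versions) is written to
    ``out_dir/cross_run_summary.json``.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    out_root = Path(manifest.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    per_run: dict = {}
    failed: list = []

    for entry in manifest.runs:
        run_dir = out_root / entry.run_id
        try:
            traj = _load_trajectory(entry)
            results = analyze_trajectory(traj, manifest.config,
                                         manifest.stages)
            write_report(results, run_dir)
            per_run[entry.run_id] = _run_summary_row(traj, results)
            log(f"[{entry.run_id}] ok ({traj.n_frames} frames)")
        except Exception as exc:
            failed.append(entry.run_id)
            per_run[entry.run_id] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
            }
            run_dir.mkdir(parents=True, exist_ok=True)
            (run_dir / "error.log").write_text(traceback.format_exc())
            log(f"[{entry.run_id}] FAILED: {exc}")

    ok_rows = [(rid, row) for rid, row in per_run.items()
               if row.get("status") == "ok" and "n_clusters" in row]
    r2_overall = _safe_r2(
        [row["n_sulfates"] for _, row in ok_rows],
        [row["n_clusters"] for _, row in ok_rows],
    )
    r2_per_linkage: dict = {}
    for kind in ("beta_1_3", "beta_1_4"):
        rows = [row for _, row in ok_rows if row["linkage_kind"] == kind]
        r2_per_linkage[kind] = _safe_r2(
            [row["n_sulfates"] for row in rows],
            [row["n_clusters"] for row in rows],
        )

    summary = CrossRunSummary(per_run=per_run, r2_overall=r2_overall,
                              r2_per_linkage=r2_per_linkage,
                              failed_runs=sorted(failed))
    doc = {
        "provenance": {
            "gagconf_version": _pkg_version,
            "numpy_version": np.__version__,
            "python_version": sys.version.split()[0],
            "config": asdict(manifest.config),
            "stages": list(manifest.stages),
            "runs": [asdict(e) for e in manifest.runs],
        },
        "per_run": per_run,
        "regressions": {
            "n_clusters_vs_n_sulfates_r2_overall": r2_overall,
            "n_clusters_vs_n_sulfates_r2_per_linkage": r2_per_linkage,
        },
        "failed_runs": sorted(failed),
    }
    (out_root / "cross_run_summary.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True, default=float) + "\n")
    return summary


def _safe_r2(x, y) -> Optional[float]:
    try:
        return linear_r2(x, y)
    except ValueError:
        return None


def load_manifest(path) -> RunManifest:
    """Parse a YAML manifest.

    Schema::

        out_dir: results
        stages: [torsions, hbonds, pucker, rmsd, cluster, landscape]  # optional
        config:              # optional, AnalysisConfig fields
          hbond_distance_cutoff: 3.0
          cluster_epsilon: 2.0
        runs:
          - id: c4s_b13
            trajectory: c4s.pdb       # or .dcd
            topology: c4s.top.json
            energies: c4s.energies.csv   # optional
            ground_truth: c4s.truth.json # optional
    """
    import yaml
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "runs" not in doc:
        raise ValueError(f"{path}: manifest must be a mapping with a 'runs' list")
    base = Path(path).parent

    def resolve(p):
        return None if p is None else str((base / p).resolve()
                                          if not Path(p).is_absolute()
                                          else Path(p))

    runs = []
    for i, r in enumerate(doc["runs"] or []):
        for key in ("id", "trajectory", "topology"):
            if key not in r:
                raise ValueError(f"{path}: run #{i} missing field {key!r}")
        runs.append(RunEntry(
            run_id=str(r["id"]),
            trajectory=resolve(r["trajectory"]),
            topology=resolve(r["topology"]),
            energies=resolve(r.get("energies")),
            ground_truth=resolve(r.get("ground_truth")),
        ))
    cfg_fields = doc.get("config") or {}
    allowed = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(cfg_fields) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    config = AnalysisConfig(**cfg_fields)
    for entry in runs:
        for p in (entry.trajectory, entry.topology, entry.energies,
                  entry.ground_truth):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
    return RunManifest(
        runs=runs,
        config=config,
        out_dir=str(base / doc["out_dir"]) if "out_dir" in doc
        and not Path(doc["out_dir"]).is_absolute() else doc.get(
            "out_dir", str(base / "gagconf_out")),
        stages=tuple(doc.get("stages", ALL_STAGES)),
    )
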
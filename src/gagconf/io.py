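"""File formats: multi-model PDB, DCD, topology sidecar JSON, reports.

The trajectory formats carry coordinates only; chemistry (bonds, moieties,
H-bond roles, partial charges, the glycosidic linkage) travels in a JSON
sidecar with the versioned schema ``gagconf-topology/1``, because PDB and
DCD encode none of it.  Coordinates are Å throughout; PDB round trips are
exact to the format's 10⁻³ Å precision and DCD round trips to float32.

MDAnalysis provides the underlying PDB/DCD engines; a light pre-scan of
PDB text enforces this package's stricter contract (per-MODEL atom-count
consistency, malformed-line reporting with line numbers).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import AtomRecord, LinkageSpec, Topology, TopologyError, Trajectory

__all__ = [
    "TOPOLOGY_SCHEMA",
    "write_topology_json",
    "read_topology_json",
    "write_multi_model_pdb",
    "read_multi_model_pdb",
    "write_dcd",
    "read_dcd",
    "read_energies_csv",
    "write_energies_csv",
    "write_report",
    "write_ground_truth_json",
    "read_ground_truth_json",
]

TOPOLOGY_SCHEMA = "gagconf-topology/1"


# --------------------------------------------------------------------------
# topology sidecar JSON
# --------------------------------------------------------------------------


def write_topology_json(topology: Topology, path) -> None:
    """Serialize a topology to the ``gagconf-topology/1`` sidecar schema."""
    doc = {
        "format": TOPOLOGY_SCHEMA,
        "atoms": [
            {
                "id": a.atom_id,
                "name": a.name,
                "element": a.element,
                "residue_index": a.residue_index,
                "residue_name": a.residue_name,
                "moiety": a.moiety,
                "charge": a.charge,
                "hbond_role": sorted(a.hbond_role),
            }
            for a in topology.atoms
        ],
        "bonds": sorted(sorted(b) for b in topology.bonds),
        "rings": [list(r) for r in topology.rings],
        "linkage": None if topology.linkage is None else {
            "kind": topology.linkage.kind,
            "phi_atoms": list(topology.linkage.phi_atoms),
            "psi_atoms": list(topology.linkage.psi_atoms),
        },
        "water_residue_indices": sorted(topology.water_residue_indices),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_topology_json(path) -> Topology:
    """Parse a ``gagconf-topology/1`` sidecar into a validated Topology."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TopologyError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("format") != TOPOLOGY_SCHEMA:
        raise TopologyError(
            f"{path}: unsupported topology format {doc.get('format')!r} "
            f"(expected {TOPOLOGY_SCHEMA!r})"
        )
    required = {"id", "name", "element", "residue_index", "residue_name",
                "moiety"}
    atoms = []
    for entry in doc.get("atoms", []):
        missing = required - set(entry)
        if missing:
            raise TopologyError(
                f"{path}: atom entry {entry.get('id', '?')} missing fields "
                f"{sorted(missing)}"
            )
        atoms.append(AtomRecord(
            atom_id=int(entry["id"]),
            name=str(entry["name"]),
            element=str(entry["element"]),
            residue_index=int(entry["residue_index"]),
            residue_name=str(entry["residue_name"]),
            moiety=str(entry["moiety"]),
            charge=float(entry.get("charge", 0.0)),
            hbond_role=frozenset(entry.get("hbond_role", ())),
        ))
    linkage = None
    if doc.get("linkage") is not None:
        lk = doc["linkage"]
        linkage = LinkageSpec(kind=lk["kind"],
                              phi_atoms=tuple(lk["phi_atoms"]),
                              psi_atoms=tuple(lk["psi_atoms"]))
    return Topology(
        atoms=atoms,
        bonds={frozenset(b) for b in doc.get("bonds", [])},
        rings=[tuple(r) for r in doc.get("rings", [])],
        linkage=linkage,
        water_residue_indices=set(doc.get("water_residue_indices", [])),
    )


def _check_annotation_coverage(topology: Topology, names, resids) -> None:
    """Hard error naming the first trajectory atom the sidecar lacks."""
    if len(names) != topology.n_atoms:
        raise TopologyError(
            f"coordinate file has {len(names)} atoms but the topology "
            f"annotation describes {topology.n_atoms}"
        )
    for a, (name, res) in zip(topology.atoms, zip(names, resids)):
        if a.name != name or a.residue_index != res:
            raise TopologyError(
                f"annotation mismatch at atom id {a.atom_id}: file has "
                f"{name!r} in residue {res}, annotation has {a.name!r} in "
                f"residue {a.residue_index}"
            )


# --------------------------------------------------------------------------
# multi-model PDB
# --------------------------------------------------------------------------


def _prescan_pdb(path) -> int:
    """Validate PDB text; returns the atom count per model.

    Raises on malformed ATOM/HETATM lines (with 1-based line number) and on
    models whose atom counts disagree (naming the offending MODEL).
    """
    counts = []        # (model_serial, n_atoms)
    current = None     # model serial or "1" for implicit single model
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current is not None:
                    counts.append((current, n))
                try:
                    current = line.split()[1]
                except IndexError:
                    current = str(len(counts) + 1)
                n = 0
            elif rec == "ENDMDL":
                if current is not None:
                    counts.append((current, n))
                    current, n = None, 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = "1"
                    n = 0
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    if not line[12:16].strip():
                        raise ValueError("empty atom name")
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: malformed ATOM/HETATM record at line "
                        f"{lineno}: {line.rstrip()!r} ({exc})"
                    ) from exc
                n += 1
    if current is not None:
        counts.append((current, n))
    if not counts:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    ref_model, ref = counts[0]
    for model, cnt in counts[1:]:
        if cnt != ref:
            raise ValueError(
                f"{path}: MODEL {model} has {cnt} atoms, expected {ref} "
                f"(as in MODEL {ref_model})"
            )
    return ref


def read_multi_model_pdb(path, topology_annotation) -> Trajectory:
    """Read a multi-model PDB plus its topology sidecar into a Trajectory.

    ``topology_annotation`` is the path of the ``gagconf-topology/1`` JSON
    sidecar; the file's atoms must match it one-for-one (hard error naming
    the first mismatching atom otherwise).  A file without MODEL records is
    read as a single frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    _prescan_pdb(path)
    topology = read_topology_json(topology_annotation)
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = [a.name for a in u.atoms]
        resids = [int(r) - 1 for r in u.atoms.resids]  # PDB is 1-based
        _check_annotation_coverage(topology, names, resids)
        coords = np.stack([u.atoms.positions.astype(float).copy()
                           for _ in u.trajectory])
    return Trajectory(topology=topology, coords=coords)


def write_multi_model_pdb(traj: Trajectory, path) -> None:
    """Write every frame as one MODEL of a PDB file (10⁻³ Å precision)."""
    import MDAnalysis as mda
    top = traj.topology
    resdict = {}
    for a in top.atoms:
        resdict.setdefault(a.residue_index, a.residue_name)
    resindices = [a.residue_index for a in top.atoms]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=top.n_atoms,
            n_residues=len(resdict),
            atom_resindex=resindices,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in top.atoms])
        u.add_TopologyAttr("elements", [a.element for a in top.atoms])
        u.add_TopologyAttr("resnames",
                           [resdict[i][:4] for i in sorted(resdict)])
        u.add_TopologyAttr("resids", [i + 1 for i in sorted(resdict)])
        with mda.coordinates.PDB.PDBWriter(str(path), multiframe=True,
                                           n_atoms=top.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)


# --------------------------------------------------------------------------
# DCD
# --------------------------------------------------------------------------


def write_dcd(traj: Trajectory, path) -> None:
    """Write frames to a CHARMM/NAMD-style DCD (float32 coordinates)."""
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.DCD.DCDWriter(str(path),
                                           n_atoms=traj.n_atoms) as w:
            u = mda.Universe.empty(n_atoms=traj.n_atoms, trajectory=True)
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)


def read_dcd(topology: Topology, path) -> Trajectory:
    """Read a DCD against an in-memory topology.

    Errors if the file's atom count disagrees with the topology (stating
    expected vs found) or if the file is truncated mid-frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DCD file not found: {path}")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            reader = DCDReader(str(path))
        except Exception as exc:
            raise ValueError(f"{path}: unreadable DCD file ({exc})") from exc
        with reader:
            if reader.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"{path}: atom-count mismatch: topology expects "
                    f"{topology.n_atoms} atoms, DCD contains {reader.n_atoms}"
                )
            try:
                coords = np.stack([ts.positions.astype(float).copy()
                                   for ts in reader])
            except Exception as exc:
                raise ValueError(
                    f"{path}: truncated or corrupt DCD frame data ({exc})"
                ) from exc
    declared = _dcd_declared_frames(path)
    if declared is not None and len(coords) != declared:
        raise ValueError(
            f"{path}: truncated DCD: header declares {declared} frames but "
            f"only {len(coords)} are present"
        )
    return Trajectory(topology=topology, coords=coords)


def _dcd_declared_frames(path) -> Optional[int]:
    """NSET (frame count) from the raw DCD header, or None if unreadable.

    The reader infers its frame count from the file size, so a file
    truncated on a frame boundary parses silently; the header's declared
    count exposes the loss.
    """
    import struct
    with open(path, "rb") as fh:
        head = fh.read(12)
    if len(head) < 12:
        return None
    for endian in ("<", ">"):
        size, magic = struct.unpack(endian + "i4s", head[:8])
        if size == 84 and magic == b"CORD":
            return struct.unpack(endian + "i", head[8:12])[0]
    return None


# --------------------------------------------------------------------------
# per-frame energies CSV
# --------------------------------------------------------------------------


def write_energies_csv(energies: np.ndarray, path) -> None:
    pd.DataFrame({
        "frame": np.arange(len(energies)),
        "energy_kcal_mol": np.asarray(energies, dtype=float),
    }).to_csv(path, index=False)


def read_energies_csv(path) -> np.ndarray:
    """Read per-frame energies (kcal/mol) from a one- or two-column CSV."""
    df = pd.read_csv(path)
    if "energy_kcal_mol" in df.columns:
        return df["energy_kcal_mol"].to_numpy(dtype=float)
    numeric = df.select_dtypes("number")
    if numeric.shape[1] == 0:
        raise ValueError(f"{path}: no numeric energy column found")
    return numeric.iloc[:, -1].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# ground-truth JSON (synthetic runs)
# --------------------------------------------------------------------------


def write_ground_truth_json(truth, path) -> None:
    doc = {
        "component": [int(c) for c in truth.component],
        "phi": [float(v) for v in truth.phi],
        "psi": [float(v) for v in truth.psi],
        "hbond_status": {
            k: [bool(b) for b in v] for k, v in sorted(truth.hbond_status.items())
        },
        "bond_water_residue": {
            k: int(v) for k, v in sorted(truth.bond_water_residue.items())
        },
        "inverted_chair": [bool(b) for b in truth.inverted_chair],
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def read_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# report writer
# --------------------------------------------------------------------------


def _grid_frame(matrix: np.ndarray, row_labels, col_labels) -> pd.DataFrame:
    return pd.DataFrame(matrix, index=row_labels, columns=col_labels)


def _round6(x):
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    if isinstance(x, (float, np.floating)):
        return float(round(float(x), 10))
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def write_report(results: dict, out_dir) -> list:
    """Write CSV/JSON outputs for the supplied stage results.

    ``results`` maps stage names to stage outputs:

    ``torsions``
        dict with ``series`` (TorsionSeries), ``grid`` (TorsionDensityGrid)
        and ``summary`` (TorsionSummary).
    ``hbonds``
        dict with ``occupancy`` (OccupancySummary), ``bridging`` (list of
        BridgingWaterRecord) and ``coordination`` (water_coordination dict).
    ``pucker``
        PuckerSeriesResult.
    ``rmsd``
        per-frame array (Å).
    ``cluster``
        ClusterResult.
    ``landscape``
        dict with ``pca`` (PCAModel) and ``landscape`` (EnergyLandscape).

    Per-frame series become CSV files, matrices become CSV matrices with
    axis annotations, and scalar statistics are aggregated in
    ``summary.json``.  Column ordering is fixed, so identical inputs yield
    byte-identical outputs.  Returns the list of files written.
    """
    known = ("torsions", "hbonds", "pucker", "rmsd", "cluster", "landscape")
    present = {k: v for k, v in results.items() if v is not None}
    unknown = set(present) - set(known)
    if unknown:
        raise ValueError(f"unknown stage results {sorted(unknown)}")
    if not present:
        raise ValueError("nothing to report: no stage results supplied")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    summary: dict = {}

    def emit_csv(name, df: pd.DataFrame, index=False):
        p = out / name
        df.to_csv(p, index=index, float_format="%.6f")
        written.append(p)

    if "torsions" in present:
        t = present["torsions"]
        series, grid, tsum = t["series"], t["grid"], t["summary"]
        emit_csv("torsion_series.csv", pd.DataFrame({
            "frame": np.arange(series.n_frames),
            "phi_deg": series.phi,
            "psi_deg": series.psi,
        }))
        centers = [f"{c:.1f}" for c in grid.bin_centers()]
        emit_csv("torsion_density.csv",
                 _grid_frame(grid.probabilities, centers, centers),
                 index=True)
        summary["torsions"] = {
            "linkage_kind": series.linkage_kind,
            "n_frames": series.n_frames,
            "preferred_phi_psi_deg": [list(p) for p in tsum.preferred],
            "n_modes": tsum.n_modes,
            "spread_phi_circular_sd_deg": tsum.spread_phi_circ_std,
            "spread_phi_interpercentile_deg": tsum.spread_phi_arc_5_95,
            "spread_psi_circular_sd_deg": tsum.spread_psi_circ_std,
            "spread_psi_interpercentile_deg": tsum.spread_psi_arc_5_95,
        }

    if "hbonds" in present:
        h = present["hbonds"]
        occ = h["occupancy"]
        emit_csv("hbond_counts.csv", pd.DataFrame({
            "frame": np.arange(occ.n_frames),
            "intra_molecular_bonds": occ.per_frame_counts,
        }))
        emit_csv("hbond_occupancy.csv", pd.DataFrame(
            [(d, a, f) for (d, a), f in occ.per_bond.items()],
            columns=["donor_heavy_id", "acceptor_id", "occupancy"],
        ))
        bridging = h.get("bridging", [])
        emit_csv("bridging_waters.csv", pd.DataFrame(
            [(r.frame, r.water_residue,
              ";".join(str(i) for i in sorted(r.solute_partners)))
             for r in bridging],
            columns=["frame", "water_residue", "solute_partner_ids"],
        ))
        coord = {}
        for key, val in h.get("coordination", {}).items():
            if key == "solute":
                coord["solute"] = val
            else:
                res, moi, ids = key
                coord[f"res{res}:{moi}:" + "-".join(str(i) for i in ids)] = val
        summary["hbonds"] = {
            "mean_intra_molecular_count": occ.mean_intra_count,
            "n_tracked_pairs": len(occ.per_bond),
            "bridging_water_fraction":
                len({r.frame for r in bridging}) / occ.n_frames,
            "water_coordination": coord,
        }

    if "pucker" in present:
        p = present["pucker"]
        rows = []
        for ring_idx, per_frame in enumerate(p.states):
            for f, s in enumerate(per_frame):
                rows.append((f, ring_idx, s.Q, s.theta, s.phi2, s.label))
        emit_csv("pucker_series.csv", pd.DataFrame(
            rows, columns=["frame", "ring", "Q_angstrom", "theta_deg",
                           "phi2_deg", "label"]))
        summary["pucker"] = {
            f"ring_{i}": dict(sorted(props.items()))
            for i, props in enumerate(p.proportions)
        }

    if "rmsd" in present:
        series = np.asarray(present["rmsd"], dtype=float)
        emit_csv("rmsd_series.csv", pd.DataFrame({
            "frame": np.arange(len(series)),
            "rmsd_angstrom": series,
        }))
        summary["rmsd"] = {
            "mean_angstrom": float(series.mean()),
            "max_angstrom": float(series.max()),
        }

    if "cluster" in present:
        c = present["cluster"]
        emit_csv("cluster_labels.csv", pd.DataFrame({
            "frame": np.arange(c.n_frames),
            "cluster": c.labels,
        }))
        emit_csv("cluster_populations.csv", pd.DataFrame({
            "rank": np.arange(c.n_clusters),
            "count": c.populations,
            "fraction": c.population_fractions(),
        }))
        summary["cluster"] = {
            "n_clusters": c.n_clusters,
            "epsilon_angstrom": c.epsilon,
            "linkage": c.linkage,
            "top_fraction": float(c.population_fractions()[0]),
        }

    if "landscape" in present:
        l = present["landscape"]
        model, scape = l["pca"], l["landscape"]
        proj = model.projections
        emit_csv("pca_projections.csv", pd.DataFrame({
            "frame": np.arange(proj.shape[0]),
            **{f"pc{k + 1}": proj[:, k]
               for k in range(min(3, proj.shape[1]))},
        }))
        pc1_centers = 0.5 * (scape.x_edges[:-1] + scape.x_edges[1:])
        pc2_centers = 0.5 * (scape.y_edges[:-1] + scape.y_edges[1:])
        emit_csv("energy_landscape.csv", _grid_frame(
            scape.grid,
            [f"{v:.4f}" for v in pc1_centers],
            [f"{v:.4f}" for v in pc2_centers]), index=True)
        evr = model.explained_variance_ratio()
        summary["landscape"] = {
            "explained_variance_ratio_pc1": float(evr[0]),
            "explained_variance_ratio_pc2":
                float(evr[1]) if len(evr) > 1 else 0.0,
            "n_occupied_cells": scape.n_occupied,
            "global_minimum_cell": list(scape.global_minimum()[0]),
            "global_minimum_kcal_mol": scape.global_minimum()[1],
        }

    spath = out / "summary.json"
    spath.write_text(
        json.dumps(_round6(summary), indent=1, sort_keys=True) + "\n")
    written.append(spath)
    return written
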
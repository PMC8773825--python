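"""Geometric hydrogen-bond detection and occupancy statistics.

A hydrogen bond is recorded when the heavy-donor→acceptor distance is at
most 3.0 Å **and** the donor–hydrogen–acceptor angle is at least 135°,
evaluated for every polar hydrogen of every donor.  These are the common
geometric criteria used for GAG simulation analysis.  Distances honor the
minimum-image convention when the trajectory carries an orthorhombic box.

Categories: ``intra_residue`` (both atoms in one solute residue),
``inter_residue`` (two solute residues) and ``solute_water`` (either
direction).  Water–water bonds are not enumerated: the statistics of
interest here are solute-centric (intra-molecular counts, solute–water
coordination, bridging waters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import AnalysisConfig, Topology, Trajectory, minimum_image

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "OccupancySummary",
    "BridgingWaterRecord",
    "detect_hbonds",
    "detect_hbonds_trajectory",
    "occupancy",
    "bridging_waters",
    "bridging_from_records",
    "bridging_waters_trajectory",
    "water_coordination",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: D···A distance (Å) and D-H···A angle (deg)."""

    max_donor_acceptor_distance: float = 3.0
    min_dha_angle: float = 135.0

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")

    @staticmethod
    def from_config(config: AnalysisConfig) -> "HBondCriteria":
        return HBondCriteria(config.hbond_distance_cutoff,
                             config.hbond_angle_cutoff)


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor_heavy: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float
    category: str


@dataclass
class OccupancySummary:
    """Trajectory-level H-bond statistics.

    ``per_bond`` maps (donor_heavy, acceptor) to the fraction of frames in
    which the pair is bonded (counted once per frame even if two hydrogens
    qualify).  ``mean_intra_count`` averages the per-frame number of
    intra-molecular (solute-solute) bonded pairs over *all* frames,
    including frames with none.
    """

    per_bond: dict
    per_frame_counts: np.ndarray
    mean_intra_count: float
    n_frames: int


@dataclass(frozen=True)
class BridgingWaterRecord:
    frame: int
    water_residue: int
    solute_partners: frozenset


def _category(topology: Topology, i: int, j: int) -> Optional[str]:
    wi = topology.atoms[i].residue_index in topology.water_residue_indices
    wj = topology.atoms[j].residue_index in topology.water_residue_indices
    if wi and wj:
        return None
    if wi or wj:
        return "solute_water"
    if topology.atoms[i].residue_index == topology.atoms[j].residue_index:
        return "intra_residue"
    return "inter_residue"


def detect_hbonds(frame: np.ndarray, topology: Topology,
                  criteria: HBondCriteria = HBondCriteria(),
                  box: Optional[np.ndarray] = None,
                  frame_index: int = 0) -> list:
    """All hydrogen bonds in one frame, sorted by (donor, acceptor, hydrogen).

    ``frame`` is an ``(n_atoms, 3)`` coordinate array.  Detection is
    frame-local and exact: a candidate list is built by a distance query
    (KD-tree for large systems, a dense distance matrix otherwise) and
    every candidate is then checked against both criteria, so the result
    is identical to brute-force enumeration of all donor/acceptor pairs.
    """
    frame = np.asarray(frame, dtype=float)
    donors = topology.donors()
    acceptors = topology.acceptors()
    if not donors or not acceptors:
        return []
    d_heavy = np.array([d for d, _ in donors])
    d_hyd = np.array([h for _, h in donors])
    acc = np.array(acceptors)
    cutoff = criteria.max_donor_acceptor_distance

    dpos = frame[d_heavy]
    apos = frame[acc]
    if box is None and len(d_heavy) * len(acc) <= 250_000:
        delta = dpos[:, None, :] - apos[None, :, :]
        dist = np.linalg.norm(delta, axis=2)
        cand = np.argwhere(dist <= cutoff)
        pairs = [(int(i), int(j), float(dist[i, j])) for i, j in cand]
    else:
        if box is not None:
            # KD-tree with box wrapping: wrap coordinates into the box
            b = np.asarray(box, dtype=float)
            tree = cKDTree(np.mod(apos, b), boxsize=b)
            query = np.mod(dpos, b)
        else:
            tree = cKDTree(apos)
            query = dpos
        pairs = []
        for i, js in enumerate(tree.query_ball_point(query, cutoff)):
            for j in js:
                delta = minimum_image(dpos[i] - apos[j], box)
                pairs.append((i, int(j), float(np.linalg.norm(delta))))

    min_cos_supp = np.cos(np.radians(criteria.min_dha_angle))
    records = []
    for i, j, dist in pairs:
        di, hi, ai = int(d_heavy[i]), int(d_hyd[i]), int(acc[j])
        if di == ai:
            continue
        cat = _category(topology, di, ai)
        if cat is None:
            continue
        hd = minimum_image(frame[di] - frame[hi], box)
        ha = minimum_image(frame[ai] - frame[hi], box)
        nh = np.linalg.norm(hd) * np.linalg.norm(ha)
        cosang = float(np.dot(hd, ha) / nh) if nh > 0 else 1.0
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle >= criteria.min_dha_angle:
            records.append(HBondRecord(frame_index, di, hi, ai, dist, angle, cat))
    records.sort(key=lambda r: (r.donor_heavy, r.acceptor, r.hydrogen))
    return records


def detect_hbonds_trajectory(traj: Trajectory,
                             criteria: HBondCriteria = HBondCriteria()) -> list:
    """Concatenated per-frame records for a whole trajectory."""
    out = []
    for f in range(traj.n_frames):
        out.extend(detect_hbonds(traj.frame(f), traj.topology, criteria,
                                 box=traj.frame_box(f), frame_index=f))
    return out


def occupancy(records: list, n_frames: int) -> OccupancySummary:
    """Per-bond occupancies and per-frame intra-molecular bond counts.

    A (donor, acceptor) pair present via multiple hydrogens in one frame
    counts once; the per-frame count series covers intra-molecular
    (solute-solute) bonds and includes zero-bond frames.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    seen_pairs: dict = {}
    intra_pairs_per_frame: dict = {}
    for r in records:
        if r.frame >= n_frames:
            raise ValueError(
                f"record frame {r.frame} outside trajectory of {n_frames} frames"
            )
        seen_pairs.setdefault((r.donor_heavy, r.acceptor), set()).add(r.frame)
        if r.category in ("intra_residue", "inter_residue"):
            intra_pairs_per_frame.setdefault(r.frame, set()).add(
                (r.donor_heavy, r.acceptor)
            )
    per_bond = {
        pair: len(frames) / n_frames
        for pair, frames in sorted(seen_pairs.items())
    }
    counts = np.zeros(n_frames, dtype=int)
    for f, pairs in intra_pairs_per_frame.items():
        counts[f] = len(pairs)
    return OccupancySummary(
        per_bond=per_bond,
        per_frame_counts=counts,
        mean_intra_count=float(counts.mean()),
        n_frames=n_frames,
    )


def _water_links(records: list, topology: Topology):
    """(frame, water_residue) -> set of solute partner atom ids."""
    waters = topology.water_residue_indices
    links: dict = {}
    for r in records:
        if r.category != "solute_water":
            continue
        dres = topology.atoms[r.donor_heavy].residue_index
        ares = topology.atoms[r.acceptor].residue_index
        if dres in waters:
            wres, solute_atom = dres, r.acceptor
        else:
            wres, solute_atom = ares, r.donor_heavy
        links.setdefault((r.frame, wres), set()).add(solute_atom)
    return links


def bridging_waters(frame: np.ndarray, topology: Topology,
                    criteria: HBondCriteria = HBondCriteria(),
                    box: Optional[np.ndarray] = None,
                    frame_index: int = 0) -> list:
    """Waters H-bonded to ≥2 distinct solute heavy atoms in this frame."""
    records = detect_hbonds(frame, topology, criteria, box=box,
                            frame_index=frame_index)
    return bridging_from_records(records, topology)


def bridging_from_records(records: list, topology: Topology) -> list:
    out = [
        BridgingWaterRecord(frame=f, water_residue=w,
                            solute_partners=frozenset(partners))
        for (f, w), partners in _water_links(records, topology).items()
        if len(partners) >= 2
    ]
    out.sort(key=lambda r: (r.frame, r.water_residue))
    return out


def bridging_waters_trajectory(traj: Trajectory,
                               criteria: HBondCriteria = HBondCriteria()
                               ) -> list:
    records = detect_hbonds_trajectory(traj, criteria)
    return bridging_from_records(records, traj.topology)


def water_coordination(records: list, topology: Topology,
                       n_frames: int) -> dict:
    """Mean number of distinct waters H-bonded per frame, per moiety group.

    Returns ``{(residue_index, moiety, atom_ids): mean, ..., "solute": mean}``
    where each key is one chemical group instance (each sulfate, hydroxyl,
    the carboxylate, ...).  Distinct waters are counted once per group and
    frame even if linked through several atoms.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    links = _water_links(records, topology)
    instances = [
        (res, moi, ids) for res, moi, ids in topology.moiety_instances()
        if res not in topology.water_residue_indices and moi != "ion"
    ]
    atom_to_instance = {}
    for inst in instances:
        for i in inst[2]:
            atom_to_instance[i] = inst
    counts = {inst: 0 for inst in instances}
    solute_waters = 0
    for (f, wres), partners in links.items():
        touched = {atom_to_instance[a] for a in partners if a in atom_to_instance}
        for inst in touched:
            counts[inst] += 1
        solute_waters += 1
    out = {inst: counts[inst] / n_frames for inst in instances}
    out["solute"] = solute_waters / n_frames
    return out
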
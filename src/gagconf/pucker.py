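"""Six-membered-ring pucker via the Cremer–Pople construction.

For a ring of six atoms ordered O5, C1, C2, C3, C4, C5, out-of-plane
displacements z_j about the mean plane through the centroid define the
puckering amplitude Q, the polar angle θ ∈ [0°, 180°] and the azimuthal
phase φ₂ ∈ [0°, 360°).  θ ≈ 0° is the ⁴C₁ chair for this atom ordering,
θ ≈ 180° the inverted ¹C₄ chair, θ ≈ 90° the boat/twist-boat equator.
Canonical conformer labels are assigned by the nearest reference point
among the 38 IUPAC conformers on the (θ, φ₂) sphere, with ties broken
toward chairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, TopologyError, Trajectory

__all__ = ["PuckerState", "cremer_pople", "pucker_series", "PuckerSeriesResult"]

_PLANAR_Q = 1e-8  # Å; below this amplitude the ring is reported planar


@dataclass(frozen=True)
class PuckerState:
    """Cremer–Pople parameters and canonical conformer label."""

    Q: float          # total puckering amplitude, Å
    theta: float      # deg, [0, 180]
    phi2: float       # deg, [0, 360)
    label: str


def _reference_conformers():
    """(θ, φ₂, label) for the 38 canonical pyranose conformers.

    Reference latitudes: chairs at the poles; boats (B) and twist-boats
    (S) alternating every 30° on the equator; envelopes (E) at 54.7°/125.3°
    and half-chairs (H) at 50.8°/129.2°, each every 30° in φ₂.  Labels use
    the conventional superscript-before/subscript-after order for the
    O5,C1,C2,C3,C4,C5 numbering with O5 as position O.
    """
    refs = [(0.0, 0.0, "4C1"), (180.0, 0.0, "1C4")]
    boats = ["3,OB", "B1,4", "5,2B", "B3,O", "1,4B", "B5,2"]
    twists = ["3S1", "5S1", "2SO", "1S3", "1S5", "OS2"]
    for k in range(6):
        refs.append((90.0, 60.0 * k, boats[k]))
        refs.append((90.0, 60.0 * k + 30.0, twists[k]))
    envelopes_n = ["3E", "E1", "5E", "E3", "1E", "E5"]   # θ = 54.7
    envelopes_s = ["E2", "OE", "E4", "2E", "EO", "4E"]   # θ = 125.3
    halves_n = ["3H2", "5H4", "5HO", "1HO", "1H2", "3H4"]
    halves_s = ["2H1", "2H3", "4H3", "4H5", "OH5", "OH1"]
    for k in range(6):
        refs.append((54.7, 60.0 * k + 30.0, envelopes_n[k]))
        refs.append((125.3, 60.0 * k, envelopes_s[k]))
        refs.append((50.8, 60.0 * k, halves_n[k]))
        refs.append((129.2, 60.0 * k + 30.0, halves_s[k]))
    return refs


_REFS = _reference_conformers()


def _nearest_label(theta: float, phi2: float) -> str:
    t = np.radians(theta)
    best = None
    for rt, rp, label in _REFS:
        rt_r = np.radians(rt)
        dphi = np.radians(phi2 - rp)
        # great-circle distance on the (θ, φ₂) sphere
        cosd = (np.cos(t) * np.cos(rt_r)
                + np.sin(t) * np.sin(rt_r) * np.cos(dphi))
        dist = np.arccos(np.clip(cosd, -1.0, 1.0))
        is_chair = label in ("4C1", "1C4")
        key = (dist, 0 if is_chair else 1)
        if best is None or key < best[0]:
            best = (key, label)
    return best[1]


def cremer_pople(ring_coords: np.ndarray) -> PuckerState:
    """Cremer–Pople parameters of one six-membered ring.

    ``ring_coords`` are the 6 atom positions ordered O5, C1, C2, C3, C4,
    C5.  Invariant under rigid motion; reflection through the mean plane
    maps θ to 180° − θ.
    """
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise ValueError("ring_coords must be 6 ordered 3-vectors")
    if np.any(np.linalg.norm(r[:, None] - r[None, :], axis=2)
              [np.triu_indices(6, 1)] < 1e-6):
        raise ValueError("coincident ring atoms")
    center = r.mean(axis=0)
    rel = r - center
    j = np.arange(6)
    rp = np.sum(rel * np.sin(2 * np.pi * j / 6)[:, None], axis=0)
    rpp = np.sum(rel * np.cos(2 * np.pi * j / 6)[:, None], axis=0)
    n = np.cross(rp, rpp)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ValueError("degenerate ring geometry")
    n /= n_norm
    z = rel @ n
    # m = 2 generalized ring coordinates and the m = 3 alternating sum
    q2cos = np.sqrt(1.0 / 3.0) * np.sum(z * np.cos(2 * np.pi * 2 * j / 6))
    q2sin = -np.sqrt(1.0 / 3.0) * np.sum(z * np.sin(2 * np.pi * 2 * j / 6))
    q3 = np.sqrt(1.0 / 6.0) * np.sum(z * (-1.0) ** j)
    q2 = np.hypot(q2cos, q2sin)
    Q = float(np.hypot(q2, q3))
    if Q < _PLANAR_Q:
        return PuckerState(Q=Q, theta=0.0, phi2=0.0, label="planar")
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi2 = float(np.degrees(np.arctan2(q2sin, q2cos)) % 360.0)
    return PuckerState(Q=Q, theta=theta, phi2=phi2,
                       label=_nearest_label(theta, phi2))


@dataclass
class PuckerSeriesResult:
    """Per-ring, per-frame pucker states plus label proportions."""

    states: list          # list over rings of list over frames of PuckerState
    proportions: list     # list over rings of {label: fraction}


def pucker_series(traj: Trajectory, topology: Topology = None
                  ) -> PuckerSeriesResult:
    """Pucker every annotated ring in every frame."""
    top = topology if topology is not None else traj.topology
    if not top.rings:
        raise TopologyError("topology has no annotated rings")
    states = []
    proportions = []
    for ring in top.rings:
        ring = list(ring)
        per_frame = [
            cremer_pople(traj.coords[f, ring]) for f in range(traj.n_frames)
        ]
        labels, counts = np.unique([s.label for s in per_frame],
                                   return_counts=True)
        states.append(per_frame)
        proportions.append({
            str(l): float(c) / traj.n_frames for l, c in zip(labels, counts)
        })
    return PuckerSeriesResult(states=states, proportions=proportions)
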
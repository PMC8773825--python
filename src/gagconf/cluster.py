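"""Superposition, RMSD series and matrices, and agglomerative clustering.

The conformational-diversity analysis mirrors the standard MD workflow:
every frame is least-squares superposed (Kabsch, reflections excluded)
before RMSD is taken; frames are clustered by hierarchical agglomeration
on the pairwise best-fit RMSD matrix, merging until the minimum
inter-cluster linkage distance exceeds ε (default 2.0 Å, the customary
value for small molecules); replicate runs are compared through their
rank-ordered cluster population profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .core import Trajectory

__all__ = [
    "SuperpositionResult",
    "ClusterResult",
    "kabsch_superpose",
    "rmsd_to_reference",
    "pairwise_rmsd_matrix",
    "hier_agglo",
    "cluster_trajectory",
    "compare_replicates",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference."""

    rotation: np.ndarray     # 3×3 proper orthogonal
    translation: np.ndarray  # 3-vector, Å
    rmsd: float              # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ClusterResult:
    labels: np.ndarray       # per-frame cluster index in [0, n_clusters)
    n_clusters: int
    populations: np.ndarray  # frame counts, sorted descending
    epsilon: float
    linkage: str

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def population_fractions(self) -> np.ndarray:
        return self.populations / self.populations.sum()


def _resolve_subset(n_atoms: int, atom_subset) -> np.ndarray:
    if atom_subset is None:
        return np.arange(n_atoms)
    idx = np.asarray(sorted(atom_subset), dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise ValueError("atom subset references atoms outside the system")
    return idx


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     atom_subset=None) -> SuperpositionResult:
    """Least-squares optimal rotation + translation (reflections excluded).

    Requires at least 3 non-collinear atoms in the subset so the rotation
    is well determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have matching shapes")
    idx = _resolve_subset(mobile.shape[0], atom_subset)
    x = mobile[idx]
    y = reference[idx]
    if len(idx) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinearity check: rank of the centered reference
    if np.linalg.matrix_rank(yc, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom subset")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    # residual evaluated on the transformed coordinates: free of the
    # catastrophic cancellation the trace formula suffers near rmsd = 0
    resid = xc @ rot.T - yc
    rmsd = float(np.sqrt(np.sum(resid ** 2) / len(idx)))
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _reference_coords(traj: Trajectory, reference_frame) -> np.ndarray:
    if isinstance(reference_frame, str):
        if reference_frame == "first":
            return traj.coords[0]
        if reference_frame == "lowest_energy":
            if traj.energies is None:
                raise ValueError(
                    "lowest-energy reference requested but the trajectory "
                    "carries no energies"
                )
            return traj.coords[int(np.argmin(traj.energies))]
        raise ValueError(f"unknown reference {reference_frame!r}")
    ref = np.asarray(reference_frame, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("external reference must be an (n_atoms, 3) frame")
    return ref


def rmsd_to_reference(traj: Trajectory, reference_frame="first",
                      atom_subset=None) -> np.ndarray:
    """Per-frame best-fit RMSD (Å) to a chosen reference structure.

    ``reference_frame`` is ``"first"``, ``"lowest_energy"`` (requires
    per-frame energies) or an explicit ``(n_atoms, 3)`` coordinate array,
    e.g. a crystal structure read from a single-frame PDB.
    """
    ref = _reference_coords(traj, reference_frame)
    return np.array([
        kabsch_superpose(traj.coords[f], ref, atom_subset).rmsd
        for f in range(traj.n_frames)
    ])


def pairwise_rmsd_matrix(traj: Trajectory, atom_subset=None,
                         stride: int = 1) -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs over strided frames.

    Kabsch is evaluated in closed form for all pairs at once via batched
    3×3 SVDs, so the full matrix of a few thousand frames stays cheap.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = _resolve_subset(traj.n_atoms, atom_subset)
    x = traj.coords[::stride][:, idx, :]
    n = x.shape[0]
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.einsum("fij,fij->f", xc, xc)
    ii, jj = np.triu_indices(n, k=1)
    out = np.zeros((n, n))
    chunk = 200_000
    for lo in range(0, len(ii), chunk):
        a = ii[lo:lo + chunk]
        b = jj[lo:lo + chunk]
        h = np.einsum("pik,pij->pkj", xc[a], xc[b])
        _, s, _ = np.linalg.svd(h)
        det = np.linalg.det(h)
        smin = np.where(det < 0, -s[:, 2], s[:, 2])
        tr = s[:, 0] + s[:, 1] + smin
        msd = (norms[a] + norms[b] - 2.0 * tr) / len(idx)
        r = np.sqrt(np.maximum(msd, 0.0))
        out[a, b] = r
        out[b, a] = r
    return out


def hier_agglo(matrix: np.ndarray, epsilon: float,
               linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering cut at inter-cluster distance ε.

    Starts from singletons and merges the closest pair of clusters under
    the chosen linkage rule (average, single or complete) until the
    minimum inter-cluster linkage distance exceeds ε.  Cluster indices
    are assigned by population rank (0 = most populated), ties broken by
    the smallest member frame index.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    n = m.shape[0]
    if n == 1:
        raw = np.zeros(1, dtype=int)
    else:
        condensed = squareform(m, checks=False)
        z = scipy_linkage(condensed, method=linkage)
        # merges happen in non-decreasing linkage distance for these
        # monotone rules, so cutting the tree at ε is exactly "stop when
        # the minimum inter-cluster distance exceeds ε"
        raw = fcluster(z, t=epsilon, criterion="distance") - 1
    return _relabel(raw, epsilon, linkage)


def _relabel(raw: np.ndarray, epsilon: float, linkage: str) -> ClusterResult:
    """Renumber clusters by descending population (ties: first frame)."""
    ids, counts = np.unique(raw, return_counts=True)
    first = {i: int(np.argmax(raw == i)) for i in ids}
    order = sorted(ids, key=lambda i: (-counts[list(ids).index(i)], first[i]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[i] for i in raw], dtype=int)
    pops = np.array(sorted(counts, reverse=True), dtype=int)
    return ClusterResult(labels=labels, n_clusters=len(ids), populations=pops,
                         epsilon=float(epsilon), linkage=linkage)


def cluster_trajectory(traj: Trajectory, epsilon: float = 2.0,
                       linkage: str = "average", stride: int = 1,
                       atom_subset=None) -> ClusterResult:
    """Cluster solute-heavy-atom conformations of a trajectory.

    With ``stride > 1`` a sieve is applied: the strided frames are
    clustered exactly and every remaining frame is assigned to the cluster
    of its nearest strided frame (by best-fit RMSD).  Defaults select the
    solute heavy atoms, since the analysis targets the disaccharide
    conformation, not water arrangement.
    """
    if atom_subset is None:
        atom_subset = traj.topology.heavy_solute_ids()
    matrix = pairwise_rmsd_matrix(traj, atom_subset=atom_subset, stride=stride)
    res = hier_agglo(matrix, epsilon, linkage)
    if stride == 1:
        return res
    idx = np.asarray(sorted(atom_subset), dtype=int)
    strided = np.arange(traj.n_frames)[::stride]
    labels = np.empty(traj.n_frames, dtype=int)
    labels[strided] = res.labels
    xs = traj.coords[strided][:, idx, :]
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    ns = np.einsum("fij,fij->f", xs_c, xs_c)
    rest = np.setdiff1d(np.arange(traj.n_frames), strided)
    if rest.size:
        ys = traj.coords[rest][:, idx, :]
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        nr = np.einsum("fij,fij->f", ys_c, ys_c)
        # chunk the (rest × strided) cross-correlation so the batched
        # 3×3 SVD stack stays within a fixed memory budget
        chunk = max(1, 2_000_000 // max(1, len(strided)))
        for lo in range(0, rest.size, chunk):
            yc = ys_c[lo:lo + chunk]
            h = np.einsum("qik,pij->qpkj", yc, xs_c)
            s = np.linalg.svd(h, compute_uv=False)
            det = np.linalg.det(h)
            smin = np.where(det < 0, -s[..., 2], s[..., 2])
            tr = s[..., 0] + s[..., 1] + smin
            msd = (nr[lo:lo + chunk, None] + ns[None, :] - 2.0 * tr) / len(idx)
            labels[rest[lo:lo + chunk]] = res.labels[np.argmin(msd, axis=1)]
    ids, counts = np.unique(labels, return_counts=True)
    pops = np.array(sorted(counts, reverse=True), dtype=int)
    return ClusterResult(labels=labels, n_clusters=len(ids), populations=pops,
                         epsilon=float(epsilon), linkage=linkage)


def compare_replicates(results: Sequence[ClusterResult]) -> float:
    """Max relative deviation of rank-ordered population fractions.

    Profiles are aligned by population rank (missing ranks padded with 0)
    and the deviation is ``max over ranks and replicate pairs of
    |p_a − p_b| / max(p_a, p_b)`` on population fractions.  Identical
    replicates give 0; the customary convergence check accepts < 0.10.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicate cluster results")
    eps = {r.epsilon for r in results}
    lk = {r.linkage for r in results}
    if len(eps) > 1 or len(lk) > 1:
        raise ValueError("replicates must share epsilon and linkage")
    n_ranks = max(r.n_clusters for r in results)
    profiles = []
    for r in results:
        p = np.zeros(n_ranks)
        frac = r.population_fractions()
        p[:len(frac)] = frac
        profiles.append(p)
    worst = 0.0
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            pa, pb = profiles[a], profiles[b]
            denom = np.maximum(pa, pb)
            mask = denom > 0
            if mask.any():
                dev = np.max(np.abs(pa - pb)[mask] / denom[mask])
                worst = max(worst, float(dev))
    return worst
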
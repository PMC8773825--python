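"""Toy molecular-mechanics energy, frame quenching, PCA and landscapes.

The potential-energy-landscape methodology — quench every frame (steepest
descent, then conjugate gradient), project the trajectory onto its first
two principal components, and plot the per-cell minimum quenched energy —
is exercised here on a documented toy force field: harmonic bonds and
angles, optional cosine torsions, shifted-cutoff Coulomb and
Lennard-Jones.  The landscape construction is the point; the force field
is deliberately simple and is not a carbohydrate force field.  For real
MD data, user-supplied per-frame energies can be passed straight to
:func:`build_landscape`.

Conventions: energies kcal/mol, distances Å; harmonic terms use
``E = k (x - x0)**2`` (no ½); Coulomb constant 332.0636 kcal·Å/mol/e².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .core import Topology, Trajectory
from .cluster import kabsch_superpose

__all__ = [
    "ToyForceField",
    "PCAModel",
    "EnergyLandscape",
    "energy_and_gradient",
    "quench",
    "minimize_sd",
    "minimize_cg",
    "pca_frames",
    "build_landscape",
]

COULOMB_K = 332.0636

#: element -> (sigma Å, epsilon kcal/mol); hydrogens get no LJ well
_LJ_TABLE = {
    "C": (3.40, 0.090),
    "O": (3.00, 0.170),
    "N": (3.25, 0.170),
    "S": (3.55, 0.250),
    "H": (1.00, 0.000),
}


@dataclass
class ToyForceField:
    """Parameter container; all index arrays refer to topology atom ids."""

    bonds: np.ndarray            # (nb, 2) int
    bond_k: np.ndarray           # kcal/mol/Å²
    bond_r0: np.ndarray          # Å
    angles: np.ndarray           # (na, 3) int, vertex in the middle
    angle_k: np.ndarray          # kcal/mol/rad²
    angle_t0: np.ndarray         # rad
    torsions: np.ndarray         # (nt, 4) int
    torsion_v: np.ndarray        # kcal/mol
    torsion_n: np.ndarray        # periodicity
    torsion_gamma: np.ndarray    # rad
    charges: np.ndarray          # e
    lj_sigma: np.ndarray         # per-atom Å
    lj_eps: np.ndarray           # per-atom kcal/mol
    nb_pairs: np.ndarray         # (np, 2) int, separated by >= 3 bonds
    dielectric: float = 4.0
    cutoff: float = 10.0

    @classmethod
    def from_reference(cls, topology: Topology, reference: np.ndarray,
                       bond_k: float = 300.0, angle_k: float = 50.0,
                       dielectric: float = 4.0, cutoff: float = 10.0
                       ) -> "ToyForceField":
        """Build a force field whose bonded minima sit at the reference frame.

        Equilibrium bond lengths and angles are read off the reference
        geometry, so the reference conformation is a strain-free point of
        the bonded terms; charges come from the topology; LJ parameters
        from a per-element table.  No torsion terms are generated (the
        synthetic conformers place no barrier information in them).
        """
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (topology.n_atoms, 3):
            raise ValueError("reference frame does not match topology")
        bonds = np.array(sorted(tuple(sorted(b)) for b in topology.bonds),
                         dtype=int).reshape(-1, 2)
        r0 = np.linalg.norm(ref[bonds[:, 0]] - ref[bonds[:, 1]], axis=1)
        adj: dict = {}
        for i, j in bonds:
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
        angles = []
        for j in sorted(adj):
            nb = sorted(adj[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    angles.append((nb[x], j, nb[y]))
        angles = np.array(angles, dtype=int) if angles else np.zeros((0, 3), int)
        t0 = np.zeros(len(angles))
        for k, (i, j, l) in enumerate(angles):
            u = ref[i] - ref[j]
            v = ref[l] - ref[j]
            c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            t0[k] = np.arccos(np.clip(c, -1.0, 1.0))
        # nonbonded pairs: graph distance >= 3 (1-2 and 1-3 excluded)
        n = topology.n_atoms
        excluded = {tuple(sorted(b)) for b in bonds.tolist()}
        for i, j, l in angles.tolist():
            excluded.add(tuple(sorted((i, l))))
        pairs = [
            (i, j) for i in range(n) for j in range(i + 1, n)
            if (i, j) not in excluded
        ]
        missing = [a.element for a in topology.atoms if a.element not in _LJ_TABLE]
        if missing:
            raise KeyError(
                f"no Lennard-Jones parameters for element(s) {sorted(set(missing))}"
            )
        sigma = np.array([_LJ_TABLE[a.element][0] for a in topology.atoms])
        eps = np.array([_LJ_TABLE[a.element][1] for a in topology.atoms])
        charges = np.array([a.charge for a in topology.atoms])
        return cls(
            bonds=bonds, bond_k=np.full(len(bonds), bond_k), bond_r0=r0,
            angles=angles, angle_k=np.full(len(angles), angle_k), angle_t0=t0,
            torsions=np.zeros((0, 4), int), torsion_v=np.zeros(0),
            torsion_n=np.zeros(0), torsion_gamma=np.zeros(0),
            charges=charges, lj_sigma=sigma, lj_eps=eps,
            nb_pairs=np.array(pairs, dtype=int) if pairs else np.zeros((0, 2), int),
            dielectric=dielectric, cutoff=cutoff,
        )


def energy_and_gradient(frame: np.ndarray, topology: Topology,
                        ff: ToyForceField):
    """Total toy energy (kcal/mol) and its per-atom gradient (kcal/mol/Å).

    Bonded terms plus shifted-cutoff nonbonded terms over pairs separated
    by at least three bonds; the nonbonded energy is shifted to zero at
    the cutoff so it is continuous there.
    """
    x = np.asarray(frame, dtype=float)
    if topology is not None and x.shape[0] != topology.n_atoms:
        raise ValueError("frame does not match topology")
    g = np.zeros_like(x)
    e = 0.0

    if len(ff.bonds):
        d = x[ff.bonds[:, 0]] - x[ff.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        delta = r - ff.bond_r0
        e += float(np.sum(ff.bond_k * delta ** 2))
        f = (2.0 * ff.bond_k * delta / r)[:, None] * d
        np.add.at(g, ff.bonds[:, 0], f)
        np.add.at(g, ff.bonds[:, 1], -f)

    if len(ff.angles):
        i, j, l = ff.angles[:, 0], ff.angles[:, 1], ff.angles[:, 2]
        u = x[i] - x[j]
        v = x[l] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - c ** 2, 1e-12))
        theta = np.arccos(c)
        dd = theta - ff.angle_t0
        e += float(np.sum(ff.angle_k * dd ** 2))
        pref = 2.0 * ff.angle_k * dd
        di = (pref / (nu * s))[:, None] * (c[:, None] * uh - vh)
        dl = (pref / (nv * s))[:, None] * (c[:, None] * vh - uh)
        np.add.at(g, i, di)
        np.add.at(g, l, dl)
        np.add.at(g, j, -(di + dl))

    if len(ff.torsions):
        ti, tj, tk, tl = (ff.torsions[:, m] for m in range(4))
        b1 = x[tj] - x[ti]
        b2 = x[tk] - x[tj]
        b3 = x[tl] - x[tk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        phi = np.arctan2(
            np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1),
            np.sum(n1 * n2, axis=1),
        )
        e += float(np.sum(ff.torsion_v
                          * (1.0 + np.cos(ff.torsion_n * phi - ff.torsion_gamma))))
        dV = -ff.torsion_v * ff.torsion_n * np.sin(ff.torsion_n * phi
                                                   - ff.torsion_gamma)
        n1sq = np.sum(n1 ** 2, axis=1)
        n2sq = np.sum(n2 ** 2, axis=1)
        dphi_di = -(nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        f12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
        f32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
        dphi_dj = -(1.0 + f12) * dphi_di + f32 * dphi_dl
        dphi_dk = f12 * dphi_di - (1.0 + f32) * dphi_dl
        for idx, dp in ((ti, dphi_di), (tj, dphi_dj), (tk, dphi_dk),
                        (tl, dphi_dl)):
            np.add.at(g, idx, dV[:, None] * dp)

    if len(ff.nb_pairs):
        i, j = ff.nb_pairs[:, 0], ff.nb_pairs[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        within = r < ff.cutoff
        if within.any():
            i, j, d, r = i[within], j[within], d[within], r[within]
            qq = COULOMB_K * ff.charges[i] * ff.charges[j] / ff.dielectric
            sig = 0.5 * (ff.lj_sigma[i] + ff.lj_sigma[j])
            epsp = np.sqrt(ff.lj_eps[i] * ff.lj_eps[j])
            rc = ff.cutoff

            def pairwise(rr):
                sr6 = (sig / rr) ** 6
                return qq / rr + 4.0 * epsp * (sr6 ** 2 - sr6)

            e += float(np.sum(pairwise(r) - pairwise(np.full_like(r, rc))))
            sr6 = (sig / r) ** 6
            de_dr = -qq / r ** 2 + 4.0 * epsp * (-12.0 * sr6 ** 2
                                                 + 6.0 * sr6) / r
            f = (de_dr / r)[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

    if not np.isfinite(e):
        raise FloatingPointError("non-finite toy energy (overlapping atoms?)")
    return e, g


# --------------------------------------------------------------------------
# minimizers
# --------------------------------------------------------------------------


def _secant_line_search(fun, grad, x, d, f0, g0, max_steps: int = 8):
    """Nearly exact line search along d (exact for quadratic energies).

    Secant iteration on the directional derivative; falls back to
    backtracking if the model step increases the energy.  Returns
    (alpha, f_new) with f_new <= f0.
    """
    s0 = float(np.dot(g0, d))
    if s0 >= 0:
        return 0.0, f0
    alpha = min(1.0, 1.0 / max(1.0, np.max(np.abs(d))))
    a_prev, s_prev = 0.0, s0
    best_a, best_f = 0.0, f0
    for _ in range(max_steps):
        g1 = grad(x + alpha * d)
        s1 = float(np.dot(g1, d))
        f1 = fun(x + alpha * d)
        if f1 < best_f:
            best_a, best_f = alpha, f1
        if abs(s1) <= 1e-12 * max(1.0, abs(s0)):
            break
        denom = s1 - s_prev
        if denom == 0.0:
            break
        a_next = alpha - s1 * (alpha - a_prev) / denom
        if not np.isfinite(a_next) or a_next <= 0:
            break
        a_prev, s_prev = alpha, s1
        alpha = a_next
    if best_a == 0.0:
        # backtracking rescue
        alpha = min(1.0, 1.0 / max(1.0, np.max(np.abs(d))))
        for _ in range(40):
            f1 = fun(x + alpha * d)
            if f1 < f0:
                return alpha, f1
            alpha *= 0.5
        return 0.0, f0
    return best_a, best_f


def minimize_cg(fun: Callable, grad: Callable, x0: np.ndarray,
                max_iter: int = 1000, gtol: float = 1e-10):
    """Polak–Ribière (PR+) conjugate gradient with near-exact line search.

    On a strictly quadratic function the line search is exact and the
    iteration reaches the minimum in at most ``dim`` steps.  The energy
    sequence is non-increasing by construction.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = fun(x)
    g = grad(x)
    d = -g
    stalls = 0
    for it in range(max_iter):
        if np.linalg.norm(g) <= gtol:
            break
        alpha, f_new = _secant_line_search(fun, grad, x, d, f, g)
        if alpha == 0.0:
            break
        # two consecutive iterations with negligible progress: converged
        # to line-search resolution
        if f - f_new <= 1e-12 * max(1.0, abs(f)):
            stalls += 1
            if stalls >= 2:
                x = x + alpha * d
                f = f_new
                break
        else:
            stalls = 0
        x = x + alpha * d
        g_new = grad(x)
        beta = max(0.0, float(np.dot(g_new, g_new - g) / np.dot(g, g)))
        d = -g_new + beta * d
        if np.dot(d, g_new) >= 0:   # restart if not a descent direction
            d = -g_new
        f, g = f_new, g_new
    return x, f


def minimize_sd(fun: Callable, grad: Callable, x0: np.ndarray,
                max_iter: int = 100, gtol: float = 1.0,
                max_step: float = 0.01):
    """Steepest descent with backtracking from a small fixed trial step.

    ``max_step`` caps the largest per-coordinate displacement (Å) of a
    trial step; steps that increase the energy are halved.  Stops when the
    RMS gradient drops below ``gtol`` (kcal/mol/Å) or after ``max_iter``
    steps — the usual pre-conditioning stage before conjugate gradient.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = fun(x)
    for _ in range(max_iter):
        g = grad(x)
        if np.sqrt(np.mean(g ** 2)) <= gtol:
            break
        gmax = np.max(np.abs(g))
        if gmax == 0:
            break
        alpha = max_step / gmax
        accepted = False
        for _ in range(30):
            f_new = fun(x - alpha * g)
            if f_new < f:
                x = x - alpha * g
                f = f_new
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    return x, f


def quench(frame: np.ndarray, topology: Topology, ff: ToyForceField,
           max_cg_iter: int = 1000):
    """Energy-minimize one frame: steepest descent, then conjugate gradient.

    Returns ``(minimized_frame, energy)`` with energy ≤ the starting
    energy.  Raises on a non-finite starting energy.
    """
    x0 = np.asarray(frame, dtype=float)
    shape = x0.shape
    cache = {"key": None, "val": None}

    def both(v):
        key = v.tobytes()
        if cache["key"] != key:
            e, g = energy_and_gradient(v.reshape(shape), topology, ff)
            cache["key"], cache["val"] = key, (e, g.ravel())
        return cache["val"]

    def fun(v):
        return both(v)[0]

    def grd(v):
        return both(v)[1]

    e0 = fun(x0.ravel())
    if not np.isfinite(e0):
        raise FloatingPointError("non-finite starting energy")
    x, _ = minimize_sd(fun, grd, x0.ravel())
    # gradient tolerance scaled to system size (RMS ~1e-5 kcal/mol/Å)
    x, e = minimize_cg(fun, grd, x, max_iter=max_cg_iter,
                       gtol=1e-5 * np.sqrt(x.size))
    return x.reshape(shape), float(min(e, e0))


# --------------------------------------------------------------------------
# PCA and landscape
# --------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Coordinate PCA of (superposed) frames.

    ``components`` are orthonormal rows ordered by explained variance;
    each row's largest-magnitude entry is made positive so the sign
    convention is deterministic.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    projections: np.ndarray
    atom_subset: np.ndarray

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


def pca_frames(traj: Trajectory, atom_subset=None, align: bool = True
               ) -> PCAModel:
    """PCA on flattened Cartesian coordinates of the selected atoms.

    Frames are best-fit superposed onto the first frame before
    decomposition (``align=True``) so rigid-body motion does not dominate
    the leading components.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    if atom_subset is None:
        atom_subset = traj.topology.heavy_solute_ids()
    idx = np.asarray(sorted(atom_subset), dtype=int)
    coords = traj.coords[:, idx, :]
    if align:
        ref = coords[0]
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            sup = kabsch_superpose(coords[f], ref)
            aligned[f] = sup.apply(coords[f])
        coords = aligned
    flat = coords.reshape(coords.shape[0], -1)
    n_comp = min(flat.shape[0] - 1, flat.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    proj = pca.fit_transform(flat)
    comps = pca.components_.copy()
    # deterministic sign: largest-magnitude entry of each component positive
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            proj[:, k] = -proj[:, k]
    return PCAModel(mean=pca.mean_, components=comps,
                    eigenvalues=pca.explained_variance_,
                    projections=proj, atom_subset=idx)


@dataclass
class EnergyLandscape:
    """Minimum energy over a (PC1, PC2) grid; empty cells are NaN."""

    grid: np.ndarray        # (n, n) min energy per cell, NaN where empty
    x_edges: np.ndarray     # (n+1,) PC1 bin edges
    y_edges: np.ndarray     # (n+1,) PC2 bin edges
    frame_cells: np.ndarray  # (F, 2) cell index of every frame

    @property
    def n_occupied(self) -> int:
        return int(np.sum(~np.isnan(self.grid)))

    def global_minimum(self):
        flat = np.nanargmin(self.grid)
        ij = np.unravel_index(flat, self.grid.shape)
        return (int(ij[0]), int(ij[1])), float(self.grid[ij])


def build_landscape(model: PCAModel, energies: np.ndarray,
                    grid_size: int = 50) -> EnergyLandscape:
    """Bin PC1/PC2 projections and record the minimum energy per cell.

    Ranges span the data min/max padded by 5% on each side; the landscape
    statistic is the minimum (not mean) energy, which preserves basin and
    saddle structure.
    """
    energies = np.asarray(energies, dtype=float)
    proj = model.projections
    if energies.shape != (proj.shape[0],):
        raise ValueError(
            f"energies length {energies.shape} does not match "
            f"{proj.shape[0]} frames"
        )
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    pc1 = proj[:, 0]
    pc2 = proj[:, 1] if proj.shape[1] > 1 else proj[:, 0]

    def edges(v):
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = 0.05 * span if span > 0 else max(abs(hi), 1.0) * 0.05
        return np.linspace(lo - pad, hi + pad, grid_size + 1)

    xe, ye = edges(pc1), edges(pc2)
    xi = np.clip(np.searchsorted(xe, pc1, side="right") - 1, 0, grid_size - 1)
    yi = np.clip(np.searchsorted(ye, pc2, side="right") - 1, 0, grid_size - 1)
    grid = np.full((grid_size, grid_size), np.nan)
    for f in range(len(energies)):
        cur = grid[xi[f], yi[f]]
        if np.isnan(cur) or energies[f] < cur:
            grid[xi[f], yi[f]] = energies[f]
    return EnergyLandscape(grid=grid, x_edges=xe, y_edges=ye,
                           frame_cells=np.column_stack([xi, yi]))
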
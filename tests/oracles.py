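"""Independent reference implementations used only by the test suite.

Each oracle is written directly from the defining mathematics (brute-force
enumeration, closed-form expressions, textbook constructions) without
reusing package code paths, so agreement between a package function and
its oracle is a genuine dual-route check.
"""

import numpy as np


# --------------------------------------------------------------------------
# dihedral angle (atan2 cross-product construction, coded independently)
# --------------------------------------------------------------------------


def dihedral_oracle(a, b, c, d):
    """IUPAC-sign dihedral (deg) via in-plane projections.

    Projects the outer bonds onto the plane perpendicular to the central
    bond and takes the signed angle between the projections — a different
    construction from the cross-product/atan2 formula used in the package.
    """
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    v = (a - b) - np.dot(a - b, axis) * axis   # near bond, projected
    w = (d - c) - np.dot(d - c, axis) * axis   # far bond, projected
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(axis, v), w))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# --------------------------------------------------------------------------
# brute-force H-bond detection
# --------------------------------------------------------------------------


def brute_force_hbonds(frame, topology, max_dist, min_angle, box=None):
    """All (donor_heavy, hydrogen, acceptor) triples passing the criteria.

    Enumerates every polar hydrogen against every acceptor with no
    neighbor pruning.  Water-water pairs are skipped (outside the solute-
    centric statistics, matching the package contract).  Returns a sorted
    list of (donor_heavy, hydrogen, acceptor) tuples.
    """
    frame = np.asarray(frame, dtype=float)

    def mi(delta):
        if box is None:
            return delta
        b = np.asarray(box, dtype=float)
        return delta - b * np.round(delta / b)

    waters = topology.water_residue_indices
    out = []
    for h in topology.atoms:
        if "polar_hydrogen" not in h.hbond_role:
            continue
        heavies = [j for j in topology.bonded_to(h.atom_id)
                   if "donor_heavy" in topology.atoms[j].hbond_role]
        assert len(heavies) == 1
        dh = heavies[0]
        for acc in topology.atoms:
            if "acceptor" not in acc.hbond_role or acc.atom_id == dh:
                continue
            d_water = topology.atoms[dh].residue_index in waters
            a_water = acc.residue_index in waters
            if d_water and a_water:
                continue
            dist = float(np.linalg.norm(mi(frame[dh] - frame[acc.atom_id])))
            if dist > max_dist:
                continue
            v1 = mi(frame[dh] - frame[h.atom_id])
            v2 = mi(frame[acc.atom_id] - frame[h.atom_id])
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if angle >= min_angle:
                out.append((dh, h.atom_id, acc.atom_id))
    return sorted(out)


# --------------------------------------------------------------------------
# quaternion (Horn) superposition
# --------------------------------------------------------------------------


def horn_superpose_rmsd(mobile, reference):
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = xc.T @ yc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy,        szx - sxz,        sxy - syx],
        [syz - szy,       sxx - syy - szz,  sxy + syx,        szx + sxz],
        [szx - sxz,       sxy + syx,       -sxx + syy - szz,  syz + szy],
        [sxy - syx,       szx + sxz,        syz + szy,       -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    n = len(x)
    msd = (np.sum(xc ** 2) + np.sum(yc ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


# --------------------------------------------------------------------------
# exhaustive hierarchical agglomeration
# --------------------------------------------------------------------------


def brute_force_agglo(matrix, epsilon, linkage="average"):
    """Agglomeration by explicit cluster-pair scanning.

    Maintains clusters as frozensets and at every step recomputes the full
    linkage distance between every pair of clusters from the original
    matrix, merging the minimum (ties by smallest sorted member tuple)
    while it does not exceed epsilon.  Returns a set of frozensets.
    """
    m = np.asarray(matrix, dtype=float)
    clusters = [frozenset([i]) for i in range(m.shape[0])]

    def dist(a, b):
        vals = [m[i, j] for i in a for j in b]
        if linkage == "average":
            return sum(vals) / len(vals)
        if linkage == "single":
            return min(vals)
        if linkage == "complete":
            return max(vals)
        raise ValueError(linkage)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                key = (d, tuple(sorted(clusters[i])), tuple(sorted(clusters[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        if d > epsilon:
            break
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return set(clusters)


# --------------------------------------------------------------------------
# finite-difference gradient
# --------------------------------------------------------------------------


def fd_gradient(fun, x, h=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        xp = flat.copy()
        xm = flat.copy()
        xp[i] += h
        xm[i] -= h
        gf[i] = (fun(xp.reshape(x.shape)) - fun(xm.reshape(x.shape))) / (2 * h)
    return g


# --------------------------------------------------------------------------
# von Mises circular standard deviation (closed form)
# --------------------------------------------------------------------------


def von_mises_circular_sd_deg(kappa):
    """Closed-form circular SD (deg) of a von Mises distribution.

    R = I1(kappa)/I0(kappa); circular SD = sqrt(-2 ln R).
    """
    from scipy.special import i0e, i1e
    r = i1e(kappa) / i0e(kappa)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


# --------------------------------------------------------------------------
# Cremer-Pople reference values for constructed chairs
# --------------------------------------------------------------------------


def ideal_chair(z0=0.25, radius=1.45, clockwise=True):
    """Six ring positions with alternating ±z0 displacement, atom 0 up.

    ``clockwise`` selects the in-plane winding direction (viewed from +z).
    """
    sign = -1.0 if clockwise else 1.0
    ang = sign * np.radians(60.0 * np.arange(6))
    xy = np.stack([radius * np.cos(ang), radius * np.sin(ang)], axis=1)
    z = z0 * (-1.0) ** np.arange(6)
    return np.column_stack([xy, z])
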
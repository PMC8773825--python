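"""Internal-coordinate geometry helpers.

Atoms are placed by the standard internal-coordinate construction (the
"natural extension reference frame"): given three placed reference atoms
``a, b, c``, a new atom ``x`` is located by its bond length ``r = |x - c|``,
valence angle ``theta = angle(x, c, b)`` and dihedral
``chi = dihedral(x, c, b, a)``.  All functions broadcast over leading
dimensions so a whole trajectory of placements runs in one call.
"""

from __future__ import annotations

import numpy as np

from .torsions import dihedral

__all__ = ["place_nerf", "bond_angle", "measure_internal"]


def _normalize(v):
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def bond_angle(a, b, c):
    """Valence angle a-b-c in degrees; broadcasts over leading dims."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u = _normalize(a - b)
    v = _normalize(c - b)
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def place_nerf(a, b, c, r, theta_deg, chi_deg):
    """Place atom x with |x-c| = r, angle(x,c,b) = theta, dih(x,c,b,a) = chi.

    The sign convention matches :func:`gagconf.torsions.dihedral`:
    ``dihedral(x, c, b, a) == chi`` for the returned point.
    """
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    r = np.asarray(r, dtype=float)[..., None]
    theta = np.radians(np.asarray(theta_deg, dtype=float))[..., None]
    chi = np.radians(np.asarray(chi_deg, dtype=float))[..., None]

    u = _normalize(c - b)           # axis from b toward c
    n = _normalize(np.cross(b - a, u))
    m = np.cross(n, u)
    d = (
        -u * np.cos(theta) * r
        + m * (np.sin(theta) * np.cos(chi)) * r
        + n * (np.sin(theta) * np.sin(chi)) * r
    )
    return c + d


def measure_internal(x, c, b, a):
    """Inverse of :func:`place_nerf`: (r, theta_deg, chi_deg) of x w.r.t. c,b,a."""
    x, c, b, a = (np.asarray(v, dtype=float) for v in (x, c, b, a))
    r = float(np.linalg.norm(x - c))
    theta = float(bond_angle(x, c, b))
    chi = float(dihedral(x, c, b, a))
    return r, theta, chi
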
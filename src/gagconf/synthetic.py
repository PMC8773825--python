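"""Synthetic disaccharide trajectories with planted statistical structure.

The generator emulates the statistical structure of explicit-solvent MD
runs of chondroitin-sulfate-like disaccharides without any force-field
dynamics: each frame's glycosidic torsions (Φ, Ψ) are drawn from a mixture
of von Mises components, the two idealized ⁴C₁ pyranose rings are rebuilt
at those torsions by internal-coordinate construction, hydrogen bonds are
planted with prescribed occupancies by local geometric surgery, and decoy
bulk waters are kept far enough from the solute that they can never
satisfy the 3.0 Å detection criterion spuriously.

Every planted quantity — mixture component per frame, exact torsions,
per-frame bond status, bridging-water assignments — is returned in a
:class:`GroundTruth` record, so each analysis stage can be validated
against exact truth.  Identical :class:`SyntheticRunSpec` (including the
seed) yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .core import AtomRecord, LinkageSpec, Topology, Trajectory, wrap_angle
from .geometry import bond_angle, measure_internal, place_nerf
from .torsions import dihedral

__all__ = [
    "DisaccharideSpec",
    "MixtureComponent",
    "TorsionMixture",
    "PlantedHBond",
    "SyntheticRunSpec",
    "GroundTruth",
    "build_disaccharide",
    "sample_trajectory",
    "assign_toy_charges",
    "kappa_for_circular_std",
]

SULFATION_SITES = frozenset({"GlcA-2S", "GalNAc-4S", "GalNAc-6S"})

# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DisaccharideSpec:
    """Which disaccharide to build.

    ``acid_amine`` order (GlcA first) pairs with the β1→3 linkage,
    ``amine_acid`` (GalNAc first) with β1→4, as in chondroitin sulfate.
    """

    linkage: str
    sulfation: frozenset = frozenset()
    residue_order: str = "acid_amine"

    def __post_init__(self):
        object.__setattr__(self, "sulfation", frozenset(self.sulfation))
        if self.linkage not in ("beta_1_3", "beta_1_4"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.residue_order not in ("acid_amine", "amine_acid"):
            raise ValueError(f"unknown residue order {self.residue_order!r}")
        expected = "acid_amine" if self.linkage == "beta_1_3" else "amine_acid"
        if self.residue_order != expected:
            raise ValueError(
                f"residue order {self.residue_order!r} is inconsistent with "
                f"linkage {self.linkage!r} (chondroitin chemistry pairs "
                f"beta_1_3 with acid_amine and beta_1_4 with amine_acid)"
            )
        if not self.sulfation <= SULFATION_SITES:
            raise ValueError(
                f"unknown sulfation sites {sorted(self.sulfation - SULFATION_SITES)}"
            )

    @property
    def n_sulfates(self) -> int:
        return len(self.sulfation)


@dataclass(frozen=True)
class MixtureComponent:
    mean_phi: float
    mean_psi: float
    kappa_phi: float
    kappa_psi: float
    weight: float

    def __post_init__(self):
        if self.kappa_phi <= 0 or self.kappa_psi <= 0:
            raise ValueError("von Mises concentrations must be positive")
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")


@dataclass(frozen=True)
class TorsionMixture:
    """Mixture of independent von Mises (Φ, Ψ) components."""

    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        object.__setattr__(self, "components", comps)

    @staticmethod
    def single(mean_phi: float, mean_psi: float, sd_deg: float = 15.0
               ) -> "TorsionMixture":
        k = kappa_for_circular_std(sd_deg)
        return TorsionMixture((MixtureComponent(mean_phi, mean_psi, k, k, 1.0),))


@dataclass(frozen=True)
class PlantedHBond:
    """A hydrogen bond to realize in a Bernoulli(occupancy) subset of frames.

    ``donor`` and ``acceptor`` are ``(residue_index, atom_name)`` paths into
    the solute.  For ``via_water`` bonds both named atoms must be acceptors
    (a dedicated water donates to both, forming a bridge); for direct bonds
    the donor must carry a polar hydrogen.
    """

    donor: tuple
    acceptor: tuple
    occupancy: float
    via_water: bool = False

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy must be within [0, 1], got {self.occupancy}"
            )
        object.__setattr__(self, "donor", (int(self.donor[0]), str(self.donor[1])))
        object.__setattr__(self, "acceptor",
                           (int(self.acceptor[0]), str(self.acceptor[1])))

    @property
    def key(self) -> str:
        return (f"{self.donor[0]}:{self.donor[1]}->"
                f"{self.acceptor[0]}:{self.acceptor[1]}"
                + ("~w" if self.via_water else ""))


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Full recipe for one synthetic trajectory.

    ``pucker_label`` is either a single canonical conformer (``"4C1"``,
    the default, or ``"1C4"``) or a mapping ``{label: probability}`` for a
    per-frame mixture of the two chairs.  ``component_energy_offsets``
    optionally assigns a baseline potential energy (kcal/mol) to each
    torsional component, producing a per-frame energy trace with Gaussian
    noise ``energy_noise_sigma`` — the planted analogue of distinct energy
    basins.
    """

    disaccharide: DisaccharideSpec
    torsions: TorsionMixture
    pucker_label: Union[str, dict] = "4C1"
    planted_hbonds: tuple = ()
    n_bulk_waters: int = 0
    n_frames: int = 1
    seed: int = 0
    jitter_sigma: float = 0.05
    component_energy_offsets: Optional[tuple] = None
    energy_noise_sigma: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "planted_hbonds", tuple(self.planted_hbonds))
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.n_bulk_waters < 0:
            raise ValueError("n_bulk_waters must be >= 0")
        if self.component_energy_offsets is not None:
            offs = tuple(float(x) for x in self.component_energy_offsets)
            if len(offs) != len(self.torsions.components):
                raise ValueError(
                    "component_energy_offsets must have one entry per "
                    "mixture component"
                )
            object.__setattr__(self, "component_energy_offsets", offs)
        labels = (self.pucker_label if isinstance(self.pucker_label, dict)
                  else {self.pucker_label: 1.0})
        if not set(labels) <= {"4C1", "1C4"}:
            raise ValueError("pucker_label supports the chairs '4C1' and '1C4'")
        if abs(sum(labels.values()) - 1.0) > 1e-9:
            raise ValueError("pucker label probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Planted per-frame truth for a synthetic run."""

    component: np.ndarray          # (F,) mixture component index
    phi: np.ndarray                # (F,) realized torsions, deg
    psi: np.ndarray
    hbond_status: dict             # bond key -> (F,) bool, realized presence
    bond_water_residue: dict       # bond key -> water residue index (via_water)
    inverted_chair: np.ndarray     # (F,) bool, True where both rings are ¹C₄
    planted_bonds: tuple = ()


# --------------------------------------------------------------------------
# von Mises helpers
# --------------------------------------------------------------------------


def kappa_for_circular_std(sd_deg: float) -> float:
    """Concentration κ whose von Mises circular SD equals ``sd_deg``.

    Uses the closed-form relation SD = sqrt(-2 ln(I₁(κ)/I₀(κ))).
    """
    if sd_deg <= 0:
        raise ValueError("circular SD must be positive")
    target_r = float(np.exp(-0.5 * np.radians(sd_deg) ** 2))

    def f(k):
        # scaled Bessel ratio is overflow-safe for large concentrations
        return i1e(k) / i0e(k) - target_r

    return float(brentq(f, 1e-6, 1e6))


# --------------------------------------------------------------------------
# residue templates
# --------------------------------------------------------------------------

_RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")
_RING_RADIUS = 1.4566
_RING_Z = 0.25
_TET = 109.4712206344907  # tetrahedral angle, deg


def _chair_ring() -> dict:
    """Ideal ⁴C₁ chair: hexagon with alternating ±0.25 Å z displacements.

    The ring runs clockwise in the xy plane when viewed from +z; with this
    winding the Cremer–Pople mean-plane normal points along +z and the
    O5-up chair lands at θ ≈ 0 (⁴C₁).
    """
    coords = {}
    for k, name in enumerate(_RING_NAMES):
        ang = np.radians(-60.0 * k)
        z = _RING_Z if k % 2 == 0 else -_RING_Z
        coords[name] = np.array(
            [_RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang), z]
        )
    return coords


def _exo_dirs(p, nb1, nb2):
    """(equatorial, axial) unit substituent directions at ring atom ``p``.

    Both directions make tetrahedral angles with the two ring bonds; the
    axial one is the one more nearly parallel to the template z axis.
    """
    a = (nb1 - p) / np.linalg.norm(nb1 - p)
    b = (nb2 - p) / np.linalg.norm(nb2 - p)
    g = float(a @ b)
    u = -(a + b)
    u /= np.linalg.norm(u)
    ua = -np.sqrt((1.0 + g) / 2.0)        # u·a by construction
    alpha = (np.cos(np.radians(_TET))) / ua
    w = np.cross(a, b)
    w /= np.linalg.norm(w)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    d1 = alpha * u + beta * w
    d2 = alpha * u - beta * w
    if abs(d1[2]) >= abs(d2[2]):
        ax, eq = d1, d2
    else:
        ax, eq = d2, d1
    return eq, ax


@dataclass
class _Residue:
    kind: str                      # "GlcA" or "GalNAc"
    name: str                      # residue name incl. sulfation suffix
    order: list                    # atom names in build order
    coords: dict                   # name -> (3,) template coordinates
    meta: dict                     # name -> (element, moiety, roles)
    bonds: list                    # (name, name) pairs
    chain_refs: dict               # name -> (c, b, a) reference names


def _residue_template(kind: str, *, s2=False, s4=False, s6=False,
                      glyco_pos: Optional[int] = None) -> _Residue:
    """Idealized ⁴C₁ residue template with substituents.

    ``glyco_pos`` marks O3 or O4 as the glycosidic oxygen (no hydrogen,
    backbone acceptor).  The anomeric O1/HO1 are always built; the
    assembler drops them for the non-reducing residue and reuses the O1
    position as the glycosidic attachment direction.  Nonpolar CH
    hydrogens are omitted throughout: no analysis stage consumes them.
    """
    ring = _chair_ring()
    order = list(_RING_NAMES)
    coords = dict(ring)
    meta = {}
    bonds = []
    chain_refs: dict = {}
    for name in _RING_NAMES:
        el = "O" if name == "O5" else "C"
        roles = frozenset({"acceptor"}) if name == "O5" else frozenset()
        meta[name] = (el, "ring", roles)
    for i, j in zip(_RING_NAMES, _RING_NAMES[1:] + _RING_NAMES[:1]):
        bonds.append((i, j))

    neighbors = {
        "C1": ("O5", "C2"), "C2": ("C1", "C3"), "C3": ("C2", "C4"),
        "C4": ("C3", "C5"), "C5": ("C4", "O5"),
    }

    def add_direct(name, parent, direction, length, element, moiety, roles):
        coords[name] = coords[parent] + direction * length
        order.append(name)
        meta[name] = (element, moiety, frozenset(roles))
        bonds.append((parent, name))
        n1, n2 = neighbors[parent]
        chain_refs[name] = (parent, n1, n2)

    def add_nerf(name, refs, r, theta, chi, element, moiety, roles):
        c, b, a = refs
        coords[name] = place_nerf(coords[a], coords[b], coords[c], r, theta, chi)
        order.append(name)
        meta[name] = (element, moiety, frozenset(roles))
        bonds.append((c, name))
        chain_refs[name] = refs

    def add_hydroxyl(oname, parent, direction, hname):
        add_direct(oname, parent, direction, 1.43, "O", "hydroxyl",
                   {"donor_heavy", "acceptor"})
        add_nerf(hname, (oname, parent, neighbors[parent][0]),
                 0.96, 108.0, 180.0, "H", "hydroxyl", {"polar_hydrogen"})

    def add_sulfate(oname, parent, direction, tag):
        # ester O + S + three terminal O; the whole group is one moiety
        add_direct(oname, parent, direction, 1.43, "O", "sulfate", {"acceptor"})
        sname = f"S{tag}"
        add_nerf(sname, (oname, parent, neighbors[parent][0]),
                 1.60, 118.0, 180.0, "S", "sulfate", set())
        for k, chi in enumerate((60.0, 180.0, 300.0), start=1):
            add_nerf(f"O{tag}S{k}", (sname, oname, parent),
                     1.45, 105.0, chi, "O", "sulfate", {"acceptor"})

    def eq(parent):
        n1, n2 = neighbors[parent]
        return _exo_dirs(coords[parent], coords[n1], coords[n2])[0]

    def ax(parent):
        n1, n2 = neighbors[parent]
        return _exo_dirs(coords[parent], coords[n1], coords[n2])[1]

    # anomeric position (β ⇒ equatorial at C1 for both sugars in ⁴C₁)
    add_direct("O1", "C1", eq("C1"), 1.43, "O", "anomeric",
               {"donor_heavy", "acceptor"})
    add_nerf("HO1", ("O1", "C1", "O5"), 0.96, 108.0, 180.0,
             "H", "anomeric", {"polar_hydrogen"})

    if kind == "GlcA":
        if s2:
            add_sulfate("O2", "C2", eq("C2"), "2")
        else:
            add_hydroxyl("O2", "C2", eq("C2"), "HO2")
        if glyco_pos == 3:
            add_direct("O3", "C3", eq("C3"), 1.43, "O", "ring", {"acceptor"})
        else:
            add_hydroxyl("O3", "C3", eq("C3"), "HO3")
        if glyco_pos == 4:
            add_direct("O4", "C4", eq("C4"), 1.43, "O", "ring", {"acceptor"})
        else:
            add_hydroxyl("O4", "C4", eq("C4"), "HO4")
        # carboxylate at C5
        add_direct("C6", "C5", eq("C5"), 1.52, "C", "carboxylate", set())
        add_nerf("O6A", ("C6", "C5", "O5"), 1.25, 117.0, 90.0,
                 "O", "carboxylate", {"acceptor"})
        add_nerf("O6B", ("C6", "C5", "O5"), 1.25, 117.0, 270.0,
                 "O", "carboxylate", {"acceptor"})
        rname = "GlcA" + ("2S" if s2 else "")
    elif kind == "GalNAc":
        # acetamido at C2
        add_direct("N2", "C2", eq("C2"), 1.45, "N", "acetamido", {"donor_heavy"})
        # amide plane rotated to 270° about C2-N2: keeps the chain clear of
        # the partner residue across the β1→3 linkage at typical Φ/Ψ
        add_nerf("HN2", ("N2", "C2", "C1"), 1.01, 117.0, 90.0,
                 "H", "acetamido", {"polar_hydrogen"})
        add_nerf("C2N", ("N2", "C2", "C1"), 1.33, 123.0, 270.0,
                 "C", "acetamido", set())
        add_nerf("O2N", ("C2N", "N2", "C2"), 1.23, 122.0, 0.0,
                 "O", "acetamido", {"acceptor"})
        add_nerf("CME", ("C2N", "N2", "C2"), 1.50, 115.0, 180.0,
                 "C", "acetamido", set())
        if glyco_pos == 3:
            add_direct("O3", "C3", eq("C3"), 1.43, "O", "ring", {"acceptor"})
        else:
            add_hydroxyl("O3", "C3", eq("C3"), "HO3")
        # galacto configuration: O4 axial
        if s4:
            add_sulfate("O4", "C4", ax("C4"), "4")
        else:
            add_hydroxyl("O4", "C4", ax("C4"), "HO4")
        # exocyclic C6-O6 arm
        add_direct("C6", "C5", eq("C5"), 1.52, "C", "other", set())
        if s6:
            # chain: C6-O6(-S6(-O6S1..3))
            add_nerf("O6", ("C6", "C5", "O5"), 1.43, 109.5, 180.0,
                     "O", "sulfate", {"acceptor"})
            chain_refs["O6"] = ("C6", "C5", "O5")
            add_nerf("S6", ("O6", "C6", "C5"), 1.60, 118.0, 180.0,
                     "S", "sulfate", set())
            for k, chi in enumerate((60.0, 180.0, 300.0), start=1):
                add_nerf(f"O6S{k}", ("S6", "O6", "C6"),
                         1.45, 105.0, chi, "O", "sulfate", {"acceptor"})
        else:
            add_nerf("O6", ("C6", "C5", "O5"), 1.43, 109.5, 180.0,
                     "O", "hydroxyl", {"donor_heavy", "acceptor"})
            add_nerf("HO6", ("O6", "C6", "C5"), 0.96, 108.0, 180.0,
                     "H", "hydroxyl", {"polar_hydrogen"})
        suffix = ("4S" if s4 else "") + ("6S" if s6 else "")
        rname = "GalNAc" + suffix
    else:
        raise ValueError(f"unknown residue kind {kind!r}")

    return _Residue(kind=kind, name=rname, order=order, coords=coords,
                    meta=meta, bonds=bonds, chain_refs=chain_refs)


# --------------------------------------------------------------------------
# disaccharide assembly
# --------------------------------------------------------------------------

_GLYCOSIDIC_VALENCE_ANGLE = 116.0  # C1-Og-Cx', deg


@dataclass
class _BuildRecipe:
    """Everything needed to rebuild the reducing residue at new (Φ, Ψ).

    ``entries`` hold ``(atom_index, (c, b, a) indices, r, theta, chi)``
    with ``chi`` a float or the sentinel strings ``"phi"``/``"psi"``.
    ``base`` is the full solute frame at the reference torsions;
    ``rebuilt`` lists the atom indices the entries overwrite.
    """

    base: np.ndarray
    entries: list
    rebuilt: list


def _templates_for(spec: DisaccharideSpec):
    s2 = "GlcA-2S" in spec.sulfation
    s4 = "GalNAc-4S" in spec.sulfation
    s6 = "GalNAc-6S" in spec.sulfation
    if spec.residue_order == "acid_amine":     # GlcA (β1→3) GalNAc
        tpl_a = _residue_template("GlcA", s2=s2)
        tpl_b = _residue_template("GalNAc", s4=s4, s6=s6, glyco_pos=3)
        og_name, attach, after = "O3", "C3", "C4"
    else:                                      # GalNAc (β1→4) GlcA
        tpl_a = _residue_template("GalNAc", s4=s4, s6=s6)
        tpl_b = _residue_template("GlcA", s2=s2, glyco_pos=4)
        og_name, attach, after = "O4", "C4", "C5"
    return tpl_a, tpl_b, og_name, attach, after


def _assemble(spec: DisaccharideSpec, phi: float, psi: float):
    """Build topology + reference frame + rebuild recipe."""
    tpl_a, tpl_b, og_name, attach, after = _templates_for(spec)

    a_names = [n for n in tpl_a.order if n not in ("O1", "HO1")]
    b_names = list(tpl_b.order)

    atoms = []
    index = {}
    for n in a_names:
        el, moi, roles = tpl_a.meta[n]
        index[(0, n)] = len(atoms)
        atoms.append(AtomRecord(len(atoms), n, el, 0, tpl_a.name, moi,
                                0.0, roles))
    for n in b_names:
        el, moi, roles = tpl_b.meta[n]
        index[(1, n)] = len(atoms)
        atoms.append(AtomRecord(len(atoms), n, el, 1, tpl_b.name, moi,
                                0.0, roles))

    bonds = set()
    for i, j in tpl_a.bonds:
        if "O1" in (i, j) or "HO1" in (i, j):
            continue
        bonds.add(frozenset((index[(0, i)], index[(0, j)])))
    for i, j in tpl_b.bonds:
        bonds.add(frozenset((index[(1, i)], index[(1, j)])))
    bonds.add(frozenset((index[(0, "C1")], index[(1, og_name)])))

    coords = np.zeros((len(atoms), 3))
    for n in a_names:
        coords[index[(0, n)]] = tpl_a.coords[n]
    og_idx = index[(1, og_name)]
    coords[og_idx] = tpl_a.coords["O1"]   # glycosidic O sits where O1 was

    # ring chain of residue B, walked from the attachment carbon
    ring_cycle = list(_RING_NAMES)
    start = ring_cycle.index(attach)
    walk = [ring_cycle[(start + k) % 6] for k in range(6)]  # C3,C4,C5,O5,C1,C2

    entries = []
    tb = tpl_b.coords

    def b_idx(name):
        return index[(1, name)]

    # attach carbon: Φ; next ring atom: Ψ; both anchored through residue A
    r_at = float(np.linalg.norm(tb[attach] - tb[og_name]))
    entries.append((b_idx(attach),
                    (og_idx, index[(0, "C1")], index[(0, "O5")]),
                    r_at, _GLYCOSIDIC_VALENCE_ANGLE, "phi"))
    r_af = float(np.linalg.norm(tb[after] - tb[attach]))
    th_af = float(bond_angle(tb[after], tb[attach], tb[og_name]))
    entries.append((b_idx(after),
                    (b_idx(attach), og_idx, index[(0, "C1")]),
                    r_af, th_af, "psi"))
    # remaining ring atoms: internal coordinates copied from the template
    chain = [og_name, attach, after]
    for name in walk[2:]:
        c, b, a = chain[-1], chain[-2], chain[-3]
        r, th, chi = measure_internal(tb[name], tb[c], tb[b], tb[a])
        entries.append((b_idx(name), (b_idx(c), b_idx(b), b_idx(a)), r, th, chi))
        chain.append(name)
    # substituents of residue B: template reference triples
    for name in b_names:
        if name in _RING_NAMES or name == og_name:
            continue
        c, b, a = tpl_b.chain_refs[name]
        r, th, chi = measure_internal(tb[name], tb[c], tb[b], tb[a])
        entries.append((b_idx(name), (b_idx(c), b_idx(b), b_idx(a)), r, th, chi))

    recipe = _BuildRecipe(base=coords, entries=entries,
                          rebuilt=[e[0] for e in entries])
    frame = _rebuild(recipe, np.array([phi]), np.array([psi]))[0]

    phi_atoms = (index[(0, "O5")], index[(0, "C1")], og_idx, b_idx(attach))
    psi_atoms = (index[(0, "C1")], og_idx, b_idx(attach), b_idx(after))
    linkage = LinkageSpec(kind=spec.linkage, phi_atoms=phi_atoms,
                          psi_atoms=psi_atoms)
    rings = [
        tuple(index[(0, n)] for n in _RING_NAMES),
        tuple(index[(1, n)] for n in _RING_NAMES),
    ]
    topology = Topology(atoms=atoms, bonds=bonds, rings=rings, linkage=linkage)
    return topology, frame, recipe


def _rebuild(recipe: _BuildRecipe, phi: np.ndarray, psi: np.ndarray
             ) -> np.ndarray:
    """Vectorized reconstruction of all frames at the given torsions."""
    F = len(phi)
    coords = np.broadcast_to(recipe.base, (F,) + recipe.base.shape).copy()
    for idx, (c, b, a), r, th, chi in recipe.entries:
        if chi == "phi":
            chi_v = phi
        elif chi == "psi":
            chi_v = psi
        else:
            chi_v = np.full(F, chi)
        coords[:, idx] = place_nerf(
            coords[:, a], coords[:, b], coords[:, c],
            np.full(F, r), np.full(F, th), chi_v,
        )
    return coords


def build_disaccharide(spec: DisaccharideSpec, phi: float, psi: float):
    """Build an idealized disaccharide at the requested glycosidic torsions.

    Returns ``(topology, frame)`` where ``frame`` is an ``(n_atoms, 3)``
    coordinate array.  The realized Φ/Ψ equal the request to well within
    0.5° (the construction is exact up to floating-point error).
    """
    phi, psi = float(phi), float(psi)
    for label, v in (("phi", phi), ("psi", psi)):
        if not -180.0 < v <= 180.0:
            raise ValueError(f"{label} must lie in (-180, 180], got {v}")
    topology, frame, _ = _assemble(spec, phi, psi)
    topology = assign_toy_charges(topology)
    return topology, frame


# --------------------------------------------------------------------------
# toy charges
# --------------------------------------------------------------------------

_WATER_CHARGES = {"O": -0.834, "H": 0.417}


def assign_toy_charges(topology: Topology) -> Topology:
    """Assign documented per-moiety toy charges.

    Targets: every sulfate group sums to −1 e, the carboxylate to −1 e,
    water and all neutral moieties (hydroxyl, anomeric, acetamido, ring)
    to 0, so the total solute charge is −(1 + number of sulfate groups).
    These are bookkeeping charges for the toy force field, not fitted
    charges.
    """
    charges = {}
    for res, moiety, ids in topology.moiety_instances():
        group = [topology.atoms[i] for i in ids]
        if moiety in ("hydroxyl", "anomeric"):
            for a in group:
                charges[a.atom_id] = 0.4 if a.element == "H" else -0.4
        elif moiety == "sulfate":
            for a in group:
                if a.element == "S":
                    charges[a.atom_id] = 1.25
                else:
                    bonded = topology.bonded_to(a.atom_id)
                    ester = any(topology.atoms[j].element != "S" for j in bonded)
                    charges[a.atom_id] = -0.25 if ester else -2.0 / 3.0
        elif moiety == "carboxylate":
            for a in group:
                charges[a.atom_id] = 0.8 if a.element == "C" else -0.9
        elif moiety == "acetamido":
            table = {"N": -0.6, "H": 0.4, "O": -0.5}
            for a in group:
                if a.element == "C":
                    has_o = any(
                        topology.atoms[j].element == "O"
                        for j in topology.bonded_to(a.atom_id)
                    )
                    charges[a.atom_id] = 0.55 if has_o else 0.15
                else:
                    charges[a.atom_id] = table[a.element]
        elif moiety == "water":
            for a in group:
                charges[a.atom_id] = _WATER_CHARGES[a.element]
        elif moiety == "ion":
            for a in group:
                charges[a.atom_id] = 1.0 if a.element in ("Na", "K") else -1.0
        else:  # ring, other
            for a in group:
                charges[a.atom_id] = 0.0
    atoms = [replace(a, charge=charges[a.atom_id]) for a in topology.atoms]
    return Topology(atoms=atoms, bonds=topology.bonds, rings=topology.rings,
                    linkage=topology.linkage,
                    water_residue_indices=topology.water_residue_indices)


# --------------------------------------------------------------------------
# trajectory sampling
# --------------------------------------------------------------------------

_HB_ON_DISTANCE = 2.8     # realized donor-acceptor distance when planted on
_HB_OFF_DISTANCE = 3.6    # explicit break distance (> cutoff + jitter margin)
_OH_BOND = 0.96
_BULK_MIN_DIST = 5.0      # decoy waters stay at least this far from solute
_BULK_MAX_DIST = 14.0


def _water_atoms(res_index: int, start_id: int):
    out = []
    specs = [("OW", "O", frozenset({"donor_heavy", "acceptor"})),
             ("HW1", "H", frozenset({"polar_hydrogen"})),
             ("HW2", "H", frozenset({"polar_hydrogen"}))]
    for k, (name, el, roles) in enumerate(specs):
        out.append(AtomRecord(start_id + k, name, el, res_index, "HOH",
                              "water", _WATER_CHARGES[el], roles))
    return out


def _sample_far_positions(rng, n, solute_cloud, center):
    """Rejection-sample ``n`` points ≥ _BULK_MIN_DIST from every cloud point."""
    out = []
    lo = center - _BULK_MAX_DIST
    hi = center + _BULK_MAX_DIST
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200000:
            raise RuntimeError("could not place bulk waters; box too crowded")
        p = rng.uniform(lo, hi)
        d2 = np.sum((solute_cloud - p) ** 2, axis=1)
        if d2.min() >= _BULK_MIN_DIST ** 2:
            if out:
                prev = np.array(out)
                if np.sum((prev - p) ** 2, axis=1).min() < 2.6 ** 2:
                    continue
            out.append(p)
    return np.array(out)


def _resolve_atom(topology: Topology, path, what: str) -> int:
    res, name = path
    for a in topology.atoms:
        if a.residue_index == res and a.name == name:
            return a.atom_id
    raise ValueError(f"{what} atom {name!r} not found in residue {res}")


def sample_trajectory(run: SyntheticRunSpec):
    """Draw a synthetic trajectory; returns ``(Trajectory, GroundTruth)``.

    Per frame: a mixture component is drawn by weight, (Φ, Ψ) are drawn
    from its von Mises marginals, the reducing residue is rebuilt at those
    torsions, Gaussian jitter of ``jitter_sigma`` is added to every atom,
    and each planted H-bond is realized (donor-acceptor distance 2.8 Å,
    D-H-A angle 180°) or explicitly broken (distance 3.6 Å, hydrogen
    pointing away) by moving the designated exocyclic atom or bridging
    water.  Surgery happens after jitter, so planted geometry is exact and
    the ground-truth record is never flipped by noise.
    """
    rng = np.random.default_rng(run.seed)
    comps = run.torsions.components
    weights = np.array([c.weight for c in comps])
    F = run.n_frames

    component = rng.choice(len(comps), size=F, p=weights)
    mu_phi = np.radians([c.mean_phi for c in comps])
    mu_psi = np.radians([c.mean_psi for c in comps])
    k_phi = np.array([c.kappa_phi for c in comps])
    k_psi = np.array([c.kappa_psi for c in comps])
    phi = wrap_angle(np.degrees(rng.vonmises(mu_phi[component], k_phi[component])))
    psi = wrap_angle(np.degrees(rng.vonmises(mu_psi[component], k_psi[component])))
    phi = np.atleast_1d(phi)
    psi = np.atleast_1d(psi)

    solute_top, _, recipe = _assemble(run.disaccharide, comps[0].mean_phi,
                                      comps[0].mean_psi)
    solute = _rebuild(recipe, phi, psi)
    n_solute = solute.shape[1]

    # chair mixture: a global mirror through the mean plane turns both
    # ⁴C₁ rings into ¹C₄ (a testing device, not physical ring dynamics);
    # mirrored frames have their torsion signs flipped accordingly
    labels = (run.pucker_label if isinstance(run.pucker_label, dict)
              else {run.pucker_label: 1.0})
    p_inverted = labels.get("1C4", 0.0)
    inverted = rng.random(F) < p_inverted
    if inverted.any():
        solute[inverted, :, 2] *= -1.0
        phi = np.where(inverted, wrap_angle(-phi), phi)
        psi = np.where(inverted, wrap_angle(-psi), psi)

    # jitter before surgery: planted bonds keep exact geometry
    if run.jitter_sigma > 0:
        solute = solute + rng.normal(0.0, run.jitter_sigma, solute.shape)

    # waters: one dedicated water per via_water bond, then decoys
    via = [b for b in run.planted_hbonds if b.via_water]
    direct = [b for b in run.planted_hbonds if not b.via_water]
    n_waters = len(via) + run.n_bulk_waters

    atoms = list(solute_top.atoms)
    bonds = set(solute_top.bonds)
    water_res = set()
    for w in range(n_waters):
        res = 2 + w
        wat = _water_atoms(res, len(atoms))
        bonds.add(frozenset((wat[0].atom_id, wat[1].atom_id)))
        bonds.add(frozenset((wat[0].atom_id, wat[2].atom_id)))
        atoms.extend(wat)
        water_res.add(res)
    topology = Topology(atoms=atoms, bonds=bonds, rings=solute_top.rings,
                        linkage=solute_top.linkage,
                        water_residue_indices=water_res)
    topology = assign_toy_charges(topology)

    coords = np.zeros((F, len(atoms), 3))
    coords[:, :n_solute] = solute

    # static far positions for decoys and parked bridge waters, checked
    # against the solute cloud of strided frames with margin over 4.5 Å
    stride = max(1, F // 64)
    cloud = solute[::stride].reshape(-1, 3)
    center = solute[0].mean(axis=0)
    far = _sample_far_positions(rng, n_waters, cloud, center)
    hw_dirs = rng.normal(size=(n_waters, 2, 3))
    hw_dirs /= np.linalg.norm(hw_dirs, axis=2, keepdims=True)
    for w in range(n_waters):
        ow = n_solute + 3 * w
        coords[:, ow] = far[w]
        coords[:, ow + 1] = far[w] + _OH_BOND * hw_dirs[w, 0]
        coords[:, ow + 2] = far[w] + _OH_BOND * hw_dirs[w, 1]
    if run.jitter_sigma > 0 and n_waters:
        coords[:, n_solute:] += rng.normal(
            0.0, run.jitter_sigma, coords[:, n_solute:].shape
        )

    hbond_status: dict = {}
    bond_water: dict = {}
    moved: set = set()

    # direct planted bonds: translate the movable exocyclic partner
    for pb in direct:
        d_heavy = _resolve_atom(topology, pb.donor, "donor")
        acc = _resolve_atom(topology, pb.acceptor, "acceptor")
        arec, drec = topology.atoms[acc], topology.atoms[d_heavy]
        if "donor_heavy" not in drec.hbond_role:
            raise ValueError(f"planted donor {pb.donor} has no donor role")
        if "acceptor" not in arec.hbond_role:
            raise ValueError(f"planted acceptor {pb.acceptor} has no acceptor role")
        hyds = [j for j in topology.bonded_to(d_heavy)
                if "polar_hydrogen" in topology.atoms[j].hbond_role]
        if not hyds:
            raise ValueError(f"planted donor {pb.donor} carries no polar hydrogen")
        hyd = hyds[0]
        if drec.moiety not in ("hydroxyl", "anomeric"):
            raise ValueError(
                f"planted direct bond requires an exocyclic hydroxyl/anomeric "
                f"donor to move; {pb.donor} is {drec.moiety}"
            )
        if d_heavy in moved or hyd in moved:
            raise ValueError(f"atom {pb.donor} used by two planted bonds")
        moved.update((d_heavy, hyd))

        on = rng.random(F) < pb.occupancy
        u = coords[:, d_heavy] - coords[:, acc]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        dist = np.where(on, _HB_ON_DISTANCE, _HB_OFF_DISTANCE)[:, None]
        coords[:, d_heavy] = coords[:, acc] + u * dist
        to_acc = coords[:, acc] - coords[:, d_heavy]
        to_acc /= np.linalg.norm(to_acc, axis=1, keepdims=True)
        h_dir = np.where(on[:, None], to_acc, -to_acc)
        coords[:, hyd] = coords[:, d_heavy] + _OH_BOND * h_dir
        hbond_status[pb.key] = on

    # via-water bonds: a dedicated water bridges the two named acceptors
    for w, pb in enumerate(via):
        a1 = _resolve_atom(topology, pb.donor, "bridge partner")
        a2 = _resolve_atom(topology, pb.acceptor, "bridge partner")
        for i, path in ((a1, pb.donor), (a2, pb.acceptor)):
            if "acceptor" not in topology.atoms[i].hbond_role:
                raise ValueError(
                    f"via_water bridge partner {path} must be an acceptor"
                )
        ow = n_solute + 3 * w
        res = 2 + w
        on = rng.random(F) < pb.occupancy

        p1 = coords[:, a1]
        p2 = coords[:, a2]
        mid = 0.5 * (p1 + p2)
        d = np.linalg.norm(p2 - p1, axis=1)
        feasible = d < 2.0 * _HB_ON_DISTANCE - 1e-3
        on = on & feasible
        h = np.sqrt(np.maximum(_HB_ON_DISTANCE ** 2 - (d / 2.0) ** 2, 0.0))
        axis = (p2 - p1) / np.maximum(d, 1e-12)[:, None]
        out_dir = mid - center
        out_dir = out_dir - axis * np.sum(out_dir * axis, axis=1, keepdims=True)
        nrm = np.linalg.norm(out_dir, axis=1, keepdims=True)
        fallback = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        fb_n = np.linalg.norm(fallback, axis=1, keepdims=True)
        out_dir = np.where(nrm > 1e-8, out_dir / np.maximum(nrm, 1e-12),
                           fallback / np.maximum(fb_n, 1e-12))
        ow_pos = mid + out_dir * h[:, None]
        u1 = (p1 - ow_pos)
        u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
        u2 = (p2 - ow_pos)
        u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
        onc = on[:, None]
        coords[:, ow] = np.where(onc, ow_pos, coords[:, ow])
        coords[:, ow + 1] = np.where(onc, ow_pos + _OH_BOND * u1,
                                     coords[:, ow + 1])
        coords[:, ow + 2] = np.where(onc, ow_pos + _OH_BOND * u2,
                                     coords[:, ow + 2])
        hbond_status[pb.key] = on
        bond_water[pb.key] = res

    energies = None
    if run.component_energy_offsets is not None:
        offsets = np.asarray(run.component_energy_offsets)
        energies = offsets[component]
        if run.energy_noise_sigma > 0:
            energies = energies + rng.normal(0.0, run.energy_noise_sigma, F)

    traj = Trajectory(topology=topology, coords=coords, box=None,
                      frame_interval=1.0, energies=energies)
    truth = GroundTruth(component=component, phi=phi, psi=psi,
                        hbond_status=hbond_status,
                        bond_water_residue=bond_water,
                        inverted_chair=inverted,
                        planted_bonds=run.planted_hbonds)
    return traj, truth
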
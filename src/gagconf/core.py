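"""Domain types shared by every analysis stage.

The pipeline operates on two-ring glycosaminoglycan (GAG) solutes — here
chondroitin-sulfate-like disaccharides of D-glucuronic acid (GlcA) and
N-acetyl-D-galactosamine (GalNAc) — surrounded by explicit water.  The
static description of such a system (atoms, bonds, rings, donor/acceptor
roles, the glycosidic linkage) lives in :class:`Topology`; the dynamic part
(Cartesian coordinates per frame, optional box and per-frame energies) in
:class:`Trajectory`.

Conventions used throughout the package:

* coordinates in Å, angles in degrees in the half-open interval
  ``(-180, +180]``, energies in kcal/mol;
* 0-based indices everywhere in memory; 1-based only at file-format
  boundaries (PDB serial numbers);
* atom ordering is stable: frame ``i``, atom ``j`` always refers to the
  same :class:`AtomRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "MOIETIES",
    "HBOND_ROLES",
    "AtomRecord",
    "LinkageSpec",
    "Topology",
    "Trajectory",
    "AnalysisConfig",
    "TopologyError",
]

#: Chemical-group tags an atom may carry.  ``ring`` covers ring carbons and
#: the endocyclic oxygen; the glycosidic oxygen is tagged ``ring`` as well
#: (it is part of the backbone, not of a substituent group).
MOIETIES = frozenset(
    {"ring", "hydroxyl", "sulfate", "carboxylate", "acetamido",
     "anomeric", "water", "ion", "other"}
)

#: Hydrogen-bonding roles.  A heavy atom may be a donor (it carries at least
#: one polar hydrogen), an acceptor, or both; polar hydrogens are flagged
#: separately so detection can iterate D-H...A triplets directly.
HBOND_ROLES = frozenset({"donor_heavy", "acceptor", "polar_hydrogen"})

LinkageKind = Literal["beta_1_3", "beta_1_4"]


class TopologyError(ValueError):
    """Raised when a topology annotation is inconsistent or incomplete."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the system.

    Parameters
    ----------
    atom_id:
        0-based position of the atom in the coordinate arrays.
    name:
        Short atom name, e.g. ``"O5"``, ``"C1"``, ``"HO3"``, ``"S4"``,
        ``"OW"``.
    element:
        Chemical element symbol.
    residue_index:
        0-based residue number; residue 0 is the non-reducing-end sugar.
    residue_name:
        Chemical residue name (``"GlcA"``, ``"GalNAc6S"``, ``"HOH"``, ...).
    moiety:
        One of :data:`MOIETIES`.
    charge:
        Partial charge in elementary-charge units.
    hbond_role:
        Subset of :data:`HBOND_ROLES`.
    """

    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    moiety: str
    charge: float = 0.0
    hbond_role: frozenset = frozenset()

    def __post_init__(self):
        if self.moiety not in MOIETIES:
            raise TopologyError(
                f"atom {self.name!r} (id {self.atom_id}): unknown moiety "
                f"{self.moiety!r}"
            )
        role = frozenset(self.hbond_role)
        if not role <= HBOND_ROLES:
            raise TopologyError(
                f"atom {self.name!r} (id {self.atom_id}): unknown hbond role "
                f"{sorted(role - HBOND_ROLES)}"
            )
        object.__setattr__(self, "hbond_role", role)


@dataclass(frozen=True)
class LinkageSpec:
    """The glycosidic linkage and the atom quadruples defining Φ and Ψ.

    For a β1→3 linkage Φ is the dihedral O5-C1-O3′-C3′ and Ψ is
    C1-O3′-C3′-C4′; for β1→4 they are O5-C1-O4′-C4′ and C1-O4′-C4′-C5′
    (primed atoms belong to the reducing-end residue).
    """

    kind: LinkageKind
    phi_atoms: tuple
    psi_atoms: tuple

    def __post_init__(self):
        if self.kind not in ("beta_1_3", "beta_1_4"):
            raise TopologyError(f"unknown linkage kind {self.kind!r}")
        for label, quad in (("phi", self.phi_atoms), ("psi", self.psi_atoms)):
            if len(quad) != 4:
                raise TopologyError(f"{label}_atoms must name 4 atoms")
        object.__setattr__(self, "phi_atoms", tuple(int(i) for i in self.phi_atoms))
        object.__setattr__(self, "psi_atoms", tuple(int(i) for i in self.psi_atoms))


@dataclass
class Topology:
    """Static description of the solute + solvent system.

    ``rings`` lists each pyranose ring as the 6-tuple of atom ids in the
    order O5, C1, C2, C3, C4, C5 — the order assumed by the pucker stage.
    """

    atoms: list
    bonds: set
    rings: list = field(default_factory=list)
    linkage: Optional[LinkageSpec] = None
    water_residue_indices: set = field(default_factory=set)

    def __post_init__(self):
        self.bonds = {frozenset(b) for b in self.bonds}
        self.rings = [tuple(int(a) for a in ring) for ring in self.rings]
        self.water_residue_indices = set(self.water_residue_indices)
        self._validate()

    # -- derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def solute_atom_ids(self) -> set:
        """Ids of atoms belonging to neither water nor ions."""
        return {
            a.atom_id
            for a in self.atoms
            if a.residue_index not in self.water_residue_indices
            and a.moiety != "ion"
        }

    @property
    def water_atom_ids(self) -> set:
        return {
            a.atom_id
            for a in self.atoms
            if a.residue_index in self.water_residue_indices
        }

    def bonded_to(self, atom_id: int) -> list:
        return sorted(
            next(iter(b - {atom_id}))
            for b in self.bonds
            if atom_id in b and len(b) == 2
        )

    def donors(self) -> list:
        """(heavy, hydrogen) pairs for every polar hydrogen."""
        out = []
        for a in self.atoms:
            if "polar_hydrogen" in a.hbond_role:
                heavies = [
                    j for j in self.bonded_to(a.atom_id)
                    if "donor_heavy" in self.atoms[j].hbond_role
                ]
                if len(heavies) != 1:
                    raise TopologyError(
                        f"polar hydrogen {a.name!r} (id {a.atom_id}) must be "
                        f"bonded to exactly one donor heavy atom, found "
                        f"{len(heavies)}"
                    )
                out.append((heavies[0], a.atom_id))
        return out

    def acceptors(self) -> list:
        return [a.atom_id for a in self.atoms if "acceptor" in a.hbond_role]

    def heavy_solute_ids(self) -> list:
        sol = self.solute_atom_ids
        return sorted(
            a.atom_id for a in self.atoms
            if a.atom_id in sol and a.element != "H"
        )

    def moiety_instances(self) -> list:
        """Connected groups of same-moiety atoms.

        Returns a list of ``(residue_index, moiety, tuple_of_atom_ids)``,
        one per chemical group instance: each sulfate, each hydroxyl, the
        carboxylate, the acetamido group, each ring, each water.  Two
        sulfates on one residue form two instances because their atoms are
        not mutually bonded.
        """
        parent = {a.atom_id: a.atom_id for a in self.atoms}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for b in self.bonds:
            i, j = tuple(b)
            ai, aj = self.atoms[i], self.atoms[j]
            if (ai.moiety, ai.residue_index) == (aj.moiety, aj.residue_index):
                parent[find(i)] = find(j)
        groups: dict = {}
        for a in self.atoms:
            groups.setdefault(find(a.atom_id), []).append(a.atom_id)
        out = []
        for ids in groups.values():
            a0 = self.atoms[ids[0]]
            out.append((a0.residue_index, a0.moiety, tuple(sorted(ids))))
        out.sort(key=lambda t: (t[0], t[1], t[2]))
        return out

    def n_sulfate_groups(self) -> int:
        return sum(1 for _, m, _ in self.moiety_instances() if m == "sulfate")

    # -- validation ----------------------------------------------------
    def _validate(self):
        n = self.n_atoms
        for idx, a in enumerate(self.atoms):
            if a.atom_id != idx:
                raise TopologyError(
                    f"atom ids must equal list positions; atom {a.name!r} has "
                    f"id {a.atom_id} at position {idx}"
                )
        for b in self.bonds:
            for i in b:
                if not 0 <= i < n:
                    raise TopologyError(f"bond references unknown atom id {i}")
        for ring in self.rings:
            if len(ring) != 6:
                raise TopologyError("rings must have exactly 6 atoms")
            for i in ring:
                if not 0 <= i < n:
                    raise TopologyError(f"ring references unknown atom id {i}")
            for i, j in zip(ring, ring[1:] + ring[:1]):
                if frozenset((i, j)) not in self.bonds:
                    raise TopologyError(
                        f"ring {ring} is not a cycle in the bond graph "
                        f"({i}-{j} missing)"
                    )
        if self.linkage is not None:
            for i in self.linkage.phi_atoms + self.linkage.psi_atoms:
                if not 0 <= i < n:
                    raise TopologyError(f"linkage references unknown atom id {i}")
        # waters: exactly 1 acceptor oxygen + 2 polar hydrogens
        waters: dict = {}
        for a in self.atoms:
            if a.residue_index in self.water_residue_indices:
                waters.setdefault(a.residue_index, []).append(a)
        for res, atoms in waters.items():
            n_o = sum(
                1 for a in atoms
                if a.element == "O" and "acceptor" in a.hbond_role
            )
            n_h = sum(1 for a in atoms if "polar_hydrogen" in a.hbond_role)
            if (n_o, n_h) != (1, 2):
                raise TopologyError(
                    f"water residue {res} must contain 1 acceptor oxygen and "
                    f"2 polar hydrogens, found {n_o} and {n_h}"
                )
        for a in self.atoms:
            if "polar_hydrogen" in a.hbond_role and a.element != "H":
                raise TopologyError(
                    f"atom {a.name!r} (id {a.atom_id}) is tagged "
                    f"polar_hydrogen but is not a hydrogen"
                )
        # solute and water atom sets are disjoint by construction
        self.donors()  # raises on dangling polar hydrogens


@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates over a fixed topology.

    Attributes
    ----------
    coords:
        ``(n_frames, n_atoms, 3)`` float array, Å.
    box:
        Optional orthorhombic box lengths, ``(n_frames, 3)`` Å.  When
        present, inter-atomic distances use the minimum-image convention.
    frame_interval:
        Time between stored frames (ps); metadata only.
    energies:
        Optional per-frame potential energy (kcal/mol).
    """

    topology: Topology
    coords: np.ndarray
    box: Optional[np.ndarray] = None
    frame_interval: float = 1.0
    energies: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"every frame must have one coordinate per topology atom: "
                f"got {self.coords.shape[1]} coordinates for "
                f"{self.topology.n_atoms} atoms"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.shape != (self.n_frames,):
                raise ValueError("energies must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def frame_box(self, i: int) -> Optional[np.ndarray]:
        return None if self.box is None else self.box[i]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with field-standard defaults.

    Defaults: geometric H-bond criteria of 3.0 Å (heavy-donor to acceptor)
    and 135° (D-H-A); agglomerative-clustering cutoff ε = 2.0 Å; torsion
    histogram bins of 3.6° (a 100×100 grid over the torus); 10 Å nonbonded
    cutoff for the toy force field; 50 bins per principal-component axis
    for energy landscapes.
    """

    hbond_distance_cutoff: float = 3.0
    hbond_angle_cutoff: float = 135.0
    cluster_epsilon: float = 2.0
    torsion_bin_width: float = 3.6
    nonbonded_cutoff: float = 10.0
    rng_seed: int = 0
    landscape_grid: int = 50

    def __post_init__(self):
        for name in ("hbond_distance_cutoff", "hbond_angle_cutoff",
                     "cluster_epsilon", "torsion_bin_width",
                     "nonbonded_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_bins = 360.0 / self.torsion_bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("torsion_bin_width must divide 360 evenly")
        if self.landscape_grid < 1:
            raise ValueError("landscape_grid must be >= 1")


def wrap_angle(angle):
    """Map angles (deg) into the canonical interval ``(-180, 180]``."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def minimum_image(delta: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` is ``(..., 3)``; ``box`` is ``(3,)`` orthorhombic box lengths
    or None (no wrapping).
    """
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)
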
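# Methods

This note documents the models implemented in `gagconf`, the parameter
choices, the scope of the synthetic generator, the numerical decisions,
and the known limitations. All defaults quoted here live in
`gagconf.core.AnalysisConfig` and are overridable per stage.

## Molecular model

A disaccharide is a pair of pyranose residues — D-glucuronic acid (GlcA)
and N-acetyl-D-galactosamine (GalNAc) — joined by a β1→3 bond (GlcA
first: GlcA-β1→3-GalNAc) or a β1→4 bond (GalNAc first:
GalNAc-β1→4-GlcA). Sulfation sites are GlcA-2S, GalNAc-4S and
GalNAc-6S, giving 8 sulfation patterns per linkage and a 16-member
library overall. Topologies carry explicit per-atom annotations
(element, residue, chemical moiety, hydrogen-bond roles), bond lists,
the two six-membered rings, the glycosidic linkage quadruples and the
set of water residues. File I/O uses multi-model PDB or DCD coordinates
plus a JSON topology sidecar, because neither coordinate format can
express these annotations; the reader cross-checks the sidecar against
the coordinate file (atom counts per model, names per atom id) and
reports the first mismatch by model number, line number or atom id. DCD
reads additionally compare the frame count declared in the header with
the frames actually present, so truncated files fail loudly instead of
silently shortening the trajectory.

## Glycosidic torsions

Φ and Ψ are the dihedral angles of the linkage quadruples
(O5–C1–O_link–C_x and C1–O_link–C_x–C_{x±1}), computed with the
standard atan2 formulation and the IUPAC sign convention (clockwise
positive when viewed from the second to the third atom). The test suite
checks the implementation against an independent geometric construction
(projection of the outer bonds onto the plane perpendicular to the
central bond) on randomized quadruples.

Densities are histograms on a toroidal (Φ, Ψ) grid with 3.6° bins
(100×100), half-open bins starting at −180°, +180 wrapped to −180 so
every frame lands in exactly one bin; the grid sums to 1 exactly.

Preferred angles are local maxima of the density with probability at
least 10% of the global maximum, with toroidal wrap-around at the grid
edges. Because a raw histogram of a finite sample has many spurious
single-bin maxima (a unimodal run of a few thousand frames produces
dozens above the 10% threshold), mode detection runs on a copy of the
grid smoothed with a wrapped Gaussian kernel (σ = 2 bins = 7.2°,
configurable via `mode_smoothing_sigma_bins`; 0 disables smoothing).
The reported density grid itself is never smoothed. With the default
smoothing, planted bimodal von Mises mixtures at n = 20,000 frames are
recovered with both modes within one bin of their planted centers.

Two spread measures are reported, because "spread" admits more than one
reasonable definition for circular data: the circular standard
deviation (from the mean resultant length) and the 5–95%
inter-percentile arc (the shortest arc containing the central 90% of
the sample). They agree on near-Gaussian unimodal data and diverge on
multimodal data, which is itself informative.

## Hydrogen bonds

A hydrogen bond is a donor-heavy/hydrogen/acceptor triple with
D···A ≤ 3.0 Å and D–H···A angle ≥ 135° (both boundaries inclusive, both
configurable). Roles come from the topology annotations (hydroxyl and
water oxygens donate and accept; ring, sulfate, carboxylate and
carbonyl oxygens accept). Candidate pairs are enumerated with a KD-tree
when the donor×acceptor pair count is large and a dense distance matrix
otherwise; the two paths are equivalent and both are tested against a
brute-force all-pairs oracle. Water–water bonds are outside the
solute-centric statistics and are skipped everywhere.

Per-pair occupancy is the fraction of frames in which a
(donor-heavy, acceptor) pair is bonded, counted once per frame even if
two hydrogens qualify. The mean intramolecular count averages the
number of solute–solute bonded pairs per frame over all frames,
including frames with none. A bridging water is a water H-bonded to at
least two distinct solute heavy atoms in the same frame (donating or
accepting). Water coordination numbers are reported per chemical-group
instance (each hydroxyl, sulfate, carboxylate, ring oxygen) and for the
solute as a whole.

## Ring pucker

Cremer–Pople puckering coordinates (Q, θ, φ₂) are computed per ring per
frame from the standard z-displacement formulation relative to the
mean-plane frame. Conformer labels (⁴C₁, ¹C₄, boats, twist-boats,
half-chairs, envelopes) are assigned by nearest reference conformer on
the (θ, φ₂) sphere; amplitudes below 10⁻⁸ Å are labelled planar. The
descriptors are invariant under rigid motion to 10⁻⁹ and flip
θ → 180° − θ (⁴C₁ ↔ ¹C₄) under mirror inversion, both asserted in the
tests against analytically constructed rings.

## Superposition and clustering

Optimal superposition uses the Kabsch algorithm (SVD of the covariance,
determinant-corrected to exclude reflections); the RMSD from the
residual formula is accurate to better than 10⁻⁸ Å on rigid-motion
copies and agrees with an independent quaternion (Horn) oracle to
10⁻⁹. Degenerate inputs (fewer than 3 atoms, collinear point sets) are
rejected.

Conformer clustering is hierarchical agglomerative clustering on the
pairwise best-fit RMSD matrix of solute heavy atoms, merging while the
inter-cluster linkage distance (average by default; single and complete
also available) is below ε = 2.0 Å. The implementation is tested for
exact agreement with an exhaustive brute-force agglomeration oracle on
random instances. For long trajectories a sieve is available: cluster
every k-th frame exactly, then assign the remaining frames to the
nearest cluster centroid frame by batched RMSD. Replicate agreement
between runs of the same specification is summarized as the maximum
over population ranks of |p_a − p_b| / max(p_a, p_b) over all replicate
pairs; planted three-family mixtures across three seeds stay below
0.10 when the per-replicate frame count keeps multinomial noise small
(n ≈ 10⁴).

## Toy force field, quenching, PCA landscapes

The energy landscape stage needs per-frame energies. When a run
supplies an energies CSV they are used verbatim. Otherwise frames are
quenched with a deliberately simple toy force field: harmonic bonds and
angles of the form k·δ² (k = 300 kcal/mol/Å² for bonds, 50 kcal/mol/rad²
for angles), optional cosine torsion terms, and shifted-cutoff Coulomb
(k_e = 332.0636 kcal·Å/mol/e², distance-independent dielectric 4) and
Lennard-Jones terms over pairs separated by three or more bonds, with a
10 Å cutoff and the potential shifted to zero at the cutoff. The
`from_reference` constructor takes equilibrium bond lengths and angles
from a reference frame, making that frame strain-free for the bonded
terms. This is an internally consistent, differentiable surrogate — not
a chemically calibrated force field — and is validated by
finite-difference gradient checks rather than against experiment.

Quenching runs a few steepest-descent steps followed by Polak–Ribière
(PR+) conjugate gradient with a secant line search; the energy sequence
is non-increasing, a stretched bond reaches its analytic minimum within
10⁻⁶ Å, and on a strictly quadratic function CG reaches the
direct-solve minimum in at most d iterations (d = number of degrees of
freedom). In the pipeline, quenching is capped at 30 frames (evenly
strided) and 200 CG iterations per frame to bound runtime; supplied
energies bypass the cap.

PCA operates on frames aligned to the first frame (alignment removes
rigid-body motion; it can be disabled), with a deterministic sign
convention on the components. The landscape bins PC1/PC2 projections on
a 50×50 grid (configurable) spanning the data range padded by 5%, and
records the **minimum** energy per cell — the minimum, not the mean,
preserves basin depths and saddle structure. Empty cells are NaN and
every frame maps to exactly one cell, so frame counts are conserved.

## Pipeline

`run_pipeline` applies the configured stages to every run in a
manifest, writes per-run reports (CSV series plus a rounded
`summary.json`), isolates failures (a failing run gets an `error.log`;
the others complete), and writes a cross-run summary with provenance
(package, numpy and Python versions, full configuration). Across runs
it fits cluster count against sulfate count and reports R² overall and
per linkage class (`None` where fewer than three runs or a degenerate
fit make R² meaningless). Outputs are byte-identical across repeated
runs on the same inputs.

## Synthetic generator: scope and margins

The generator produces geometrically idealized, annotation-complete
trajectories with planted ground truth. It is a test instrument, not a
simulator: frames are independent draws, not a dynamical trajectory.

- **Builder**: residues are built as ideal ⁴C₁ chairs with standard
  bond lengths and tetrahedral geometry, joined at the requested
  (Φ, Ψ); the realized torsions match the request to well within 0.5°.
  Torsion mixtures are von Mises in Φ and Ψ with κ derived from a
  requested circular standard deviation; per-frame Gaussian jitter
  (default σ = 0.05 Å) perturbs all coordinates.
- **Planted direct H-bonds**: the donor hydroxyl is rotated to aim at
  the acceptor and the contact is set to 2.8 Å in "on" frames and
  3.6 Å in "off" frames — both clear of the 3.0 Å decision boundary,
  so planted truth is unambiguous under the default criteria.
- **Planted water bridges**: a water is placed 2.8 Å from both
  partners. This is geometrically feasible only when the partners are
  closer than 5.6 Å, so a bridge planted in a frame where the sampled
  torsions put the partners farther apart is marked "off" in the
  ground truth (the planted occupancy is an upper bound; choosing
  partner pairs that stay under 5.6 Å across the torsion distribution
  makes it exact). Bulk waters are parked at least 5 Å from the solute
  and from each other, outside H-bond range.
- **Pucker mixing**: a ¹C₄ fraction inverts the GalNAc ring
  z-displacements; the per-frame chair assignment is recorded.
- **Energies**: optional per-component energy offsets plus Gaussian
  noise produce per-frame energies with known basin structure.
- **Charges**: toy partial charges give each solute a net charge of
  −(1 + number of sulfates).

Everything is driven by a single integer seed (< 2³¹) and is
bit-reproducible.

## Numerical choices

- float64 throughout analysis; DCD storage is float32 (round trip
  within 10⁻⁴ Å), PDB coordinates have 3 decimal places (5×10⁻⁴ Å).
- Dihedrals use atan2, never arccos, to keep the sign and avoid
  precision loss near 0°/180°.
- Batched pairwise RMSD uses the trace formula, which loses roughly
  half the significant digits near zero (~10⁻⁷ Å on exact copies); the
  single-pair path uses the residual formula (<10⁻⁸ Å). The batched
  path is only used for sieve assignment, where this is irrelevant.
- Circular statistics (means, standard deviations, percentile arcs)
  always operate on wrapped angles in (−180°, 180°].
- Reports round to 6 decimals with sorted keys, making reruns
  byte-identical.

## Limitations

- The generator's frames are i.i.d. samples, so time-correlated
  quantities (lifetimes, autocorrelations, kinetics) are out of scope.
- The toy force field is a surrogate for exercising the minimizer and
  landscape code; its energies are not comparable to any molecular
  mechanics force field.
- Ring geometry in the builder is idealized; pucker analysis of real
  trajectories is supported, but the generator only plants chair
  states (no boats or skew-boats).
- Planted water bridges require the partner pair to be within
  geometric reach (see above); occupancies for marginal pairs are
  upper bounds.
- Periodic-boundary support is limited to the minimum-image convention
  for orthorhombic boxes in hydrogen-bond detection.
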
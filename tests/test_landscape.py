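import numpy as np
import pytest

from oracles import fd_gradient

from gagconf.core import AtomRecord, Topology, Trajectory
from gagconf.landscape import (
    COULOMB_K,
    EnergyLandscape,
    ToyForceField,
    build_landscape,
    energy_and_gradient,
    minimize_cg,
    minimize_sd,
    pca_frames,
    quench,
)
from gagconf.synthetic import (
    MixtureComponent,
    SyntheticRunSpec,
    TorsionMixture,
    kappa_for_circular_std,
    sample_trajectory,
)
from conftest import make_spec


def _chain_topology(n=4, charges=(0.3, -0.3, 0.3, -0.3)):
    atoms = [AtomRecord(i, f"C{i}", "C", 0, "GlcA", "other", charges[i],
                        frozenset()) for i in range(n)]
    bonds = {(i, i + 1) for i in range(n - 1)}
    return Topology(atoms=atoms, bonds=bonds)


def _chain_frame():
    return np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                     [2.3, 1.2, 0.0], [3.8, 1.4, 0.9]])


class TestToyForceField:
    def test_reference_is_strain_free_for_bonded_terms(self):
        top = _chain_topology()
        ref = _chain_frame()
        ff = ToyForceField.from_reference(top, ref)
        # zero out the nonbonded terms: pure bonded energy must vanish
        ff.nb_pairs = np.zeros((0, 2), int)
        e, g = energy_and_gradient(ref, top, ff)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.max(np.abs(g)) < 1e-9

    def test_exclusions_1_2_and_1_3(self):
        top = _chain_topology()
        ff = ToyForceField.from_reference(top, _chain_frame())
        pairs = {tuple(p) for p in ff.nb_pairs.tolist()}
        assert (0, 1) not in pairs and (1, 2) not in pairs  # 1-2
        assert (0, 2) not in pairs and (1, 3) not in pairs  # 1-3
        assert (0, 3) in pairs                              # 1-4 kept

    def test_shape_mismatch(self):
        top = _chain_topology()
        with pytest.raises(ValueError, match="reference"):
            ToyForceField.from_reference(top, np.zeros((3, 3)))

    def test_single_bond_closed_form(self):
        atoms = [AtomRecord(i, f"C{i}", "C", 0, "GlcA", "other", 0.0,
                            frozenset()) for i in range(2)]
        top = Topology(atoms=atoms, bonds={(0, 1)})
        ref = np.array([[0.0, 0.0, 0.0], [1.54, 0.0, 0.0]])
        ff = ToyForceField.from_reference(top, ref, bond_k=300.0)
        x = ref.copy()
        x[1, 0] = 2.0
        e, g = energy_and_gradient(x, top, ff)
        assert e == pytest.approx(300.0 * (2.0 - 1.54) ** 2, abs=1e-12)
        assert g[1, 0] == pytest.approx(2 * 300.0 * (2.0 - 1.54), abs=1e-9)

    def test_coulomb_shifted_cutoff_closed_form(self):
        atoms = [AtomRecord(0, "O1", "O", 0, "GlcA", "other", 0.5,
                            frozenset()),
                 AtomRecord(1, "O2", "O", 1, "GalNAc", "other", -0.5,
                            frozenset())]
        top = Topology(atoms=atoms, bonds=set())
        ff = ToyForceField.from_reference(
            top, np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]))
        # suppress LJ to isolate Coulomb
        ff.lj_eps = np.zeros(2)
        r, rc, q1q2, eps = 4.0, 10.0, -0.25, 4.0
        want = COULOMB_K * q1q2 / eps * (1.0 / r - 1.0 / rc)
        e, _ = energy_and_gradient(
            np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]), top, ff)
        assert e == pytest.approx(want, abs=1e-12)

    def test_energy_zero_beyond_cutoff(self):
        atoms = [AtomRecord(0, "O1", "O", 0, "GlcA", "other", 0.5,
                            frozenset()),
                 AtomRecord(1, "O2", "O", 1, "GalNAc", "other", -0.5,
                            frozenset())]
        top = Topology(atoms=atoms, bonds=set())
        frame = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        ff = ToyForceField.from_reference(top, frame)
        e, g = energy_and_gradient(frame, top, ff)
        assert e == 0.0
        assert np.all(g == 0.0)

    def test_unknown_element_rejected(self):
        atoms = [AtomRecord(0, "FE", "Fe", 0, "GlcA", "other", 0.0,
                            frozenset())]
        top = Topology(atoms=atoms, bonds=set())
        with pytest.raises(KeyError, match="Fe"):
            ToyForceField.from_reference(top, np.zeros((1, 3)))


class TestGradientOracle:
    def test_matches_finite_differences(self):
        top = _chain_topology()
        ref = _chain_frame()
        ff = ToyForceField.from_reference(top, ref)
        # add a torsion term to exercise the dihedral gradient
        ff.torsions = np.array([[0, 1, 2, 3]])
        ff.torsion_v = np.array([2.5])
        ff.torsion_n = np.array([3.0])
        ff.torsion_gamma = np.array([np.radians(60.0)])
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = ref + rng.normal(0, 0.2, ref.shape)
            _, g = energy_and_gradient(x, top, ff)
            g_fd = fd_gradient(lambda v: energy_and_gradient(v, top, ff)[0],
                               x, h=1e-6)
            scale = max(1.0, np.max(np.abs(g_fd)))
            assert np.max(np.abs(g - g_fd)) / scale < 1e-5

    def test_synthetic_disaccharide_gradient(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture.single(-75.0, 115.0),
            n_frames=1, seed=3,
        )
        traj, _ = sample_trajectory(run)
        top = traj.topology
        ff = ToyForceField.from_reference(top, traj.coords[0])
        x = traj.coords[0] + np.random.default_rng(1).normal(
            0, 0.05, traj.coords[0].shape)
        _, g = energy_and_gradient(x, top, ff)
        g_fd = fd_gradient(lambda v: energy_and_gradient(v, top, ff)[0],
                           x, h=1e-6)
        scale = max(1.0, np.max(np.abs(g_fd)))
        assert np.max(np.abs(g - g_fd)) / scale < 1e-4


class TestMinimizers:
    def test_cg_quadratic_in_dim_iterations(self):
        rng = np.random.default_rng(9)
        d = 12
        a = rng.normal(size=(d, d))
        A = a @ a.T + d * np.eye(d)
        b = rng.normal(size=d)
        fun = lambda x: 0.5 * x @ A @ x - b @ x
        grad = lambda x: A @ x - b
        x_star = np.linalg.solve(A, b)
        x, f = minimize_cg(fun, grad, np.zeros(d), max_iter=d, gtol=0.0)
        assert np.max(np.abs(x - x_star)) < 1e-9

    def test_cg_energy_non_increasing(self):
        rng = np.random.default_rng(10)
        d = 8
        a = rng.normal(size=(d, d))
        A = a @ a.T + np.eye(d)
        b = rng.normal(size=d)
        seen = []
        fun = lambda x: float(0.5 * x @ A @ x - b @ x)
        grad = lambda x: A @ x - b
        x0 = rng.normal(size=d)

        def fun_logged(x):
            v = fun(x)
            return v
        x, f = minimize_cg(fun_logged, grad, x0)
        assert f <= fun(x0) + 1e-12

    def test_sd_decreases_energy(self):
        fun = lambda x: float(np.sum(x ** 2))
        grad = lambda x: 2 * x
        x0 = np.full(6, 2.0)
        x, f = minimize_sd(fun, grad, x0, max_iter=50, gtol=1e-9)
        assert f < fun(x0)


class TestQuench:
    def test_stretched_bond_reaches_analytic_minimum(self):
        atoms = [AtomRecord(i, f"C{i}", "C", 0, "GlcA", "other", 0.0,
                            frozenset()) for i in range(2)]
        top = Topology(atoms=atoms, bonds={(0, 1)})
        ref = np.array([[0.0, 0.0, 0.0], [1.54, 0.0, 0.0]])
        ff = ToyForceField.from_reference(top, ref)
        start = np.array([[0.0, 0.0, 0.0], [2.4, 0.0, 0.0]])
        xmin, e = quench(start, top, ff)
        r = np.linalg.norm(xmin[1] - xmin[0])
        assert r == pytest.approx(1.54, abs=1e-6)
        assert e <= 1e-10

    def test_energy_never_increases(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_4"),
            torsions=TorsionMixture.single(-70.0, -120.0),
            n_frames=4, seed=13,
        )
        traj, _ = sample_trajectory(run)
        top = traj.topology
        ff = ToyForceField.from_reference(top, traj.coords[0])
        for f in range(traj.n_frames):
            e0, _ = energy_and_gradient(traj.coords[f], top, ff)
            _, e = quench(traj.coords[f], top, ff, max_cg_iter=200)
            assert e <= e0 + 1e-12


def _point_cloud_traj(frames):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    atoms = [AtomRecord(i, f"C{i}", "C", 0, "GlcA", "other", 0.0,
                        frozenset()) for i in range(n)]
    top = Topology(atoms=atoms, bonds=set())
    return Trajectory(topology=top, coords=frames)


class TestPCA:
    def _rank2_frames(self, seed=0, n_frames=300, n_atoms=10):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n_atoms, 3)) * 2
        v1 = rng.normal(size=(n_atoms, 3))
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=(n_atoms, 3))
        v2 -= v1 * np.sum(v1 * v2)
        v2 /= np.linalg.norm(v2)
        a = rng.normal(0, 3.0, n_frames)
        b = rng.normal(0, 1.0, n_frames)
        frames = base[None] + a[:, None, None] * v1 + b[:, None, None] * v2
        return frames, v1.ravel(), v2.ravel()

    def test_planted_rank2_variance_and_directions(self):
        frames, v1, v2 = self._rank2_frames()
        model = pca_frames(_point_cloud_traj(frames), align=False)
        evr = model.explained_variance_ratio()
        assert evr[:2].sum() >= 0.98
        for comp, v in ((model.components[0], v1), (model.components[1], v2)):
            cos = abs(float(comp @ v))
            assert np.degrees(np.arccos(np.clip(cos, 0, 1))) < 5.0

    def test_components_orthonormal(self):
        frames, _, _ = self._rank2_frames(seed=1)
        model = pca_frames(_point_cloud_traj(frames), align=False)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_projection_reconstruction(self):
        frames, _, _ = self._rank2_frames(seed=2, n_frames=50)
        model = pca_frames(_point_cloud_traj(frames), align=False)
        flat = frames.reshape(50, -1)
        recon = model.mean + model.projections @ model.components
        assert np.allclose(recon, flat, atol=1e-8)

    def test_frame_duplication_preserves_components(self):
        frames, _, _ = self._rank2_frames(seed=3, n_frames=80)
        m1 = pca_frames(_point_cloud_traj(frames), align=False)
        m2 = pca_frames(_point_cloud_traj(np.repeat(frames, 2, axis=0)),
                        align=False)
        assert np.allclose(np.abs(m1.components[:2]),
                           np.abs(m2.components[:2]), atol=1e-8)

    def test_alignment_removes_rigid_motion(self):
        rng = np.random.default_rng(4)
        frames, _, _ = self._rank2_frames(seed=5, n_frames=60)
        rotated = np.empty_like(frames)
        for f in range(len(frames)):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            rotated[f] = frames[f] @ q.T + rng.normal(size=3) * 5
        m_plain = pca_frames(_point_cloud_traj(frames), align=False)
        m_rot = pca_frames(_point_cloud_traj(rotated), align=True)
        evr = m_rot.explained_variance_ratio()
        # rigid motion must not create large extra variance directions
        assert evr[:2].sum() >= 0.95
        assert m_plain.explained_variance_ratio()[:2].sum() >= 0.98

    def test_needs_two_frames(self):
        with pytest.raises(ValueError, match="2 frames"):
            pca_frames(_point_cloud_traj(np.zeros((1, 5, 3))))


class TestLandscape:
    def _model(self, seed=0, n_frames=400):
        frames, _, _ = TestPCA()._rank2_frames(seed=seed, n_frames=n_frames)
        return pca_frames(_point_cloud_traj(frames), align=False)

    def test_frame_count_conserved(self):
        model = self._model()
        energies = np.random.default_rng(0).normal(size=400)
        scape = build_landscape(model, energies, grid_size=50)
        assert scape.frame_cells.shape == (400, 2)
        assert scape.frame_cells.min() >= 0
        assert scape.frame_cells.max() < 50
        # every frame's cell is non-empty
        for i, j in scape.frame_cells:
            assert not np.isnan(scape.grid[i, j])

    def test_min_statistic(self):
        model = self._model(seed=1)
        energies = np.random.default_rng(1).normal(size=400)
        scape = build_landscape(model, energies)
        (_, _), vmin = scape.global_minimum()
        assert vmin == pytest.approx(energies.min())
        # per-cell minimum: grid value ≤ every member frame energy
        for f, (i, j) in enumerate(scape.frame_cells):
            assert scape.grid[i, j] <= energies[f] + 1e-12

    def test_energy_length_mismatch(self):
        model = self._model(seed=2)
        with pytest.raises(ValueError, match="does not match"):
            build_landscape(model, np.zeros(17))

    def test_two_basin_offsets_separate(self):
        # two torsional components with distinct planted energy offsets:
        # the landscape must show two disjoint occupied regions whose
        # minima differ by the planted offset
        k = kappa_for_circular_std(8.0)
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture((
                MixtureComponent(30, -170, k, k, 0.5),
                MixtureComponent(110, 30, k, k, 0.5),
            )),
            component_energy_offsets=(0.0, 5.0),
            n_frames=300, seed=29,
        )
        traj, truth = sample_trajectory(run)
        model = pca_frames(traj)
        scape = build_landscape(model, traj.energies)
        cells0 = {tuple(c) for c in scape.frame_cells[truth.component == 0]}
        cells1 = {tuple(c) for c in scape.frame_cells[truth.component == 1]}
        assert cells0.isdisjoint(cells1)
        e0 = np.nanmin([scape.grid[c] for c in cells0])
        e1 = np.nanmin([scape.grid[c] for c in cells1])
        assert e1 - e0 == pytest.approx(5.0, abs=1e-9)
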
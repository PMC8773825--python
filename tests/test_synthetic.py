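import numpy as np
import pytest

from oracles import von_mises_circular_sd_deg

from gagconf.core import Trajectory
from gagconf.pucker import cremer_pople
from gagconf.synthetic import (
    DisaccharideSpec,
    MixtureComponent,
    PlantedHBond,
    SyntheticRunSpec,
    TorsionMixture,
    build_disaccharide,
    kappa_for_circular_std,
    sample_trajectory,
)
from gagconf.torsions import dihedral, extract_phi_psi
from conftest import make_spec

ALL_SULFATIONS = [
    (), ("GlcA-2S",), ("GalNAc-4S",), ("GalNAc-6S",),
    ("GlcA-2S", "GalNAc-4S"), ("GlcA-2S", "GalNAc-6S"),
    ("GalNAc-4S", "GalNAc-6S"), ("GlcA-2S", "GalNAc-4S", "GalNAc-6S"),
]


class TestSpecValidation:
    def test_unknown_linkage(self):
        with pytest.raises(ValueError, match="linkage"):
            DisaccharideSpec(linkage="alpha_1_2")

    def test_linkage_order_pairing_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DisaccharideSpec(linkage="beta_1_3", residue_order="amine_acid")

    def test_unknown_sulfation_site(self):
        with pytest.raises(ValueError, match="sulfation"):
            make_spec("beta_1_4", ["GlcA-3S"])

    def test_mixture_weights_must_sum_to_one(self):
        k = kappa_for_circular_std(15.0)
        with pytest.raises(ValueError, match="sum to 1"):
            TorsionMixture((MixtureComponent(-70, -120, k, k, 0.5),
                            MixtureComponent(60, 100, k, k, 0.6)))

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            TorsionMixture(())

    def test_occupancy_bounds(self):
        with pytest.raises(ValueError, match="occupancy"):
            PlantedHBond((0, "O2"), (1, "O5"), 1.2)

    def test_energy_offsets_length_checked(self):
        with pytest.raises(ValueError, match="one entry per"):
            SyntheticRunSpec(disaccharide=make_spec("beta_1_3"),
                             torsions=TorsionMixture.single(-70, -120),
                             component_energy_offsets=(0.0, 1.0))

    def test_pucker_label_restricted_to_chairs(self):
        with pytest.raises(ValueError, match="chair"):
            SyntheticRunSpec(disaccharide=make_spec("beta_1_3"),
                             torsions=TorsionMixture.single(-70, -120),
                             pucker_label="2SO")

    def test_kappa_requires_positive_sd(self):
        with pytest.raises(ValueError, match="positive"):
            kappa_for_circular_std(0.0)

    def test_kappa_matches_closed_form(self):
        for sd in (5.0, 15.0, 40.0):
            k = kappa_for_circular_std(sd)
            assert von_mises_circular_sd_deg(k) == pytest.approx(sd, abs=1e-8)


class TestBuilder:
    @pytest.mark.parametrize("linkage", ["beta_1_3", "beta_1_4"])
    @pytest.mark.parametrize("sulfation", ALL_SULFATIONS)
    def test_all_16_members_build_consistently(self, linkage, sulfation):
        spec = make_spec(linkage, sulfation)
        top, frame = build_disaccharide(spec, -70.0, -120.0)
        # torsion round trip
        phi = dihedral(*(frame[i] for i in top.linkage.phi_atoms))
        psi = dihedral(*(frame[i] for i in top.linkage.psi_atoms))
        assert phi == pytest.approx(-70.0, abs=0.5)
        assert psi == pytest.approx(-120.0, abs=0.5)
        # both rings in the canonical chair
        for ring in top.rings:
            assert cremer_pople(frame[list(ring)]).label == "4C1"
        # toy charge bookkeeping: total = -(1 + number of sulfates)
        total = sum(a.charge for a in top.atoms)
        assert total == pytest.approx(-(1 + len(sulfation)), abs=1e-9)
        assert top.n_sulfate_groups() == len(sulfation)

    def test_torsion_round_trip_across_angles(self):
        spec = make_spec("beta_1_4")
        rng = np.random.default_rng(0)
        for _ in range(10):
            want_phi = float(rng.uniform(-179, 179))
            want_psi = float(rng.uniform(-179, 179))
            top, frame = build_disaccharide(spec, want_phi, want_psi)
            phi = dihedral(*(frame[i] for i in top.linkage.phi_atoms))
            psi = dihedral(*(frame[i] for i in top.linkage.psi_atoms))
            assert phi == pytest.approx(want_phi, abs=0.5)
            assert psi == pytest.approx(want_psi, abs=0.5)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            build_disaccharide(make_spec("beta_1_3"), -200.0, 0.0)

    def test_no_steric_collapse(self):
        # no non-bonded heavy-atom pair closer than 1.5 Å at typical torsions
        for linkage in ("beta_1_3", "beta_1_4"):
            top, frame = build_disaccharide(make_spec(linkage), -70.0, -120.0)
            heavy = [a.atom_id for a in top.atoms if a.element != "H"]
            for ii, i in enumerate(heavy):
                for j in heavy[ii + 1:]:
                    if frozenset((i, j)) in top.bonds:
                        continue
                    d = np.linalg.norm(frame[i] - frame[j])
                    assert d > 1.5, (top.atoms[i].name, top.atoms[j].name, d)


class TestSampling:
    def test_bit_identical_determinism(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_4", ["GalNAc-6S"]),
            torsions=TorsionMixture.single(-70.0, -120.0),
            planted_hbonds=(PlantedHBond((0, "O3"), (1, "O5"), 0.4),),
            n_bulk_waters=5, n_frames=25, seed=33,
            component_energy_offsets=(2.0,), energy_noise_sigma=0.5,
        )
        t1, g1 = sample_trajectory(run)
        t2, g2 = sample_trajectory(run)
        assert np.array_equal(t1.coords, t2.coords)
        assert np.array_equal(t1.energies, t2.energies)
        assert np.array_equal(g1.phi, g2.phi)
        for k in g1.hbond_status:
            assert np.array_equal(g1.hbond_status[k], g2.hbond_status[k])

    def test_torsions_follow_ground_truth(self, small_run):
        traj, truth = small_run
        series = extract_phi_psi(traj)
        dphi = np.abs((series.phi - truth.phi + 180) % 360 - 180)
        # 0.05 Å jitter on four ~1.4 Å-separated atoms: several degrees
        assert np.median(dphi) < 10.0

    def test_component_assignment_weights(self):
        k = kappa_for_circular_std(10.0)
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture((
                MixtureComponent(-70, -120, k, k, 0.7),
                MixtureComponent(60, 100, k, k, 0.3),
            )),
            n_frames=5000, seed=5,
        )
        _, truth = sample_trajectory(run)
        assert np.mean(truth.component == 0) == pytest.approx(0.7, abs=0.03)

    def test_planted_direct_bond_geometry_exact(self, small_run):
        traj, truth = small_run
        top = traj.topology
        idx = {(a.residue_index, a.name): a.atom_id for a in top.atoms}
        d, a = idx[(0, "O3")], idx[(1, "O5")]
        h = next(j for j in top.bonded_to(d)
                 if "polar_hydrogen" in top.atoms[j].hbond_role)
        on = truth.hbond_status["0:O3->1:O5"]
        dist = np.linalg.norm(traj.coords[:, d] - traj.coords[:, a], axis=1)
        assert np.allclose(dist[on], 2.8, atol=1e-9)
        assert np.allclose(dist[~on], 3.6, atol=1e-9)
        # on-frames: hydrogen exactly on the D→A axis (180° DHA angle)
        hd = traj.coords[on, d] - traj.coords[on, h]
        ha = traj.coords[on, a] - traj.coords[on, h]
        cos = np.sum(hd * ha, axis=1) / (
            np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
        assert np.allclose(cos, -1.0, atol=1e-9)

    def test_planted_occupancy_converges(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_4"),
            torsions=TorsionMixture.single(-70.0, -120.0),
            planted_hbonds=(PlantedHBond((0, "O3"), (1, "O5"), 0.35),),
            n_frames=4000, seed=17,
        )
        _, truth = sample_trajectory(run)
        assert truth.hbond_status["0:O3->1:O5"].mean() == pytest.approx(
            0.35, abs=0.02)

    def test_via_water_bridge_geometry(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture.single(-75.0, 115.0),
            planted_hbonds=(
                PlantedHBond((0, "O5"), (1, "O6"), 0.6, via_water=True),),
            n_bulk_waters=3, n_frames=300, seed=21,
        )
        traj, truth = sample_trajectory(run)
        top = traj.topology
        idx = {(a.residue_index, a.name): a.atom_id for a in top.atoms}
        key = "0:O5->1:O6~w"
        res = truth.bond_water_residue[key]
        ow = next(a.atom_id for a in top.atoms
                  if a.residue_index == res and a.name == "OW")
        on = truth.hbond_status[key]
        assert 0.4 < on.mean() < 0.8
        for a_path in ((0, "O5"), (1, "O6")):
            d = np.linalg.norm(
                traj.coords[on, ow] - traj.coords[on, idx[a_path]], axis=1)
            assert np.allclose(d, 2.8, atol=1e-9)
        # off-frames: the bridge water is parked far away
        for a_path in ((0, "O5"), (1, "O6")):
            d = np.linalg.norm(
                traj.coords[~on, ow] - traj.coords[~on, idx[a_path]], axis=1)
            assert d.min() > 4.0

    def test_bulk_waters_cannot_bond(self, small_run):
        traj, _ = small_run
        top = traj.topology
        solute = sorted(top.solute_atom_ids)
        ow_ids = [a.atom_id for a in top.atoms if a.name == "OW"]
        d = np.linalg.norm(
            traj.coords[:, ow_ids, None, :] - traj.coords[:, None, solute, :],
            axis=3)
        # 5.0 Å placement minus two 3σ jitters still clears the 3.0 Å cutoff
        assert d.min() > 4.0

    def test_pucker_mixture_fraction_and_labels(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture.single(-75.0, 115.0),
            pucker_label={"4C1": 0.7, "1C4": 0.3},
            n_frames=400, seed=11, jitter_sigma=0.0,
        )
        traj, truth = sample_trajectory(run)
        assert truth.inverted_chair.mean() == pytest.approx(0.3, abs=0.07)
        ring = list(traj.topology.rings[0])
        for f in (int(np.argmax(truth.inverted_chair)),
                  int(np.argmin(truth.inverted_chair))):
            label = cremer_pople(traj.coords[f, ring]).label
            assert label == ("1C4" if truth.inverted_chair[f] else "4C1")

    def test_component_energy_offsets(self):
        k = kappa_for_circular_std(10.0)
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture((
                MixtureComponent(-70, -120, k, k, 0.5),
                MixtureComponent(60, 100, k, k, 0.5),
            )),
            component_energy_offsets=(0.0, 3.0),
            n_frames=200, seed=2,
        )
        traj, truth = sample_trajectory(run)
        assert traj.energies is not None
        assert np.all(traj.energies[truth.component == 0] == 0.0)
        assert np.all(traj.energies[truth.component == 1] == 3.0)

    def test_planted_donor_without_hydrogen_rejected(self):
        # in beta_1_3 the GalNAc O3 is the glycosidic oxygen: no donor role
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture.single(-75.0, 115.0),
            planted_hbonds=(PlantedHBond((1, "O3"), (0, "O5"), 0.5),),
            n_frames=2, seed=1,
        )
        with pytest.raises(ValueError, match="donor"):
            sample_trajectory(run)

    def test_via_water_partner_must_accept(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_3"),
            torsions=TorsionMixture.single(-75.0, 115.0),
            planted_hbonds=(
                PlantedHBond((0, "C1"), (1, "O5"), 0.5, via_water=True),),
            n_frames=2, seed=1,
        )
        with pytest.raises(ValueError, match="acceptor"):
            sample_trajectory(run)

    def test_same_donor_in_two_bonds_rejected(self):
        run = SyntheticRunSpec(
            disaccharide=make_spec("beta_1_4"),
            torsions=TorsionMixture.single(-70.0, -120.0),
            planted_hbonds=(
                PlantedHBond((0, "O3"), (1, "O5"), 0.5),
                PlantedHBond((0, "O3"), (1, "O2"), 0.5),
            ),
            n_frames=2, seed=1,
        )
        with pytest.raises(ValueError, match="two planted bonds"):
            sample_trajectory(run)
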
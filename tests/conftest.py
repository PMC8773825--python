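import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from gagconf.synthetic import (
    DisaccharideSpec,
    PlantedHBond,
    SyntheticRunSpec,
    TorsionMixture,
    sample_trajectory,
)


def make_spec(linkage="beta_1_4", sulfation=()):
    order = "acid_amine" if linkage == "beta_1_3" else "amine_acid"
    return DisaccharideSpec(linkage=linkage, sulfation=frozenset(sulfation),
                            residue_order=order)


@pytest.fixture
def small_run():
    """A 40-frame β1→4 run with one planted direct bond and a few waters."""
    run = SyntheticRunSpec(
        disaccharide=make_spec("beta_1_4", ["GalNAc-4S"]),
        torsions=TorsionMixture.single(-70.0, -120.0),
        planted_hbonds=(PlantedHBond((0, "O3"), (1, "O5"), 0.5),),
        n_bulk_waters=6,
        n_frames=40,
        seed=101,
    )
    return sample_trajectory(run)


@pytest.fixture
def tiny_traj():
    """A 5-frame run without waters, for cheap structural tests."""
    run = SyntheticRunSpec(
        disaccharide=make_spec("beta_1_3"),
        torsions=TorsionMixture.single(-75.0, 115.0),
        n_frames=5,
        seed=7,
    )
    return sample_trajectory(run)[0]


def random_frame_run(seed, n_waters=10, occupancy=0.5):
    """One random synthetic frame with waters, for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    linkage = "beta_1_3" if rng.integers(2) else "beta_1_4"
    sites = ["GlcA-2S", "GalNAc-4S", "GalNAc-6S"]
    sulf = [s for s in sites if rng.random() < 0.5]
    bonds = []
    if linkage == "beta_1_4":
        bonds.append(PlantedHBond((0, "O3"), (1, "O5"), occupancy))
    run = SyntheticRunSpec(
        disaccharide=make_spec(linkage, sulf),
        torsions=TorsionMixture.single(
            float(rng.uniform(-120, -40)), float(rng.uniform(-160, 160))),
        planted_hbonds=tuple(bonds),
        n_bulk_waters=n_waters,
        n_frames=1,
        seed=int(rng.integers(2 ** 31 - 1)),
        jitter_sigma=0.3,   # larger jitter: more borderline geometries
    )
    return sample_trajectory(run)[0]
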
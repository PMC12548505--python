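import numpy as np
import pytest

from pibridge.ringgeom import CationSite, RingGroup
from pibridge.synthetic import ideal_ring_coords


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ring(centroid, normal, ring_id="R0", layer="upper", snapshot_index=0):
    return RingGroup(
        atom_coords=ideal_ring_coords(np.asarray(centroid, float), normal),
        ring_id=ring_id,
        layer=layer,
        snapshot_index=snapshot_index,
    )


def make_cation(coord, species="Y3+", site_id="C0", layer="bath", snapshot_index=0):
    return CationSite(
        coord=np.asarray(coord, float),
        species=species,
        site_id=site_id,
        layer=layer,
        snapshot_index=snapshot_index,
    )


def random_rings(rng, n, box=25.0, snapshot_index=0):
    rings = []
    for i in range(n):
        centroid = rng.uniform(0, box, 3)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        rings.append(
            make_ring(
                centroid,
                normal,
                ring_id=f"R{i}",
                layer="upper" if rng.random() < 0.5 else "lower",
                snapshot_index=snapshot_index,
            )
        )
    return rings


def random_cations(rng, n, box=25.0, snapshot_index=0):
    species = ["NH3+", "K+", "Y3+"]
    return [
        make_cation(
            rng.uniform(0, box, 3),
            species=species[int(rng.integers(3))],
            site_id=f"C{i}",
            layer=["upper", "lower", "bath"][int(rng.integers(3))],
            snapshot_index=snapshot_index,
        )
        for i in range(n)
    ]
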
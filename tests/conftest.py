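import numpy as np
import pandas as pd
import pytest

from gjctools import (
    ClassStateMap,
    MetadataSimConfig,
    ParticleTable,
    simulate_metadata,
    simulate_toy_pore,
)


@pytest.fixture
def default_class_map() -> ClassStateMap:
    """Eight-class protomer map: classes 5, 6, 8 flexible; 1-4, 7 pore-lining."""
    return ClassStateMap.default_protomer_map()


@pytest.fixture
def unexpanded_table() -> ParticleTable:
    """Three particles, one record each, ready for symmetry expansion."""
    return ParticleTable(
        pd.DataFrame(
            {
                "particle_id": ["p1@mic1.mrcs", "p2@mic1.mrcs", "p3@mic2.mrcs"],
                "class_id": [1, 5, 7],
            }
        )
    )


@pytest.fixture
def small_sim():
    """200 independent particles at p = 0.57, D6-expanded, with ground truth."""
    cfg = MetadataSimConfig(n_particles=200, p_pln=0.57, seed=11)
    return simulate_metadata(cfg)


@pytest.fixture
def two_ring_pore():
    """Toy pore: wide ring (r=10) at z=0, constriction ring (r=6) at z=20.

    With 1.7 A atoms the inscribed-sphere radii at the ring planes are 8.3
    and 4.3 A exactly.
    """
    return simulate_toy_pore([(0.0, 10.0, 24), (20.0, 6.0, 24)], atom_vdw=1.7)


def grid_search_radius(atoms, z, axis_xy=(0.0, 0.0), max_shift=5.0,
                       coarse=0.1, fine=0.01):
    """Exhaustive in-plane grid oracle for the inscribed-sphere radius.

    Scans the allowed centre disk at ``coarse`` spacing, then refines around
    the best point at ``fine`` (= 0.01 A) spacing. Independent of the
    optimizer code path.
    """
    def clearances(centers):
        d = np.sqrt(
            (atoms.coords[None, :, 0] - centers[:, 0, None]) ** 2
            + (atoms.coords[None, :, 1] - centers[:, 1, None]) ** 2
            + (atoms.coords[None, :, 2] - z) ** 2
        )
        return (d - atoms.vdw[None, :]).min(axis=1)

    g = np.arange(-max_shift, max_shift + coarse / 2, coarse)
    gx, gy = np.meshgrid(axis_xy[0] + g, axis_xy[1] + g)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    keep = np.hypot(centers[:, 0] - axis_xy[0], centers[:, 1] - axis_xy[1]) <= max_shift
    centers = centers[keep]
    vals = clearances(centers)
    best = centers[np.argmax(vals)]

    f = np.arange(-coarse, coarse + fine / 2, fine)
    fx, fy = np.meshgrid(best[0] + f, best[1] + f)
    centers2 = np.column_stack([fx.ravel(), fy.ravel()])
    vals2 = clearances(centers2)
    return float(vals2.max())
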
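import numpy as np
import pytest

from lidkit.io import AtomRecord, Structure
from lidkit.synthetic import make_toy_chain


@pytest.fixture(scope="session")
def toy_chain():
    """50-residue helix-loop-helix toy protein (deterministic)."""
    return make_toy_chain(50, seed=7)


@pytest.fixture(scope="session")
def lid_chain():
    """Toy chain numbered 100-159 so the PFL-style lid residues exist."""
    return make_toy_chain(60, seed=11, start_resid=100)


def ca_only_structure(coords, chain="A", start_resid=1):
    """Build a Cα-only Structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            altloc="",
            resname="ALA",
            chain=chain,
            resid=start_resid + i,
            coords=coords[i].copy(),
            element="C",
        )
        for i in range(coords.shape[0])
    ]
    return Structure(atoms)


def slab_with_slit(half_width=3.0, extent=12.0, y_extent=6.0, spacing=0.5):
    """Two coplanar atomic walls (z = 0) separated by a slit of the given
    center-to-center half-width along x; the analytic bottleneck for a
    probe crossing the plane is half_width − r_vdW."""
    atoms = []
    serial = 1
    xs = np.concatenate(
        [
            np.arange(-extent, -half_width + 1e-9, spacing),
            np.arange(half_width, extent + 1e-9, spacing),
        ]
    )
    for x in xs:
        for y in np.arange(-y_extent, y_extent + 1e-9, spacing):
            atoms.append(
                AtomRecord(serial, "X", "", "WAL", "W", serial,
                           np.array([x, y, 0.0]), element="C")
            )
            serial += 1
    return Structure(atoms)
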
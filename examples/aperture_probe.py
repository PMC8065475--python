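"""Spherical-probe bottleneck through a slit between two atomic walls.

An analytic benchmark for the widest-path aperture search: two coplanar
walls of atoms (van der Waals radius 1.5 Å) separated by a 6 Å
center-to-center slit leave room for a probe of radius 3 − 1.5 = 1.5 Å.
"""

import numpy as np

import lidkit as lk
from lidkit.io import AtomRecord, Structure

atoms, serial = [], 1
xs = np.concatenate([np.arange(-12.0, -2.9999, 0.5), np.arange(3.0, 12.0001, 0.5)])
for x in xs:
    for y in np.arange(-6.0, 6.0001, 0.5):
        atoms.append(
            AtomRecord(serial, "X", "", "WAL", "W", serial,
                       np.array([x, y, 0.0]), element="C")
        )
        serial += 1
walls = Structure(atoms)

result = lk.aperture_probe(
    walls,
    interior_seed=np.array([0.0, 0.0, -5.0]),
    exterior_seed=np.array([0.0, 0.0, 5.0]),
    grid_spacing=0.5,
    radii={"C": 1.5},
    margin=0.0,
)
print(f"reachable: {result.reachable}")
print(f"bottleneck probe radius: {result.bottleneck_radius:.3f} A (analytic 1.500 A)")
print(f"path length: {len(result.path)} grid points")
print(
    "The bottleneck radius is the largest spherical probe that can travel "
    "from the interior seed to the solvent; applied to a lipase it "
    "quantifies how far open the lid aperture is."
)
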
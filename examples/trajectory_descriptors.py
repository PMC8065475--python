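"""Lid-state descriptors over a two-state synthetic trajectory.

Simulates open/close switching of the primary lid distance (Cα pair)
between 14 Å (open) and 7 Å (closed), measures the distance series, the
classifier's state fractions, and a planted hydrogen-bond occupancy.
"""

import numpy as np

import lidkit as lk
from lidkit.traj import AtomSpec, distance_series

ref = lk.make_toy_chain(40, seed=3)
spec = lk.SyntheticSpec(
    n_residues=40, two_state=(14.0, 7.0, 0.6, 15.0), n_frames=3000, seed=4
)
traj, labels = lk.simulate_two_state(ref, spec, pair=(10, 30))

ds = distance_series(traj, AtomSpec("A", 10, "CA"), AtomSpec("A", 30, "CA"))
states = [lk.classify_state(v) for v in ds.values]
print(f"primary lid distance: mean {lk.to_nm(ds.mean):.3f} nm, "
      f"sd {lk.to_nm(ds.sd):.3f} nm, range {lk.to_nm(ds.range_dd):.3f} nm")
print(f"open fraction: planted {labels.mean():.3f}, "
      f"classified {np.mean([s == 'open' for s in states]):.3f}")

plan = np.random.default_rng(5).random(3000) < 0.35
hb_traj, truth = lk.plant_hbond_series(plan)
hs = lk.hbond_series(
    hb_traj, AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"), AtomSpec("A", 1, "H")
)
print(f"H-bond occupancy: planted {truth:.3f}, measured {hs.occupancy:.3f}")
print(
    "The mean/sd of the lid distance is the style of summary used for MD "
    "tables (in nm); matching planted vs measured values shows the "
    "descriptors read the geometry exactly."
)
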
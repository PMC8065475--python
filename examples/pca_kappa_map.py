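"""Essential-dynamics PCA and the PC-distance correlation (κ) map.

Plants a large-amplitude motion on residues 121-123 of a 60-residue toy
chain, runs PCA, computes κ between the PC1 projection and every Cα-Cα
distance, and shows that the |κ|Δd-weighted map localizes the planted
band.
"""

import numpy as np

import lidkit as lk

band = [121, 122, 123]
ref = lk.make_toy_chain(60, seed=11, start_resid=100)
ca = lk.select(ref, atom_names={"CA"})
outward = ca.coords[np.isin(ca.resids, band)].mean(axis=0) - ca.coords.mean(axis=0)
mode = lk.localized_mode(ref, band, outward)
spec = lk.SyntheticSpec(
    n_residues=60, mode_vectors=mode, mode_sigmas=np.array([3.0]),
    n_frames=2000, noise_sigma=0.05, seed=14,
)
traj, _ = lk.simulate_modes_trajectory(ref, spec)

sel = {"atom_names": {"CA"}}
res = lk.pca(traj, selection=sel)
km = lk.kappa_map(res, lk.all_pair_distances(traj, selection=sel))
w = km.weighted

print(f"PC1 eigenvalue: {res.eigenvalues[0]:.2f} A^2 (planted 9.0 A^2)")
i, j = np.unravel_index(np.argmax(w), w.shape)
print(f"|kappa|*delta_d maximum: {w[i, j]:.2f} A at pair "
      f"({km.resids[i]}, {km.resids[j]})")
hits = np.mean([
    km.resids[k] in band or km.resids[int(np.argmax(w[k]))] in band
    for k in range(len(km.resids))
])
print(f"row maxima touching the planted band 121-123: {100 * hits:.0f}%")
print(
    "κ correlates each residue-pair distance with the dominant collective "
    "motion; weighting by the distance range Δd highlights which residues "
    "carry the large-amplitude, PC1-correlated motion — here the planted "
    "lid band."
)
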
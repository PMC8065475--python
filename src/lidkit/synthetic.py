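"""Synthetic structures and trajectories with planted ground truth.

MD production runs of hundreds of nanoseconds cannot be regenerated at
test time, so every analysis stage in this package is validated against
generated data whose statistical structure is known exactly:

* harmonic fluctuations about a reference structure along planted
  orthonormal displacement modes with chosen per-mode variances
  (PCA / RMSF / ENM cross-checks);
* a Cα–Cα distance coupled linearly to the first mode amplitude, so the
  PC–distance correlation κ is +1 (or −1) by construction;
* two-state open/close switching of the primary lid descriptor with known
  dwell statistics and per-frame labels (classifier validation);
* donor–H–acceptor geometries constructed per frame to satisfy or violate
  the hydrogen-bond criterion according to a plan, giving an exactly known
  occupancy.

Everything is deterministic under a fixed seed (``numpy`` Generator; no
global or time-based state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AtomRecord, Structure, Trajectory

__all__ = [
    "SyntheticSpec",
    "make_toy_chain",
    "localized_mode",
    "rigid_basis",
    "orthogonalize_to_rigid",
    "random_orthonormal_modes",
    "simulate_modes_trajectory",
    "simulate_two_state",
    "plant_hbond_series",
]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-mode trajectory.

    ``mode_vectors`` is (k, 3n) with orthonormal rows over the n Cα sites;
    ``mode_sigmas`` are the per-mode displacement standard deviations (Å).
    ``coupled_pair = (resid_i, resid_j, slope, intercept)`` forces the
    Cα_i–Cα_j distance to ``slope * a_1(t) + intercept`` exactly.
    ``noise_sigma`` adds i.i.d. Gaussian jitter (Å) per coordinate, which
    emulates the fast uncorrelated fluctuations real trajectories carry on
    top of their essential modes.
    """

    n_residues: int = 60
    mode_vectors: np.ndarray | None = None
    mode_sigmas: np.ndarray | None = None
    coupled_pair: tuple[int, int, float, float] | None = None
    two_state: tuple[float, float, float, float] | None = None  # open, closed, p_open, dwell
    n_frames: int = 5000
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode_vectors is not None:
            self.mode_vectors = np.atleast_2d(np.asarray(self.mode_vectors, float))
            self.mode_sigmas = np.atleast_1d(np.asarray(self.mode_sigmas, float))
            if np.any(self.mode_sigmas < 0):
                raise ValueError("mode sigmas must be non-negative")
            G = self.mode_vectors @ self.mode_vectors.T
            if not np.allclose(G, np.eye(G.shape[0]), atol=1e-8):
                raise ValueError("mode vectors must be orthonormal")


_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C"}


def _ca_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding helix-loop-helix Cα trace (ideal α-helix geometry)."""
    n1 = n // 2
    n2 = n - n1
    rise, radius, twist = 1.5, 2.3, np.radians(100.0)
    pts = []
    for i in range(n1):
        pts.append(
            [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i]
        )
    z_top = rise * (n1 - 1)
    # second helix: parallel axis 10 Å away in x, descending
    for i in range(n2):
        pts.append(
            [
                10.0 + radius * np.cos(-twist * i + 0.7),
                radius * np.sin(-twist * i + 0.7),
                z_top + 2.0 - rise * i,
            ]
        )
    pts = np.array(pts)
    pts += rng.normal(scale=0.05, size=pts.shape)  # break exact symmetries
    return pts


def make_toy_chain(
    n_residues: int,
    seed: int = 0,
    chain: str = "A",
    start_resid: int = 1,
) -> Structure:
    """Deterministic toy protein: helix-loop-helix Cα trace with dummy
    backbone (N, C, O) and a two-atom sidechain stub (CB, CG) per residue.

    The sidechain stub supports N-Cα-Cβ-Cγ dihedral tests; elements carry
    plausible masses so mass-weighted centers of mass are exercised.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    ca = _ca_trace(n_residues, rng)
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n_residues):
        # local frame along the chain
        prev_ca = ca[i - 1] if i > 0 else ca[i] - np.array([0.0, 0.0, 1.5])
        next_ca = ca[i + 1] if i < n_residues - 1 else ca[i] + np.array([0.0, 0.0, 1.5])
        t = next_ca - prev_ca
        t /= np.linalg.norm(t)
        u = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(t, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        offsets = {
            "N": -1.2 * t + 0.5 * u,
            "CA": np.zeros(3),
            "C": 1.2 * t + 0.4 * u,
            "O": 1.5 * t + 1.4 * v,
            "CB": 1.2 * u + 0.9 * v,
            "CG": 2.1 * u + 1.9 * v,
        }
        for name, off in offsets.items():
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    altloc="",
                    resname="ALA" if name != "CG" else "ABU",
                    chain=chain,
                    resid=start_resid + i,
                    coords=ca[i] + off,
                    occupancy=1.0,
                    bfactor=0.0,
                    element=_BACKBONE_ELEMENTS[name],
                )
            )
            serial += 1
    # uniform residue name keeps PDB round-trips simple
    atoms = [
        AtomRecord(
            serial=a.serial,
            name=a.name,
            altloc=a.altloc,
            resname="ALA",
            chain=a.chain,
            resid=a.resid,
            coords=a.coords,
            occupancy=a.occupancy,
            bfactor=a.bfactor,
            element=a.element,
        )
        for a in atoms
    ]
    return Structure(atoms)


def _ca_indices(ref: Structure) -> np.ndarray:
    return np.array([i for i, a in enumerate(ref.atoms) if a.name == "CA"])


def _residue_indices(ref: Structure) -> dict[int, np.ndarray]:
    out: dict[int, list[int]] = {}
    for i, a in enumerate(ref.atoms):
        out.setdefault(a.resid, []).append(i)
    return {r: np.array(ix) for r, ix in out.items()}


def localized_mode(
    ref: Structure, resids, direction: np.ndarray
) -> np.ndarray:
    """Orthonormal 3n mode vector displacing the given residues' Cα sites
    along one common direction (n = number of Cα atoms in ``ref``)."""
    ca_idx = _ca_indices(ref)
    resid_of_ca = [ref.atoms[i].resid for i in ca_idx]
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    v = np.zeros((len(ca_idx), 3))
    for k, r in enumerate(resid_of_ca):
        if r in set(resids):
            v[k] = direction
    flat = v.ravel()
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise ValueError("no Cα atoms match the given resids")
    return flat / norm


def rigid_basis(ca_coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3n) of rigid-body displacements of a Cα set."""
    coords = np.asarray(ca_coords, float)
    n = coords.shape[0]
    center = coords.mean(axis=0)
    rel = coords - center
    vecs = []
    for ax in np.eye(3):
        vecs.append(np.tile(ax, n))  # translations
    for ax in np.eye(3):
        vecs.append(np.cross(np.tile(ax, (n, 1)), rel).ravel())  # rotations
    Q, _ = np.linalg.qr(np.array(vecs).T)
    return Q.T


def orthogonalize_to_rigid(ref: Structure, mode: np.ndarray) -> np.ndarray:
    """Project a 3n mode vector onto the complement of rigid-body motions.

    Superposition-based analyses (RMSF, PCA) remove the global translation
    and rotation of every frame; a planted mode is exactly recoverable by
    them only if it carries no rigid-body component.  Returns the
    projected, renormalized mode.
    """
    ca_idx = _ca_indices(ref)
    R = rigid_basis(ref.coords[ca_idx])
    v = np.asarray(mode, float).copy()
    v -= R.T @ (R @ v)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("mode is entirely rigid-body")
    return v / norm


def random_orthonormal_modes(
    n_residues: int, k: int, rng: np.random.Generator,
    exclude_rigid_of: Structure | None = None,
) -> np.ndarray:
    """k orthonormal random 3n-vectors (rows), optionally constrained to
    the rigid-motion-orthogonal complement of a reference structure."""
    M = rng.normal(size=(3 * n_residues, k))
    if exclude_rigid_of is not None:
        ca_idx = _ca_indices(exclude_rigid_of)
        R = rigid_basis(exclude_rigid_of.coords[ca_idx])
        M -= R.T @ (R @ M)
    Q, _ = np.linalg.qr(M)
    return Q[:, :k].T


def simulate_modes_trajectory(
    ref: Structure, spec: SyntheticSpec
) -> tuple[Trajectory, np.ndarray]:
    """Harmonic-mode trajectory: frame_t = ref + Σ_k a_k(t) v_k.

    Mode displacements act on whole residues (each residue is translated
    by its Cα-site displacement) so residue-level descriptors such as
    centers of mass move consistently.  Returns the trajectory and the
    (n_frames, k) amplitude matrix — the planted ground truth.

    With ``coupled_pair = (i, j, slope, intercept)``, residue j is
    additionally translated along the i→j axis so the Cα_i–Cα_j distance
    equals ``slope·a_1(t) + intercept`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ca_idx = _ca_indices(ref)
    n_ca = len(ca_idx)
    res_idx = _residue_indices(ref)
    resid_of_ca = [ref.atoms[i].resid for i in ca_idx]

    if spec.mode_vectors is None:
        amps = np.zeros((spec.n_frames, 0))
        modes = np.zeros((0, 3 * n_ca))
        sigmas = np.zeros(0)
    else:
        modes = spec.mode_vectors
        sigmas = spec.mode_sigmas
        if modes.shape[1] != 3 * n_ca:
            raise ValueError(
                f"mode vectors have dimension {modes.shape[1]}, expected {3 * n_ca}"
            )
        amps = rng.normal(size=(spec.n_frames, modes.shape[0])) * sigmas[None, :]

    base = ref.coords
    # map every atom to the Cα row of its residue, so residues move rigidly
    ca_row_of_resid = {r: k for k, r in enumerate(resid_of_ca)}
    atom_to_ca = np.array([ca_row_of_resid[a.resid] for a in ref.atoms])

    if modes.size:
        disp_ca = (amps @ modes).reshape(spec.n_frames, n_ca, 3)
        frames = base[None, :, :] + disp_ca[:, atom_to_ca, :]
    else:
        frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(scale=spec.noise_sigma, size=frames.shape)

    if spec.coupled_pair is not None:
        ri, rj, slope, intercept = spec.coupled_pair
        a1 = amps[:, 0] if amps.size else np.zeros(spec.n_frames)
        target = slope * a1 + intercept
        if np.any(target <= 0):
            raise ValueError(
                "coupled distance target is not positive on some frames; "
                "reduce slope or raise intercept"
            )
        ia = ca_idx[resid_of_ca.index(ri)]
        ja = ca_idx[resid_of_ca.index(rj)]
        axis = frames[:, ja, :] - frames[:, ia, :]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        shift = frames[:, ia, :] + target[:, None] * axis - frames[:, ja, :]
        frames[:, res_idx[rj], :] += shift[:, None, :]
    return Trajectory(topology=ref, frames=frames), amps


def simulate_two_state(
    ref: Structure,
    spec: SyntheticSpec,
    pair: tuple[int, int] = (123, 140),
) -> tuple[Trajectory, np.ndarray]:
    """Two-state open↔closed switching of one Cα–Cα descriptor.

    The state sequence is a seeded two-state Markov chain with stationary
    open probability ``p_open`` and mean dwell time ``dwell`` frames; per
    frame, residue ``pair[1]`` is translated along the pair axis so the
    descriptor sits exactly at ``open_value`` or ``closed_value`` (Å).
    Returns the trajectory and the true per-frame boolean labels
    (True = open).
    """
    if spec.two_state is None:
        raise ValueError("spec.two_state is not set")
    open_value, closed_value, p_open, dwell = spec.two_state
    if not 0.0 <= p_open <= 1.0:
        raise ValueError("p_open must be in [0, 1]")
    dwell = max(float(dwell), 1.0)
    rng = np.random.default_rng(spec.seed)
    p_oc = min((1.0 - p_open) / dwell, 1.0)
    p_co = min(p_open / dwell, 1.0)
    labels = np.empty(spec.n_frames, dtype=bool)
    state = bool(rng.random() < p_open)
    for f in range(spec.n_frames):
        labels[f] = state
        r = rng.random()
        if state and r < p_oc:
            state = False
        elif not state and r < p_co:
            state = True

    ca_idx = _ca_indices(ref)
    resid_of_ca = [ref.atoms[i].resid for i in ca_idx]
    res_idx = _residue_indices(ref)
    ri, rj = pair
    ia = ca_idx[resid_of_ca.index(ri)]
    ja = ca_idx[resid_of_ca.index(rj)]
    base = ref.coords
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    target = np.where(labels, open_value, closed_value)
    axis = base[ja] - base[ia]
    axis = axis / np.linalg.norm(axis)
    shift = base[ia][None, :] + target[:, None] * axis[None, :] - base[ja][None, :]
    frames[:, res_idx[rj], :] += shift[:, None, :]
    return Trajectory(topology=ref, frames=frames), labels


def plant_hbond_series(
    plan: np.ndarray,
    violation: str = "distance",
    seed: int = 0,
) -> tuple[Trajectory, float]:
    """Trajectory of a donor–H–acceptor triplet with planted occupancy.

    ``plan`` is the per-frame boolean target (True = bond present).  On
    violating frames the geometry breaks either the distance term
    (``violation="distance"``: D···A stretched to 4.5 Å, still linear) or
    only the angle term (``violation="angle"``: D···A kept below 3.5 Å but
    the donor–H···acceptor arrangement bent ~90° from linear, so a
    distance-only criterion still accepts the frame).  Returns the
    trajectory and the exact planted occupancy.
    """
    plan = np.asarray(plan, dtype=bool)
    if violation not in ("distance", "angle"):
        raise ValueError("violation must be 'distance' or 'angle'")
    donor = AtomRecord(1, "N", "", "ASN", "A", 1, np.zeros(3), element="N")
    hydro = AtomRecord(2, "H", "", "ASN", "A", 1, np.array([1.0, 0.0, 0.0]), element="H")
    accep = AtomRecord(3, "O", "", "MET", "A", 2, np.array([2.9, 0.0, 0.0]), element="O")
    anchor = AtomRecord(4, "CA", "", "ASN", "A", 1, np.array([-1.5, 0.0, 0.0]), element="C")
    topo = Structure([donor, hydro, accep, anchor])
    frames = np.empty((plan.size, 4, 3))
    good_a = np.array([2.9, 0.0, 0.0])
    bad_dist_a = np.array([4.5, 0.0, 0.0])
    bad_angle_a = np.array([1.0, 2.8, 0.0])  # |D-A| ≈ 2.97 Å, ~90° off linear
    for f, present in enumerate(plan):
        frames[f, 0] = donor.coords
        frames[f, 1] = hydro.coords
        frames[f, 3] = anchor.coords
        if present:
            frames[f, 2] = good_a
        else:
            frames[f, 2] = bad_dist_a if violation == "distance" else bad_angle_a
    return Trajectory(topology=topo, frames=frames), float(plan.mean())
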
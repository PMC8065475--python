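"""Per-frame descriptors over trajectories.

RMSD/RMSF, distance time series (atom–atom and atom–to–center-of-mass),
geometric hydrogen-bond occupancy, ligand end-to-end distances, sidechain
dihedral series and windowed segment statistics.  All values are computed
in Å; :func:`to_nm` is provided for report layers that follow the nm
convention of MD papers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import (
    GeometryError,
    Structure,
    Trajectory,
    center_of_mass,
    dihedral,
    kabsch_superpose,
    select,
)

__all__ = [
    "AtomSpec",
    "DistanceSeries",
    "HBondCriterion",
    "HBondSeries",
    "rmsd_series",
    "rmsf",
    "distance_series",
    "com_distance_series",
    "hbond_series",
    "end_to_end_series",
    "dihedral_series",
    "segment_stats",
    "to_nm",
]


def to_nm(value_angstrom):
    """Convert Å to nm (the unit used in MD summary tables)."""
    return np.asarray(value_angstrom, dtype=float) / 10.0


@dataclass(frozen=True)
class AtomSpec:
    """(chain, resid, atom name) address of one atom in a topology."""

    chain: str
    resid: int
    name: str

    def resolve(self, s: Structure) -> int:
        try:
            return s.atom_index(self.chain, self.resid, self.name)
        except KeyError as exc:
            raise KeyError(f"cannot resolve atom spec {self}: {exc}") from exc


@dataclass
class DistanceSeries:
    """A per-frame distance observable with its summary statistics."""

    pair_label: str
    values: np.ndarray  # Å
    times: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1); 0 for a single frame."""
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def range_dd(self) -> float:
        """Δd = d_max − d_min, the amplitude weight of the κ map."""
        return self.max - self.min


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    The default (donor–acceptor ≤ 3.5 Å; donor–H···acceptor within 30° of
    linear) is the de-facto standard of MD analysis tools.  When the
    trajectory carries no polar hydrogen for a donor (united-atom force
    fields), the criterion degrades to distance-only.
    """

    max_da_distance: float = 3.5  # Å
    max_h_angle_dev: float = 30.0  # degrees from linear

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_h_angle_dev <= 0:
            raise ValueError("criterion parameters must be positive")


@dataclass
class HBondSeries:
    triplet_label: str
    present: np.ndarray  # bool per frame
    times: np.ndarray | None = None

    @property
    def occupancy(self) -> float:
        """Fraction of frames in which the bond criterion is satisfied."""
        return float(np.mean(self.present))


# ---------------------------------------------------------------------------


def _resolve_selection_indices(s: Structure, selection: dict | None) -> np.ndarray:
    if selection is None:
        return np.arange(s.n_atoms)
    sub = select(s, **selection)
    serials = {a.serial for a in sub.atoms}
    return np.array([i for i, a in enumerate(s.atoms) if a.serial in serials])


def rmsd_series(
    traj: Trajectory, ref: Structure, selection: dict | None = None
) -> np.ndarray:
    """Per-frame RMSD (Å) to ``ref`` after Kabsch superposition.

    ``selection`` keywords are forwarded to :func:`lidkit.io.select` and
    must resolve to the same atoms (1:1, same order) in both topology and
    reference.
    """
    idx_traj = _resolve_selection_indices(traj.topology, selection)
    idx_ref = _resolve_selection_indices(ref, selection)
    if len(idx_traj) != len(idx_ref):
        raise ValueError(
            f"selection maps to {len(idx_traj)} trajectory atoms but "
            f"{len(idx_ref)} reference atoms"
        )
    ref_xyz = ref.coords[idx_ref]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.frames[f][idx_traj], ref_xyz)
    return out


def rmsf(
    traj: Trajectory, selection: dict | None = None, superpose: bool = True
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the mean structure.

    With ``superpose=True`` every frame is first superposed onto the mean
    structure, and the mean is refined once more from the superposed frames
    (two-pass iterative superposition), which removes rigid-body drift.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _resolve_selection_indices(traj.topology, selection)
    X = traj.frames[:, idx, :].copy()
    if superpose:
        for _ in range(2):
            mean = X.mean(axis=0)
            for f in range(X.shape[0]):
                R, t, _ = kabsch_superpose(X[f], mean)
                X[f] = X[f] @ R.T + t
    mean = X.mean(axis=0)
    return np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))


def distance_series(
    traj: Trajectory, a: AtomSpec, b: AtomSpec, label: str | None = None
) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms."""
    ia = a.resolve(traj.topology)
    ib = b.resolve(traj.topology)
    vals = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    label = label or f"{a.chain}/{a.resid}/{a.name}-{b.chain}/{b.resid}/{b.name}"
    return DistanceSeries(pair_label=label, values=vals, times=traj.times)


def com_distance_series(
    traj: Trajectory,
    atom: AtomSpec,
    chain: str,
    resid_range: tuple[int, int],
    weighting: str = "mass",
    atoms: str = "all",
    label: str | None = None,
) -> DistanceSeries:
    """Per-frame distance from one atom to the center of mass of a residue range.

    The reference descriptor of lid aperture: e.g. the hinge Leu Cα against
    the COM of the lid-helix residues.
    """
    ia = atom.resolve(traj.topology)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.frame_structure(f)
        sub = select(frame, chain=chain, resid_range=resid_range)
        com = center_of_mass(sub, weighting=weighting, atoms=atoms)
        vals[f] = np.linalg.norm(traj.frames[f, ia, :] - com)
    label = label or (
        f"{atom.chain}/{atom.resid}/{atom.name}-COM({chain}:"
        f"{resid_range[0]}-{resid_range[1]})"
    )
    return DistanceSeries(pair_label=label, values=vals, times=traj.times)


def hbond_series(
    traj: Trajectory,
    donor: AtomSpec,
    acceptor: AtomSpec,
    hydrogen: AtomSpec | None = None,
    crit: HBondCriterion | None = None,
    label: str | None = None,
) -> HBondSeries:
    """Per-frame hydrogen-bond presence and overall occupancy.

    A frame counts as bonded when the donor–acceptor distance is within
    ``crit.max_da_distance`` and — if a hydrogen atom is given — the
    donor–H···acceptor angle deviates from linearity by at most
    ``crit.max_h_angle_dev`` degrees.  Without a hydrogen (united-atom
    topologies) the distance term alone decides.
    """
    crit = crit or HBondCriterion()
    i_d = donor.resolve(traj.topology)
    i_a = acceptor.resolve(traj.topology)
    i_h = hydrogen.resolve(traj.topology) if hydrogen is not None else None
    D = traj.frames[:, i_d, :]
    A = traj.frames[:, i_a, :]
    ok = np.linalg.norm(D - A, axis=1) <= crit.max_da_distance
    if i_h is not None:
        H = traj.frames[:, i_h, :]
        hd = D - H
        ha = A - H
        cosang = np.sum(hd * ha, axis=1) / (
            np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok &= (180.0 - ang) <= crit.max_h_angle_dev
    label = label or f"{donor.chain}/{donor.resid}/{donor.name}->" \
        f"{acceptor.chain}/{acceptor.resid}/{acceptor.name}"
    return HBondSeries(triplet_label=label, present=ok, times=traj.times)


def end_to_end_series(
    traj: Trajectory, first_atom: AtomSpec, last_atom: AtomSpec, label: str | None = None
) -> DistanceSeries:
    """Ligand end-to-end distance (e.g. detergent N to terminal chain carbon).

    Alias of :func:`distance_series`; kept as its own entry point because
    the folded/extended state of a bound ligand is a named observable.
    """
    return distance_series(traj, first_atom, last_atom, label=label)


def dihedral_series(
    traj: Trajectory,
    p1: AtomSpec,
    p2: AtomSpec,
    p3: AtomSpec,
    p4: AtomSpec,
) -> np.ndarray:
    """Per-frame signed dihedral (degrees) over a 4-atom spec.

    The canonical use is the N-Cα-Cβ-Cγ sidechain angle of the aromatic
    lid residue, whose sign distinguishes inward/outward ring orientation.
    """
    idx = [p.resolve(traj.topology) for p in (p1, p2, p3, p4)]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = dihedral(*(traj.frames[f, i, :] for i in idx))
    return out


def segment_stats(
    series: DistanceSeries | np.ndarray,
    windows: list[tuple[float, float]],
    times: np.ndarray | None = None,
) -> list[dict]:
    """Mean ± sample sd of a series over [start, end) time windows.

    When the series carries no times, window bounds are interpreted as
    frame indices.  Empty windows raise.
    """
    if isinstance(series, DistanceSeries):
        values = series.values
        times = series.times if times is None else times
        label = series.pair_label
    else:
        values = np.asarray(series, dtype=float)
        label = ""
    axis = times if times is not None else np.arange(values.size)
    out = []
    for lo, hi in windows:
        mask = (axis >= lo) & (axis < hi)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"window [{lo}, {hi}) selects no frames")
        vals = values[mask]
        out.append(
            {
                "label": label,
                "start": lo,
                "end": hi,
                "n_frames": n,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
            }
        )
    return out
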
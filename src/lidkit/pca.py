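"""Essential-dynamics PCA and the PC–distance correlation (κ) map.

PCA diagonalizes the covariance of superposed Cα coordinates; the
projection of frame ``n`` onto principal mode ``m`` is the series PC_n.
For every residue pair (i, j) with per-frame distance d_ij,n the map

    κ_ij = [ (1/N_f) Σ_n PC_n d_ij,n  −  PC̄ · d̄_ij ] / (σ_PC σ_ij)

is the population-convention Pearson correlation between the mode
projection and that distance series.  Multiplying |κ_ij| by the observed
distance range Δd_ij = d_max − d_min yields the amplitude-weighted map
that highlights large-amplitude motions correlated with the chosen mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Structure, Trajectory, kabsch_superpose
from .traj import _resolve_selection_indices

__all__ = [
    "PCAResult",
    "PairDistanceSet",
    "KappaMap",
    "pca",
    "all_pair_distances",
    "kappa_map",
    "weighted_kappa_map",
]


@dataclass
class PCAResult:
    """Eigen-decomposition of the coordinate covariance.

    ``eigenvalues`` (Å², descending), ``eigenvectors`` (columns,
    orthonormal 3n-vectors) and ``projections`` (N_f × n_modes; zero-mean
    per mode).
    """

    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    atom_indices: np.ndarray
    resids: np.ndarray
    static: bool = False


@dataclass
class PairDistanceSet:
    """All pairwise Cα distance series of a selection.

    ``values`` has shape (n_pairs, N_f) in condensed (i < j) order;
    ``pair_index[(i, j)]`` maps a residue-index pair to its row.
    """

    resids: np.ndarray
    values: np.ndarray

    @property
    def n(self) -> int:
        return self.resids.size

    def row(self, i: int, j: int) -> np.ndarray:
        i, j = (i, j) if i < j else (j, i)
        n = self.n
        k = i * n - i * (i + 1) // 2 + (j - i - 1)
        return self.values[k]


@dataclass
class KappaMap:
    """κ, Δd and |κ|Δd matrices over a residue selection.

    Degenerate pairs (zero-variance distance, or a static mode) carry
    κ = 0 and are flagged in ``degenerate_mask`` rather than dropped, so
    the matrices stay rectangular for heat-map rendering.
    """

    resids: np.ndarray
    kappa: np.ndarray
    delta_d: np.ndarray
    degenerate_mask: np.ndarray

    @property
    def weighted(self) -> np.ndarray:
        return np.abs(self.kappa) * self.delta_d


def pca(
    traj: Trajectory,
    selection: dict | None = None,
    superpose_to: str = "mean",
    n_modes: int | None = None,
) -> PCAResult:
    """Essential-dynamics PCA of (by default Cα) coordinates.

    Frames are superposed either to the iteratively refined mean structure
    (default) or to the first frame, the covariance of the flattened
    coordinates is diagonalized, and each centered frame is projected onto
    the eigenvectors.  A static trajectory is legal and returns all-zero
    eigenvalues with ``static=True``.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = _resolve_selection_indices(traj.topology, selection)
    if idx.size < 3:
        raise ValueError("PCA selection needs at least 3 atoms")
    X = traj.frames[:, idx, :].copy()
    if superpose_to == "first_frame":
        ref = X[0].copy()
        for f in range(X.shape[0]):
            R, t, _ = kabsch_superpose(X[f], ref)
            X[f] = X[f] @ R.T + t
    elif superpose_to == "mean":
        for _ in range(2):
            ref = X.mean(axis=0)
            for f in range(X.shape[0]):
                R, t, _ = kabsch_superpose(X[f], ref)
                X[f] = X[f] @ R.T + t
    else:
        raise ValueError(f"unknown superpose_to {superpose_to!r}")

    mean = X.mean(axis=0)
    flat = (X - mean).reshape(X.shape[0], -1)  # (N_f, 3n)
    cov = flat.T @ flat / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_modes is not None:
        evals = evals[:n_modes]
        evecs = evecs[:, :n_modes]
    projections = flat @ evecs
    static = bool(np.all(evals < 1e-12))
    resids = traj.topology.resids[idx]
    return PCAResult(
        mean_coords=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
        atom_indices=idx,
        resids=resids,
        static=static,
    )


def all_pair_distances(traj: Trajectory, selection: dict | None = None) -> PairDistanceSet:
    """Per-frame distances for every (i < j) pair of the selection."""
    idx = _resolve_selection_indices(traj.topology, selection)
    X = traj.frames[:, idx, :]
    n = idx.size
    iu, ju = np.triu_indices(n, k=1)
    vals = np.linalg.norm(X[:, iu, :] - X[:, ju, :], axis=2).T  # (n_pairs, N_f)
    return PairDistanceSet(resids=traj.topology.resids[idx], values=vals)


def kappa_map(
    pca_result: PCAResult,
    distances: PairDistanceSet,
    mode_index: int = 0,
    convention: str = "population",
) -> KappaMap:
    """PC–distance correlation map for one principal mode.

    ``convention`` selects the variance normalization: ``"population"``
    (1/N_f, the printed prefactor of the defining formula — the default)
    or ``"sample"`` (1/(N_f−1)); κ itself is identical under both since
    the factors cancel, but the flag is kept for explicitness in derived
    statistics.
    """
    if convention not in ("population", "sample"):
        raise ValueError(f"unknown convention {convention!r}")
    pc = pca_result.projections[:, mode_index]
    nf = pc.size
    if distances.values.shape[1] != nf:
        raise ValueError(
            f"distance series have {distances.values.shape[1]} frames, "
            f"projections have {nf}"
        )
    d = distances.values  # (n_pairs, N_f)
    pc_mean = pc.mean()
    pc_sd = pc.std()  # population
    d_mean = d.mean(axis=1)
    d_sd = d.std(axis=1)
    cov = d @ pc / nf - d_mean * pc_mean
    degenerate = (d_sd == 0) | (pc_sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kap = np.where(degenerate, 0.0, cov / (d_sd * pc_sd))
    kap = np.clip(kap, -1.0, 1.0)
    dd = d.max(axis=1) - d.min(axis=1)

    n = distances.n
    kappa_m = np.zeros((n, n))
    delta_m = np.zeros((n, n))
    degen_m = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    kappa_m[iu, ju] = kap
    kappa_m[ju, iu] = kap
    delta_m[iu, ju] = dd
    delta_m[ju, iu] = dd
    degen_m[iu, ju] = degenerate
    degen_m[ju, iu] = degenerate
    # self-pairs have identically zero distance series: degenerate
    np.fill_diagonal(degen_m, True)
    return KappaMap(
        resids=distances.resids,
        kappa=kappa_m,
        delta_d=delta_m,
        degenerate_mask=degen_m,
    )


def weighted_kappa_map(km: KappaMap) -> np.ndarray:
    """Elementwise |κ|·Δd (Å); zero wherever Δd = 0."""
    return km.weighted
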
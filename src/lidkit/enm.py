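"""Cα elastic-network model (anisotropic network flavour).

One grain per residue, placed at the Cα.  Every residue pair is connected
by a harmonic spring; the force constant follows a two-regime,
cutoff-free rule in the spirit of force fields fitted to MD covariances:

* sequence-proximal pairs (|i − j| ≤ ``seq_neighbor_cutoff``) are stiff,
  with ``k = k_seq / s**2`` for sequence separation ``s``;
* all remaining pairs decay with Cartesian distance as
  ``k = k_cart * d**(-cart_exponent)`` (default exponent 6), so no hard
  distance cutoff is ever applied.

The constants are deliberately configuration-exposed: the published
parameter-free force fields of this family do not print a single set of
constants, and only relative quantities (mode shapes, normalized
mobilities, correlations) are meaningful here.

Diagonalizing the 3n × 3n Hessian yields 3n − 6 internal vibration modes
(six zero-frequency rigid-body modes for any generic 3-D structure).  The
pseudo-inverse over internal modes gives per-residue mean-square
fluctuations (predicted B-factors up to scale), normalized mobilities and
the inter-residue cross-correlation (covariance) map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "ENMParams",
    "ENMModel",
    "ModeSet",
    "build_enm",
    "normal_modes",
    "predicted_bfactors",
    "normalized_mobility",
    "enm_covariance_map",
]


@dataclass(frozen=True)
class ENMParams:
    """Force-constant rule parameters.

    seq_neighbor_cutoff : int
        Largest sequence separation treated as the stiff near-neighbour
        regime.
    k_seq : float
        Scale of the near-sequential force constants (model units);
        the pair constant is ``k_seq / s**2``.
    k_cart : float
        Scale of the distance-decaying distal constants; the pair constant
        is ``k_cart * d**(-cart_exponent)`` with ``d`` in Å.
    cart_exponent : float
        Inverse-power decay exponent for distal pairs.
    min_distance : float
        Guard (Å): node pairs closer than this are rejected as duplicates.
    """

    seq_neighbor_cutoff: int = 3
    k_seq: float = 60.0
    k_cart: float = 6.0e4
    cart_exponent: float = 6.0
    min_distance: float = 1.0

    def __post_init__(self):
        if self.k_seq <= 0 or self.k_cart <= 0:
            raise ValueError("force-constant scales must be positive")
        if self.cart_exponent <= 0:
            raise ValueError("cart_exponent must be positive")

    def force_constant(self, seq_sep: int, distance: float) -> float:
        if seq_sep <= self.seq_neighbor_cutoff:
            return self.k_seq / float(seq_sep) ** 2
        return self.k_cart * float(distance) ** (-self.cart_exponent)


@dataclass
class ENMModel:
    """Assembled network: nodes, springs and the 3n × 3n Hessian."""

    nodes: np.ndarray
    resids: np.ndarray
    springs: list[tuple[int, int, float]]
    hessian: np.ndarray


@dataclass
class ModeSet:
    """Eigen-decomposition of an ENM Hessian.

    Eigenvalues are ascending; the first ``n_zero`` modes are the
    rigid-body null space (6 for a generic 3-D structure).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are modes
    n_zero: int

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.shape[0] // 3


_ZERO_MODE_RTOL = 1e-8


def build_enm(
    ca_coords: np.ndarray,
    resids: np.ndarray | None = None,
    params: ENMParams | None = None,
) -> ENMModel:
    """Assemble the network and Hessian from Cα coordinates.

    Every ordered pair (i < j) contributes one spring whose constant comes
    from the two-regime rule; sequence separation is taken from ``resids``
    when given (so chain breaks and deposited numbering are honoured) and
    from array position otherwise.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("ca_coords must have shape (n, 3)")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes to build a network")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    params = params or ENMParams()
    if resids is None:
        resids = np.arange(1, n + 1)
    resids = np.asarray(resids, dtype=int)
    if resids.shape != (n,):
        raise ValueError("resids length must match number of nodes")

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    iu, ju = np.triu_indices(n, k=1)
    if np.any(dist[iu, ju] < params.min_distance):
        bad = np.argmin(dist[iu, ju])
        raise ValueError(
            f"nodes {iu[bad]} and {ju[bad]} are closer than "
            f"min_distance={params.min_distance} Å"
        )

    springs = []
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in zip(iu, ju):
        s = abs(int(resids[j]) - int(resids[i]))
        s = max(s, 1)
        k = params.force_constant(s, dist[i, j])
        springs.append((int(i), int(j), float(k)))
        e = diff[j, i] / dist[i, j]
        block = k * np.outer(e, e)
        sl_i = slice(3 * i, 3 * i + 3)
        sl_j = slice(3 * j, 3 * j + 3)
        hessian[sl_i, sl_i] += block
        hessian[sl_j, sl_j] += block
        hessian[sl_i, sl_j] -= block
        hessian[sl_j, sl_i] -= block
    return ENMModel(nodes=coords, resids=resids, springs=springs, hessian=hessian)


def normal_modes(model: ENMModel) -> ModeSet:
    """Full eigen-decomposition of the Hessian (unit masses).

    Raises if more than six near-zero eigenvalues are found, which signals
    degenerate (e.g. collinear) geometry.
    """
    evals, evecs = scipy.linalg.eigh(model.hessian)
    # clip small negative round-off
    tol = _ZERO_MODE_RTOL * max(evals[-1], 1e-30)
    n_zero = int(np.sum(np.abs(evals) < tol))
    if n_zero > 6:
        raise ValueError(
            f"{n_zero} near-zero modes found: degenerate (collinear?) geometry"
        )
    if np.any(evals < -tol):
        raise ValueError("Hessian has significantly negative eigenvalues")
    evals = np.clip(evals, 0.0, None)
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero)


def _pseudo_inverse_blocks(ms: ModeSet) -> np.ndarray:
    """(n, n, 3, 3) blocks of the Hessian pseudo-inverse over internal modes."""
    n = ms.n_nodes
    lam = ms.eigenvalues[ms.n_zero :]
    if lam.size == 0 or np.all(lam == 0):
        raise ValueError("no internal modes: all-zero spectrum")
    V = ms.eigenvectors[:, ms.n_zero :]  # (3n, m)
    W = V / np.sqrt(lam)[None, :]
    cov = W @ W.T  # full pseudo-inverse, (3n, 3n)
    return cov.reshape(n, 3, n, 3).transpose(0, 2, 1, 3)


def predicted_bfactors(ms: ModeSet) -> np.ndarray:
    """Per-residue mean-square fluctuation profile (arbitrary scale).

    Proportional to the trace of each diagonal 3 × 3 block of the Hessian
    pseudo-inverse, i.e. ``sum_m v_im**2 / lambda_m`` over internal modes —
    the coarse-grained analogue of a crystallographic B-factor.
    """
    blocks = _pseudo_inverse_blocks(ms)
    return np.array([np.trace(blocks[i, i]) for i in range(ms.n_nodes)])


def normalized_mobility(ms: ModeSet) -> np.ndarray:
    """Predicted B-factor profile rescaled so its maximum is exactly 1."""
    b = predicted_bfactors(ms)
    return b / b.max()


def enm_covariance_map(ms: ModeSet) -> np.ndarray:
    """Normalized inter-residue cross-correlation matrix in [−1, 1].

    ``C_ij = tr(P_ij) / sqrt(tr(P_ii) tr(P_jj))`` with ``P`` the
    pseudo-inverse blocks; the diagonal is exactly 1.
    """
    blocks = _pseudo_inverse_blocks(ms)
    traces = np.trace(blocks, axis1=2, axis2=3)  # (n, n)
    diag = np.diag(traces)
    corr = traces / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(corr, 1.0)
    return corr
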
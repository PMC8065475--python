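"""Lid-conformation descriptors, open/closed classification and the
spherical-probe aperture test.

The descriptor set follows the monoglyceride-lipase convention: a handful
of named Cα–Cα distances across the lid (helix H5 and the facing linker),
the distance from the hinge leucine Cα to the center of mass of the
lid-helix residues (the aperture descriptor), and the N-Cα-Cβ-Cγ sidechain
dihedral of the aromatic lid residue whose sign reports inward/outward
ring orientation.  Residue numbers default to the archaeal lipase (PFL)
numbering but are fully configurable for homologs.

The aperture probe asks how large a spherical probe can travel from an
interior seed (near the catalytic serine) to the solvent: on a 3-D grid
the clearance of a point is its distance to the nearest van der Waals
surface, and the bottleneck radius is the widest-path value (maximize the
minimum clearance along the path) between the two seeds.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GeometryError, Structure, center_of_mass, dihedral, select
from .traj import to_nm

__all__ = [
    "DescriptorScheme",
    "LidThresholds",
    "LidDescriptorSet",
    "ApertureResult",
    "BONDI_RADII",
    "compute_descriptors",
    "classify_state",
    "aperture_probe",
]

#: Bondi van der Waals radii (Å) for common elements.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}


@dataclass(frozen=True)
class DescriptorScheme:
    """Residue numbering of the named descriptors (PFL defaults)."""

    chain: str = "A"
    pair_primary: tuple[int, int] = (123, 140)  # lid residue vs linker
    pair_secondary: tuple[int, int] = (124, 142)
    pair_helix_anchor: tuple[int, int] = (122, 204)
    pair_alcohol_pocket: tuple[int, int] = (31, 153)
    aperture_atom: tuple[int, str] = (140, "CA")
    aperture_com_range: tuple[int, int] = (121, 131)
    dihedral_resid: int = 123
    dihedral_atoms: tuple[str, str, str, str] = ("N", "CA", "CB", "CG")
    com_weighting: str = "mass"
    com_atoms: str = "all"  # "all" (default) or "ca_only"


@dataclass(frozen=True)
class LidThresholds:
    """Cutoffs (Å) on the primary lid distance for state classification.

    Defaults bracket the published reference points: closed homolog lids
    near 8.4 Å, the most closed simulated mean near 7.6 Å, and the open
    crystal value near 14.9 Å.  Boundary values fall to the lower state.
    """

    t_closed: float = 9.0
    t_open: float = 12.0

    def __post_init__(self):
        if not self.t_closed < self.t_open:
            raise ValueError("t_closed must be below t_open")


@dataclass
class LidDescriptorSet:
    """Named lid descriptors of one structure/frame (distances in Å)."""

    d_123_140: float | None
    d_124_142: float | None
    d_122_204: float | None
    d_31_153: float | None
    aperture_com: float | None
    chi_f123: float | None
    state: str | None = None
    missing: tuple[str, ...] = ()

    def distances_nm(self) -> dict:
        """The distance descriptors converted to nm, for report tables."""
        out = {}
        for name in ("d_123_140", "d_124_142", "d_122_204", "d_31_153", "aperture_com"):
            v = getattr(self, name)
            out[name] = None if v is None else float(to_nm(v))
        return out


def _ca(s: Structure, chain: str, resid: int) -> np.ndarray | None:
    try:
        return s.atoms[s.atom_index(chain, resid, "CA")].coords
    except KeyError:
        return None


def compute_descriptors(
    s: Structure,
    scheme: DescriptorScheme | None = None,
    thresholds: LidThresholds | None = None,
) -> LidDescriptorSet:
    """Evaluate every named descriptor on one structure or frame.

    A missing residue disables the affected descriptor (recorded in
    ``missing``) without failing the rest.  The state label is attached
    when the primary distance is available.
    """
    scheme = scheme or DescriptorScheme()
    missing: list[str] = []
    vals: dict[str, float | None] = {}
    pair_fields = {
        "d_123_140": scheme.pair_primary,
        "d_124_142": scheme.pair_secondary,
        "d_122_204": scheme.pair_helix_anchor,
        "d_31_153": scheme.pair_alcohol_pocket,
    }
    for name, (ri, rj) in pair_fields.items():
        a = _ca(s, scheme.chain, ri)
        b = _ca(s, scheme.chain, rj)
        if a is None or b is None:
            vals[name] = None
            missing.append(name)
        else:
            vals[name] = float(np.linalg.norm(a - b))

    ap_resid, ap_name = scheme.aperture_atom
    try:
        idx = s.atom_index(scheme.chain, ap_resid, ap_name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = select(s, chain=scheme.chain, resid_range=scheme.aperture_com_range)
        if sub.n_atoms == 0:
            raise KeyError("empty COM range")
        com = center_of_mass(sub, weighting=scheme.com_weighting, atoms=scheme.com_atoms)
        vals["aperture_com"] = float(np.linalg.norm(s.atoms[idx].coords - com))
    except (KeyError, ValueError):
        vals["aperture_com"] = None
        missing.append("aperture_com")

    try:
        pts = [
            s.atoms[s.atom_index(scheme.chain, scheme.dihedral_resid, nm)].coords
            for nm in scheme.dihedral_atoms
        ]
        vals["chi_f123"] = dihedral(*pts)
    except (KeyError, GeometryError):
        vals["chi_f123"] = None
        missing.append("chi_f123")

    out = LidDescriptorSet(missing=tuple(missing), **vals)
    if out.d_123_140 is not None:
        out.state = classify_state(out, thresholds)
    return out


def classify_state(
    d: LidDescriptorSet | float, thresholds: LidThresholds | None = None
) -> str:
    """Open/intermediate/closed label from the primary lid distance (Å).

    ``closed`` iff d ≤ t_closed, ``open`` iff d > t_open, else
    ``intermediate`` — so a value exactly on a boundary goes to the lower
    (more closed) state, deterministically.
    """
    thresholds = thresholds or LidThresholds()
    value = d.d_123_140 if isinstance(d, LidDescriptorSet) else float(d)
    if value is None:
        raise ValueError("primary lid distance is missing; cannot classify")
    if value <= thresholds.t_closed:
        return "closed"
    if value <= thresholds.t_open:
        return "intermediate"
    return "open"


# ---------------------------------------------------------------------------
# aperture probe
# ---------------------------------------------------------------------------


@dataclass
class ApertureResult:
    """Outcome of the widest-path probe search.

    ``bottleneck_radius`` is the largest probe radius (Å) that passes from
    the interior seed to the exterior seed; ``path`` lists the grid points
    (Å) of the optimal route when reachable.
    """

    bottleneck_radius: float
    path: list[np.ndarray]
    reachable: bool


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=int,
)


def _clearance_grid(
    coords: np.ndarray, radii: np.ndarray, origin: np.ndarray, shape, spacing: float
) -> np.ndarray:
    """min over atoms of (|p − atom| − r_vdW) on every grid point."""
    ax = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    clearance = np.full(shape, np.inf)
    for a, r in zip(coords, radii):
        d = np.sqrt((gx - a[0]) ** 2 + (gy - a[1]) ** 2 + (gz - a[2]) ** 2) - r
        np.minimum(clearance, d, out=clearance)
    return clearance


def aperture_probe(
    s: Structure,
    interior_seed: np.ndarray,
    exterior_seed: np.ndarray,
    grid_spacing: float = 0.5,
    radii: dict | None = None,
    margin: float = 3.0,
) -> ApertureResult:
    """Bottleneck probe radius between two seed points.

    On a regular grid covering the structure (plus ``margin`` Å and both
    seeds), the clearance of each point is its distance to the nearest
    atomic van der Waals surface (Bondi radii by default, by element).
    A widest-path search over 26-connected neighbours maximizes the
    minimum clearance along the route; cells with non-positive clearance
    are impassable, and two seeds separated by such cells are unreachable.
    """
    radii = radii or BONDI_RADII
    coords = s.coords
    rads = np.array(
        [radii.get(a.element.upper(), BONDI_RADII["C"]) for a in s.atoms]
    )
    interior_seed = np.asarray(interior_seed, dtype=float)
    exterior_seed = np.asarray(exterior_seed, dtype=float)
    for label, seed in (("interior", interior_seed), ("exterior", exterior_seed)):
        if np.min(np.linalg.norm(coords - seed, axis=1) - rads) <= 0:
            raise ValueError(f"{label} seed lies inside an atom's vdW sphere")
    if grid_spacing > 1.0:
        warnings.warn(
            f"grid spacing {grid_spacing} Å is coarse; bottleneck radii may "
            "be unreliable",
            stacklevel=2,
        )

    pts = np.vstack([coords, interior_seed, exterior_seed])
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = tuple(int(np.floor((hi[k] - lo[k]) / grid_spacing)) + 1 for k in range(3))
    if np.prod(shape) > 4e6:
        raise ValueError(
            f"grid of shape {shape} is too large; increase grid_spacing"
        )
    clearance = _clearance_grid(coords, rads, lo, shape, grid_spacing)

    def to_idx(p):
        return tuple(
            int(np.clip(round((p[k] - lo[k]) / grid_spacing), 0, shape[k] - 1))
            for k in range(3)
        )

    start = to_idx(interior_seed)
    goal = to_idx(exterior_seed)

    # widest path: max-heap on the bottleneck value reached so far
    best = np.full(shape, -np.inf)
    prev = {}
    c0 = clearance[start]
    if c0 <= 0 or clearance[goal] <= 0:
        return ApertureResult(0.0, [], False)
    best[start] = c0
    heap = [(-c0, start)]
    while heap:
        negb, u = heapq.heappop(heap)
        b = -negb
        if b < best[u]:
            continue
        if u == goal:
            break
        for off in _NEIGHBOR_OFFSETS:
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            cv = clearance[v]
            if cv <= 0:
                continue
            nb = min(b, cv)
            if nb > best[v]:
                best[v] = nb
                prev[v] = u
                heapq.heappush(heap, (-nb, v))
    if not np.isfinite(best[goal]) or best[goal] <= 0:
        return ApertureResult(0.0, [], False)
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    pts_path = [lo + grid_spacing * np.array(p, dtype=float) for p in path]
    return ApertureResult(float(best[goal]), pts_path, True)
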
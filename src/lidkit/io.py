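"""Structure and trajectory I/O plus geometric primitives.

PDB is the native format: single-model files for structures and the
multi-model dialect (``MODEL``/``ENDMDL``) for trajectories.  Parsing and
writing are delegated to :mod:`biotite.structure.io.pdb`; this module adds
the altloc-resolution policies, fixed-column validation with line numbers,
and the light-weight containers the rest of the package works with.

Internal length unit is the ångström throughout; report layers convert to
nm where conventional.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "PDBParseError",
    "GeometryError",
    "parse_pdb",
    "parse_pdb_models",
    "read_multimodel_pdb",
    "load_trajectory",
    "write_pdb",
    "write_trajectory",
    "select",
    "kabsch_superpose",
    "dihedral",
    "center_of_mass",
    "ATOMIC_MASSES",
]


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear points etc.)."""


#: Standard atomic masses (u) for the elements that occur in protein /
#: detergent topologies; unknown elements fall back to carbon.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record after altloc resolution.

    ``resid`` keeps the deposited (1-based) numbering; insertion codes are
    preserved in ``icode`` rather than folded into the number.
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resid: int
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    icode: str = ""
    hetatm: bool = False

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), ATOMIC_MASSES["C"])


@dataclass
class Structure:
    """An ordered collection of atoms from one PDB model."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __post_init__(self):
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise ValueError(f"non-finite coordinates for atom {a.serial}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in Å (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        return Structure(
            [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)],
            model_id=self.model_id,
        )

    @property
    def resids(self) -> np.ndarray:
        return np.array([a.resid for a in self.atoms], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        """Index of the unique atom matching (chain, resid, name)."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain == chain and a.resid == resid and a.name == name
        ]
        if not hits:
            raise KeyError(f"no atom {name} in {chain}/{resid}")
        if len(hits) > 1:
            raise KeyError(f"ambiguous atom {name} in {chain}/{resid}")
        return hits[0]


@dataclass
class Trajectory:
    """Frames of coordinates bound to a fixed topology.

    ``frames`` is an (n_frames, n_atoms, 3) array in Å; ``times`` (ns) is
    optional and must be strictly increasing when given.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.frames.shape[0],):
                raise ValueError("times length must equal number of frames")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_COORD_SLICES = (slice(30, 38), slice(38, 46), slice(46, 54))


def _validate_pdb_lines(text: str) -> int:
    """Pre-scan fixed-column records; return the ATOM/HETATM count.

    Raises :class:`PDBParseError` naming the 1-based line number of the
    first malformed record.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: ATOM/HETATM record shorter than 54 columns"
            )
        for sl in _COORD_SLICES:
            try:
                float(line[sl])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparsable coordinate field {line[sl]!r}"
                ) from None
        n += 1
    return n


def _array_to_structure(arr: AtomArray, model_id: int) -> Structure:
    atoms = []
    occ = (
        arr.occupancy
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(arr.array_length())
    )
    bf = (
        arr.b_factor
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(arr.array_length())
    )
    alt = (
        arr.altloc_id
        if "altloc_id" in arr.get_annotation_categories()
        else np.full(arr.array_length(), " ")
    )
    serial = (
        arr.atom_id
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=int(serial[i]),
                name=str(arr.atom_name[i]),
                altloc=str(alt[i]).strip(),
                resname=str(arr.res_name[i]),
                chain=str(arr.chain_id[i]),
                resid=int(arr.res_id[i]),
                icode=str(arr.ins_code[i]).strip(),
                coords=np.array(arr.coord[i], dtype=float),
                occupancy=float(occ[i]),
                bfactor=float(bf[i]),
                element=str(arr.element[i]),
                hetatm=bool(arr.hetero[i]),
            )
        )
    return Structure(atoms, model_id=model_id)


_EXTRA_FIELDS = ["atom_id", "b_factor", "occupancy"]


def _resolve_altloc(arr: AtomArray, policy: str, label: str | None) -> AtomArray:
    """Collapse altloc duplicates according to the requested policy."""
    alt = arr.altloc_id
    blank = np.isin(alt, (" ", "", "."))
    if policy == "label":
        if label is None:
            raise ValueError("altloc policy 'label' requires altloc_label")
        return arr[blank | (alt == label)]
    # group duplicate (chain, resid, icode, name) records and keep one
    keys = {}
    keep = np.ones(arr.array_length(), dtype=bool)
    for i in range(arr.array_length()):
        if blank[i]:
            continue
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i], arr.atom_name[i])
        if key not in keys:
            keys[key] = i
            continue
        j = keys[key]
        if policy == "first":
            keep[i] = False
        elif policy == "highest_occupancy":
            if arr.occupancy[i] > arr.occupancy[j]:
                keep[j] = False
                keys[key] = i
            else:
                keep[i] = False
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
    return arr[keep]


def parse_pdb(
    text: str,
    altloc_policy: str = "first",
    altloc_label: str | None = None,
    model: int = 1,
) -> Structure:
    """Parse one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    text
        Full PDB file content.
    altloc_policy
        ``"first"`` (keep the first-listed conformation, the default,
        matching the convention of retaining the main conformation of
        double-conformation residues), ``"highest_occupancy"``, or
        ``"label"`` (keep only records whose altloc equals
        ``altloc_label``).
    model
        1-based model number to extract.
    """
    if _validate_pdb_lines(text) == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    pdb = PDBFile.read(_io.StringIO(text))
    arr = pdb.get_structure(model=model, altloc="all", extra_fields=_EXTRA_FIELDS)
    arr = _resolve_altloc(arr, altloc_policy, altloc_label)
    return _array_to_structure(arr, model_id=model)


def parse_pdb_models(
    text: str, altloc_policy: str = "first", altloc_label: str | None = None
) -> list[Structure]:
    """Parse every model of a (possibly multi-model) PDB file."""
    if _validate_pdb_lines(text) == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    pdb = PDBFile.read(_io.StringIO(text))
    out = []
    for m in range(1, pdb.get_model_count() + 1):
        arr = pdb.get_structure(model=m, altloc="all", extra_fields=_EXTRA_FIELDS)
        arr = _resolve_altloc(arr, altloc_policy, altloc_label)
        out.append(_array_to_structure(arr, model_id=m))
    return out


def read_multimodel_pdb(text: str, times: np.ndarray | None = None) -> Trajectory:
    """Read a multi-model PDB file as a :class:`Trajectory`.

    The first model supplies the topology; every model must contain the
    same atoms in the same order.
    """
    models = parse_pdb_models(text)
    n = models[0].n_atoms
    for m in models[1:]:
        if m.n_atoms != n:
            raise PDBParseError(
                f"model {m.model_id} has {m.n_atoms} atoms, expected {n}"
            )
    frames = np.stack([m.coords for m in models])
    return Trajectory(topology=models[0], frames=frames, times=times)


def load_trajectory(
    path: str,
    topology_path: str | None = None,
    times: np.ndarray | None = None,
) -> Trajectory:
    """Load a trajectory from disk.

    Multi-model PDB is the native dialect.  Any other extension is handed
    to MDAnalysis (optional dependency) as an adapter for binary formats
    (XTC/TRR/DCD...), which then requires ``topology_path``.
    """
    if str(path).lower().endswith(".pdb"):
        with open(path) as fh:
            return read_multimodel_pdb(fh.read(), times=times)
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "binary trajectory formats require the optional MDAnalysis "
            "dependency (pip install lidkit[traj])"
        ) from exc
    if topology_path is None:
        raise ValueError("binary trajectory formats require topology_path")
    with open(topology_path) as fh:
        topo = parse_pdb(fh.read())
    u = mda.Universe(topology_path, path)
    frames = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
    t = np.array([ts.time for ts in u.trajectory], dtype=float) / 1000.0  # ps -> ns
    if times is None and np.all(np.diff(t) > 0):
        times = t
    return Trajectory(topology=topo, frames=frames, times=times)


def _structure_to_array(s: Structure) -> AtomArray:
    n = s.n_atoms
    arr = AtomArray(n)
    arr.coord = s.coords
    arr.chain_id = np.array([a.chain for a in s.atoms])
    arr.res_id = s.resids
    arr.ins_code = np.array([a.icode for a in s.atoms])
    arr.res_name = np.array([a.resname for a in s.atoms])
    arr.atom_name = np.array([a.name for a in s.atoms])
    arr.element = np.array([a.element for a in s.atoms])
    arr.hetero = np.array([a.hetatm for a in s.atoms])
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms]))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in s.atoms]))
    arr.set_annotation("b_factor", np.array([a.bfactor for a in s.atoms]))
    return arr


def write_pdb(s: Structure) -> str:
    """Serialize a :class:`Structure` to standard fixed-column PDB text."""
    pdb = PDBFile()
    pdb.set_structure(_structure_to_array(s))
    return "\n".join(pdb.lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a :class:`Trajectory` to multi-model PDB text."""
    from biotite.structure import stack as _stack

    template = _structure_to_array(traj.topology)
    arrays = []
    for i in range(traj.n_frames):
        arr = template.copy()
        arr.coord = traj.frames[i]
        arrays.append(arr)
    stack = _stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    return "\n".join(pdb.lines) + "\n"


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def select(
    s: Structure,
    chain: str | None = None,
    resid_range: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
    resnames: set[str] | None = None,
    hetatm: bool | None = None,
) -> Structure:
    """Filter atoms; all given criteria must match.  Order is preserved.

    An empty result is legal (some descriptors tolerate missing residues)
    but is flagged with a warning.
    """
    if s.n_atoms == 0:
        raise ValueError("cannot select from an empty structure")
    out = []
    for a in s.atoms:
        if chain is not None and a.chain != chain:
            continue
        if resid_range is not None and not (resid_range[0] <= a.resid <= resid_range[1]):
            continue
        if atom_names is not None and a.name not in atom_names:
            continue
        if resnames is not None and a.resname not in resnames:
            continue
        if hetatm is not None and a.hetatm != hetatm:
            continue
        out.append(a)
    if not out:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return Structure(out, model_id=s.model_id)


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best matches
    ``ref``; ``R`` is a proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {ref.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    mob_mean = mobile.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = ref - ref_mean
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise GeometryError("points are collinear; rotation is underdetermined")
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ref_mean - R @ mob_mean
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, range (−180, 180].

    Positive angles are clockwise when viewed from ``p2`` toward ``p3``.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points: dihedral undefined")
    b2_hat = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2_hat))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def center_of_mass(
    s: Structure, weighting: str = "mass", atoms: str = "all"
) -> np.ndarray:
    """Weighted mean position (Å) of a structure or selection.

    ``weighting`` is ``"mass"`` or ``"uniform"``; ``atoms`` is ``"all"`` or
    ``"ca_only"`` (Cα atoms only).  Both variants exist because descriptor
    definitions in the literature are often silent on this choice.
    """
    if atoms == "ca_only":
        s = select(s, atom_names={"CA"})
    elif atoms != "all":
        raise ValueError(f"unknown atoms mode {atoms!r}")
    if s.n_atoms == 0:
        raise ValueError("empty selection has no center of mass")
    if weighting == "mass":
        w = s.masses
    elif weighting == "uniform":
        w = np.ones(s.n_atoms)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (s.coords * w[:, None]).sum(axis=0) / w.sum()
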
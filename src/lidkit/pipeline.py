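"""End-to-end orchestration: ENM → descriptors/H-bonds → PCA/κ → states.

The pipeline is a pure function of (inputs, config, seed): rerunning with
identical inputs produces byte-identical summary output.  Each stage
writes its tables (TSV with ``#`` header comments) into the output
directory; a MANIFEST records which stages completed, so partial output
from a failed run is interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enm import ENMParams, build_enm, enm_covariance_map, normal_modes, \
    normalized_mobility, predicted_bfactors
from .io import Structure, Trajectory, load_trajectory, parse_pdb, select
from .lid import DescriptorScheme, LidThresholds, compute_descriptors
from .pca import all_pair_distances, kappa_map, pca
from .traj import AtomSpec, HBondCriterion, hbond_series, rmsf, to_nm

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; see the MANIFEST for completed stages."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    structure_path: str
    output_dir: str
    trajectory_path: str | None = None
    chain: str = "A"
    altloc_policy: str = "first"
    enm: ENMParams = field(default_factory=ENMParams)
    scheme: DescriptorScheme = field(default_factory=DescriptorScheme)
    thresholds: LidThresholds = field(default_factory=LidThresholds)
    hbond_criterion: HBondCriterion = field(default_factory=HBondCriterion)
    hbond_triplets: list = field(default_factory=list)  # [(donor, hydrogen|None, acceptor)]
    pca_mode_index: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "enm" in kwargs:
            kwargs["enm"] = ENMParams(**kwargs["enm"])
        if "scheme" in kwargs:
            kwargs["scheme"] = DescriptorScheme(**kwargs["scheme"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = LidThresholds(**kwargs["thresholds"])
        if "hbond_criterion" in kwargs:
            kwargs["hbond_criterion"] = HBondCriterion(**kwargs["hbond_criterion"])
        if "hbond_triplets" in kwargs:
            kwargs["hbond_triplets"] = [
                tuple(AtomSpec(**a) if a else None for a in trip)
                for trip in kwargs["hbond_triplets"]
            ]
        return cls(**kwargs)


def _write_tsv(path: Path, header: list[str], rows, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# lidkit {__version__}\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6f}"
    return str(x)


def _write_matrix(path: Path, mat: np.ndarray, resids: np.ndarray, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lidkit {__version__}\n# {comment}\n")
        fh.write("resid\t" + "\t".join(str(r) for r in resids) + "\n")
        for r, row in zip(resids, mat):
            fh.write(str(r) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every applicable stage and return the machine-readable summary.

    Stages: structure parsing, ENM profiles, per-frame descriptors and
    H-bond occupancies (when a trajectory is given), PCA with the κ and
    |κ|Δd maps, and a JSON summary echoing the mean ± sd descriptor table
    in nm.  Any stage failure raises :class:`PipelineError` after writing
    the MANIFEST; completed outputs are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {"lidkit_version": __version__, "seed": cfg.seed}

    def _finish(stage: str, exc: Exception) -> PipelineError:
        manifest[stage] = f"failed: {exc}"
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # --- structure ---------------------------------------------------------
    try:
        with open(cfg.structure_path) as fh:
            structure = parse_pdb(fh.read(), altloc_policy=cfg.altloc_policy)
        manifest["structure"] = "ok"
    except Exception as exc:
        raise _finish("structure", exc) from exc

    # --- ENM ---------------------------------------------------------------
    try:
        ca = select(structure, chain=cfg.chain, atom_names={"CA"}, hetatm=False)
        model = build_enm(ca.coords, ca.resids, cfg.enm)
        modes = normal_modes(model)
        b = predicted_bfactors(modes)
        mob = normalized_mobility(modes)
        corr = enm_covariance_map(modes)
        _write_tsv(
            out / "enm_modes.tsv",
            ["mode", "eigenvalue"],
            list(enumerate(modes.eigenvalues)),
            "ENM eigenvalues (ascending; first n_zero are rigid-body)",
        )
        _write_tsv(
            out / "enm_profiles.tsv",
            ["resid", "bfactor", "mobility"],
            zip(ca.resids, b, mob),
            "predicted B-factor (arbitrary scale) and normalized mobility",
        )
        _write_matrix(out / "enm_covariance.tsv", corr, ca.resids, "Cα cross-correlation")
        summary["enm"] = {
            "n_residues": int(ca.n_atoms),
            "n_zero_modes": int(modes.n_zero),
            "mobility_max_resid": int(ca.resids[int(np.argmax(mob))]),
        }
        manifest["enm"] = "ok"
    except Exception as exc:
        raise _finish("enm", exc) from exc

    # --- crystal-structure descriptors ------------------------------------
    try:
        desc = compute_descriptors(structure, cfg.scheme, cfg.thresholds)
        summary["structure_descriptors_nm"] = desc.distances_nm()
        summary["structure_state"] = desc.state
        manifest["descriptors_structure"] = "ok"
    except Exception as exc:
        raise _finish("descriptors_structure", exc) from exc

    # --- trajectory stages -------------------------------------------------
    if cfg.trajectory_path is not None:
        try:
            traj = load_trajectory(cfg.trajectory_path, cfg.structure_path)
            manifest["trajectory"] = "ok"
        except Exception as exc:
            raise _finish("trajectory", exc) from exc

        try:
            rows = []
            per_frame = []
            for f in range(traj.n_frames):
                d = compute_descriptors(traj.frame_structure(f), cfg.scheme, cfg.thresholds)
                per_frame.append(d)
                rows.append(
                    [f]
                    + [
                        d.d_123_140,
                        d.d_124_142,
                        d.d_122_204,
                        d.d_31_153,
                        d.aperture_com,
                        d.chi_f123,
                    ]
                    + [d.state]
                )
            _write_tsv(
                out / "descriptors.tsv",
                ["frame", "d_123_140", "d_124_142", "d_122_204", "d_31_153",
                 "aperture_com", "chi_f123", "state"],
                [[x if x is not None else "nan" for x in row] for row in rows],
                "per-frame lid descriptors (Å, degrees)",
            )
            table = {}
            for name in ("d_123_140", "d_124_142", "d_122_204", "d_31_153", "aperture_com"):
                vals = np.array(
                    [getattr(d, name) for d in per_frame if getattr(d, name) is not None],
                    dtype=float,
                )
                if vals.size:
                    table[name] = {
                        "mean_nm": float(to_nm(vals.mean())),
                        "sd_nm": float(to_nm(vals.std(ddof=1))) if vals.size > 1 else 0.0,
                    }
            summary["trajectory_descriptors_nm"] = table
            states = [d.state for d in per_frame if d.state is not None]
            summary["state_fractions"] = {
                s: states.count(s) / len(states) for s in ("open", "intermediate", "closed")
            } if states else {}
            manifest["descriptors_trajectory"] = "ok"
        except Exception as exc:
            raise _finish("descriptors_trajectory", exc) from exc

        try:
            hb_rows = []
            for trip in cfg.hbond_triplets:
                donor, hydrogen, acceptor = trip
                series = hbond_series(
                    traj, donor, acceptor, hydrogen, cfg.hbond_criterion
                )
                hb_rows.append([series.triplet_label, series.occupancy])
            _write_tsv(
                out / "hbonds.tsv",
                ["triplet", "occupancy"],
                hb_rows,
                "hydrogen-bond occupancies",
            )
            summary["hbond_occupancy"] = {r[0]: r[1] for r in hb_rows}
            manifest["hbonds"] = "ok"
        except Exception as exc:
            raise _finish("hbonds", exc) from exc

        try:
            sel = {"chain": cfg.chain, "atom_names": {"CA"}, "hetatm": False}
            result = pca(traj, selection=sel)
            dists = all_pair_distances(traj, selection=sel)
            km = kappa_map(result, dists, mode_index=cfg.pca_mode_index)
            _write_tsv(
                out / "pca_eigenvalues.tsv",
                ["mode", "eigenvalue_A2"],
                list(enumerate(result.eigenvalues[: min(20, result.eigenvalues.size)])),
                "PCA eigenvalues (descending)",
            )
            _write_tsv(
                out / "pca_projections.tsv",
                ["frame", "pc1", "pc2", "pc3"],
                [
                    [f] + list(result.projections[f, :3])
                    for f in range(result.projections.shape[0])
                ],
                "projections onto the first principal modes (Å)",
            )
            _write_matrix(out / "kappa.tsv", km.kappa, km.resids, "κ map")
            _write_matrix(out / "kappa_weighted.tsv", km.weighted, km.resids, "|κ|Δd map (Å)")
            w = km.weighted.copy()
            summary["pca"] = {
                "eigenvalue_1_A2": float(result.eigenvalues[0]),
                "kappa_weighted_argmax_resids": [
                    int(km.resids[i]) for i in np.unravel_index(np.argmax(w), w.shape)
                ],
            }
            manifest["pca_kappa"] = "ok"
        except Exception as exc:
            raise _finish("pca_kappa", exc) from exc

    manifest["summary"] = "ok"
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
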
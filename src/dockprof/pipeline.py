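"""End-to-end orchestration: read → (align) → matrix → cluster → significance
→ interactions → FI profile, with a machine-readable run manifest.

Every stage writes its outputs under ``output_dir``; the manifest records
input hashes, all parameters (including defaulted ones) and stage timings
so a methods paragraph can be reconstructed from a finished run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    build_cluster_model,
    cluster_fraction,
    pairwise_rmsd_matrix,
    reference_rmsd,
)
from .geometry import align_frames
from .interactions import (
    InteractionParams,
    detect_interactions,
    perceive_frame,
    perceive_ligand,
    records_to_frame,
)
from .io_structures import (
    check_pose_frame_links,
    load_moiety_scheme,
    read_poses,
    read_receptor_frames,
)
from .profiling import (
    build_profile,
    moiety_breakdown,
    plot_residue_totals,
    residue_totals,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``metric`` must be chosen explicitly between ``superposed`` (RMSD after
    optimal rigid-body superposition — pose shape) and ``inplace`` (no
    fitting — pose placement; meaningful once frames share one alignment).
    ``cut_distance``/``n_clusters``: exactly one cluster-cut criterion.
    ``significance``: ``threshold`` applies the mean + 2·SD population rule;
    ``all`` profiles every cluster (small synthetic systems cannot satisfy
    the threshold by construction).
    """

    frames_dir: str
    poses_file: str
    moiety_config: str
    output_dir: str
    metric: str = "superposed"
    cut_distance: float | None = 2.0
    n_clusters: int | None = None
    sd_convention: str = "sample"
    significance: str = "threshold"
    align: bool = False
    reference_frame: str | None = None
    reference_pose: int | None = None  # index into the pose list
    cutoffs: dict = field(default_factory=dict)
    frame_key: str = "frame_id"
    rank_key: str = "rank"
    score_key: str = "score"
    write_matrix: bool = False
    plot: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("frames_dir", "poses_file", "moiety_config"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"config: {name} does not exist: {p}")
        if self.metric not in ("superposed", "inplace"):
            raise PipelineError(f"config: unknown metric {self.metric!r}")
        if (self.cut_distance is None) == (self.n_clusters is None):
            raise PipelineError("config: give exactly one of cut_distance / n_clusters")
        if self.sd_convention not in ("sample", "population"):
            raise PipelineError(f"config: unknown sd_convention {self.sd_convention!r}")
        if self.significance not in ("threshold", "all"):
            raise PipelineError(f"config: unknown significance {self.significance!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the full post-processing pipeline; returns the manifest dict.

    Outputs written to ``config.output_dir``: ``alignment.csv`` (if
    aligning), ``rmsd_matrix.txt`` (optional), ``clusters.csv``,
    ``significance.json``, ``interactions.csv``, ``profile.csv``,
    ``moiety_breakdown.csv``, ``residue_totals.csv``,
    ``reference_rmsd.json`` (if a reference pose is set) and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = InteractionParams().override(**config.cutoffs)
    manifest: dict = {
        "tool": "dockprof",
        "version": __version__,
        "config": asdict(config),
        "cutoffs": params.as_dict(),
        "timings": {},
        "inputs": {},
        "stages": {},
    }
    t_all = time.time()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                log(f"[{name}] ...")
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timings"][name] = round(time.time() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"{name}: {exc}") from exc
                return False

        return _Ctx()

    # --- read ---------------------------------------------------------------
    with stage("read"):
        frame_paths = sorted(Path(config.frames_dir).glob("*.pdb"))
        if not frame_paths:
            raise PipelineError(f"read: no PDB files in {config.frames_dir}")
        frames = read_receptor_frames(frame_paths)
        poses = read_poses(config.poses_file, frame_key=config.frame_key,
                           rank_key=config.rank_key, score_key=config.score_key)
        check_pose_frame_links(poses, frames)
        scheme = load_moiety_scheme(config.moiety_config, poses[0])
        manifest["inputs"] = {
            "n_frames": len(frames),
            "n_poses": len(poses),
            "ligand": poses[0].ligand_name,
            "moieties": scheme.labels,
            "poses_sha256": _sha256(Path(config.poses_file)),
            "moiety_config_sha256": _sha256(Path(config.moiety_config)),
        }
        log(f"[read] {len(frames)} frames, {len(poses)} poses")

    # --- align (optional) ---------------------------------------------------
    if config.align:
        with stage("align"):
            ref_id = config.reference_frame or frames[0].frame_id
            ref = next((f for f in frames if f.frame_id == ref_id), None)
            if ref is None:
                raise PipelineError(f"align: unknown reference frame {ref_id!r}")
            _, report = align_frames(frames, ref)
            pd.DataFrame(report).to_csv(out / "alignment.csv", index=False)
            manifest["stages"]["align"] = {"reference_frame": ref_id,
                                           "n_aligned": len(report)}

    # --- RMSD matrix + clustering + significance ----------------------------
    with stage("cluster"):
        matrix = pairwise_rmsd_matrix(poses, metric=config.metric)
        if config.write_matrix:
            matrix.to_text(out / "rmsd_matrix.txt")
        model = build_cluster_model(
            matrix,
            cut_distance=config.cut_distance,
            n_clusters=config.n_clusters,
            sd_convention=config.sd_convention,
            significance=config.significance,
        )
        frac = cluster_fraction(model, len(poses))
        rows = [
            {"pose_id": pid, "cluster": c, "population": model.populations[c],
             "significant": c in model.significant}
            for pid, c in model.assignment.items()
        ]
        pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
        sig = {
            "n_poses": len(poses),
            "n_clusters": len(model.populations),
            "populations": {str(k): v for k, v in sorted(model.populations.items())},
            "mean_pop": model.mean_pop,
            "sd_pop": model.sd_pop,
            "sd_convention": model.sd_convention,
            "threshold": model.threshold,
            "significant": sorted(model.significant),
            "scp": {str(k): v for k, v in model.scp.items()},
            "tpsc": model.tpsc,
            "significant_fraction": frac,
            "metric": config.metric,
            "cut_distance": config.cut_distance,
            "n_clusters_requested": config.n_clusters,
        }
        with open(out / "significance.json", "w") as fh:
            json.dump(sig, fh, indent=1, sort_keys=True)
        manifest["stages"]["cluster"] = {
            "n_clusters": len(model.populations),
            "significant": sorted(model.significant),
            "tpsc": model.tpsc,
            "significant_fraction": frac,
        }
        log(f"[cluster] {len(model.populations)} clusters, "
            f"{len(model.significant)} significant (TPSC={model.tpsc}, "
            f"fraction={frac:.3f})")

    # --- reference RMSD (optional) ------------------------------------------
    if config.reference_pose is not None:
        with stage("reference_rmsd"):
            ref_pose = poses[config.reference_pose]
            per_cluster = {}
            for c in sorted(model.significant):
                members = [p for p in poses if model.assignment[p.pose_id] == c]
                mean, sd, _ = reference_rmsd(members, ref_pose, metric=config.metric)
                per_cluster[str(c)] = {"mean": round(mean, 4), "sd": round(sd, 4),
                                       "n": len(members)}
            with open(out / "reference_rmsd.json", "w") as fh:
                json.dump({"reference_pose": ref_pose.pose_id,
                           "metric": config.metric,
                           "clusters": per_cluster}, fh, indent=1, sort_keys=True)
            manifest["stages"]["reference_rmsd"] = per_cluster

    # --- interactions -------------------------------------------------------
    with stage("interactions"):
        if model.tpsc == 0:
            raise PipelineError(
                "interactions: no significant clusters — nothing to profile "
                "(rerun with significance: all to profile every cluster)"
            )
        frames_by = {f.frame_id: f for f in frames}
        frame_chem = {}
        lig_chem = perceive_ligand(poses[0])
        records = []
        sig_poses = [p for p in poses if model.assignment[p.pose_id] in model.significant]
        for pose in sig_poses:
            if pose.frame_id not in frame_chem:
                frame_chem[pose.frame_id] = perceive_frame(frames_by[pose.frame_id])
            records.extend(
                detect_interactions(pose, frames_by[pose.frame_id], scheme, params,
                                    ligand_chem=lig_chem,
                                    frame_chem=frame_chem[pose.frame_id])
            )
        records_to_frame(records).to_csv(out / "interactions.csv", index=False)
        manifest["stages"]["interactions"] = {
            "n_records": len(records),
            "n_poses_profiled": len(sig_poses),
        }
        log(f"[interactions] {len(records)} records over {len(sig_poses)} poses")

    # --- FI profile ---------------------------------------------------------
    with stage("profile"):
        profile = build_profile(records, model, metadata={
            "metric": config.metric,
            "cut_distance": config.cut_distance,
            "n_clusters": config.n_clusters,
            "sd_convention": config.sd_convention,
            "significance": config.significance,
            "cutoffs": params.as_dict(),
        })
        profile.to_frame().to_csv(out / "profile.csv", index=False)
        totals = residue_totals(profile)
        totals.to_csv(out / "residue_totals.csv", index=False)
        breakdown = moiety_breakdown(profile)
        breakdown.to_csv(out / "moiety_breakdown.csv")
        if config.plot and len(totals):
            plot_residue_totals(totals, out / "residue_totals.png")
        manifest["stages"]["profile"] = {
            "n_rows": len(profile.rows),
            "n_residues": len(totals),
            "top_residues": totals.head(5)["residue"].tolist(),
        }
        log(f"[profile] {len(profile.rows)} rows, top residues: "
            f"{', '.join(totals.head(5)['residue'])}")

    manifest["timings"]["total"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
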
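"""Pose clustering and significant-cluster selection.

Docked poses of one ligand are clustered on their pairwise heavy-atom RMSD
matrix with unweighted average linkage (UPGMA on the distance matrix).
Clusters whose population exceeds the mean cluster population by more than
twice the standard deviation,

    threshold = x_bar + 2 * delta,

are flagged *significant* and carried forward to interaction profiling;
SCP is a significant cluster's population and TPSC the total population
over all significant clusters.

Note that with very few clusters no population can exceed x_bar + 2*delta:
for k clusters the largest attainable z-score is (k-1)/sqrt(k) under the
sample-SD convention (sqrt(k-1) under population SD), so at least 6
(resp. 5) clusters are needed before any cluster can be significant at
all. Small synthetic systems therefore use the ``significance="all"``
escape hatch; see :func:`build_cluster_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import (
    inplace_rmsd,
    kabsch_superpose,
    pairwise_inplace_rmsd,
    pairwise_superposed_rmsd,
)
from .io_structures import LigandPose

__all__ = [
    "RmsdMatrix",
    "ClusterModel",
    "pairwise_rmsd_matrix",
    "average_linkage_cluster",
    "significant_clusters",
    "build_cluster_model",
    "cluster_fraction",
    "reference_rmsd",
]

Metric = Literal["superposed", "inplace"]


@dataclass
class RmsdMatrix:
    """Symmetric pairwise RMSD matrix over an ordered pose-id list."""

    pose_ids: list[str]
    values: np.ndarray
    metric: str = "superposed"

    def validate(self, tol: float = 1e-9) -> None:
        v = self.values
        if v.shape != (len(self.pose_ids), len(self.pose_ids)):
            raise ValueError("matrix shape does not match pose count")
        if not np.all(np.isfinite(v)):
            raise ValueError("RMSD matrix contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("RMSD matrix contains negative entries")
        if np.max(np.abs(np.diagonal(v))) > tol:
            raise ValueError("RMSD matrix diagonal is not zero")
        if np.max(np.abs(v - v.T)) > tol:
            raise ValueError("RMSD matrix is not symmetric")

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.pose_ids) + "\n")
            for row in self.values:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_text(cls, path, metric: str = "superposed") -> "RmsdMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split("\t")
            values = np.loadtxt(fh)
        m = cls(pose_ids=ids, values=np.atleast_2d(values), metric=metric)
        m.validate(tol=1e-6)
        return m


@dataclass
class ClusterModel:
    """Cluster assignment, populations and the significance report.

    Labels are 1-based and sorted by descending population (label 1 is the
    most populated cluster; ties broken by first-seen pose order).
    """

    assignment: dict[str, int]
    populations: dict[int, int]
    mean_pop: float = 0.0
    sd_pop: float = 0.0
    threshold: float = 0.0
    significant: set[int] = field(default_factory=set)
    scp: dict[int, int] = field(default_factory=dict)
    tpsc: int = 0
    sd_convention: str = "sample"
    metadata: dict = field(default_factory=dict)

    @property
    def n_poses(self) -> int:
        return len(self.assignment)

    def members(self, label: int) -> list[str]:
        return [p for p, c in self.assignment.items() if c == label]

    def validate(self) -> None:
        if sum(self.populations.values()) != len(self.assignment):
            raise ValueError("cluster populations do not sum to pose count")
        expected = self.mean_pop + 2.0 * self.sd_pop
        if abs(self.threshold - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError("threshold != mean + 2*sd")
        if self.significant != {c for c, n in self.populations.items() if n > self.threshold}:
            raise ValueError("significant set inconsistent with threshold")
        if self.tpsc != sum(self.scp.values()):
            raise ValueError("TPSC != sum of SCP")


def pairwise_rmsd_matrix(poses: Sequence[LigandPose], metric: Metric = "superposed") -> RmsdMatrix:
    """Heavy-atom pairwise RMSD matrix over all poses of one ligand."""
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    names = {p.ligand_name for p in poses}
    if len(names) > 1:
        raise ValueError(f"poses mix ligands: {sorted(names)}")
    coords = np.stack([p.heavy_coords() for p in poses])
    if metric == "superposed":
        values = pairwise_superposed_rmsd(coords)
    elif metric == "inplace":
        values = pairwise_inplace_rmsd(coords)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = RmsdMatrix(pose_ids=[p.pose_id for p in poses], values=values, metric=metric)
    m.validate(tol=1e-9)
    return m


def _relabel_by_population(pose_ids: list[str], raw: np.ndarray) -> tuple[dict[str, int], dict[int, int]]:
    """1-based labels in descending-population order, ties by first-seen pose."""
    first_seen: dict[int, int] = {}
    counts: dict[int, int] = {}
    for i, lab in enumerate(raw):
        lab = int(lab)
        counts[lab] = counts.get(lab, 0) + 1
        first_seen.setdefault(lab, i)
    order = sorted(counts, key=lambda c: (-counts[c], first_seen[c]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    assignment = {pid: remap[int(lab)] for pid, lab in zip(pose_ids, raw)}
    populations = {remap[c]: n for c, n in counts.items()}
    return assignment, populations


def average_linkage_cluster(matrix: RmsdMatrix, *, cut_distance: float | None = None,
                            n_clusters: int | None = None) -> ClusterModel:
    """Agglomerative clustering with unweighted average linkage.

    Exactly one of ``cut_distance`` (merge-distance threshold, Å) or
    ``n_clusters`` must be given. Returns a :class:`ClusterModel` with
    assignment and populations only; apply :func:`significant_clusters`
    (or use :func:`build_cluster_model`) to fill the significance report.
    """
    matrix.validate(tol=1e-6)
    if (cut_distance is None) == (n_clusters is None):
        raise ValueError("give exactly one of cut_distance or n_clusters")
    n = len(matrix.pose_ids)
    if n == 1:
        raw = np.array([1])
    else:
        Z = linkage(squareform(matrix.values, checks=False), method="average")
        if cut_distance is not None:
            raw = fcluster(Z, t=float(cut_distance), criterion="distance")
        else:
            k = int(n_clusters)
            if not 1 <= k <= n:
                raise ValueError(f"n_clusters must be in [1, {n}]")
            raw = fcluster(Z, t=k, criterion="maxclust")
    assignment, populations = _relabel_by_population(matrix.pose_ids, raw)
    model = ClusterModel(assignment=assignment, populations=populations)
    model.metadata = {
        "metric": matrix.metric,
        "linkage": "average",
        "cut_distance": cut_distance,
        "n_clusters": n_clusters,
    }
    return model


def significant_clusters(populations: dict[int, int],
                         sd_convention: str = "sample") -> dict:
    """Population-threshold significance report: threshold = mean + 2 * SD.

    ``sd_convention`` is ``"sample"`` (n-1 denominator, the default) or
    ``"population"`` (n denominator). A single cluster has SD defined as 0
    and is never significant (the inequality is strict). Returns a dict
    with ``mean_pop``, ``sd_pop``, ``threshold``, ``significant`` (set of
    labels), ``scp`` and ``tpsc``.
    """
    if not populations:
        raise ValueError("empty population map")
    vals = np.array(list(populations.values()), dtype=float)
    mean = float(vals.mean())
    if len(vals) == 1:
        sd = 0.0
    elif sd_convention == "sample":
        sd = float(vals.std(ddof=1))
    elif sd_convention == "population":
        sd = float(vals.std(ddof=0))
    else:
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    threshold = mean + 2.0 * sd
    significant = {c for c, p in populations.items() if p > threshold}
    scp = {c: populations[c] for c in sorted(significant)}
    return {
        "mean_pop": mean,
        "sd_pop": sd,
        "threshold": threshold,
        "significant": significant,
        "scp": scp,
        "tpsc": sum(scp.values()),
        "sd_convention": sd_convention,
    }


def build_cluster_model(matrix: RmsdMatrix, *, cut_distance: float | None = None,
                        n_clusters: int | None = None,
                        sd_convention: str = "sample",
                        significance: str = "threshold") -> ClusterModel:
    """Cluster and fill the significance report in one step.

    ``significance="threshold"`` applies the population threshold
    mean + 2*SD; ``significance="all"`` declares every cluster significant
    (every cluster profiled, FI weighted by plain population share) —
    intended for small synthetic systems where the threshold is
    unattainable by construction (see module docstring).
    """
    model = average_linkage_cluster(matrix, cut_distance=cut_distance, n_clusters=n_clusters)
    if significance == "threshold":
        rep = significant_clusters(model.populations, sd_convention=sd_convention)
    elif significance == "all":
        rep = significant_clusters(model.populations, sd_convention=sd_convention)
        rep["significant"] = set(model.populations)
        rep["scp"] = dict(sorted(model.populations.items()))
        rep["tpsc"] = sum(model.populations.values())
    else:
        raise ValueError(f"unknown significance mode {significance!r}")
    model.mean_pop = rep["mean_pop"]
    model.sd_pop = rep["sd_pop"]
    model.threshold = rep["mean_pop"] + 2.0 * rep["sd_pop"]
    model.significant = rep["significant"]
    model.scp = rep["scp"]
    model.tpsc = rep["tpsc"]
    model.sd_convention = sd_convention
    model.metadata["sd_convention"] = sd_convention
    model.metadata["significance"] = significance
    if significance == "threshold":
        model.validate()
    return model


def cluster_fraction(model: ClusterModel, total_poses: int) -> float:
    """Fraction of all docked poses captured by the significant clusters."""
    if total_poses == 0:
        raise ValueError("total_poses is zero")
    if total_poses < model.tpsc:
        raise ValueError("total_poses smaller than TPSC")
    return model.tpsc / total_poses


def reference_rmsd(cluster_poses: Sequence[LigandPose], reference: LigandPose,
                   metric: Metric = "superposed") -> tuple[float, float, list[float]]:
    """Per-pose RMSD of a cluster against a reference pose (e.g. a crystal pose).

    Returns ``(mean, sample SD, per-pose list)`` — the "mean ± SD Å"
    headline number quoted for a cluster's fidelity to a known binding
    mode. SD is 0 for a single pose.
    """
    if not cluster_poses:
        raise ValueError("empty cluster")
    ref = reference.heavy_coords()
    vals: list[float] = []
    for pose in cluster_poses:
        pc = pose.heavy_coords()
        if pc.shape != ref.shape or pose.elements != reference.elements:
            raise ValueError(
                f"pose {pose.pose_id} does not share atom correspondence with reference"
            )
        if metric == "superposed":
            _, r = kabsch_superpose(pc, ref)
        elif metric == "inplace":
            r = inplace_rmsd(pc, ref)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        vals.append(r)
    arr = np.array(vals)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd, vals
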
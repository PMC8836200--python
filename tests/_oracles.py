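"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the superposition
oracle minimises RMSD numerically over rigid transforms, the clustering
oracle re-derives average-linkage agglomeration from the raw distance
matrix at every merge, and the population-threshold oracle uses the
standard-library statistics module.
"""

from __future__ import annotations

import statistics

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rmsd_after_transform(params: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    rot = Rotation.from_rotvec(params[:3])
    moved = rot.apply(A) + params[3:]
    return float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))


def min_rmsd_numeric(A: np.ndarray, B: np.ndarray, n_starts: int = 6,
                     seed: int = 0) -> float:
    """Global minimum RMSD over rigid transforms by multi-start minimisation.

    The optimal translation for any rotation aligns the centroids, so the
    search runs over the 3-parameter rotation vector only, on the smooth
    mean-squared objective; the minimum over several random starts is the
    global one for this small, well-behaved landscape.
    """
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)

    def msd(rv):
        moved = Rotation.from_rotvec(rv).apply(A0)
        return float(np.mean(np.sum((moved - B0) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(3)] + [Rotation.random(random_state=rng).as_rotvec()
                              for _ in range(n_starts - 1)]
    best = np.inf
    for rv in starts:
        res = minimize(msd, rv, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 2000})
        best = min(best, res.fun)
    return float(np.sqrt(max(best, 0.0)))


def upgma_partitions(D: np.ndarray) -> list[list[set[int]]]:
    """Brute-force average-linkage agglomeration.

    Returns the list of partitions (as sets of frozen index sets) after
    each merge, starting from singletons. Average inter-cluster distance is
    recomputed from the raw matrix at every step; equal-distance merges
    take the lexicographically smallest cluster pair.
    """
    n = D.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    partitions = [[set(c) for c in clusters]]
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(np.mean([D[a, b] for a in clusters[i] for b in clusters[j]]))
                key = (min(clusters[i]), min(clusters[j]))
                if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and
                                          (best is None or key < best[2])):
                    best = (i, j, key)
                    best_d = d
        i, j, _ = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
        partitions.append([set(c) for c in clusters])
    return partitions


def significance_report_oracle(pops: list[int], sample_sd: bool = True) -> dict:
    """Population-threshold significance by direct formula (statistics module)."""
    mean = statistics.fmean(pops)
    if len(pops) == 1:
        sd = 0.0
    elif sample_sd:
        sd = statistics.stdev(pops)
    else:
        sd = statistics.pstdev(pops)
    threshold = mean + 2.0 * sd
    significant = {i for i, p in enumerate(pops) if p > threshold}
    return {"mean": mean, "sd": sd, "threshold": threshold, "significant": significant}


def partition_of(assignment: dict, pose_ids: list[str]) -> set[frozenset]:
    """Canonical label-free partition induced by an assignment map."""
    groups: dict[int, set] = {}
    for pid in pose_ids:
        groups.setdefault(assignment[pid], set()).add(pid)
    return {frozenset(g) for g in groups.values()}
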
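import numpy as np
import pytest
from hypothesis import given, strategies as st

from dockprof.clustering import (
    RmsdMatrix,
    average_linkage_cluster,
    build_cluster_model,
    cluster_fraction,
    pairwise_rmsd_matrix,
    reference_rmsd,
    significant_clusters,
)
from dockprof.geometry import inplace_rmsd, kabsch_superpose

from _oracles import partition_of, significance_report_oracle, upgma_partitions
from conftest import make_pose


def random_matrix(rng, n):
    d = rng.uniform(0.1, 10.0, size=(n, n))
    d = np.triu(d, 1)
    d = d + d.T
    return RmsdMatrix(pose_ids=[f"p{i}" for i in range(n)], values=d)


# ---------------------------------------------------------------------------
# RMSD matrix
# ---------------------------------------------------------------------------

def test_matrix_identical_poses_is_zero(toy_ligand):
    p1 = make_pose(toy_ligand.coords, "a")
    p2 = make_pose(toy_ligand.coords, "b")
    m = pairwise_rmsd_matrix([p1, p2], metric="superposed")
    assert np.allclose(m.values, 0.0, atol=1e-9)


def test_matrix_metric_semantics(toy_ligand):
    """A translated copy is distance 0 under superposition but the
    translation norm in place."""
    base = toy_ligand.coords
    shifted = base + np.array([3.0, 4.0, 0.0])
    rng = np.random.default_rng(0)
    other = base + rng.normal(scale=1.0, size=base.shape)
    poses = [make_pose(base, "p1"), make_pose(other, "p2"), make_pose(shifted, "p3")]
    sup = pairwise_rmsd_matrix(poses, metric="superposed")
    inp = pairwise_rmsd_matrix(poses, metric="inplace")
    assert sup.values[0, 2] == pytest.approx(0.0, abs=1e-6)
    assert inp.values[0, 2] == pytest.approx(5.0, abs=1e-9)


def test_matrix_equals_elementwise_geometry(toy_ligand):
    rng = np.random.default_rng(1)
    poses = [make_pose(toy_ligand.coords + rng.normal(scale=2.0, size=(20, 3)), f"p{i}")
             for i in range(10)]
    sup = pairwise_rmsd_matrix(poses, metric="superposed")
    inp = pairwise_rmsd_matrix(poses, metric="inplace")
    for i in range(10):
        for j in range(i + 1, 10):
            a, b = poses[i].heavy_coords(), poses[j].heavy_coords()
            assert sup.values[i, j] == pytest.approx(kabsch_superpose(a, b)[1], abs=1e-9)
            assert inp.values[i, j] == pytest.approx(inplace_rmsd(a, b), abs=1e-9)


def test_matrix_rejects_mixed_ligands(toy_ligand):
    p1 = make_pose(toy_ligand.coords, "a")
    p2 = make_pose(toy_ligand.coords, "b")
    p2.ligand_name = "other"
    with pytest.raises(ValueError, match="mix"):
        pairwise_rmsd_matrix([p1, p2])


def test_matrix_text_round_trip(tmp_path, toy_ligand):
    rng = np.random.default_rng(2)
    poses = [make_pose(toy_ligand.coords + rng.normal(size=(20, 3)), f"p{i}")
             for i in range(4)]
    m = pairwise_rmsd_matrix(poses)
    path = tmp_path / "matrix.txt"
    m.to_text(path)
    m2 = RmsdMatrix.from_text(path)
    assert m2.pose_ids == m.pose_ids
    assert np.allclose(m2.values, m.values, atol=1e-6)


# ---------------------------------------------------------------------------
# Average linkage
# ---------------------------------------------------------------------------

def test_well_separated_bundles_recovered():
    rng = np.random.default_rng(3)
    n1, n2 = 6, 4
    d = np.zeros((n1 + n2, n1 + n2))
    for i in range(n1 + n2):
        for j in range(i + 1, n1 + n2):
            same = (i < n1) == (j < n1)
            d[i, j] = d[j, i] = rng.uniform(0.1, 0.5) if same else rng.uniform(8, 10)
    m = RmsdMatrix(pose_ids=[f"p{i}" for i in range(n1 + n2)], values=d)
    model = average_linkage_cluster(m, cut_distance=2.0)
    assert model.populations == {1: 6, 2: 4}
    # label 1 must be the most populated cluster
    lab1 = {p for p, c in model.assignment.items() if c == 1}
    assert lab1 == {f"p{i}" for i in range(n1)}


def test_singleton_cut():
    rng = np.random.default_rng(4)
    m = random_matrix(rng, 6)
    model = average_linkage_cluster(m, n_clusters=6)
    assert model.populations == {i: 1 for i in range(1, 7)}


def test_exactly_one_cut_criterion():
    rng = np.random.default_rng(5)
    m = random_matrix(rng, 4)
    with pytest.raises(ValueError):
        average_linkage_cluster(m)
    with pytest.raises(ValueError):
        average_linkage_cluster(m, cut_distance=1.0, n_clusters=2)


@given(st.integers(0, 60))
def test_average_linkage_matches_bruteforce_oracle(seed):
    """Partitions equal a from-scratch agglomeration oracle at every cut level."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    m = random_matrix(rng, n)
    oracle_parts = upgma_partitions(m.values)
    for partition in oracle_parts:
        k = len(partition)
        model = average_linkage_cluster(m, n_clusters=k)
        got = partition_of(model.assignment, m.pose_ids)
        want = {frozenset(m.pose_ids[i] for i in c) for c in partition}
        assert got == want


@given(st.integers(0, 40))
def test_partition_invariant_to_pose_order(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    m = random_matrix(rng, n)
    perm = rng.permutation(n)
    m2 = RmsdMatrix(pose_ids=[m.pose_ids[i] for i in perm],
                    values=m.values[np.ix_(perm, perm)])
    for k in range(1, n + 1):
        p1 = partition_of(average_linkage_cluster(m, n_clusters=k).assignment, m.pose_ids)
        p2 = partition_of(average_linkage_cluster(m2, n_clusters=k).assignment, m2.pose_ids)
        assert p1 == p2


def test_zero_distance_duplicate_joins_cluster():
    """A pose at distance 0 from an existing pose always lands in its cluster."""
    rng = np.random.default_rng(7)
    m = random_matrix(rng, 5)
    n = 5
    ext = np.zeros((n + 1, n + 1))
    ext[:n, :n] = m.values
    ext[n, :n] = m.values[0, :]  # duplicate of pose 0
    ext[:n, n] = m.values[0, :]
    m2 = RmsdMatrix(pose_ids=m.pose_ids + ["dup"], values=ext)
    for k in range(1, n + 1):
        model = average_linkage_cluster(m2, n_clusters=k)
        assert model.assignment["dup"] == model.assignment["p0"]


# ---------------------------------------------------------------------------
# Significance (population threshold)
# ---------------------------------------------------------------------------

def test_uniform_populations_never_significant():
    rep = significant_clusters({1: 7, 2: 7, 3: 7, 4: 7})
    assert rep["sd_pop"] == 0.0
    assert rep["threshold"] == 7.0
    assert rep["significant"] == set()
    assert rep["tpsc"] == 0


def test_single_cluster_not_significant():
    rep = significant_clusters({1: 50})
    assert rep["sd_pop"] == 0.0
    assert rep["significant"] == set()


def test_significance_matches_direct_formula():
    pops = [1] * 20 + [60]
    labels = {i + 1: p for i, p in enumerate(pops)}
    rep = significant_clusters(labels)
    oracle = significance_report_oracle(pops)
    assert rep["mean_pop"] == pytest.approx(oracle["mean"], abs=1e-12)
    assert rep["sd_pop"] == pytest.approx(oracle["sd"], abs=1e-12)
    assert rep["threshold"] == pytest.approx(oracle["threshold"], abs=1e-12)
    assert rep["significant"] == {i + 1 for i in oracle["significant"]}
    assert rep["scp"] == {21: 60}
    assert rep["tpsc"] == 60


def test_population_sd_convention():
    pops = {1: 2, 2: 4, 3: 30}
    rep = significant_clusters(pops, sd_convention="population")
    oracle = significance_report_oracle([2, 4, 30], sample_sd=False)
    assert rep["sd_pop"] == pytest.approx(oracle["sd"], abs=1e-12)


@given(st.integers(0, 300))
def test_significance_random_vectors_match_oracle(seed):
    rng = np.random.default_rng(seed)
    pops = rng.integers(1, 200, size=int(rng.integers(1, 30))).tolist()
    rep = significant_clusters({i + 1: p for i, p in enumerate(pops)})
    oracle = significance_report_oracle(pops)
    assert rep["threshold"] == pytest.approx(oracle["threshold"], rel=1e-12)
    assert rep["significant"] == {i + 1 for i in oracle["significant"]}


@given(st.integers(0, 100))
def test_threshold_scaling_invariance(seed):
    """Doubling all populations doubles x̄, δ and the threshold and leaves
    the significant set unchanged."""
    rng = np.random.default_rng(seed)
    pops = {i + 1: int(p) for i, p in
            enumerate(rng.integers(1, 500, size=int(rng.integers(2, 25))))}
    rep = significant_clusters(pops)
    scaled = significant_clusters({c: 2 * p for c, p in pops.items()})
    assert scaled["mean_pop"] == 2 * rep["mean_pop"]
    assert scaled["sd_pop"] == 2 * rep["sd_pop"]
    assert scaled["threshold"] == 2 * rep["threshold"]
    assert scaled["significant"] == rep["significant"]


def test_small_cluster_counts_cannot_be_significant():
    """With k <= 5 clusters the max z-score (k-1)/sqrt(k) < 2: the threshold
    is unattainable whatever the populations."""
    rng = np.random.default_rng(8)
    for _ in range(200):
        k = int(rng.integers(1, 6))
        pops = {i + 1: int(p) for i, p in enumerate(rng.integers(1, 1000, size=k))}
        assert significant_clusters(pops)["significant"] == set()


# ---------------------------------------------------------------------------
# Fractions and reference RMSD
# ---------------------------------------------------------------------------

def test_cluster_fraction_arithmetic():
    from dockprof.clustering import ClusterModel

    model = ClusterModel(assignment={}, populations={}, tpsc=370)
    assert cluster_fraction(model, 1000) == pytest.approx(0.37)
    model.tpsc = 0
    assert cluster_fraction(model, 1000) == 0.0
    model.tpsc = 10
    assert cluster_fraction(model, 10) == 1.0
    with pytest.raises(ValueError):
        cluster_fraction(model, 0)


def test_reference_rmsd_identical_copies(toy_ligand):
    ref = make_pose(toy_ligand.coords, "ref")
    cluster = [make_pose(toy_ligand.coords, f"c{i}") for i in range(4)]
    mean, sd, per = reference_rmsd(cluster, ref, metric="inplace")
    assert mean == pytest.approx(0.0, abs=1e-12)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_reference_rmsd_hand_computed_sd(toy_ligand):
    """Two poses at in-place RMSD 1.0 and 3.0: mean 2.0, sample SD sqrt(2)."""
    n = len(toy_ligand.coords)
    ref = make_pose(toy_ligand.coords, "ref")
    p1 = make_pose(toy_ligand.coords + np.array([1.0, 0, 0]), "p1")
    p2 = make_pose(toy_ligand.coords + np.array([3.0, 0, 0]), "p2")
    mean, sd, per = reference_rmsd([p1, p2], ref, metric="inplace")
    assert per == pytest.approx([1.0, 3.0], abs=1e-12)
    assert mean == pytest.approx(2.0, abs=1e-12)
    assert sd == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_reference_rmsd_matches_geometry_recomputation(toy_ligand):
    rng = np.random.default_rng(9)
    ref = make_pose(toy_ligand.coords, "ref")
    cluster = [make_pose(toy_ligand.coords + rng.normal(scale=0.5, size=(20, 3)), f"c{i}")
               for i in range(5)]
    _, _, per = reference_rmsd(cluster, ref, metric="superposed")
    for pose, r in zip(cluster, per):
        assert r == pytest.approx(
            kabsch_superpose(pose.heavy_coords(), ref.heavy_coords())[1], abs=1e-9)


def test_reference_rmsd_correspondence_mismatch(toy_ligand):
    ref = make_pose(toy_ligand.coords, "ref")
    bad = make_pose(toy_ligand.coords, "bad")
    bad.elements = list(bad.elements)
    bad.elements[0] = "N"
    with pytest.raises(ValueError, match="correspondence"):
        reference_rmsd([bad], ref)


# ---------------------------------------------------------------------------
# build_cluster_model
# ---------------------------------------------------------------------------

def test_build_cluster_model_consistency():
    rng = np.random.default_rng(10)
    m = random_matrix(rng, 8)
    model = build_cluster_model(m, n_clusters=3)
    model.validate()
    assert model.threshold == pytest.approx(model.mean_pop + 2 * model.sd_pop)


def test_build_cluster_model_all_mode():
    rng = np.random.default_rng(11)
    m = random_matrix(rng, 8)
    model = build_cluster_model(m, n_clusters=3, significance="all")
    assert model.significant == set(model.populations)
    assert model.tpsc == 8
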
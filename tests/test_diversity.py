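"""Fingerprints, Tanimoto, PAM k-medoids vs exhaustive search, selection rule."""

import itertools

import numpy as np
import pytest

from conftest import random_distance_matrix
from vstriage.diversity_picker import (
    Clustering,
    FingerprintVector,
    fingerprint,
    kmedoids,
    select_purchase_set,
    tanimoto,
    tanimoto_distance_matrix,
)


def fpv(bits, nbits=64):
    return FingerprintVector("x", frozenset(bits), 2, nbits)


def test_fingerprint_canonical_invariance(rec):
    a = fingerprint(rec("c1ccccc1"))
    b = fingerprint(rec("C1=CC=CC=C1"))
    assert a.bits == b.bits


def test_fingerprint_radius0_shared_environment(rec):
    ethanol = fingerprint(rec("CCO"), radius=0)
    ethane = fingerprint(rec("CC"), radius=0)
    assert ethanol.bits & ethane.bits  # both contain a plain sp3 carbon


def test_fingerprint_methane_radius0(rec):
    assert len(fingerprint(rec("C"), radius=0).bits) == 1


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4}, 0.5),
        (set(), set(), 1.0),
    ],
)
def test_tanimoto_values(a, b, expected):
    assert tanimoto(fpv(a), fpv(b)) == pytest.approx(expected)


def test_tanimoto_nbits_mismatch():
    with pytest.raises(ValueError):
        tanimoto(fpv({1}), fpv({1}, nbits=128))


def test_distance_matrix_consistent_with_pairwise(rec):
    fps = [fingerprint(rec(s)) for s in ["CCO", "CCN", "c1ccccc1", "CC(=O)O"]]
    D = tanimoto_distance_matrix(fps)
    for i, j in itertools.combinations(range(4), 2):
        assert D[i, j] == pytest.approx(1.0 - tanimoto(fps[i], fps[j]))
    assert np.allclose(np.diag(D), 0)


def brute_force_kmedoids(D, k):
    n = D.shape[0]
    best = min(itertools.combinations(range(n), k),
               key=lambda m: D[:, m].min(axis=1).sum())
    return D[:, best].min(axis=1).sum()


def test_two_tight_groups():
    from scipy.spatial.distance import pdist, squareform

    pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
    D = squareform(pdist(pts))
    c = kmedoids(D, 2, seed=3)
    assert {c.assignment[i] for i in range(3)} != {c.assignment[i] for i in range(3, 6)}
    assert c.cost == pytest.approx(brute_force_kmedoids(D, 2))


def test_k_equals_n_zero_cost():
    D = random_distance_matrix(np.random.default_rng(0), 7)
    c = kmedoids(D, 7)
    assert c.cost == 0.0 and sorted(c.medoids) == list(range(7))


def test_pam_terminates_at_certified_local_optimum():
    """PAM's contract: no single medoid/non-medoid swap can lower the cost
    of its output, k = 1 is exactly optimal, and cost never increases."""
    rng = np.random.default_rng(12)
    for trial in range(50):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(1, 4))
        D = random_distance_matrix(rng, n)
        c = kmedoids(D, k, seed=trial)
        assert all(a >= b - 1e-12 for a, b in zip(c.cost_history, c.cost_history[1:]))
        if k == 1:
            assert c.cost == pytest.approx(brute_force_kmedoids(D, 1), abs=1e-12)
        med = list(c.medoids)
        for i in range(k):
            for j in range(n):
                if j in med:
                    continue
                swapped = med[:i] + [j] + med[i + 1:]
                assert D[:, swapped].min(axis=1).sum() >= c.cost - 1e-12


def test_pam_agrees_with_reference_implementation(tmp_path):
    """Dual-route check: the BUILD+SWAP trajectory lands on the same medoid
    set and cost as the Kaufman-Rousseeuw reference (R cluster::pam) on
    random instances with distinct distances (no tie ambiguity)."""
    import subprocess

    rng = np.random.default_rng(31)
    cases = []
    for trial in range(8):
        n = int(rng.integers(5, 12))
        k = int(rng.integers(2, 4))
        D = random_distance_matrix(rng, n)
        np.savetxt(tmp_path / f"d{trial}.txt", D)
        cases.append((n, k, D))
    script = tmp_path / "pam.R"
    script.write_text(
        "library(cluster)\n"
        "args <- commandArgs(trailingOnly=TRUE)\n"
        f"for (t in 0:{len(cases) - 1}) {{\n"
        f"  D <- as.matrix(read.table(file.path('{tmp_path}', paste0('d', t, '.txt'))))\n"
        "  k <- as.integer(args[t + 1])\n"
        "  p <- pam(as.dist(D), k, diss=TRUE)\n"
        "  cat(t, paste(sort(p$id.med - 1), collapse=','), "
        "nrow(D) * tail(p$objective, 1), '\\n')\n"
        "}\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)] + [str(k) for _, k, _ in cases],
        capture_output=True, text=True, check=True,
    ).stdout
    for line in out.strip().splitlines():
        t, medoids, cost = line.split()
        n, k, D = cases[int(t)]
        mine = kmedoids(D, k, seed=0)
        assert sorted(mine.medoids) == [int(m) for m in medoids.split(",")]
        assert mine.cost == pytest.approx(float(cost), rel=1e-6)


def test_kmedoids_deterministic():
    D = random_distance_matrix(np.random.default_rng(7), 40)
    c1 = kmedoids(D, 6, seed=42)
    c2 = kmedoids(D, 6, seed=42)
    assert c1.medoids == c2.medoids and c1.cost == c2.cost


def test_kmedoids_invariants():
    D = random_distance_matrix(np.random.default_rng(9), 30)
    c = kmedoids(D, 5, seed=1)
    assert len(c.medoids) == 5
    for i, m in enumerate(c.assignment):
        # assigned to a true nearest medoid (ties allowed)
        assert D[i, m] == pytest.approx(min(D[i, mm] for mm in c.medoids))
    for m in c.medoids:
        assert c.assignment[m] == m or D[m, c.assignment[m]] == 0.0


def test_kmedoids_bad_inputs():
    D = random_distance_matrix(np.random.default_rng(0), 5)
    with pytest.raises(ValueError):
        kmedoids(D, 6)
    with pytest.raises(ValueError):
        kmedoids(np.ones((3, 3)), 2)  # nonzero diagonal


def toy_clustering(groups):
    """Clustering over string ids: groups is {medoid_id: [member ids]}."""
    ids = [cid for members in groups.values() for cid in members]
    idx = {cid: i for i, cid in enumerate(ids)}
    assignment = np.zeros(len(ids), dtype=int)
    medoids = []
    for mid, members in groups.items():
        medoids.append(idx[mid])
        for cid in members:
            assignment[idx[cid]] = idx[mid]
    return Clustering(k=len(groups), medoids=medoids, assignment=assignment,
                      cost=0.0, ids=ids)


def test_selection_toy_instance():
    # 10 clusters; top-3 of the ranking adds 2 non-representatives; trim 2 worst
    groups = {f"m{i}": [f"m{i}", f"s{i}"] for i in range(10)}
    ranking = ["s0", "m0", "s1"] + [f"m{i}" for i in range(1, 10)] + \
              [f"s{i}" for i in range(2, 10)]
    report = select_purchase_set(toy_clustering(groups), ranking, target=10, top_m=3)
    assert len(report.chosen) == 10
    # s0 and s1 outrank their medoids so they ARE the cluster bests; the only
    # top-3 member not already selected is m0
    assert report.reason["s0"] == "cluster_best"
    assert report.reason["s1"] == "cluster_best"
    assert report.reason["m0"] == "topM_added"
    assert report.trimmed == ["m9"]  # the globally worst-ranked selected


def test_selection_no_additions_no_trim():
    groups = {f"m{i}": [f"m{i}"] for i in range(5)}
    ranking = [f"m{i}" for i in range(5)]
    report = select_purchase_set(toy_clustering(groups), ranking, target=5, top_m=3)
    assert report.chosen == ranking and report.trimmed == []
    assert set(report.reason.values()) == {"cluster_best"}


def test_selection_trim_removes_globally_worst():
    groups = {"m0": ["m0", "a", "b"], "m1": ["m1"], "m2": ["m2"]}
    ranking = ["a", "b", "m0", "m1", "m2"]
    report = select_purchase_set(toy_clustering(groups), ranking, target=3, top_m=3)
    # cluster bests: a, m1, m2; top-3 adds b and m0; trim the two worst-ranked
    assert set(report.chosen) == {"a", "b", "m0"}
    assert report.trimmed == ["m2", "m1"]


def test_selection_infeasible_target():
    groups = {"m0": ["m0"]}
    with pytest.raises(ValueError):
        select_purchase_set(toy_clustering(groups), ["m0"], target=5, top_m=2)
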
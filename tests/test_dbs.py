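"""Barycenter-cutoff pocket clustering, score of overlap, promiscuity labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promisite.dbs import (ClusteringParams, PocketCluster,
                           classify_promiscuity, cluster_pockets,
                           compute_cutoff, dbs4_filter, score_of_overlap)
from promisite.pockets import Pocket
from promisite.chains import Atom


def point_pocket(pid, xyz, frame="CC1"):
    """Single-atom pocket whose barycenter is exactly xyz."""
    atom = Atom("CA", "C", "ALA", 1, np.asarray(xyz, dtype=float), False)
    return Pocket(pocket_id=pid, chain_uid="x:A", ligand_id="L", atoms=[atom],
                  frame=frame, atom_keys=frozenset({(pid, "CA")}))


def keyed_pocket(pid, keys, frame="CC1"):
    """Pocket with controlled atom keys (coordinates irrelevant)."""
    atoms = [Atom("CA", "C", "ALA", i + 1, np.array([float(i), 0, 0]), False)
             for i in range(len(keys))]
    return Pocket(pocket_id=pid, chain_uid="x:A", ligand_id="L", atoms=atoms,
                  frame=frame, atom_keys=frozenset(keys))


# ---------------------------------------------------------------------------
# cutoff

def test_cutoff_zero_variance():
    p = compute_cutoff([7.0, 7.0, 7.0])
    assert (p.D, p.sigma, p.C) == (7.0, 0.0, 7.0)


def test_cutoff_hand_evaluated_population_sigma():
    p = compute_cutoff([6.0, 8.0], k=2)
    assert p.D == 7.0
    assert p.sigma == 1.0  # population sd, divisor p
    assert p.C == 5.0


def test_cutoff_k_zero_gives_mean():
    assert compute_cutoff([3.0, 5.0, 10.0], k=0).C == pytest.approx(6.0)


def test_cutoff_rejects_empty_and_negative():
    with pytest.raises(ValueError):
        compute_cutoff([])
    with pytest.raises(ValueError):
        compute_cutoff([-1.0])


# ---------------------------------------------------------------------------
# clustering

def test_single_pocket_singleton_cluster():
    out = cluster_pockets([point_pocket("p1", [0, 0, 0])],
                          ClusteringParams(2, 5, 0, 1))
    assert len(out) == 1 and out[0].member_pockets == ["p1"]


def test_identical_barycenters_merge():
    out = cluster_pockets([point_pocket("p1", [1, 1, 1]),
                           point_pocket("p2", [1, 1, 1])],
                          ClusteringParams(2, 5, 0, 2))
    assert len(out) == 1 and out[0].member_pockets == ["p1", "p2"]


def test_nonpositive_cutoff_yields_singletons():
    pockets = [point_pocket(f"p{i}", [0, 0, 0]) for i in range(3)]
    out = cluster_pockets(pockets, ClusteringParams(2, 1.0, 2.0, 3))
    assert len(out) == 3


def _bruteforce_components(points, C):
    n = len(points)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in range(n)
                         if v != u and np.linalg.norm(points[u] - points[v]) < C
                         and v not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def test_clustering_matches_component_oracle_on_random_instances():
    rng = np.random.default_rng(21)
    for _ in range(40):
        n = rng.integers(2, 25)
        pts = rng.uniform(0, 30, size=(n, 3))
        C = rng.uniform(2.0, 15.0)
        pockets = [point_pocket(f"p{i:02d}", pts[i]) for i in range(n)]
        out = cluster_pockets(pockets, ClusteringParams(0, C, 0, n))
        got = {frozenset(int(m[1:]) for m in cl.member_pockets) for cl in out}
        assert got == _bruteforce_components(pts, C)


def test_two_site_family_recovers_planted_sites(small_pipeline):
    _, truth, result = small_pipeline
    site_partition = {}
    for pocket, site in truth.pocket_site.items():
        site_partition.setdefault(site, set()).add(pocket)
    got = {frozenset(d.member_pockets) for d in result.dbs_list}
    assert got == {frozenset(v) for v in site_partition.values()}


def test_clustering_is_partition(small_pipeline):
    _, _, result = small_pipeline
    all_members = [m for d in result.dbs_list for m in d.member_pockets]
    assert len(all_members) == len(set(all_members)) == len(result.pockets)


def test_within_cluster_overlap_positive(small_pipeline):
    _, _, result = small_pipeline
    for d in result.dbs_list:
        assert d.overlap_stats["min"] > 0


def test_mixed_frames_rejected():
    with pytest.raises(ValueError):
        cluster_pockets([point_pocket("a", [0, 0, 0], frame="CC1"),
                         point_pocket("b", [0, 0, 0], frame="CC2")],
                        ClusteringParams(2, 5, 0, 2))


# ---------------------------------------------------------------------------
# score of overlap

def test_overlap_self_is_one():
    p = keyed_pocket("a", [(i, "CA") for i in range(25)])
    assert score_of_overlap(p, p) == 1.0


def test_overlap_disjoint_is_zero():
    a = keyed_pocket("a", [(1, "CA"), (2, "CA")])
    b = keyed_pocket("b", [(3, "CA"), (4, "CA")])
    assert score_of_overlap(a, b) == 0.0


def test_overlap_half_common_is_one_third():
    a = keyed_pocket("a", [(i, "CA") for i in range(10)])
    b = keyed_pocket("b", [(i, "CA") for i in range(5, 15)])
    assert score_of_overlap(a, b) == pytest.approx(1 / 3)


def test_overlap_different_frames_rejected():
    a = keyed_pocket("a", [(1, "CA")], frame="CC1")
    b = keyed_pocket("b", [(1, "CA")], frame="CC2")
    with pytest.raises(ValueError):
        score_of_overlap(a, b)


@settings(max_examples=50, derandomize=True)
@given(ka=st.sets(st.integers(0, 40), min_size=1, max_size=30),
       kb=st.sets(st.integers(0, 40), min_size=1, max_size=30))
def test_overlap_bounds_and_symmetry(ka, kb):
    a = keyed_pocket("a", [(k, "CA") for k in ka])
    b = keyed_pocket("b", [(k, "CA") for k in kb])
    s = score_of_overlap(a, b)
    assert 0.0 <= s <= 1.0
    assert s == score_of_overlap(b, a)


# ---------------------------------------------------------------------------
# promiscuity labels

def _dbs(pockets):
    return PocketCluster("CC1_1", "CC1", list(pockets))


@pytest.mark.parametrize("n_lc,expected", [(1, "S"), (2, "MP"), (3, "MP"), (4, "HP")])
def test_promiscuity_thresholds(n_lc, expected):
    pockets = [f"p{i}" for i in range(max(4, n_lc))]
    mapping = {p: f"LC{i % n_lc}" for i, p in enumerate(pockets)}
    assert classify_promiscuity(_dbs(pockets), mapping) == expected


def test_single_pocket_dbs_is_undetermined():
    assert classify_promiscuity(_dbs(["p0"]), {"p0": "LC1"}) == "UNDETERMINED"


def test_unassigned_pocket_rejected():
    with pytest.raises(ValueError):
        classify_promiscuity(_dbs(["p0", "p1"]), {"p0": "LC1"})


def test_dbs4_boundary():
    ds = [_dbs([f"p{i}" for i in range(n)]) for n in (3, 4, 5)]
    kept, counts = dbs4_filter(ds)
    assert [d.p for d in kept] == [4, 5]
    assert counts == {"kept": 2, "dropped": 1}


def test_dbs4_tally_oracle():
    rng = np.random.default_rng(2)
    sizes = rng.integers(1, 10, size=50)
    ds = [_dbs([f"d{i}p{j}" for j in range(s)]) for i, s in enumerate(sizes)]
    kept, counts = dbs4_filter(ds)
    assert counts["kept"] == int(np.sum(sizes >= 4)) == len(kept)
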
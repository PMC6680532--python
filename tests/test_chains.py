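"""Sequence identity, greedy chain clustering, Kabsch superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from promisite.chains import (SuperpositionError, cluster_chains, kabsch,
                              sequence_identity, superpose)
from promisite.synthetic import SyntheticScenario, generate_scenario
from promisite import read_complex_dir

from conftest import make_chain


# ---------------------------------------------------------------------------
# sequence identity

def test_identical_sequences_identity_one():
    assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0


def test_single_substitution_in_100():
    a = "A" * 100
    b = "A" * 50 + "C" + "A" * 49
    assert sequence_identity(a, b) == pytest.approx(0.99)
    assert sequence_identity(a, b, denominator="alignment") == pytest.approx(0.99)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        sequence_identity("", "ACD")


def _oracle_alignment(a, b, open_gap=-10.0, extend_gap=-0.5):
    """Enumerate every global alignment of two short sequences and return
    the maximum match count among the optimal-score alignments."""
    best = {"score": -np.inf, "matches": 0}

    def rec(i, j, score, matches, prev_gap):
        if i == len(a) and j == len(b):
            if score > best["score"] + 1e-12:
                best.update(score=score, matches=matches)
            elif abs(score - best["score"]) <= 1e-12:
                best["matches"] = max(best["matches"], matches)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (1.0 if a[i] == b[j] else 0.0),
                matches + (a[i] == b[j]), None)
        if i < len(a):
            cost = extend_gap if prev_gap == "a" else open_gap
            rec(i + 1, j, score + cost, matches, "a")
        if j < len(b):
            cost = extend_gap if prev_gap == "b" else open_gap
            rec(i, j + 1, score + cost, matches, "b")

    rec(0, 0, 0.0, 0, None)
    return best["matches"]


def test_identity_matches_exhaustive_alignment_oracle():
    a, b = "ACDEFGH", "ACDFGH"  # one-residue deletion
    matches = _oracle_alignment(a, b)
    assert sequence_identity(a, b) == pytest.approx(matches / len(b))
    assert sequence_identity(a, b, denominator="alignment") == pytest.approx(
        matches / len(a))  # one gap column -> columns == len(a)


def test_identity_symmetric():
    a, b = "ACDEFGHIKL", "ACDWFGHIKL"
    assert sequence_identity(a, b) == sequence_identity(b, a)


# ---------------------------------------------------------------------------
# clustering

def _chain_from_seq(uid, seq):
    coords = np.column_stack([np.arange(len(seq)) * 3.8,
                              np.zeros(len(seq)), np.zeros(len(seq))])
    ch = make_chain(coords, chain_uid=uid)
    return type(ch)(chain_uid=uid, sequence=seq, atoms=ch.atoms)


def test_identical_chains_cluster_together():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
    chains = [_chain_from_seq("a:A", seq), _chain_from_seq("b:A", seq)]
    clusters = cluster_chains(chains, superpose_members=False)
    assert len(clusters) == 1
    assert clusters[0].member_uids == ["a:A", "b:A"]


def test_chains_at_095_identity_share_cluster():
    rng = np.random.default_rng(1)
    seq = list(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
    other = seq.copy()
    for p in rng.choice(100, size=5, replace=False):
        other[p] = "W" if other[p] != "W" else "Y"
    chains = [_chain_from_seq("a:A", "".join(seq)),
              _chain_from_seq("b:A", "".join(other))]
    clusters = cluster_chains(chains, t1=0.90, superpose_members=False)
    assert len(clusters) == 1


def test_planted_three_family_recovery(tmp_path):
    scenario = SyntheticScenario(seed=2, n_chain_families=3, chains_per_family=3,
                                 within_family_identity=0.92, sites_per_family=1,
                                 pockets_per_site=3, ligand_families=3,
                                 ligands_per_family=2)
    truth = generate_scenario(scenario, tmp_path)
    chains = [c for cx in read_complex_dir(tmp_path) for c in cx.chains]
    # realized within-family identities stay above the first-pass threshold
    by_family = {}
    for ch in chains:
        by_family.setdefault(truth.chain_family[ch.chain_uid], []).append(ch)
    for members in by_family.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                assert sequence_identity(a.sequence, b.sequence) >= 0.90
    clusters = cluster_chains(chains, superpose_members=False)
    got = {frozenset(c.member_uids) for c in clusters}
    want = {frozenset(ch.chain_uid for ch in members)
            for members in by_family.values()}
    assert got == want


def test_cluster_count_nonincreasing_as_t1_drops(tmp_path):
    scenario = SyntheticScenario(seed=3, n_chain_families=3, chains_per_family=2,
                                 sites_per_family=1, pockets_per_site=2,
                                 ligand_families=3, ligands_per_family=2)
    generate_scenario(scenario, tmp_path)
    chains = [c for cx in read_complex_dir(tmp_path) for c in cx.chains]
    counts = [len(cluster_chains(chains, t1=t, t2=min(t, 0.8),
                                 superpose_members=False))
              for t in (0.95, 0.90, 0.50, 0.10)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# superposition

def _helix(n=200, seed=0):
    t = np.arange(n) * 0.35
    return np.column_stack([10 * np.cos(t), 10 * np.sin(t), 1.5 * np.arange(n)])


def test_superpose_identity():
    ch = make_chain(_helix(50))
    tr, rmsd, rmap = superpose(ch, ch)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-8)
    assert rmap == {i + 1: i + 1 for i in range(50)}


def test_superpose_rigid_invariance():
    coords = _helix(80)
    ref = make_chain(coords, chain_uid="ref:A")
    R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
    moved = make_chain(coords @ R.T + np.array([5.0, -3.0, 12.0]),
                       chain_uid="mem:A")
    tr, rmsd, _ = superpose(moved, ref)
    assert rmsd <= 1e-8
    np.testing.assert_allclose(tr.apply(moved.coords()), coords, atol=1e-6)
    assert np.linalg.det(tr.rotation) == pytest.approx(1.0)


def test_superpose_noise_rmsd_matches_monte_carlo_expectation():
    # per-axis Gaussian noise sd on one side gives RMSD ~= sd * sqrt(3)
    sd = 0.3
    coords = _helix(300)
    ref = make_chain(coords, chain_uid="ref:A")
    rng = np.random.default_rng(4)
    rmsds = []
    for _ in range(5):
        noisy = make_chain(coords + rng.normal(0, sd, coords.shape),
                           chain_uid="mem:A")
        rmsds.append(superpose(noisy, ref)[1])
    assert np.mean(rmsds) == pytest.approx(sd * np.sqrt(3), rel=0.2)


def test_kabsch_rejects_degenerate_inputs():
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(SuperpositionError):
        kabsch(line, line)
    with pytest.raises(SuperpositionError):
        kabsch(line[:2], line[:2])


def test_transforms_superpose_members_onto_reference(small_pipeline):
    _, _, result = small_pipeline
    for cl in result.chain_clusters:
        assert np.allclose(cl.transforms[cl.reference_uid].rotation, np.eye(3))
        # noisy homologs land within a few noise-sd of the reference
        assert all(r < 1.5 for r in cl.rmsds.values())


# ---------------------------------------------------------------------------
# import/export hooks

def test_cluster_table_and_transform_roundtrip(small_pipeline, tmp_path):
    from promisite.chains import (load_cluster_file, load_transform_file,
                                  write_cluster_tables)
    _, _, result = small_pipeline
    write_cluster_tables(result.chain_clusters, tmp_path)
    back = load_cluster_file(tmp_path / "chain_clusters.csv")
    assert [c.cluster_id for c in back] == \
        [c.cluster_id for c in sorted(result.chain_clusters,
                                      key=lambda c: c.cluster_id)]
    for orig in result.chain_clusters:
        loaded = next(c for c in back if c.cluster_id == orig.cluster_id)
        assert sorted(loaded.member_uids) == orig.member_uids
        assert loaded.reference_uid == orig.reference_uid
    transforms = load_transform_file(tmp_path / "transforms.json")
    for cl in result.chain_clusters:
        for uid, tr in cl.transforms.items():
            got = transforms[cl.cluster_id][uid]
            np.testing.assert_allclose(got.rotation, tr.rotation)
            np.testing.assert_allclose(got.translation, tr.translation)
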
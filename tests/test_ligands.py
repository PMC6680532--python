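"""Ligand space: descriptors, filters, Tanimoto, Butina clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from promisite.ligands import (DESCRIPTOR_NAMES, LigandCluster, LigandRecord,
                               MACCS_fingerprint, cluster_ligands,
                               druglike_filter, fingerprint_from_bits,
                               ligand_descriptors, representative_ligand,
                               tanimoto, validity_filter)


def fp(bits, n=167):
    return fingerprint_from_bits(bits, n)


def record(lid, bits):
    return LigandRecord(ligand_id=lid, fingerprint=fp(bits))


# ---------------------------------------------------------------------------
# descriptors

@pytest.mark.parametrize("smiles,expected", [
    ("c1ccccc1", {"Rings": 1, "RotatableB": 0, "ratioHC": 1.0}),   # benzene
    ("CCCC", {"RotatableB": 1}),                                    # n-butane
    ("CCO", {"HBD": 1, "HBA": 1}),                                  # ethanol
])
def test_descriptor_reference_molecules(smiles, expected):
    d = ligand_descriptors(Chem.MolFromSmiles(smiles))
    for k, v in expected.items():
        assert d[k] == pytest.approx(v)


def test_descriptor_vector_has_21_named_slots():
    d = ligand_descriptors(Chem.MolFromSmiles("CCO"))
    assert tuple(d) == DESCRIPTOR_NAMES
    assert len(d) == 21


def test_carbon_free_molecule_flags_ratio_missing():
    d = ligand_descriptors(Chem.MolFromSmiles("O=S=O"))
    assert math.isnan(d["ratioHC"])


def test_rigid_plus_rotatable_equals_bonds():
    mol = Chem.MolFromSmiles("CCOC(=O)c1ccccc1")
    d = ligand_descriptors(mol)
    assert d["RigidB"] + d["RotatableB"] == mol.GetNumBonds()


# ---------------------------------------------------------------------------
# filters

@pytest.mark.parametrize("desc,expected", [
    ({"Rings": 7, "RotatableB": 0, "ratioHC": 0.5}, False),
    ({"Rings": 6, "RotatableB": 11, "ratioHC": 0.5}, True),   # boundaries inclusive
    ({"Rings": 1, "RotatableB": 12, "ratioHC": 0.5}, False),
    ({"Rings": 1, "RotatableB": 0, "ratioHC": 0.05}, False),
    ({"Rings": 1, "RotatableB": 0, "ratioHC": 1.11}, True),
])
def test_druglike_rules(desc, expected):
    assert druglike_filter(desc) is expected


def test_druglike_missing_descriptor_is_incomputable():
    with pytest.raises(KeyError):
        druglike_filter({"Rings": 1, "RotatableB": 0, "ratioHC": float("nan")})


def test_validity_peptide_and_metal_and_oligo():
    pep = LigandRecord(ligand_id="PEP")
    assert validity_filter(pep, {"n_peptide_residues": 12}) is False
    assert pep.reason == "peptide_length"
    assert validity_filter(LigandRecord(ligand_id="PE2"),
                           {"n_peptide_residues": 10}) is True
    mg = LigandRecord(ligand_id="MG", mol=Chem.MolFromSmiles("[Mg+2]"))
    assert validity_filter(mg) is False
    oligo = LigandRecord(ligand_id="OLI")
    assert validity_filter(oligo, {"n_nucleotides": 3}) is True
    assert validity_filter(oligo, {"n_nucleotides": 4}) is False


def test_validity_exclusion_list_ids_solvents():
    gol = LigandRecord(ligand_id="GOL", smiles="OCC(O)CO")
    assert validity_filter(gol) is False
    assert gol.reason == "exclusion_list"


# ---------------------------------------------------------------------------
# tanimoto

def test_tanimoto_reference_values():
    assert tanimoto(fp({1, 5, 9}), fp({1, 5, 9})) == 1.0
    assert tanimoto(fp({1, 2}), fp({5, 6})) == 0.0
    assert tanimoto(fp({1, 2, 3, 4}), fp({3, 4, 5, 6})) == pytest.approx(2 / 6)


def test_tanimoto_empty_pair_raises():
    with pytest.raises(ValueError):
        tanimoto(fp(set()), fp(set()))
    with pytest.raises(ValueError):
        tanimoto(fp({1}, n=167), fp({1}, n=166))


@settings(max_examples=60, derandomize=True)
@given(a=st.sets(st.integers(0, 166), min_size=1, max_size=40),
       b=st.sets(st.integers(0, 166), min_size=1, max_size=40))
def test_tanimoto_symmetry_and_bounds(a, b):
    s = tanimoto(fp(a), fp(b))
    assert 0.0 <= s <= 1.0
    assert s == tanimoto(fp(b), fp(a))
    assert tanimoto(fp(a), fp(a)) == 1.0


# ---------------------------------------------------------------------------
# clustering

def test_single_ligand_is_singleton_cluster():
    out = cluster_ligands([record("a", {1, 2})])
    assert len(out) == 1 and out[0].member_ids == ["a"]
    assert math.isnan(out[0].mean_pairwise_tanimoto)


def test_pair_above_threshold_joins():
    # |A & B| = 17, |A | B| = 20 -> 0.85
    a = set(range(18))
    b = set(range(17)) | {30, 31}
    assert tanimoto(fp(a), fp(b)) == pytest.approx(0.85)
    out = cluster_ligands([record("a", a), record("b", b)], threshold=0.8)
    assert len(out) == 1 and out[0].member_ids == ["a", "b"]


def _separable_instance():
    base = set(range(60))
    records = [LigandRecord(ligand_id=f"f{i:02d}",
                            fingerprint=fp(base - {i}, n=256))
               for i in range(46)]
    records += [LigandRecord(ligand_id=f"s{j}",
                             fingerprint=fp(set(range(60 + 10 * j, 70 + 10 * j)), n=256))
                for j in range(10)]
    return records


def _connected_components(records, threshold):
    n = len(records)
    adj = [[tanimoto(records[i].fingerprint, records[j].fingerprint) >= threshold
            for j in range(n)] for i in range(n)]
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
            stack.extend(v for v in range(n) if adj[u][v] and v not in comp)
        seen |= comp
        comps.append(frozenset(records[u].ligand_id for u in comp))
    return set(comps)


def test_butina_matches_component_oracle_on_separable_instance():
    records = _separable_instance()
    clusters = cluster_ligands(records, threshold=0.8)
    assert len(clusters) == 11
    assert max(len(c.member_ids) for c in clusters) == 46
    got = {frozenset(c.member_ids) for c in clusters}
    assert got == _connected_components(records, 0.8)


def test_clustering_is_partition_and_centroid_guarantee():
    rng = np.random.default_rng(5)
    records = [record(f"r{i:02d}", set(rng.choice(167, size=30, replace=False)))
               for i in range(40)]
    clusters = cluster_ligands(records, threshold=0.6)
    members = [m for c in clusters for m in c.member_ids]
    assert sorted(members) == sorted(r.ligand_id for r in records)
    by_id = {r.ligand_id: r for r in records}
    for c in clusters:
        centroid = by_id[c.centroid_id]
        for m in c.member_ids:
            assert tanimoto(by_id[m].fingerprint, centroid.fingerprint) >= 0.6


def test_lower_threshold_never_increases_cluster_count():
    rng = np.random.default_rng(7)
    records = [record(f"r{i:02d}", set(rng.choice(167, size=25, replace=False)))
               for i in range(30)]
    counts = [len(cluster_ligands(records, threshold=t))
              for t in (0.9, 0.7, 0.5, 0.3, 0.1)]
    assert counts == sorted(counts, reverse=True)


def test_empty_input_gives_empty_list():
    assert cluster_ligands([]) == []


# ---------------------------------------------------------------------------
# representatives

def test_representative_singleton_and_tie_break():
    table = pd.DataFrame({"x": [1.0, 1.0, 5.0]}, index=["b", "a", "c"])
    assert representative_ligand(
        LigandCluster("LC1", ["a"], None), table) == "a"
    # identical vectors: lexicographically first id wins
    assert representative_ligand(
        LigandCluster("LC1", ["b", "a"], None), table) == "a"


def test_representative_weighted_distance_oracle():
    table = pd.DataFrame(
        {"d1": [0.0, 1.0, 4.0, 10.0], "d2": [0.0, 0.5, 1.0, -3.0]},
        index=["a", "b", "c", "z"])
    cluster = LigandCluster("LC1", ["a", "b", "c"], None)
    var = table.to_numpy().var(axis=0, ddof=0)
    w = 1.0 / var
    X = table.loc[["a", "b", "c"]].to_numpy()
    mean = X.mean(axis=0)
    dist = ((X - mean) ** 2 * w).sum(axis=1)
    expected = ["a", "b", "c"][int(np.argmin(dist))]
    assert representative_ligand(cluster, table) == expected


# ---------------------------------------------------------------------------
# I/O round-trips

def test_fingerprint_hex_roundtrip():
    from promisite.ligands import fingerprint_from_hex, fingerprint_to_hex
    mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
    f = MACCS_fingerprint(mol)
    back = fingerprint_from_hex(fingerprint_to_hex(f))
    assert list(back.GetOnBits()) == list(f.GetOnBits())


def test_load_sdf_structures(tmp_path):
    from promisite.ligands import load_ligand_structures
    from rdkit.Chem import AllChem, SDWriter
    path = tmp_path / "ligs.sdf"
    writer = SDWriter(str(path))
    for name, smi in [("ASP", "CC(=O)Oc1ccccc1C(=O)O"), ("ETO", "CCO")]:
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        AllChem.Compute2DCoords(mol)
        mol.SetProp("_Name", name)
        writer.write(Chem.RemoveHs(mol))
    writer.close()
    records = load_ligand_structures(path)
    assert [r.ligand_id for r in records] == ["ASP", "ETO"]
    assert all(r.fingerprint is not None for r in records)
    assert records[1].descriptors["HBD"] == 1


def test_ward_alternative_agrees_on_separable_instance():
    records = _separable_instance()
    clusters = cluster_ligands(records, threshold=0.8, method="ward")
    got = {frozenset(c.member_ids) for c in clusters}
    assert got == _connected_components(records, 0.8)
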
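"""Ligand space: validity and drug-likeness filtering, descriptors,
MACCS fingerprints, Tanimoto clustering into Ligand-Clusters.

A Ligand-Cluster is a group of ligands whose MACCS-Tanimoto similarity
to the cluster centroid is at least the clustering threshold (0.8 by
default); it stands for one "type" of ligand.  Clustering is leader
(Butina-style) clustering; a hierarchical/Ward alternative is available
behind the ``method`` switch for comparison.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

__all__ = [
    "LigandRecord",
    "LigandCluster",
    "MACCS_fingerprint",
    "fingerprint_from_bits",
    "tanimoto",
    "ligand_descriptors",
    "validity_filter",
    "druglike_filter",
    "cluster_ligands",
    "representative_ligand",
    "load_ligand_table",
    "DESCRIPTOR_NAMES",
    "DEFAULT_DRUGLIKE_RULES",
]

# The 21 ligand descriptor slots.  The first twelve are the named
# mandatory ones; the remaining nine follow a drug-likeness-profiling
# style list and are reconstructed slots (see RECONSTRUCTED_DESCRIPTORS).
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Rings", "RigidB", "RotatableB", "MW", "logP", "logD", "ratioHC",
    "HBD", "HBA", "tPSA", "carbon_frequency", "heavy_atoms",
    # reconstructed slots
    "charged_atoms", "halogens", "oxygens", "nitrogens",
    "ring_systems", "max_ring_size", "stereocenters",
    "MW_largest_fragment", "formal_charge",
)
RECONSTRUCTED_DESCRIPTORS = frozenset(DESCRIPTOR_NAMES[12:])

# Inclusive bounds per descriptor; None means unbounded on that side.
DEFAULT_DRUGLIKE_RULES: dict[str, tuple[float | None, float | None]] = {
    "Rings": (None, 6),
    "RotatableB": (None, 11),
    "ratioHC": (0.1, 1.11),
}
LIPINSKI_RULES: dict[str, tuple[float | None, float | None]] = {
    "MW": (None, 500), "logP": (None, 5), "HBD": (None, 5), "HBA": (None, 10),
}

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class LigandRecord:
    """One small molecule with fingerprint, descriptors and filter flags."""

    ligand_id: str
    smiles: str | None = None
    source_complex: str | None = None
    mol: Chem.Mol | None = None
    descriptors: dict[str, float] = field(default_factory=dict)
    fingerprint: ExplicitBitVect | None = None
    valid: bool = True
    drug_like: bool = True
    reason: str | None = None

    @property
    def heavy_atom_count(self) -> int | None:
        v = self.descriptors.get("heavy_atoms")
        return int(v) if v is not None and not math.isnan(v) else None


@dataclass
class LigandCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str | None = None
    centroid_id: str | None = None
    mean_pairwise_tanimoto: float = float("nan")

    def __post_init__(self) -> None:
        if self.representative_id is not None and self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


# ---------------------------------------------------------------------------
# fingerprints and similarity

def MACCS_fingerprint(mol: Chem.Mol) -> ExplicitBitVect:
    """166-bit MACCS-type keys (bit 0 of the 167-slot vector is unused)."""
    return MACCSkeys.GenMACCSKeys(mol)


def fingerprint_from_bits(bits: Iterable[int], n_bits: int = 167) -> ExplicitBitVect:
    fp = ExplicitBitVect(n_bits)
    for b in bits:
        fp.SetBit(int(b))
    return fp


def tanimoto(fp_a: ExplicitBitVect, fp_b: ExplicitBitVect) -> float:
    """Tanimoto similarity |a & b| / |a | b| of two equal-length bit sets.

    Identical non-empty fingerprints give 1, disjoint ones give 0.  Two
    all-zero fingerprints have an undefined similarity and raise.
    """
    if fp_a.GetNumBits() != fp_b.GetNumBits():
        raise ValueError("fingerprint lengths differ")
    a = set(fp_a.GetOnBits())
    b = set(fp_b.GetOnBits())
    union = len(a | b)
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return len(a & b) / union


# ---------------------------------------------------------------------------
# descriptors

def ligand_descriptors(mol: Chem.Mol) -> dict[str, float]:
    """Fill the 21 named descriptor slots for one molecule.

    ``ratioHC`` counts implicit plus explicit hydrogens over carbons and
    is NaN (flagged missing) for carbon-free molecules.  ``logD`` is
    approximated by logP; an external pKa-aware predictor can overwrite
    the slot.  Missing values are explicit NaN, never silent zeros.
    """
    ri = mol.GetRingInfo()
    n_heavy = mol.GetNumHeavyAtoms()
    n_c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    n_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    rot = Lipinski.NumRotatableBonds(mol)
    logp = Crippen.MolLogP(mol)
    frags = Chem.GetMolFrags(mol, asMols=True) if n_heavy else []
    ring_sizes = [len(r) for r in ri.AtomRings()]
    d = {
        "Rings": float(ri.NumRings()),
        "RigidB": float(mol.GetNumBonds() - rot),
        "RotatableB": float(rot),
        "MW": Descriptors.MolWt(mol),
        "logP": logp,
        "logD": logp,  # approximate: logP stands in at pH 7.4
        "ratioHC": (n_h / n_c) if n_c else float("nan"),
        "HBD": float(Lipinski.NumHDonors(mol)),
        "HBA": float(Lipinski.NumHAcceptors(mol)),
        "tPSA": Descriptors.TPSA(mol),
        "carbon_frequency": (n_c / n_heavy) if n_heavy else float("nan"),
        "heavy_atoms": float(n_heavy),
        "charged_atoms": float(sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() != 0)),
        "halogens": float(sum(1 for a in mol.GetAtoms()
                              if a.GetAtomicNum() in (9, 17, 35, 53))),
        "oxygens": float(sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8)),
        "nitrogens": float(sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)),
        "ring_systems": float(_n_ring_systems(mol)),
        "max_ring_size": float(max(ring_sizes)) if ring_sizes else 0.0,
        "stereocenters": float(len(Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False))),
        "MW_largest_fragment": max((Descriptors.MolWt(f) for f in frags),
                                   default=float("nan")),
        "formal_charge": float(Chem.GetFormalCharge(mol)),
    }
    assert tuple(d) == DESCRIPTOR_NAMES
    return d


def _n_ring_systems(mol: Chem.Mol) -> int:
    """Number of fused-ring systems (rings sharing an atom are one system)."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        joined = [s for s in systems if s & ring]
        for s in joined:
            systems.remove(s)
        systems.append(set().union(ring, *joined))
    return len(systems)


# ---------------------------------------------------------------------------
# validity and drug-likeness

def _load_exclusion_list() -> frozenset[str]:
    path = _DATA_DIR / "exclusions.csv"
    codes = set()
    with open(path) as fh:
        for row in csv.DictReader(fh):
            codes.add(row["code"].strip().upper())
    return frozenset(codes)


_METALS = frozenset(
    "LI BE NA MG AL K CA SC TI V CR MN FE CO NI CU ZN GA RB SR Y ZR MO RU RH "
    "PD AG CD IN SN CS BA W RE OS IR PT AU HG TL PB".split())


def validity_filter(record: LigandRecord,
                    context: Mapping | None = None,
                    exclusion_list: frozenset[str] | None = None) -> bool:
    """Flag biologically relevant ligands; reject additives and polymers.

    Invalid: covalently bonded molecules, crystallographic additives /
    salts / metals / solvents (matched against the exclusion list),
    peptides of 11+ amino acids, oligonucleotides of 4+ nucleotides.
    The record's ``valid`` flag and ``reason`` are set in place and the
    flag is returned; unresolvable records are flagged, never dropped.
    """
    context = context or {}
    if exclusion_list is None:
        exclusion_list = _load_exclusion_list()
    code = record.ligand_id.strip().upper()

    def reject(reason: str) -> bool:
        record.valid = False
        record.reason = reason
        return False

    if context.get("covalent"):
        return reject("covalent")
    if code in exclusion_list:
        return reject("exclusion_list")
    n_pep = context.get("n_peptide_residues")
    if n_pep is not None and n_pep >= 11:
        return reject("peptide_length")
    n_nt = context.get("n_nucleotides")
    if n_nt is not None and n_nt >= 4:
        return reject("oligonucleotide_length")
    if record.mol is not None:
        atoms = list(record.mol.GetAtoms())
        if len(atoms) == 1 and atoms[0].GetSymbol().upper() in _METALS:
            return reject("metal")
    elif record.smiles is None and n_pep is None and n_nt is None:
        return reject("unresolvable_composition")
    record.valid = True
    record.reason = None
    return True


def druglike_filter(descriptors: Mapping[str, float],
                    rules: Mapping[str, tuple[float | None, float | None]] | None = None,
                    lipinski: bool = False) -> bool:
    """True iff every configured rule passes (bounds inclusive).

    Defaults to the three printed rules (Rings <= 6, RotatableB <= 11,
    0.1 <= ratioH/C <= 1.11); Lipinski bounds can be switched on.  A
    missing required descriptor raises ``KeyError`` so callers can count
    "incomputable" ligands separately.
    """
    rules = dict(rules if rules is not None else DEFAULT_DRUGLIKE_RULES)
    if lipinski:
        rules.update(LIPINSKI_RULES)
    for name, (lo, hi) in rules.items():
        value = descriptors[name]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise KeyError(f"descriptor {name!r} incomputable")
        if lo is not None and value < lo:
            return False
        if hi is not None and value > hi:
            return False
    return True


# ---------------------------------------------------------------------------
# clustering

def cluster_ligands(records: Sequence[LigandRecord], threshold: float = 0.8,
                    method: str = "butina") -> list[LigandCluster]:
    """Partition fingerprinted ligands into Ligand-Clusters.

    ``method="butina"`` (default) is leader clustering: ligands are
    ranked by neighbor count at the threshold (ties by id); the densest
    unassigned ligand becomes a centroid and absorbs all its unassigned
    neighbors; singletons remain singleton clusters.  Every member of a
    cluster is within the threshold of its centroid -- member-member
    pairs may be lower.  ``method="ward"`` is agglomerative Ward
    clustering on (1 - Tanimoto) distances cut at the same threshold,
    kept as a comparison alternative.
    """
    if not records:
        return []
    for r in records:
        if r.fingerprint is None:
            raise ValueError(f"ligand {r.ligand_id} has no fingerprint")
    ids = [r.ligand_id for r in records]
    n = len(records)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(records[i].fingerprint,
                                             records[j].fingerprint)
    if method == "ward":
        labels = _ward_labels(sim, threshold)
        groups: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        members_list = sorted(groups.values(), key=lambda g: ids[min(g)])
        centroids = [None] * len(members_list)
    else:
        members_list, centroids = _butina(sim, ids, threshold)

    clusters = []
    for k, members in enumerate(members_list, start=1):
        mids = sorted(ids[i] for i in members)
        if len(members) > 1:
            pairs = [sim[i, j] for a, i in enumerate(members)
                     for j in members[a + 1:]]
            mean_sim = float(np.mean(pairs))
        else:
            mean_sim = float("nan")
        clusters.append(LigandCluster(
            cluster_id=f"LC{k}", member_ids=mids,
            centroid_id=ids[centroids[k - 1]] if centroids[k - 1] is not None else None,
            mean_pairwise_tanimoto=mean_sim))
    return clusters


def _butina(sim: np.ndarray, ids: list[str], threshold: float
            ) -> tuple[list[list[int]], list[int | None]]:
    n = sim.shape[0]
    neighbors = [{j for j in range(n) if j != i and sim[i, j] >= threshold}
                 for i in range(n)]
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), ids[i]))
    assigned = [False] * n
    members_list: list[list[int]] = []
    centroids: list[int | None] = []
    for i in order:
        if assigned[i]:
            continue
        cluster = [i] + sorted(j for j in neighbors[i] if not assigned[j])
        for j in cluster:
            assigned[j] = True
        members_list.append(cluster)
        centroids.append(i)
    # deterministic cluster numbering by smallest member id
    packed = sorted(zip(members_list, centroids),
                    key=lambda mc: min(ids[i] for i in mc[0]))
    return [m for m, _ in packed], [c for _, c in packed]


def _ward_labels(sim: np.ndarray, threshold: float) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    if dist.shape[0] == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(squareform(dist, checks=False), method="ward")
    return fcluster(Z, t=1.0 - threshold, criterion="distance")


def representative_ligand(cluster: LigandCluster,
                          table: pd.DataFrame,
                          weights: Mapping[str, float] | None = None) -> str:
    """Member closest to the cluster's mean descriptor vector.

    Distance is the weighted Euclidean distance with weights
    ``1/variance`` per descriptor computed over the whole dataset
    (``table``, ligand ids as index); zero-variance descriptors carry no
    weight.  Ties break on the lexicographically smallest ligand id.
    """
    members = sorted(cluster.member_ids)
    if len(members) == 1:
        return members[0]
    cols = [c for c in table.columns if table[c].dtype.kind in "fi"]
    X = table.loc[members, cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("representative selection needs complete descriptors")
    if weights is None:
        var = table[cols].to_numpy(dtype=float).var(axis=0, ddof=0)
        w = np.where(var > 0, 1.0 / np.where(var > 0, var, 1.0), 0.0)
    else:
        w = np.array([weights[c] for c in cols], dtype=float)
    mean = X.mean(axis=0)
    dist2 = ((X - mean) ** 2 * w).sum(axis=1)
    best = min(range(len(members)), key=lambda i: (dist2[i], members[i]))
    return members[best]


def fingerprint_to_hex(fp: ExplicitBitVect) -> str:
    """Hex-string export of a fingerprint (bit 4*i+j -> bit j of hex digit i)."""
    n = fp.GetNumBits()
    out = []
    for i in range(0, n, 4):
        nib = 0
        for j in range(4):
            if i + j < n and fp.GetBit(i + j):
                nib |= 1 << j
        out.append(f"{nib:x}")
    return "".join(out)


def fingerprint_from_hex(s: str, n_bits: int = 167) -> ExplicitBitVect:
    fp = ExplicitBitVect(n_bits)
    for i, ch in enumerate(s):
        nib = int(ch, 16)
        for j in range(4):
            if nib & (1 << j) and 4 * i + j < n_bits:
                fp.SetBit(4 * i + j)
    return fp


# ---------------------------------------------------------------------------
# table I/O

def load_ligand_structures(path: str | Path) -> list[LigandRecord]:
    """Read an SDF/MOL file into parsed, fingerprinted records.

    Ligand ids come from the molecule title (``_Name``) or fall back to
    the 1-based record index."""
    from rdkit.Chem import SDMolSupplier
    records = []
    for i, mol in enumerate(SDMolSupplier(str(path), sanitize=True), start=1):
        if mol is None:
            records.append(LigandRecord(ligand_id=f"MOL{i}", valid=False,
                                        reason="unparseable"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(LigandRecord(
            ligand_id=name or f"MOL{i}", smiles=Chem.MolToSmiles(mol),
            mol=mol, descriptors=ligand_descriptors(mol),
            fingerprint=MACCS_fingerprint(mol)))
    return records


def load_ligand_table(path: str | Path) -> list[LigandRecord]:
    """Read a ligand table CSV (columns: ligand_id, smiles[, source_complex])
    and build parsed, fingerprinted records.  Unparseable SMILES yield
    invalid records with reason ``unparseable``."""
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            rec = LigandRecord(ligand_id=row["ligand_id"].strip(),
                               smiles=row.get("smiles"),
                               source_complex=row.get("source_complex"))
            mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
            if mol is None:
                rec.valid = False
                rec.reason = "unparseable"
            else:
                rec.mol = mol
                rec.descriptors = ligand_descriptors(mol)
                rec.fingerprint = MACCS_fingerprint(mol)
            records.append(rec)
    return records
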
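"""Protein mono-chain handling: parsing, sequence-identity clustering, superposition.

Homologous mono-chains are grouped with a greedy two-pass clustering
(families at >90% identity, then family representatives merged at >80%),
and every member of a cluster is rigidly superposed onto a common
reference chain so that pocket coordinates become comparable across
homologs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align

__all__ = [
    "Atom",
    "ProteinChain",
    "LigandInstance",
    "Complex",
    "ChainCluster",
    "Transform",
    "parse_complex",
    "read_complex_dir",
    "sequence_identity",
    "cluster_chains",
    "superpose",
    "kabsch",
    "write_cluster_tables",
    "load_cluster_file",
    "load_transform_file",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a protein chain or ligand."""

    name: str
    element: str
    res_name: str
    res_num: int
    coord: np.ndarray  # shape (3,), Angstrom
    is_sidechain: bool

    def moved(self, coord: np.ndarray) -> "Atom":
        return Atom(self.name, self.element, self.res_name, self.res_num,
                    np.asarray(coord, dtype=float), self.is_sidechain)


@dataclass
class ProteinChain:
    """A protein mono-chain: sequence plus heavy-atom records.

    ``chain_uid`` is ``"<complex id>:<chain id>"``.  Residue numbers are
    1-based and strictly increasing; residues whose name is not one of the
    20 standard amino acids are translated to ``X`` and listed in
    ``nonstandard_residues``.
    """

    chain_uid: str
    sequence: str
    atoms: list[Atom]
    nonstandard_residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._res_nums = sorted({a.res_num for a in self.atoms})

    @property
    def residue_numbers(self) -> list[int]:
        return self._res_nums

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def ca_coords(self) -> dict[int, np.ndarray]:
        """Residue number -> CA coordinate."""
        return {a.res_num: a.coord for a in self.atoms if a.name == "CA"}

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LigandInstance:
    """A co-crystallized ligand occurrence inside one complex."""

    ligand_id: str          # Het-code-like identifier (PDB residue name)
    complex_id: str
    res_num: int
    coords: np.ndarray      # (n, 3) heavy-atom coordinates
    elements: list[str]


@dataclass
class Complex:
    complex_id: str
    chains: list[ProteinChain]
    ligands: list[LigandInstance]


_SOLVENT_RESNAMES = {"HOH", "WAT", "DOD"}


def parse_complex(path: str | Path, complex_id: str | None = None) -> Complex:
    """Read a PDB file into protein chains (ATOM) and ligands (HETATM).

    Only the first model of multi-model files is used.  Waters are
    dropped; every other HETATM residue becomes a :class:`LigandInstance`.
    Hydrogens, if present, are ignored.
    """
    path = Path(path)
    if complex_id is None:
        complex_id = path.stem
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no model in {path}")
    model = st[0]
    chains: list[ProteinChain] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        atoms: list[Atom] = []
        seq_parts: list[str] = []
        nonstd: list[int] = []
        last_num: int | None = None
        for res in chain:
            rname = res.name.strip()
            if res.het_flag == "H":
                if rname in _SOLVENT_RESNAMES:
                    continue
                coords, elements = _heavy_atoms(res)
                if len(coords):
                    ligands.append(LigandInstance(
                        ligand_id=rname, complex_id=complex_id,
                        res_num=res.seqid.num, coords=np.array(coords),
                        elements=elements))
                continue
            num = res.seqid.num
            if last_num is not None and num <= last_num:
                raise ValueError(
                    f"{path}: residue numbers not strictly increasing in chain {chain.name}")
            last_num = num
            one = AA3_TO_1.get(rname)
            if one is None:
                one = "X"
                nonstd.append(num)
            seq_parts.append(one)
            for at in res:
                if at.element.name == "H":
                    continue
                atoms.append(Atom(
                    name=at.name.strip(), element=at.element.name,
                    res_name=rname, res_num=num,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_sidechain=at.name.strip() not in BACKBONE_ATOM_NAMES))
        if atoms:
            chains.append(ProteinChain(
                chain_uid=f"{complex_id}:{chain.name}",
                sequence="".join(seq_parts), atoms=atoms,
                nonstandard_residues=nonstd))
    return Complex(complex_id=complex_id, chains=chains, ligands=ligands)


def _heavy_atoms(res: "gemmi.Residue") -> tuple[list[list[float]], list[str]]:
    coords, elements = [], []
    for at in res:
        if at.element.name == "H":
            continue
        coords.append([at.pos.x, at.pos.y, at.pos.z])
        elements.append(at.element.name)
    return coords, elements


def read_complex_dir(in_dir: str | Path, pattern: str = "*.pdb") -> list[Complex]:
    return [parse_complex(p) for p in sorted(Path(in_dir).glob(pattern))]


# ---------------------------------------------------------------------------
# sequence identity

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def _aligned_pairs(seq_a: str, seq_b: str) -> tuple[list[tuple[int, int]], int]:
    """Aligned (i, j) index pairs of the best global alignment and its column count."""
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    n_aligned = sum(a1 - a0 for a0, a1 in blocks_a)
    n_cols = len(seq_a) + len(seq_b) - n_aligned
    return pairs, n_cols


def sequence_identity(seq_a: str, seq_b: str, denominator: str = "shorter") -> float:
    """Global-alignment sequence identity between two amino-acid strings.

    Scoring is unit-based for determinism: match +1, mismatch 0, affine
    gaps (open -10, extend -0.5).  ``denominator="shorter"`` divides the
    match count by the shorter sequence length (the CD-HIT convention,
    the default); ``"alignment"`` divides by the number of alignment
    columns including gap columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequence_identity requires non-empty sequences")
    pairs, n_cols = _aligned_pairs(seq_a, seq_b)
    matches = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    if denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "alignment":
        denom = n_cols
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return matches / denom


# ---------------------------------------------------------------------------
# rigid superposition

@dataclass
class Transform:
    """Proper rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray    # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Transform":
        return cls(np.array(d["rotation"], dtype=float),
                   np.array(d["translation"], dtype=float))


class SuperpositionError(ValueError):
    pass


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper-rotation transform and the post-fit RMSD.  Raises
    :class:`SuperpositionError` for fewer than 3 point pairs or for
    degenerate (collinear) point sets, where the rotation about the line
    axis is undetermined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 aligned point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear inputs: covariance rank < 2
    scale = max(S[0], 1e-12)
    if S[1] / scale < 1e-8:
        raise SuperpositionError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Transform(R, t), rmsd


def superpose(member: ProteinChain, reference: ProteinChain
              ) -> tuple[Transform, float, dict[int, int]]:
    """Superpose ``member`` onto ``reference`` over sequence-aligned CA atoms.

    Returns (transform, RMSD, residue map) where the residue map sends
    member residue numbers to the aligned reference residue numbers.
    """
    pairs, _ = _aligned_pairs(member.sequence, reference.sequence)
    mem_nums = member.residue_numbers
    ref_nums = reference.residue_numbers
    ca_m = member.ca_coords()
    ca_r = reference.ca_coords()
    residue_map: dict[int, int] = {}
    P, Q = [], []
    for i, j in pairs:
        rm, rr = mem_nums[i], ref_nums[j]
        residue_map[rm] = rr
        if rm in ca_m and rr in ca_r:
            P.append(ca_m[rm])
            Q.append(ca_r[rr])
    if len(P) < 3:
        raise SuperpositionError(
            f"only {len(P)} aligned CA pairs between {member.chain_uid} "
            f"and {reference.chain_uid}")
    transform, rmsd = kabsch(np.array(P), np.array(Q))
    return transform, rmsd, residue_map


# ---------------------------------------------------------------------------
# greedy two-pass clustering

@dataclass
class ChainCluster:
    """Homologous chains superposed onto a common reference frame."""

    cluster_id: str
    member_uids: list[str]
    reference_uid: str
    transforms: dict[str, Transform] = field(default_factory=dict)
    rmsds: dict[str, float] = field(default_factory=dict)
    residue_maps: dict[str, dict[int, int]] = field(default_factory=dict)


def _greedy_pass(items: Sequence[ProteinChain], threshold: float,
                 denominator: str) -> list[list[ProteinChain]]:
    """CD-HIT-style greedy clustering: longest-first, join the first
    existing group whose representative identity exceeds ``threshold``."""
    ordered = sorted(items, key=lambda c: (-len(c), c.chain_uid))
    groups: list[list[ProteinChain]] = []
    for chain in ordered:
        for group in groups:
            rep = group[0]
            if sequence_identity(chain.sequence, rep.sequence, denominator) > threshold:
                group.append(chain)
                break
        else:
            groups.append([chain])
    return groups


def cluster_chains(chains: Sequence[ProteinChain], t1: float = 0.90,
                   t2: float = 0.80, denominator: str = "shorter",
                   superpose_members: bool = True) -> list[ChainCluster]:
    """Two-pass homologous chain clustering.

    Pass 1 groups chains into families at identity > ``t1``; pass 2
    reruns the greedy pass on family representatives at > ``t2`` and
    merges the corresponding families.  The reference chain of each
    cluster is its longest member (ties broken by uid) and all members
    are superposed onto it.
    """
    if t2 > t1:
        raise ValueError("t2 must be <= t1")
    if not chains:
        return []
    families = _greedy_pass(chains, t1, denominator)
    reps = [fam[0] for fam in families]
    rep_groups = _greedy_pass(reps, t2, denominator)
    rep_to_family = {fam[0].chain_uid: fam for fam in families}

    clusters: list[ChainCluster] = []
    merged: list[list[ProteinChain]] = []
    for group in rep_groups:
        members: list[ProteinChain] = []
        for rep in group:
            members.extend(rep_to_family[rep.chain_uid])
        merged.append(members)
    # deterministic ordering/ids by reference uid
    merged.sort(key=lambda ms: min(m.chain_uid for m in ms))
    for idx, members in enumerate(merged, start=1):
        reference = sorted(members, key=lambda c: (-len(c), c.chain_uid))[0]
        cluster = ChainCluster(
            cluster_id=f"CC{idx}",
            member_uids=sorted(m.chain_uid for m in members),
            reference_uid=reference.chain_uid)
        if superpose_members:
            for m in sorted(members, key=lambda c: c.chain_uid):
                if m.chain_uid == reference.chain_uid:
                    cluster.transforms[m.chain_uid] = Transform.identity()
                    cluster.rmsds[m.chain_uid] = 0.0
                    cluster.residue_maps[m.chain_uid] = {
                        n: n for n in m.residue_numbers}
                else:
                    tr, rmsd, rmap = superpose(m, reference)
                    cluster.transforms[m.chain_uid] = tr
                    cluster.rmsds[m.chain_uid] = rmsd
                    cluster.residue_maps[m.chain_uid] = rmap
        clusters.append(cluster)
    return clusters


# ---------------------------------------------------------------------------
# import/export hooks

def write_cluster_tables(clusters: Iterable[ChainCluster], out_dir: str | Path) -> None:
    """Write membership CSV and a JSON transform table (row-major 3x3 + 3-vector)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["cluster_id,chain_uid,is_reference,rmsd"]
    transforms: dict[str, dict] = {}
    for cl in clusters:
        for uid in cl.member_uids:
            is_ref = int(uid == cl.reference_uid)
            rmsd = cl.rmsds.get(uid, float("nan"))
            lines.append(f"{cl.cluster_id},{uid},{is_ref},{rmsd:.6f}")
            if uid in cl.transforms:
                transforms.setdefault(cl.cluster_id, {})[uid] = cl.transforms[uid].to_dict()
    (out_dir / "chain_clusters.csv").write_text("\n".join(lines) + "\n")
    (out_dir / "transforms.json").write_text(json.dumps(transforms, indent=1, sort_keys=True))


def load_cluster_file(path: str | Path) -> list[ChainCluster]:
    """Import hook: read a precomputed membership table (e.g. from an
    external clustering tool) in the CSV layout written by
    :func:`write_cluster_tables`.  Transforms are left empty."""
    rows = Path(path).read_text().strip().splitlines()[1:]
    by_id: dict[str, ChainCluster] = {}
    for row in rows:
        cid, uid, is_ref, _ = row.split(",")
        cl = by_id.setdefault(cid, ChainCluster(cid, [], uid))
        cl.member_uids.append(uid)
        if is_ref == "1":
            cl.reference_uid = uid
    return [by_id[k] for k in sorted(by_id)]


def load_transform_file(path: str | Path) -> dict[str, dict[str, Transform]]:
    """Import hook: read a transform table (e.g. exported from an external
    structure-alignment tool) in the JSON layout of :func:`write_cluster_tables`."""
    raw = json.loads(Path(path).read_text())
    return {cid: {uid: Transform.from_dict(d) for uid, d in uids.items()}
            for cid, uids in raw.items()}
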
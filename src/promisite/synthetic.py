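"""Synthetic protein-ligand complex generator with planted ground truth.

The generator emulates the statistical structure a binding-site
promiscuity analysis consumes: families of homologous mono-chains at a
controlled sequence identity, one or more spatially distinct binding
sites per family, drug-like ligands co-crystallized in those sites, and
ligand families at a controlled MACCS-Tanimoto similarity.  Every
generated pocket, chain and ligand is recorded in a ground-truth table
so downstream clustering and promiscuity labels can be checked exactly.

Chains are poly-residue backbones laid out on a smooth self-avoiding
helix with one pseudo-atom set per residue (N, CA, C, O plus up to five
side-chain pseudo-atoms chosen by residue type).  The geometry is
deliberately schematic -- pocket extraction and descriptors need atom
element/residue identity and plausible distances, not physical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .chains import AA1_TO_3
from .ligands import MACCS_fingerprint, tanimoto, ligand_descriptors, druglike_filter

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "ScenarioError",
    "generate_scenario",
    "perturb_coordinates",
    "evaluate_recovery",
    "LIGAND_FAMILY_POOLS",
]


class ScenarioError(ValueError):
    """Raised when a scenario cannot be realized; no partial output is left."""


# ---------------------------------------------------------------------------
# residue-level pseudo-atom geometry

# Up to five representative side-chain heavy atoms per residue type.
# Characteristic heteroatoms (Tyr OH, Trp NE1, Cys/Met S, ...) are kept so
# element- and residue-specific pocket descriptors are exercised.
SIDECHAIN_ATOMS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CB", "C")],
    "ARG": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C")],
    "ASN": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "ASP": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "CYS": [("CB", "C"), ("SG", "S")],
    "GLN": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("NE2", "N")],
    "GLU": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "GLY": [],
    "HIS": [("CB", "C"), ("CG", "C"), ("ND1", "N"), ("CE1", "C"), ("NE2", "N")],
    "ILE": [("CB", "C"), ("CG1", "C"), ("CG2", "C"), ("CD1", "C")],
    "LEU": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")],
    "LYS": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "MET": [("CB", "C"), ("CG", "C"), ("SD", "S"), ("CE", "C")],
    "PHE": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CE1", "C"), ("CZ", "C")],
    "PRO": [("CB", "C"), ("CG", "C"), ("CD", "C")],
    "SER": [("CB", "C"), ("OG", "O")],
    "THR": [("CB", "C"), ("OG1", "O"), ("CG2", "C")],
    "TRP": [("CB", "C"), ("CG", "C"), ("NE1", "N"), ("CZ2", "C"), ("CH2", "C")],
    "TYR": [("CB", "C"), ("CG", "C"), ("CZ", "C"), ("OH", "O")],
    "VAL": [("CB", "C"), ("CG1", "C"), ("CG2", "C")],
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Helix layout: tangential step R*omega and axial rise per residue give a
# CA-CA spacing of ~3.8 A, the physical virtual-bond length.
HELIX_RADIUS = 10.0
HELIX_OMEGA = 0.35     # rad per residue
HELIX_RISE = 1.5       # A per residue
ANCHOR_INSET = 4.0     # A, site anchor offset from the center CA toward the axis
LIGAND_SPREAD_SD = 1.1  # A, ligand heavy-atom scatter around the anchor
LIGAND_MAX_RADIUS = 2.2


# ---------------------------------------------------------------------------
# ligand family pools

# Each pool is one chemotype whose members are ring-position isomers and
# short homologs of a decorated core; MACCS keys are largely insensitive
# to substitution position, which keeps within-pool Tanimoto high while
# distinct chemotypes stay well below the clustering threshold.
LIGAND_FAMILY_POOLS: list[tuple[str, list[str]]] = [
    ("carbazole", [
        "Cc1ccc2[nH]c3ccccc3c2c1", "Cc1ccc2c(c1)[nH]c1ccccc12",
        "Cc1cccc2[nH]c3ccccc3c12", "CCc1ccc2[nH]c3ccccc3c2c1",
        "Cc1ccc2[nH]c3ccc(C)cc3c2c1", "CCc1ccc2c(c1)[nH]c1ccccc12",
        "Cc1ccc2[nH]c3cccc(C)c3c2c1", "CCc1cccc2[nH]c3ccccc3c12"]),
    ("flavone", [
        "O=c1cc(-c2ccccc2)oc2ccccc12", "O=c1cc(-c2ccccc2)oc2ccc(C)cc12",
        "O=c1cc(-c2ccc(C)cc2)oc2ccccc12", "O=c1cc(-c2ccccc2)oc2cc(C)ccc12",
        "O=c1cc(-c2cccc(C)c2)oc2ccccc12", "O=c1cc(-c2ccc(CC)cc2)oc2ccccc12",
        "O=c1cc(-c2ccccc2)oc2c(C)cccc12", "O=c1cc(-c2ccccc2C)oc2ccccc12"]),
    ("sulfaquinoline", [
        "O=S(=O)(Nc1ccccc1)c1ccc2ncccc2c1", "O=S(=O)(Nc1ccc(C)cc1)c1ccc2ncccc2c1",
        "O=S(=O)(Nc1cccc(C)c1)c1ccc2ncccc2c1", "O=S(=O)(Nc1ccccc1C)c1ccc2ncccc2c1",
        "O=S(=O)(Nc1ccc(CC)cc1)c1ccc2ncccc2c1", "O=S(=O)(Nc1ccccc1)c1ccc2cnccc2c1",
        "O=S(=O)(Nc1ccc(C)cc1C)c1ccc2ncccc2c1"]),
    ("acridinediamine", [
        "Nc1ccc2nc3ccccc3c(N)c2c1", "Nc1ccc2nc3ccc(C)cc3c(N)c2c1",
        "Cc1cc2nc3ccccc3c(N)c2cc1N", "Nc1ccc2nc3cc(C)ccc3c(N)c2c1",
        "Nc1ccc2nc3ccc(CC)cc3c(N)c2c1", "Nc1cc(C)c2nc3ccccc3c(N)c2c1",
        "CCc1cc2nc3ccccc3c(N)c2cc1N"]),
    ("anthraquinone", [
        "O=C1c2ccccc2C(=O)c2ccccc21", "Cc1ccc2c(c1)C(=O)c1ccccc1C2=O",
        "O=C1c2ccccc2C(=O)c2ccc(C)cc21", "Cc1ccc2c(c1)C(=O)c1ccc(C)cc1C2=O",
        "CCc1ccc2c(c1)C(=O)c1ccccc1C2=O", "O=C1c2cccc(C)c2C(=O)c2ccccc21"]),
    ("biphenylnitrile", [
        "N#Cc1ccc(-c2ccccc2)cc1", "N#Cc1ccc(-c2ccc(C)cc2)cc1",
        "N#Cc1ccc(-c2cccc(C)c2)cc1", "N#Cc1cccc(-c2ccccc2)c1",
        "N#Cc1ccc(-c2ccc(CC)cc2)cc1", "N#Cc1ccc(-c2ccccc2C)cc1",
        "N#Cc1cc(C)cc(-c2ccccc2)c1"]),
    ("phenothiazine", [
        "Cc1ccc2Nc3ccccc3Sc2c1", "Cc1ccc2Sc3ccccc3Nc2c1",
        "Cc1cccc2Sc3ccccc3Nc12", "CCc1ccc2Nc3ccccc3Sc2c1",
        "Cc1ccc2Nc3ccc(C)cc3Sc2c1", "CCc1ccc2Sc3ccccc3Nc2c1"]),
    ("nitroquinoxaline", [
        "O=[N+]([O-])c1ccc2nccnc2c1", "Cc1ccc2nccnc2c1[N+](=O)[O-]",
        "O=[N+]([O-])c1ccc2ncc(C)nc2c1", "Cc1cnc2cc([N+](=O)[O-])ccc2n1",
        "O=[N+]([O-])c1ccc2nccnc2c1C", "CCc1cnc2cc([N+](=O)[O-])ccc2n1"]),
    ("pyrenol", [
        "Oc1ccc2ccc3cccc4ccc1c2c34", "Oc1ccc2ccc3ccc(C)c4ccc1c2c34",
        "Oc1ccc2ccc3cc(C)cc4ccc1c2c34", "Oc1cc(C)c2ccc3cccc4ccc1c2c34"]),
    ("benzothiadiazoleamine", [
        "Nc1ccc2nsnc2c1", "Nc1ccc2nsnc2c1C", "Cc1ccc2nsnc2c1N",
        "Nc1cc(C)c2nsnc2c1", "CCc1ccc2nsnc2c1N"]),
]


# ---------------------------------------------------------------------------
# scenario / ground truth

@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``sites_per_family`` may be a single count or a per-family sequence.
    ``planted_promiscuity`` maps site ids (``"F<f>S<s>"``) to the number
    of distinct ligand families bound there; unspecified sites cycle
    through 1, 2 and 4 families (selective / moderately promiscuous /
    highly promiscuous).  The same seed and scenario always produce
    byte-identical output files.
    """

    seed: int = 0
    n_chain_families: int = 3
    chains_per_family: int = 4
    within_family_identity: float = 0.92
    sites_per_family: int | Sequence[int] = 2
    pockets_per_site: int = 5
    site_separation: float = 25.0
    ligand_families: int = 4
    ligands_per_family: int = 3
    within_family_tanimoto: float = 0.8
    planted_promiscuity: Mapping[str, int] | None = None
    coordinate_noise_sd: float = 0.25
    n_residues: int = 110

    def sites_for(self, family: int) -> int:
        if isinstance(self.sites_per_family, int):
            return self.sites_per_family
        return int(self.sites_per_family[family])

    def validate(self) -> None:
        counts = [self.n_chain_families, self.chains_per_family,
                  self.pockets_per_site, self.ligand_families,
                  self.ligands_per_family, self.n_residues]
        counts += [self.sites_for(f) for f in range(self.n_chain_families)]
        if any(c < 1 for c in counts):
            raise ScenarioError("all counts must be >= 1")
        for frac, name in [(self.within_family_identity, "within_family_identity"),
                           (self.within_family_tanimoto, "within_family_tanimoto")]:
            if not 0.0 <= frac <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1]")
        if self.site_separation <= 0:
            raise ScenarioError("site_separation must be > 0")
        if self.coordinate_noise_sd < 0:
            raise ScenarioError("coordinate_noise_sd must be >= 0")
        if self.ligand_families > len(LIGAND_FAMILY_POOLS):
            raise ScenarioError(
                f"at most {len(LIGAND_FAMILY_POOLS)} ligand families are available")


PROMISCUITY_CYCLE = (1, 2, 4)


def promiscuity_label(n_ligand_clusters: int, n_pockets: int | None = None) -> str:
    """S / MP / HP label from the number of distinct ligand clusters bound.

    A site observed through a single pocket cannot be characterized and
    is labeled UNDETERMINED when ``n_pockets`` is given as 1.
    """
    if n_pockets is not None and n_pockets == 1:
        return "UNDETERMINED"
    if n_ligand_clusters <= 1:
        return "S"
    if n_ligand_clusters <= 3:
        return "MP"
    return "HP"


@dataclass
class GroundTruth:
    """Planted labels: chain->family, pocket->site, ligand->family, site->label."""

    chain_family: dict[str, str]
    pocket_site: dict[str, str]
    ligand_family: dict[str, str]
    site_n_ligand_families: dict[str, int]
    ligand_smiles: dict[str, str] = field(default_factory=dict)

    @property
    def site_labels(self) -> dict[str, str]:
        pockets_per_site: dict[str, int] = {}
        for site in self.pocket_site.values():
            pockets_per_site[site] = pockets_per_site.get(site, 0) + 1
        return {s: promiscuity_label(n, pockets_per_site.get(s))
                for s, n in self.site_n_ligand_families.items()}

    def to_csv(self, path: str | Path) -> None:
        lines = ["record,key,value"]
        for name, mapping in [("chain_family", self.chain_family),
                              ("pocket_site", self.pocket_site),
                              ("ligand_family", self.ligand_family),
                              ("site_n_ligand_families", self.site_n_ligand_families)]:
            for k in sorted(mapping):
                lines.append(f"{name},{k},{mapping[k]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        maps: dict[str, dict] = {"chain_family": {}, "pocket_site": {},
                                 "ligand_family": {}, "site_n_ligand_families": {}}
        for line in Path(path).read_text().strip().splitlines()[1:]:
            record, key, value = line.split(",", 2)
            maps[record][key] = int(value) if record == "site_n_ligand_families" else value
        return cls(**maps)


# ---------------------------------------------------------------------------
# coordinate noise

def perturb_coordinates(coords: np.ndarray, sd: float,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Add isotropic Gaussian noise of standard deviation ``sd`` (A) per axis.

    ``sd = 0`` returns an unchanged copy.  Exactly one of ``seed``/``rng``
    supplies the randomness.
    """
    coords = np.asarray(coords, dtype=float)
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return coords.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, sd, coords.shape)


# ---------------------------------------------------------------------------
# generation internals

def _helix_frame(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CA position, unit tangent and outward radial unit vector at residue i."""
    a = HELIX_OMEGA * i
    pos = np.array([HELIX_RADIUS * math.cos(a), HELIX_RADIUS * math.sin(a),
                    HELIX_RISE * i])
    tangent = np.array([-HELIX_RADIUS * HELIX_OMEGA * math.sin(a),
                        HELIX_RADIUS * HELIX_OMEGA * math.cos(a), HELIX_RISE])
    tangent /= np.linalg.norm(tangent)
    outward = np.array([math.cos(a), math.sin(a), 0.0])
    return pos, tangent, outward


def _mutate_sequence(base: str, n_mut: int, rng: np.random.Generator) -> str:
    seq = list(base)
    if n_mut == 0:
        return base
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for p in positions:
        choices = [a for a in AA_ALPHABET if a != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _build_ligand_families(scenario: SyntheticScenario) -> list[list[tuple[str, str]]]:
    """Per family: list of (ligand_code, smiles) accepted by
    acceptance-rejection against the within-family Tanimoto band and the
    drug-likeness rules."""
    families: list[list[tuple[str, str]]] = []
    all_fps: list[list] = []
    for f in range(scenario.ligand_families):
        pool_name, pool = LIGAND_FAMILY_POOLS[f]
        accepted: list[tuple[str, str]] = []
        fps: list = []
        for smi in pool:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            desc = ligand_descriptors(mol)
            if not druglike_filter(desc):
                continue
            fp = MACCS_fingerprint(mol)
            if all(tanimoto(fp, other) >= scenario.within_family_tanimoto
                   for other in fps):
                code = f"X{f}{chr(65 + len(accepted))}"
                accepted.append((code, smi))
                fps.append(fp)
            if len(accepted) == scenario.ligands_per_family:
                break
        if len(accepted) < scenario.ligands_per_family:
            raise ScenarioError(
                f"ligand family {pool_name!r}: only {len(accepted)} of "
                f"{scenario.ligands_per_family} members satisfy the "
                f"Tanimoto >= {scenario.within_family_tanimoto} band")
        families.append(accepted)
        all_fps.append(fps)
    # distinct families must stay separable at the clustering threshold
    for i in range(len(all_fps)):
        for j in range(i + 1, len(all_fps)):
            worst = max(tanimoto(a, b) for a in all_fps[i] for b in all_fps[j])
            if worst >= scenario.within_family_tanimoto:
                raise ScenarioError(
                    f"ligand families {i} and {j} overlap at Tanimoto {worst:.2f}")
    return families


def _pdb_atom_line(serial: int, name: str, res_name: str, chain_id: str,
                   res_num: int, coord: np.ndarray, element: str,
                   hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record}{serial:>5d} {name_field} {res_name:<3s} {chain_id}"
            f"{res_num:>4d}    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


@dataclass
class _FamilyGeometry:
    sidechain_jitter: np.ndarray      # (n_res, 5, 3)
    site_centers: list[int]           # residue indices (0-based)
    site_anchors: list[np.ndarray]


def _family_geometry(scenario: SyntheticScenario, family: int,
                     rng: np.random.Generator) -> _FamilyGeometry:
    n = scenario.n_residues
    jitter = rng.normal(0.0, 0.35, size=(n, 5, 3))
    n_sites = scenario.sites_for(family)
    step = math.ceil(scenario.site_separation / HELIX_RISE)
    margin = 8
    last_center = margin + (n_sites - 1) * step
    if last_center >= n - margin:
        raise ScenarioError(
            f"cannot place {n_sites} sites {scenario.site_separation} A apart "
            f"on a {n}-residue chain")
    centers = [margin + s * step for s in range(n_sites)]
    anchors = []
    for c in centers:
        ca, _, outward = _helix_frame(c)
        anchors.append(ca - ANCHOR_INSET * outward)
    # planted-site separation invariant, asserted on generated coordinates
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            d = float(np.linalg.norm(anchors[i] - anchors[j]))
            if d < scenario.site_separation:
                raise ScenarioError(
                    f"sites {i} and {j} of family {family} are {d:.1f} A apart")
    return _FamilyGeometry(jitter, centers, anchors)


def _chain_atoms(sequence: str, geom: _FamilyGeometry
                 ) -> list[tuple[str, str, str, int, np.ndarray]]:
    """(atom_name, element, res_name3, res_num, coord) records for one chain."""
    atoms = []
    for i, aa in enumerate(sequence):
        res3 = AA1_TO_3[aa]
        num = i + 1
        ca, tangent, outward = _helix_frame(i)
        normal = np.cross(tangent, outward)
        atoms.append(("N", "N", res3, num, ca - 1.2 * tangent))
        atoms.append(("CA", "C", res3, num, ca))
        atoms.append(("C", "C", res3, num, ca + 1.2 * tangent))
        atoms.append(("O", "O", res3, num, ca + 1.2 * tangent + 1.2 * normal))
        for k, (name, element) in enumerate(SIDECHAIN_ATOMS[res3]):
            pos = ca + outward * 1.45 * (k + 1) + geom.sidechain_jitter[i, k]
            atoms.append((name, element, res3, num, pos))
    return atoms


def generate_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> GroundTruth:
    """Write one PDB file per synthetic complex plus ligand and ground-truth
    tables into ``out_dir`` and return the planted :class:`GroundTruth`.

    Each complex holds one chain (a family member) and one ligand placed
    at one planted site; a random rigid transform and Gaussian coordinate
    noise are applied per complex.  Unsatisfiable scenarios raise
    :class:`ScenarioError` before any file is written.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)

    ligand_families = _build_ligand_families(scenario)

    # --- plan everything before touching the filesystem
    n = scenario.n_residues
    n_mut = int(math.floor(n * (1.0 - scenario.within_family_identity) / 2.0))
    plan_complexes = []
    chain_family: dict[str, str] = {}
    pocket_site: dict[str, str] = {}
    site_counts: dict[str, int] = {}
    ligand_family_map: dict[str, str] = {}
    ligand_smiles: dict[str, str] = {}
    for f, members in enumerate(ligand_families):
        for code, smi in members:
            ligand_family_map[code] = f"LF{f}"
            ligand_smiles[code] = smi

    planted = dict(scenario.planted_promiscuity or {})
    geoms = []
    variant_seqs: list[list[str]] = []
    for fam in range(scenario.n_chain_families):
        geom = _family_geometry(scenario, fam, rng)
        geoms.append(geom)
        base = "".join(AA_ALPHABET[k] for k in rng.integers(0, 20, size=n))
        variant_seqs.append([_mutate_sequence(base, n_mut, rng)
                             for _ in range(scenario.chains_per_family)])

    site_index = 0
    fam_pointer = 0
    instance_counter = [0] * scenario.ligand_families
    for fam in range(scenario.n_chain_families):
        for s in range(scenario.sites_for(fam)):
            site_id = f"F{fam}S{s}"
            L = planted.get(site_id)
            if L is None:
                # auto assignment cycles S/MP/HP but stays feasible
                L = min(PROMISCUITY_CYCLE[site_index % len(PROMISCUITY_CYCLE)],
                        scenario.pockets_per_site, scenario.ligand_families)
            if L > scenario.pockets_per_site:
                raise ScenarioError(
                    f"site {site_id}: {L} ligand families need at least "
                    f"{L} pockets (have {scenario.pockets_per_site})")
            if L > scenario.ligand_families:
                raise ScenarioError(
                    f"site {site_id}: {L} ligand families requested but only "
                    f"{scenario.ligand_families} exist")
            site_counts[site_id] = L
            fams_here = [(fam_pointer + i) % scenario.ligand_families for i in range(L)]
            fam_pointer += 1
            for j in range(scenario.pockets_per_site):
                lf = fams_here[j % L]
                inst = instance_counter[lf] % scenario.ligands_per_family
                instance_counter[lf] += 1
                code, _ = ligand_families[lf][inst]
                variant = j % scenario.chains_per_family
                complex_id = f"F{fam}S{s}P{j}"
                plan_complexes.append((complex_id, fam, variant, s, code))
                chain_family[f"{complex_id}:A"] = f"CF{fam}"
                pocket_site[f"{complex_id}|{code}"] = site_id
            site_index += 1

    # --- emit files
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    smiles_mol_cache = {smi: Chem.MolFromSmiles(smi) for smi in ligand_smiles.values()}
    for complex_id, fam, variant, s, code in plan_complexes:
        geom = geoms[fam]
        sequence = variant_seqs[fam][variant]
        prot = _chain_atoms(sequence, geom)
        mol = smiles_mol_cache[ligand_smiles[code]]
        n_heavy = mol.GetNumHeavyAtoms()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        offsets = rng.normal(0.0, LIGAND_SPREAD_SD, size=(n_heavy, 3))
        norms = np.linalg.norm(offsets, axis=1, keepdims=True)
        offsets = np.where(norms > LIGAND_MAX_RADIUS,
                           offsets * (LIGAND_MAX_RADIUS / norms), offsets)
        lig_coords = geom.site_anchors[s] + offsets

        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-30.0, 30.0, size=3)
        prot_xyz = np.array([rec[4] for rec in prot]) @ rot.T + trans
        lig_xyz = lig_coords @ rot.T + trans
        all_xyz = np.vstack([prot_xyz, lig_xyz])
        all_xyz = perturb_coordinates(all_xyz, scenario.coordinate_noise_sd, rng=rng)
        prot_xyz, lig_xyz = all_xyz[:len(prot)], all_xyz[len(prot):]

        lines = []
        serial = 1
        for (name, element, res3, num, _), xyz in zip(prot, prot_xyz):
            lines.append(_pdb_atom_line(serial, name, res3, "A", num, xyz,
                                        element, hetero=False))
            serial += 1
        for k, xyz in enumerate(lig_xyz):
            lines.append(_pdb_atom_line(serial, f"{elements[k]}{k + 1}", code,
                                        "A", 900, xyz, elements[k], hetero=True))
            serial += 1
        lines.append("END")
        (out_dir / f"{complex_id}.pdb").write_text("\n".join(lines) + "\n")

    lig_lines = ["ligand_id,smiles,family"]
    for code in sorted(ligand_smiles):
        lig_lines.append(f"{code},{ligand_smiles[code]},{ligand_family_map[code]}")
    (out_dir / "ligands.csv").write_text("\n".join(lig_lines) + "\n")

    truth = GroundTruth(chain_family=chain_family, pocket_site=pocket_site,
                        ligand_family=ligand_family_map,
                        site_n_ligand_families=site_counts,
                        ligand_smiles=ligand_smiles)
    truth.to_csv(out_dir / "ground_truth.csv")
    return truth


# ---------------------------------------------------------------------------
# recovery scoring

def evaluate_recovery(truth: GroundTruth,
                      dbs_labels: Mapping[str, str],
                      pocket_to_dbs: Mapping[str, str]) -> dict:
    """Compare recovered pocket clusters against the planted sites.

    ``dbs_labels`` maps recovered DBS ids to promiscuity labels and
    ``pocket_to_dbs`` maps pocket ids to DBS ids.  Recovery is exact when
    the recovered partition of pockets equals the planted site partition
    and every label matches the planted label.
    """
    sites = sorted(set(truth.pocket_site.values()))
    site_labels = truth.site_labels
    dbs_to_pockets: dict[str, set[str]] = {}
    for pocket, dbs in pocket_to_dbs.items():
        dbs_to_pockets.setdefault(dbs, set()).add(pocket)
    site_to_pockets: dict[str, set[str]] = {}
    for pocket, site in truth.pocket_site.items():
        site_to_pockets.setdefault(site, set()).add(pocket)

    partition_match = (sorted(map(sorted, dbs_to_pockets.values()))
                       == sorted(map(sorted, site_to_pockets.values())))
    n_correct = 0
    n_sites_recovered = 0
    for site, pockets in site_to_pockets.items():
        match = [dbs for dbs, members in dbs_to_pockets.items() if members == pockets]
        if match:
            n_sites_recovered += 1
            if dbs_labels.get(match[0]) == site_labels[site]:
                n_correct += 1
    return {
        "n_sites_planted": len(sites),
        "n_dbs_recovered": len(dbs_to_pockets),
        "partition_exact": bool(partition_match),
        "n_sites_recovered_exactly": n_sites_recovered,
        "label_accuracy": n_correct / len(sites) if sites else float("nan"),
    }


def reference_scenario(seed: int = 1) -> SyntheticScenario:
    """The package's reference study: five chain families with one to
    three planted sites each (nine sites), planted promiscuity covering
    selective, moderately and highly promiscuous levels, 25 A site
    separation and five pockets per site (so every site passes the
    four-pocket occurrence filter)."""
    return SyntheticScenario(
        seed=seed,
        n_chain_families=5,
        chains_per_family=4,
        within_family_identity=0.92,
        sites_per_family=(1, 2, 3, 2, 1),
        pockets_per_site=5,
        site_separation=25.0,
        ligand_families=6,
        ligands_per_family=4,
        within_family_tanimoto=0.8,
        planted_promiscuity={
            "F0S0": 1, "F1S0": 2, "F1S1": 4, "F2S0": 1, "F2S1": 3,
            "F2S2": 4, "F3S0": 2, "F3S1": 4, "F4S0": 1,
        },
        coordinate_noise_sd=0.25,
    )


def scenario_to_dict(scenario: SyntheticScenario) -> dict:
    d = asdict(scenario)
    if not isinstance(d["sites_per_family"], int):
        d["sites_per_family"] = list(d["sites_per_family"])
    if d["planted_promiscuity"] is not None:
        d["planted_promiscuity"] = dict(d["planted_promiscuity"])
    return d
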
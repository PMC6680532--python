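"""Ligand-binding pocket estimation by proximity and pocket descriptors.

A pocket is the set of protein heavy atoms within a proximity threshold
(default 5.5 A, inclusive) of any heavy atom of one co-crystallized
ligand.  Pockets whose ligand also contacts a second chain of the same
complex sit at a chain-chain interface and are omitted.  Each pocket
carries its barycenter g(i) (unweighted atom-coordinate mean), its
radius dmax(i) (largest barycenter-to-atom distance) and a 72-slot
descriptor vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree, ConvexHull
from scipy.spatial import QhullError

from .chains import Atom, Complex, ProteinChain, Transform

__all__ = [
    "Pocket",
    "EmptyPocketError",
    "extract_pocket",
    "assign_ligand_chains",
    "interface_filter",
    "extract_complex_pockets",
    "pocket_descriptors",
    "POCKET_DESCRIPTOR_NAMES",
    "KYTE_DOOLITTLE",
]


class EmptyPocketError(ValueError):
    """The ligand is too far from the chain: no atom within the threshold."""


# Kyte-Doolittle residue hydropathy scale.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

RESIDUE_CLASSES = {
    "aliphatic": {"ALA", "VAL", "LEU", "ILE"},
    "aromatic": {"PHE", "TRP", "TYR", "HIS"},
    "charged": {"ASP", "GLU", "LYS", "ARG", "HIS"},
    "polar": {"SER", "THR", "ASN", "GLN", "CYS", "TYR", "TRP", "HIS"},
    "tiny": {"GLY", "ALA", "SER", "CYS"},
}

STANDARD_RESIDUES = tuple(sorted(KYTE_DOOLITTLE))


@dataclass
class Pocket:
    """Protein heavy atoms around one bound ligand.

    ``atom_keys`` give the atom correspondence used by the score of
    overlap: within one chain a key is ``(residue number, atom name)``;
    after mapping into a chain-cluster reference frame it is the aligned
    reference residue position plus atom name.  ``frame`` names the
    reference frame (a chain-cluster id) once mapped.
    """

    pocket_id: str
    chain_uid: str
    ligand_id: str
    atoms: list[Atom]
    frame: str | None = None
    atom_keys: frozenset = field(default_factory=frozenset)
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyPocketError(f"pocket {self.pocket_id} has no atoms")
        if not self.atom_keys:
            self.atom_keys = frozenset(
                (a.res_num, a.name) for a in self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def barycenter(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    @property
    def dmax(self) -> float:
        d = np.linalg.norm(self.coords() - self.barycenter, axis=1)
        return float(d.max())

    @property
    def residues(self) -> list[tuple[int, str]]:
        """Residues with at least one atom in the pocket."""
        seen = {}
        for a in self.atoms:
            seen[a.res_num] = a.res_name
        return sorted(seen.items())

    def to_reference(self, transform: Transform,
                     residue_map: Mapping[int, int],
                     frame: str) -> "Pocket":
        """Map the pocket into a chain-cluster reference frame.

        Atom coordinates are rigidly transformed; atom keys become
        (aligned reference position, atom name).  Atoms at unaligned
        positions keep a chain-private key so they never count as common
        with another chain's pocket.
        """
        moved = [a.moved(transform.apply(a.coord)) for a in self.atoms]
        keys = []
        for a in self.atoms:
            if a.res_num in residue_map:
                keys.append((residue_map[a.res_num], a.name))
            else:
                keys.append((self.chain_uid, a.res_num, a.name))
        return replace(self, atoms=moved, frame=frame,
                       atom_keys=frozenset(keys),
                       descriptors=dict(self.descriptors))


def extract_pocket(chain: ProteinChain, ligand_coords: np.ndarray,
                   threshold: float = 5.5, pocket_id: str = "",
                   ligand_id: str = "") -> Pocket:
    """All chain heavy atoms within ``threshold`` (inclusive) of any ligand
    heavy atom.  Raises :class:`EmptyPocketError` when nothing is in range."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    if ligand_coords.ndim != 2 or ligand_coords.shape[1] != 3:
        raise ValueError("ligand coordinates must be (n, 3)")
    tree = cKDTree(ligand_coords)
    heavy = [a for a in chain.atoms if a.element != "H"]
    coords = np.array([a.coord for a in heavy])
    dists, _ = tree.query(coords, k=1)
    mask = dists <= threshold
    atoms = [a for a, keep in zip(heavy, mask) if keep]
    if not atoms:
        raise EmptyPocketError(
            f"no atom of {chain.chain_uid} within {threshold} A of ligand {ligand_id}")
    return Pocket(pocket_id=pocket_id or f"{chain.chain_uid}|{ligand_id}",
                  chain_uid=chain.chain_uid, ligand_id=ligand_id, atoms=atoms)


def assign_ligand_chains(cx: Complex, threshold: float = 5.5
                         ) -> list[tuple[int, str | None, list[str], str]]:
    """For each ligand of a complex: (ligand index, owning chain uid or
    None, contacting chain uids, reason).

    A ligand contacting several chains is an interface ligand (owning
    chain None, reason ``interface``); one contacting no chain is out of
    range (reason ``empty``)."""
    out = []
    for li, lig in enumerate(cx.ligands):
        tree = cKDTree(lig.coords)
        touching = []
        for chain in cx.chains:
            coords = np.array([a.coord for a in chain.atoms if a.element != "H"])
            if len(coords) and (tree.query(coords, k=1)[0] <= threshold).any():
                touching.append(chain.chain_uid)
        if len(touching) == 1:
            out.append((li, touching[0], touching, "ok"))
        elif not touching:
            out.append((li, None, touching, "empty"))
        else:
            out.append((li, None, touching, "interface"))
    return out


def interface_filter(cx: Complex, threshold: float = 5.5
                     ) -> tuple[list[tuple[int, str]], list[dict]]:
    """Split a complex's ligands into kept (ligand index, chain uid) pairs
    and omission log entries (interface or empty)."""
    kept, omitted = [], []
    for li, owner, touching, reason in assign_ligand_chains(cx, threshold):
        if owner is not None:
            kept.append((li, owner))
        else:
            omitted.append({"complex_id": cx.complex_id,
                            "ligand_id": cx.ligands[li].ligand_id,
                            "ligand_index": li,
                            "chains": touching, "reason": reason})
    return kept, omitted


def extract_complex_pockets(cx: Complex, threshold: float = 5.5,
                            allowed_ligands: Iterable[str] | None = None
                            ) -> tuple[list[Pocket], list[dict]]:
    """Interface-filter a complex and extract one pocket per kept ligand.

    ``allowed_ligands`` restricts extraction to ligand ids that passed
    validity/drug-likeness (others are skipped silently as "not a study
    ligand").  Pocket ids follow ``"<complex>|<ligand id>"``.
    """
    allowed = set(allowed_ligands) if allowed_ligands is not None else None
    chains_by_uid = {c.chain_uid: c for c in cx.chains}
    pockets, omitted = [], []
    kept, omitted_log = interface_filter(cx, threshold)
    for entry in omitted_log:
        if allowed is None or entry["ligand_id"] in allowed:
            omitted.append(entry)
    for li, chain_uid in kept:
        lig = cx.ligands[li]
        if allowed is not None and lig.ligand_id not in allowed:
            continue
        pocket = extract_pocket(chains_by_uid[chain_uid], lig.coords,
                                threshold=threshold,
                                pocket_id=f"{cx.complex_id}|{lig.ligand_id}",
                                ligand_id=lig.ligand_id)
        pockets.append(pocket)
    return pockets, omitted


# ---------------------------------------------------------------------------
# descriptors

def _volume_and_pci(coords: np.ndarray) -> tuple[float, float, float]:
    """(hull volume, hull area, convexity index) or NaNs when degenerate.

    The Pocket Convexity Index is reconstructed as the ratio of the
    convex-hull volume to the volume of the smallest enclosing sphere; a
    value near 1 means a compact, convex atom cloud.
    """
    if len(coords) < 4 or np.linalg.matrix_rank(coords - coords.mean(axis=0)) < 3:
        return float("nan"), float("nan"), float("nan")
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return float("nan"), float("nan"), float("nan")
    import trimesh.nsphere
    center, radius = trimesh.nsphere.minimum_nsphere(coords)
    v_sphere = 4.0 / 3.0 * math.pi * float(radius) ** 3
    pci = hull.volume / v_sphere if v_sphere > 0 else float("nan")
    return float(hull.volume), float(hull.area), float(pci)


def _make_descriptor_names() -> tuple[str, ...]:
    names = [
        # geometry
        "volume_hull", "area_hull", "pci", "dmax", "diameter",
        "enclosing_radius", "radius_gyration", "atom_density",
        "mean_dist_barycenter", "sd_dist_barycenter",
        # counts
        "n_atoms", "n_residues", "n_sidechain_atoms", "n_backbone_atoms",
        "n_C", "n_N", "n_O", "n_S",
        # atom frequencies
        "freq_C", "freq_N", "freq_O", "freq_S", "freq_Otyr", "freq_Ntrp",
        "side_chain_atom_prop", "polar_atom_prop", "hydrophobic_atom_prop",
        # hydrophobicity
        "hydrophobicity_kd", "hydrophobicity_kd_sd",
        # residue classes
        "freq_aliphatic", "freq_aromatic", "freq_charged",
        "freq_charged_pos", "freq_charged_neg", "freq_polar", "freq_tiny",
        "freq_hydrophobic_res", "freq_small_res",
        "charge_net", "freq_sulfur_res", "freq_nonstandard_res",
        "mean_residue_volume",
        # shape (gyration tensor) and residue-class counts
        "bbox_volume", "asphericity", "shape_anisotropy",
        "n_aliphatic_res", "n_aromatic_res", "n_charged_res",
        "n_polar_res", "n_tiny_res", "n_hydrophobic_res", "n_std_res",
    ]
    names += [f"freq_res_{r}" for r in STANDARD_RESIDUES]
    assert len(names) == 72
    return tuple(names)


POCKET_DESCRIPTOR_NAMES: tuple[str, ...] = _make_descriptor_names()

# Slots beyond the documented core set are reconstructed fillers for the
# 72-slot layout; they are excluded from any cross-study comparison.
RECONSTRUCTED_POCKET_DESCRIPTORS = frozenset(
    n for n in POCKET_DESCRIPTOR_NAMES if n in {
        "area_hull", "diameter", "enclosing_radius", "radius_gyration",
        "atom_density", "mean_dist_barycenter", "sd_dist_barycenter",
        "n_sidechain_atoms", "n_backbone_atoms", "n_C", "n_N", "n_O", "n_S",
        "polar_atom_prop", "hydrophobic_atom_prop", "hydrophobicity_kd_sd",
        "freq_charged_pos", "freq_charged_neg", "freq_hydrophobic_res",
        "freq_small_res", "charge_net", "freq_sulfur_res",
        "freq_nonstandard_res", "mean_residue_volume",
        "bbox_volume", "asphericity", "shape_anisotropy",
        "n_aliphatic_res", "n_aromatic_res", "n_charged_res",
        "n_polar_res", "n_tiny_res", "n_hydrophobic_res", "n_std_res",
    })

# crude mean residue volumes (A^3) for the reconstructed slot
_RESIDUE_VOLUME = {
    "ALA": 89, "ARG": 174, "ASN": 132, "ASP": 133, "CYS": 121, "GLN": 146,
    "GLU": 147, "GLY": 75, "HIS": 155, "ILE": 131, "LEU": 131, "LYS": 146,
    "MET": 149, "PHE": 165, "PRO": 115, "SER": 105, "THR": 119, "TRP": 204,
    "TYR": 181, "VAL": 117,
}


def pocket_descriptors(pocket: Pocket) -> dict[str, float]:
    """Fill the 72 named pocket descriptor slots.

    Frequencies are fractions in [0, 1]; the 20 per-residue frequencies
    are computed over standard residues only and sum to 1 (non-standard
    residues are counted in ``freq_nonstandard_res``).  Volume and the
    convexity index need at least 4 non-coplanar atoms and are NaN
    otherwise.
    """
    coords = pocket.coords()
    n = pocket.n_atoms
    bary = pocket.barycenter
    dists = np.linalg.norm(coords - bary, axis=1)
    volume, area, pci = _volume_and_pci(coords)
    if math.isnan(volume):
        enclosing_r = float("nan")
        density = float("nan")
    else:
        import trimesh.nsphere
        _, radius = trimesh.nsphere.minimum_nsphere(coords)
        enclosing_r = float(radius)
        density = n / volume if volume > 0 else float("nan")

    elements = [a.element for a in pocket.atoms]
    n_C = elements.count("C")
    n_N = elements.count("N")
    n_O = elements.count("O")
    n_S = elements.count("S")
    n_side = sum(a.is_sidechain for a in pocket.atoms)
    n_otyr = sum(1 for a in pocket.atoms
                 if a.element == "O" and a.res_name == "TYR" and a.is_sidechain)
    n_ntrp = sum(1 for a in pocket.atoms
                 if a.element == "N" and a.res_name == "TRP" and a.is_sidechain)

    residues = pocket.residues
    res_names = [r for _, r in residues]
    n_res = len(res_names)
    std = [r for r in res_names if r in KYTE_DOOLITTLE]
    n_std = len(std)

    def res_freq(names: set[str]) -> float:
        return (sum(1 for r in std if r in names) / n_std) if n_std else float("nan")

    kd = [KYTE_DOOLITTLE[r] for r in std]
    charge = sum({"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}.get(r, 0) for r in std)

    d: dict[str, float] = {
        "volume_hull": volume,
        "area_hull": area,
        "pci": pci,
        "dmax": pocket.dmax,
        "diameter": float(max(np.linalg.norm(coords[i] - coords[j])
                              for i in range(n) for j in range(i, n))) if n > 1 else 0.0,
        "enclosing_radius": enclosing_r,
        "radius_gyration": float(np.sqrt(np.mean(dists ** 2))),
        "atom_density": density,
        "mean_dist_barycenter": float(dists.mean()),
        "sd_dist_barycenter": float(dists.std()),
        "n_atoms": float(n),
        "n_residues": float(n_res),
        "n_sidechain_atoms": float(n_side),
        "n_backbone_atoms": float(n - n_side),
        "n_C": float(n_C), "n_N": float(n_N), "n_O": float(n_O), "n_S": float(n_S),
        "freq_C": n_C / n, "freq_N": n_N / n, "freq_O": n_O / n, "freq_S": n_S / n,
        "freq_Otyr": n_otyr / n,
        "freq_Ntrp": n_ntrp / n,
        "side_chain_atom_prop": n_side / n,
        "polar_atom_prop": (n_N + n_O) / n,
        "hydrophobic_atom_prop": (n_C + n_S) / n,
        "hydrophobicity_kd": float(np.mean(kd)) if kd else float("nan"),
        "hydrophobicity_kd_sd": float(np.std(kd)) if kd else float("nan"),
        "freq_aliphatic": res_freq(RESIDUE_CLASSES["aliphatic"]),
        "freq_aromatic": res_freq(RESIDUE_CLASSES["aromatic"]),
        "freq_charged": res_freq(RESIDUE_CLASSES["charged"]),
        "freq_charged_pos": res_freq({"LYS", "ARG", "HIS"}),
        "freq_charged_neg": res_freq({"ASP", "GLU"}),
        "freq_polar": res_freq(RESIDUE_CLASSES["polar"]),
        "freq_tiny": res_freq(RESIDUE_CLASSES["tiny"]),
        "freq_hydrophobic_res": (sum(1 for r in std if KYTE_DOOLITTLE[r] > 0) / n_std
                                 ) if n_std else float("nan"),
        "freq_small_res": res_freq({"GLY", "ALA", "SER", "CYS", "THR", "ASP",
                                    "ASN", "PRO", "VAL"}),
        "charge_net": float(charge),
        "freq_sulfur_res": res_freq({"CYS", "MET"}),
        "freq_nonstandard_res": (n_res - n_std) / n_res if n_res else float("nan"),
        "mean_residue_volume": (float(np.mean([_RESIDUE_VOLUME[r] for r in std]))
                                if n_std else float("nan")),
    }
    # gyration-tensor shape descriptors
    centered = coords - bary
    gyr = centered.T @ centered / n
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    tr = lam.sum()
    if tr > 0:
        d["asphericity"] = float(lam[0] - 0.5 * (lam[1] + lam[2]))
        d["shape_anisotropy"] = float(
            1.5 * (lam ** 2).sum() / tr ** 2 - 0.5)
    else:
        d["asphericity"] = 0.0
        d["shape_anisotropy"] = 0.0
    extent = coords.max(axis=0) - coords.min(axis=0)
    d["bbox_volume"] = float(np.prod(extent))
    d["n_aliphatic_res"] = float(sum(1 for r in std if r in RESIDUE_CLASSES["aliphatic"]))
    d["n_aromatic_res"] = float(sum(1 for r in std if r in RESIDUE_CLASSES["aromatic"]))
    d["n_charged_res"] = float(sum(1 for r in std if r in RESIDUE_CLASSES["charged"]))
    d["n_polar_res"] = float(sum(1 for r in std if r in RESIDUE_CLASSES["polar"]))
    d["n_tiny_res"] = float(sum(1 for r in std if r in RESIDUE_CLASSES["tiny"]))
    d["n_hydrophobic_res"] = float(sum(1 for r in std if KYTE_DOOLITTLE[r] > 0))
    d["n_std_res"] = float(n_std)
    for r in STANDARD_RESIDUES:
        d[f"freq_res_{r}"] = (std.count(r) / n_std) if n_std else float("nan")
    assert set(d) == set(POCKET_DESCRIPTOR_NAMES)
    return {name: d[name] for name in POCKET_DESCRIPTOR_NAMES}


def druggability_score(pocket: Pocket, plugin=None) -> float:
    """Druggability scoring hook.

    No built-in model is shipped; supply a callable ``plugin(pocket)``
    to compute a score, otherwise NaN ("not computed") is returned.
    """
    if plugin is not None:
        return float(plugin(pocket))
    return float("nan")
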
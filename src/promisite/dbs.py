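"""Druggable-binding-site (DBS) identification: cluster overlapping
pockets of one homologous chain cluster with an adaptive barycenter
cutoff, validate with the score of overlap, and label promiscuity.

The cutoff is C = D - k*sigma where D and sigma are the mean and
standard deviation of the p observed pocket radii dmax(i) (k = 2 by
default).  Two pockets fall in the same Pocket-Cluster when their
barycenter distance is below C; clusters are the connected components
of that relation, so transitivity holds for any k.  One Pocket-Cluster
of one chain cluster is one DBS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .pockets import Pocket

__all__ = [
    "ClusteringParams",
    "PocketCluster",
    "compute_cutoff",
    "cluster_pockets",
    "score_of_overlap",
    "classify_promiscuity",
    "dbs4_filter",
]

logger = logging.getLogger(__name__)

PROMISCUITY_LEVELS = ("S", "MP", "HP", "UNDETERMINED")


@dataclass(frozen=True)
class ClusteringParams:
    """Adaptive cutoff parameters of one chain cluster's pocket population."""

    k: float
    D: float       # mean of the p observed dmax values (A)
    sigma: float   # standard deviation of the dmax values (A)
    p: int         # population size

    @property
    def C(self) -> float:
        """Cutoff length (A); may be <= 0 for high-variance populations."""
        return self.D - self.k * self.sigma


def compute_cutoff(dmax_values: Sequence[float], k: float = 2.0,
                   ddof: int = 0) -> ClusteringParams:
    """Cutoff C = D - k*sigma from the observed pocket radii.

    ``sigma`` is the population standard deviation by default
    (``ddof=0``); a single-pocket population has sigma 0 and C = dmax.
    """
    values = np.asarray(list(dmax_values), dtype=float)
    if values.size == 0:
        raise ValueError("compute_cutoff needs at least one dmax value")
    if (values < 0).any():
        raise ValueError("dmax values must be >= 0")
    D = float(values.mean())
    sigma = float(values.std(ddof=ddof)) if values.size > ddof else 0.0
    return ClusteringParams(k=float(k), D=D, sigma=sigma, p=int(values.size))


@dataclass
class PocketCluster:
    """One DBS: a transitive group of overlapping pockets."""

    dbs_id: str
    chain_cluster_id: str
    member_pockets: list[str]
    params: ClusteringParams | None = None
    associated_ligand_clusters: set[str] = field(default_factory=set)
    promiscuity: str | None = None
    overlap_stats: dict[str, float] = field(default_factory=dict)
    protein_class: str | None = None

    @property
    def p(self) -> int:
        return len(self.member_pockets)

    @property
    def n_ligand_clusters(self) -> int:
        return len(self.associated_ligand_clusters)


def cluster_pockets(pockets: Sequence[Pocket], params: ClusteringParams,
                    chain_cluster_id: str = "CC") -> list[PocketCluster]:
    """Group pockets whose barycenters are closer than C into Pocket-Clusters.

    The edge condition is strict (< C); clusters are connected
    components, numbered deterministically by their smallest member
    pocket id.  When C <= 0 every pocket becomes a singleton cluster
    (logged): the population is too heterogeneous for the criterion.
    """
    if not pockets:
        return []
    frames = {p.frame for p in pockets}
    if len(frames) > 1:
        raise ValueError("pockets must share one reference frame")
    ids = [p.pocket_id for p in pockets]
    C = params.C
    if C <= 0:
        logger.warning("cutoff C=%.2f <= 0 for %s: all pockets kept as singletons",
                       C, chain_cluster_id)
        labels = np.arange(len(pockets))
    else:
        bary = np.array([p.barycenter for p in pockets])
        dist = squareform(pdist(bary)) if len(pockets) > 1 else np.zeros((1, 1))
        adj = csr_matrix((dist < C) & ~np.eye(len(pockets), dtype=bool))
        _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: min(ids[i] for i in g))
    clusters = []
    for ordinal, group in enumerate(ordered, start=1):
        members = sorted(ids[i] for i in group)
        cl = PocketCluster(dbs_id=f"{chain_cluster_id}_{ordinal}",
                           chain_cluster_id=chain_cluster_id,
                           member_pockets=members, params=params)
        if len(group) > 1:
            sos = [score_of_overlap(pockets[a], pockets[b])
                   for idx, a in enumerate(group) for b in group[idx + 1:]]
            cl.overlap_stats = {"mean": float(np.mean(sos)),
                                "min": float(np.min(sos)),
                                "max": float(np.max(sos))}
            if cl.overlap_stats["min"] == 0.0:
                logger.info("DBS %s joins non-overlapping pockets transitively",
                            cl.dbs_id)
        else:
            cl.overlap_stats = {"mean": 1.0, "min": 1.0, "max": 1.0}
        clusters.append(cl)
    return clusters


def score_of_overlap(pocket_a: Pocket, pocket_b: Pocket) -> float:
    """Jaccard-type proportion of atoms common to two pockets:
    n_common / (n_a + n_b - n_common), in [0, 1].

    Atoms are "common" when they share an atom key -- (aligned residue
    position, atom name) for pockets mapped into one chain-cluster
    reference frame, or identical atom records on the same chain.  A
    pocket against itself scores 1.
    """
    if pocket_a.frame != pocket_b.frame:
        raise ValueError(
            f"pockets {pocket_a.pocket_id} and {pocket_b.pocket_id} live in "
            f"different reference frames ({pocket_a.frame} vs {pocket_b.frame})")
    n_common = len(pocket_a.atom_keys & pocket_b.atom_keys)
    denom = pocket_a.n_atoms + pocket_b.n_atoms - n_common
    return n_common / denom


def classify_promiscuity(dbs: PocketCluster,
                         pocket_ligand_clusters: Mapping[str, str]) -> str:
    """Label a DBS from the number of distinct Ligand-Clusters it binds.

    L = 1 -> S (selective); L in {2, 3} -> MP; L >= 4 -> HP.  A DBS seen
    through a single pocket cannot be characterized and is labeled
    UNDETERMINED, reported separately from S.  The label and the
    associated ligand clusters are stored on the DBS and returned.
    """
    lcs = set()
    for pid in dbs.member_pockets:
        if pid not in pocket_ligand_clusters:
            raise ValueError(f"pocket {pid} has no ligand-cluster assignment")
        lcs.add(pocket_ligand_clusters[pid])
    dbs.associated_ligand_clusters = lcs
    if dbs.p == 1:
        dbs.promiscuity = "UNDETERMINED"
    elif len(lcs) == 1:
        dbs.promiscuity = "S"
    elif len(lcs) <= 3:
        dbs.promiscuity = "MP"
    else:
        dbs.promiscuity = "HP"
    return dbs.promiscuity


def dbs4_filter(dbs_list: Sequence[PocketCluster], min_pockets: int = 4
                ) -> tuple[list[PocketCluster], dict[str, int]]:
    """Keep DBS described by at least ``min_pockets`` pockets (default 4),
    the population on which promiscuity statistics are reliable.
    Returns (kept list, {"kept": ..., "dropped": ...})."""
    kept = [d for d in dbs_list if d.p >= min_pockets]
    counts = {"kept": len(kept), "dropped": len(dbs_list) - len(kept)}
    return kept, counts
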
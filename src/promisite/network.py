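"""Bipartite DBS / Ligand-Cluster interaction network.

DBS nodes carry their promiscuity label and protein class; ligand nodes
are ligand clusters, called selective when they bind exactly one DBS
(degree 1) and promiscuous otherwise.  An edge exists as soon as one
ligand of the cluster contacts one pocket of the DBS; edges are
unweighted and deduplicated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "tabulate",
    "subnetwork",
    "class_share_table",
    "write_graphml",
    "write_edge_list",
]


def class_share_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Counts per category plus their percentage of the total, the
    percentage rounded to one decimal."""
    total = sum(counts.values())
    rows = [{"category": k, "count": v,
             "percent": round(100.0 * v / total, 1) if total else float("nan")}
            for k, v in counts.items()]
    rows.append({"category": "Total", "count": total,
                 "percent": 100.0 if total else float("nan")})
    return pd.DataFrame(rows)


def build_network(dbs_attrs: Mapping[str, Mapping],
                  interactions: Iterable[tuple[str, str]],
                  ligand_cluster_attrs: Mapping[str, Mapping] | None = None
                  ) -> nx.Graph:
    """Build the bipartite graph from DBS attributes and (dbs_id,
    ligand_cluster_id) interaction pairs.

    ``dbs_attrs`` maps each DBS id to its node attributes (at least
    ``promiscuity``; optionally ``protein_class``, ``n_pockets``).  Any
    interaction naming an unknown DBS id is a dangling reference and is
    rejected.  Ligand nodes receive ``promiscuity`` = "selective" /
    "promiscuous" from their degree.
    """
    g = nx.Graph()
    for dbs_id, attrs in dbs_attrs.items():
        g.add_node(dbs_id, kind="dbs", **dict(attrs))
    lc_attrs = dict(ligand_cluster_attrs or {})
    for lc_id, attrs in lc_attrs.items():
        g.add_node(lc_id, kind="ligand_cluster", **dict(attrs))
    for dbs_id, lc_id in interactions:
        if dbs_id not in dbs_attrs:
            raise ValueError(f"interaction references unknown DBS {dbs_id!r}")
        if lc_id in dbs_attrs:
            raise ValueError(f"{lc_id!r} is a DBS id, not a ligand cluster")
        if lc_id not in g:
            g.add_node(lc_id, kind="ligand_cluster")
        g.nodes[lc_id]["kind"] = "ligand_cluster"
        g.add_edge(dbs_id, lc_id)
    for node, data in g.nodes(data=True):
        if data["kind"] == "ligand_cluster":
            deg = g.degree(node)
            data["promiscuity"] = "selective" if deg <= 1 else "promiscuous"
    assert nx.is_bipartite(g) or g.number_of_edges() == 0
    return g


def _dbs_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("kind") == "dbs"]


def _lc_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d.get("kind") == "ligand_cluster"]


def tabulate(g: nx.Graph) -> dict[str, pd.DataFrame]:
    """Summary tables of the interaction network.

    ``dbs_promiscuity``: DBS and pocket counts with percentages per
    S/MP/HP level.  ``ligand_cluster_dedication``: ligand clusters whose
    DBS all share one promiscuity level ("dedicated") versus "mixed"
    clusters spanning several levels, with a breakdown of the mixed
    combinations and member-ligand counts.  ``ligand_cluster_promiscuity``:
    per DBS level, how many interacting ligand clusters are selective
    versus promiscuous, with the mean number of DBS and protein classes
    bound by the promiscuous ones; the "All DBS" row uses distinct
    counts, not the column sum, because a ligand cluster can bind DBS of
    several levels.
    """
    dbs_nodes = _dbs_nodes(g)
    lc_nodes = _lc_nodes(g)
    levels = ("S", "MP", "HP")

    # --- table 1 style: DBS and pockets per promiscuity level
    dbs_counts = {lv: 0 for lv in levels}
    pocket_counts = {lv: 0 for lv in levels}
    for n in dbs_nodes:
        lv = g.nodes[n].get("promiscuity")
        if lv in dbs_counts:
            dbs_counts[lv] += 1
            pocket_counts[lv] += int(g.nodes[n].get("n_pockets", 0))
    t_dbs = class_share_table(dbs_counts).rename(columns={
        "count": "n_dbs", "percent": "dbs_percent"})
    t_p = class_share_table(pocket_counts)
    t_dbs["n_pockets"] = t_p["count"]
    t_dbs["pocket_percent"] = t_p["percent"]

    # --- table 2 style: dedicated vs mixed ligand clusters
    def lc_levels(lc: str) -> frozenset:
        return frozenset(g.nodes[nb]["promiscuity"] for nb in g.neighbors(lc))

    def lc_ligands(lc: str) -> int:
        return int(g.nodes[lc].get("n_ligands", 1))

    ded_rows = []
    total_lc = len(lc_nodes)
    total_ligands = sum(lc_ligands(lc) for lc in lc_nodes)
    mixed_detail: dict[frozenset, int] = {}
    buckets: dict[str, list[str]] = {lv: [] for lv in levels}
    buckets["Mixed"] = []
    for lc in lc_nodes:
        lvs = lc_levels(lc)
        if len(lvs) == 1 and next(iter(lvs)) in levels:
            buckets[next(iter(lvs))].append(lc)
        elif len(lvs) >= 2:
            buckets["Mixed"].append(lc)
            mixed_detail[lvs] = mixed_detail.get(lvs, 0) + 1
    for name in ["S", "MP", "HP", "Mixed"]:
        members = buckets[name]
        n_lig = sum(lc_ligands(lc) for lc in members)
        tani = [g.nodes[lc].get("mean_tanimoto") for lc in members]
        tani = [t for t in tani if t is not None and not np.isnan(t)]
        ded_rows.append({
            "dedicated_to": name if name == "Mixed" else f"{name} DBS",
            "n_ligand_clusters": len(members),
            "percent": round(100.0 * len(members) / total_lc, 1) if total_lc else float("nan"),
            "mean_tanimoto": float(np.mean(tani)) if tani else float("nan"),
            "n_ligands": n_lig,
            "ligand_percent": round(100.0 * n_lig / total_ligands, 1) if total_ligands else float("nan"),
        })
    ded_rows.append({
        "dedicated_to": "ALL", "n_ligand_clusters": total_lc, "percent": 100.0,
        "mean_tanimoto": float("nan"), "n_ligands": total_ligands,
        "ligand_percent": 100.0})
    t_ded = pd.DataFrame(ded_rows)
    t_mixed = pd.DataFrame(
        [{"levels": "+".join(sorted(k)), "n_ligand_clusters": v}
         for k, v in sorted(mixed_detail.items(), key=lambda kv: kv[0])])

    # --- table 3 style: ligand-cluster promiscuity per interacting DBS level
    def lc_row(members: list[str], label: str) -> dict:
        selective = [lc for lc in members if g.degree(lc) <= 1]
        promiscuous = [lc for lc in members if g.degree(lc) >= 2]
        deg = [g.degree(lc) for lc in promiscuous]
        ncls = []
        for lc in promiscuous:
            pcs = {g.nodes[nb].get("protein_class") for nb in g.neighbors(lc)}
            ncls.append(len({p for p in pcs if p is not None}) or len(pcs))
        return {
            "dbs_level": label, "total": len(members),
            "selective": len(selective), "promiscuous": len(promiscuous),
            "mean_dbs_bound": float(np.mean(deg)) if deg else float("nan"),
            "sd_dbs_bound": float(np.std(deg)) if deg else float("nan"),
            "mean_protein_classes": float(np.mean(ncls)) if ncls else float("nan"),
        }

    rows3 = []
    for lv in levels:
        members = [lc for lc in lc_nodes
                   if any(g.nodes[nb]["promiscuity"] == lv for nb in g.neighbors(lc))]
        rows3.append(lc_row(members, f"{lv} DBS"))
    rows3.append(lc_row(list(lc_nodes), "All DBS"))
    t_lc = pd.DataFrame(rows3)

    return {"dbs_promiscuity": t_dbs,
            "ligand_cluster_dedication": t_ded,
            "mixed_breakdown": t_mixed,
            "ligand_cluster_promiscuity": t_lc}


def subnetwork(g: nx.Graph, protein_class: str | None = None,
               seed_dbs: Sequence[str] | None = None) -> nx.Graph:
    """Two-step induced expansion around a seed DBS set.

    Seeds are either given explicitly or taken as all DBS of one protein
    class.  The expansion adds the seeds' ligand clusters and then every
    DBS of those ligand clusters; the induced subgraph on that node set
    is returned (re-running the expansion on the result adds nothing).
    """
    if seed_dbs is None:
        if protein_class is None:
            raise ValueError("give either protein_class or seed_dbs")
        seed_dbs = [n for n in _dbs_nodes(g)
                    if g.nodes[n].get("protein_class") == protein_class]
        if not seed_dbs:
            raise ValueError(f"unknown protein class {protein_class!r}")
    else:
        missing = [s for s in seed_dbs if s not in g]
        if missing:
            raise ValueError(f"unknown seed nodes {missing}")
    nodes = set(seed_dbs)
    lcs = {nb for s in seed_dbs for nb in g.neighbors(s)}
    nodes |= lcs
    nodes |= {nb for lc in lcs for nb in g.neighbors(lc)}
    sub = g.subgraph(nodes).copy()
    for node, data in sub.nodes(data=True):
        if data["kind"] == "ligand_cluster":
            data["promiscuity"] = ("selective" if sub.degree(node) <= 1
                                   else "promiscuous")
    return sub


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    clean = g.copy()
    for _, data in clean.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    nx.write_graphml(clean, str(path))


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    lines = ["dbs_id,ligand_cluster_id"]
    for a, b in sorted(g.edges()):
        if g.nodes[a].get("kind") != "dbs":
            a, b = b, a
        lines.append(f"{a},{b}")
    Path(path).write_text("\n".join(lines) + "\n")
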
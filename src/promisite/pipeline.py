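"""End-to-end orchestration: ligands -> chains -> pockets -> DBS ->
statistics -> interaction network, with a manifest of stage counts.

The input directory holds one PDB file per protein-ligand complex plus
a ``ligands.csv`` table (ligand_id, smiles).  Every configurable
threshold lives in :class:`PipelineConfig`; the config is serialized
into the output directory together with a JSON manifest so a run is
fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chains as chainmod
from . import dbs as dbsmod
from . import ligands as ligmod
from . import network as netmod
from . import pockets as pockmod
from . import stats as statsmod

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Study parameters; the defaults are the protocol's printed values."""

    proximity_threshold: float = 5.5    # A, pocket estimation
    tanimoto_threshold: float = 0.8     # ligand clustering
    identity_t1: float = 0.90           # chain family pass
    identity_t2: float = 0.80           # representative merge pass
    identity_denominator: str = "shorter"
    k: float = 2.0                      # barycenter cutoff C = D - k*sigma
    sigma_ddof: int = 0                 # population standard deviation
    min_pockets: int = 4                # DBS4 occurrence filter
    seed: int = 0
    cluster_method: str = "butina"
    run_cart: bool = False              # needs enough groups per class
    cart_repeats: int = 20
    lipinski: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    manifest: dict
    ligand_records: list
    ligand_clusters: list
    chain_clusters: list
    pockets: list
    dbs_list: list
    dbs4_list: list
    pocket_ligand_clusters: dict[str, str]
    pocket_to_dbs: dict[str, str]
    network: object
    tables: dict[str, pd.DataFrame]
    anova: pd.DataFrame | None = None
    cart: object | None = None


def run_all(in_dir: str | Path, out_dir: str | Path,
            config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full protocol on a directory of complexes.

    Emits per-stage CSV tables, a GraphML network, the serialized config
    and ``manifest.json`` into ``out_dir`` and returns the in-memory
    result.  Any stage failure aborts with the stage name in the
    exception message.
    """
    config = config or PipelineConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # --- stage 1: ligand space ------------------------------------------
    try:
        records = ligmod.load_ligand_table(in_dir / "ligands.csv")
        exclusions = ligmod._load_exclusion_list()
        for rec in records:
            if rec.valid:
                ligmod.validity_filter(rec, exclusion_list=exclusions)
        for rec in records:
            if not rec.valid:
                rec.drug_like = False
                continue
            try:
                rec.drug_like = ligmod.druglike_filter(
                    rec.descriptors, lipinski=config.lipinski)
            except KeyError:
                rec.drug_like = False
                rec.reason = "incomputable"
        usable = [r for r in records if r.valid and r.drug_like]
        clusters = ligmod.cluster_ligands(usable, config.tanimoto_threshold,
                                          method=config.cluster_method)
        table = pd.DataFrame([r.descriptors for r in usable],
                             index=[r.ligand_id for r in usable])
        for cl in clusters:
            cl.representative_id = ligmod.representative_ligand(cl, table)
        lig_to_cluster = {m: cl.cluster_id for cl in clusters
                          for m in cl.member_ids}
    except Exception as exc:  # noqa: BLE001 - annotate the stage
        raise RuntimeError(f"stage 'ligands' failed: {exc}") from exc
    manifest["stages"]["ligands"] = {
        "parsed": len(records),
        "valid": sum(r.valid for r in records),
        "drug_like": len(usable),
        "ligand_clusters": len(clusters),
    }

    # --- stage 2: chain space -------------------------------------------
    try:
        complexes = chainmod.read_complex_dir(in_dir)
        mono_chains = [c for cx in complexes for c in cx.chains]
        chain_clusters = chainmod.cluster_chains(
            mono_chains, t1=config.identity_t1, t2=config.identity_t2,
            denominator=config.identity_denominator)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'chains' failed: {exc}") from exc
    manifest["stages"]["chains"] = {
        "complexes": len(complexes),
        "mono_chains": len(mono_chains),
        "chain_clusters": len(chain_clusters),
    }

    # --- stage 3: pockets ------------------------------------------------
    usable_ids = {r.ligand_id for r in usable}
    cluster_of_chain = {uid: cl for cl in chain_clusters for uid in cl.member_uids}
    try:
        pockets = []
        omitted_all = []
        for cx in complexes:
            pocks, omitted = pockmod.extract_complex_pockets(
                cx, threshold=config.proximity_threshold,
                allowed_ligands=usable_ids)
            omitted_all.extend(omitted)
            for p in pocks:
                cl = cluster_of_chain[p.chain_uid]
                pockets.append(p.to_reference(
                    cl.transforms[p.chain_uid],
                    cl.residue_maps[p.chain_uid], cl.cluster_id))
        for p in pockets:
            p.descriptors = pockmod.pocket_descriptors(p)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'pockets' failed: {exc}") from exc
    manifest["stages"]["pockets"] = {
        "pockets": len(pockets),
        "omitted_interface_or_empty": len(omitted_all),
    }

    # --- stage 4: DBS -----------------------------------------------------
    try:
        pocket_lc = {}
        for p in pockets:
            if p.ligand_id in lig_to_cluster:
                pocket_lc[p.pocket_id] = lig_to_cluster[p.ligand_id]
        dbs_list = []
        by_frame: dict[str, list] = {}
        for p in pockets:
            by_frame.setdefault(p.frame, []).append(p)
        for frame in sorted(by_frame):
            group = sorted(by_frame[frame], key=lambda p: p.pocket_id)
            params = dbsmod.compute_cutoff([p.dmax for p in group],
                                           k=config.k, ddof=config.sigma_ddof)
            dbs_list.extend(dbsmod.cluster_pockets(group, params, frame))
        for d in dbs_list:
            dbsmod.classify_promiscuity(d, pocket_lc)
        dbs4_list, dbs4_counts = dbsmod.dbs4_filter(dbs_list, config.min_pockets)
        pocket_to_dbs = {pid: d.dbs_id for d in dbs_list
                         for pid in d.member_pockets}
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'dbs' failed: {exc}") from exc
    manifest["stages"]["dbs"] = {
        "dbs": len(dbs_list),
        "dbs4": dbs4_counts["kept"],
        "dbs4_dropped": dbs4_counts["dropped"],
        "labels": {lv: sum(d.promiscuity == lv for d in dbs_list)
                   for lv in dbsmod.PROMISCUITY_LEVELS},
    }

    # --- stage 5: statistics ---------------------------------------------
    anova = None
    cart = None
    try:
        rows, labels, groups = [], [], []
        for d in dbs4_list:
            for pid in d.member_pockets:
                p = next(pk for pk in pockets if pk.pocket_id == pid)
                rows.append(p.descriptors)
                labels.append(d.promiscuity)
                groups.append(d.dbs_id)
        if rows:
            X = pd.DataFrame(rows)
            level_counts = pd.Series(labels).value_counts()
            if (level_counts >= 2).sum() >= 2:
                anova = statsmod.comparison_table(X, labels)
                anova.to_csv(out_dir / "anova_pockets.csv", index=False)
            if config.run_cart:
                mask = [l in ("S", "HP") for l in labels]
                ds = statsmod.GroupedDataset(
                    X[mask].reset_index(drop=True),
                    np.array(labels)[mask], np.array(groups)[mask])
                n_groups = {c: len(set(ds.groups[ds.y == c]))
                            for c in set(ds.y)}
                if len(n_groups) == 2 and min(n_groups.values()) >= 5:
                    cart = statsmod.cart_train_eval(
                        ds, repeats=config.cart_repeats, seed=config.seed,
                        positive_label="HP")
                else:
                    manifest["stages"].setdefault("stats", {})[
                        "cart_skipped"] = f"insufficient groups: {n_groups}"
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
    manifest["stages"].setdefault("stats", {})
    manifest["stages"]["stats"]["anova_descriptors"] = (
        0 if anova is None else int(len(anova)))
    if cart is not None:
        manifest["stages"]["stats"]["cart"] = {
            k: round(v, 4) for k, v in cart.metrics_mean.items()}

    # --- stage 6: network -------------------------------------------------
    try:
        lc_sizes = {cl.cluster_id: len(cl.member_ids) for cl in clusters}
        lc_tani = {cl.cluster_id: cl.mean_pairwise_tanimoto for cl in clusters}
        dbs_attrs = {d.dbs_id: {"promiscuity": d.promiscuity,
                                "n_pockets": d.p,
                                "protein_class": ""}
                     for d in dbs4_list}
        edges = sorted({(d.dbs_id, lc) for d in dbs4_list
                        for lc in d.associated_ligand_clusters})
        lc_attrs = {lc: {"n_ligands": lc_sizes.get(lc, 1),
                         "mean_tanimoto": lc_tani.get(lc, float("nan"))}
                    for _, lc in edges}
        net = netmod.build_network(dbs_attrs, edges, lc_attrs)
        tables = netmod.tabulate(net)
        netmod.write_graphml(net, out_dir / "network.graphml")
        netmod.write_edge_list(net, out_dir / "edges.csv")
        for name, tab in tables.items():
            tab.to_csv(out_dir / f"table_{name}.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc
    manifest["stages"]["network"] = {
        "dbs_nodes": len(dbs_attrs),
        "ligand_cluster_nodes": len({lc for _, lc in edges}),
        "edges": len(edges),
    }

    # --- persist ----------------------------------------------------------
    _write_outputs(out_dir, config, manifest, records, clusters,
                   chain_clusters, pockets, dbs_list, pocket_lc,
                   pocket_to_dbs)
    return PipelineResult(
        manifest=manifest, ligand_records=records, ligand_clusters=clusters,
        chain_clusters=chain_clusters, pockets=pockets, dbs_list=dbs_list,
        dbs4_list=dbs4_list, pocket_ligand_clusters=pocket_lc,
        pocket_to_dbs=pocket_to_dbs, network=net, tables=tables,
        anova=anova, cart=cart)


def _write_outputs(out_dir, config, manifest, records, clusters,
                   chain_clusters, pockets, dbs_list, pocket_lc,
                   pocket_to_dbs) -> None:
    config.to_yaml(out_dir / "config.yaml")

    lig_rows = []
    for r in records:
        row = {"ligand_id": r.ligand_id, "smiles": r.smiles,
               "valid": r.valid, "drug_like": r.drug_like,
               "reason": r.reason or ""}
        row.update(r.descriptors)
        lig_rows.append(row)
    pd.DataFrame(lig_rows).to_csv(out_dir / "ligand_table.csv", index=False)

    pd.DataFrame([
        {"cluster_id": cl.cluster_id, "ligand_id": m,
         "is_representative": int(m == cl.representative_id),
         "mean_pairwise_tanimoto": cl.mean_pairwise_tanimoto}
        for cl in clusters for m in cl.member_ids
    ]).to_csv(out_dir / "ligand_clusters.csv", index=False)

    chainmod.write_cluster_tables(chain_clusters, out_dir)

    pock_rows = []
    for p in sorted(pockets, key=lambda p: p.pocket_id):
        row = {"pocket_id": p.pocket_id, "chain_uid": p.chain_uid,
               "ligand_id": p.ligand_id, "frame": p.frame,
               "n_atoms": p.n_atoms, "dmax": p.dmax,
               "ligand_cluster": pocket_lc.get(p.pocket_id, ""),
               "dbs_id": pocket_to_dbs.get(p.pocket_id, "")}
        row.update(p.descriptors)
        pock_rows.append(row)
    pd.DataFrame(pock_rows).to_csv(out_dir / "pockets.csv", index=False)

    dbs_rows = []
    for d in sorted(dbs_list, key=lambda d: d.dbs_id):
        dbs_rows.append({
            "dbs_id": d.dbs_id, "chain_cluster": d.chain_cluster_id,
            "p": d.p, "L": d.n_ligand_clusters, "label": d.promiscuity,
            "so_mean": d.overlap_stats.get("mean"),
            "so_min": d.overlap_stats.get("min"),
            "so_max": d.overlap_stats.get("max"),
            "C": d.params.C, "D": d.params.D, "sigma": d.params.sigma})
    pd.DataFrame(dbs_rows).to_csv(out_dir / "dbs.csv", index=False)

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
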
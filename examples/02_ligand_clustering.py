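"""Cluster drug-like ligands into Ligand-Clusters by MACCS-Tanimoto.

Three carbazole isomers and one coumarin: the isomers share nearly all
MACCS keys (Tanimoto >= 0.8) and form one cluster; the coumarin stays a
singleton.  The cluster representative is the member closest to the
cluster's mean descriptor vector under inverse-variance weights.
"""

import pandas as pd
from rdkit import Chem

from promisite import (MACCS_fingerprint, cluster_ligands, druglike_filter,
                       ligand_descriptors, representative_ligand, tanimoto)
from promisite.ligands import LigandRecord

smiles = {
    "CZ1": "Cc1ccc2[nH]c3ccccc3c2c1",
    "CZ2": "Cc1ccc2c(c1)[nH]c1ccccc12",
    "CZ3": "CCc1ccc2[nH]c3ccccc3c2c1",
    "COU": "O=c1ccc2ccccc2o1",
}
records = []
for lid, smi in smiles.items():
    mol = Chem.MolFromSmiles(smi)
    rec = LigandRecord(ligand_id=lid, smiles=smi, mol=mol,
                       descriptors=ligand_descriptors(mol),
                       fingerprint=MACCS_fingerprint(mol))
    rec.drug_like = druglike_filter(rec.descriptors)
    records.append(rec)
    print(f"{lid}: Rings={rec.descriptors['Rings']:.0f} "
          f"RotatableB={rec.descriptors['RotatableB']:.0f} "
          f"ratioH/C={rec.descriptors['ratioHC']:.2f} "
          f"drug-like={rec.drug_like}")

print("Tanimoto CZ1-CZ2:",
      round(tanimoto(records[0].fingerprint, records[1].fingerprint), 3))
clusters = cluster_ligands(records, threshold=0.8)
table = pd.DataFrame({r.ligand_id: r.descriptors for r in records}).T
for cl in clusters:
    rep = representative_ligand(cl, table)
    print(f"{cl.cluster_id}: members={cl.member_ids} representative={rep}")
# One multi-member cluster = one ligand "type"; its representative stands
# in for the cluster in any downstream diversity summary.
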
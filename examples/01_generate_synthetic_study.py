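"""Generate a small synthetic protein-ligand study with planted truth.

Two homologous chain families, two binding sites each, drug-like ligands
from Tanimoto-coherent families placed in the sites.  The ground truth
records which pocket belongs to which planted site and how many ligand
families each site binds.
"""

from pathlib import Path

from promisite import SyntheticScenario, generate_scenario

out = Path("scratch/example_study")
scenario = SyntheticScenario(seed=7, n_chain_families=2, chains_per_family=4,
                             sites_per_family=2, pockets_per_site=5,
                             ligand_families=4, ligands_per_family=3)
truth = generate_scenario(scenario, out)

print(f"complexes written: {len(truth.pocket_site)} (one pocket each)")
print(f"planted sites and promiscuity labels: {truth.site_labels}")
print(f"ligand families: {sorted(set(truth.ligand_family.values()))}")
# Each site's label follows from the number of distinct ligand families
# bound there: 1 -> S (selective), 2-3 -> MP, >= 4 -> HP.
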
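"""Extract a ligand-proximity pocket and inspect its descriptors.

A pocket is every protein heavy atom within 5.5 A of any ligand heavy
atom.  Its barycenter and radius dmax drive the downstream site
clustering; the 72 descriptors characterize its geometry and chemistry.
"""

from pathlib import Path

from promisite import (SyntheticScenario, generate_scenario, parse_complex,
                       pocket_descriptors)
from promisite.pockets import extract_complex_pockets

src = Path("scratch/example_pockets")
generate_scenario(SyntheticScenario(seed=13, n_chain_families=1,
                                    sites_per_family=1, pockets_per_site=2,
                                    ligand_families=2, ligands_per_family=2), src)
cx = parse_complex(sorted(src.glob("*.pdb"))[0])
pockets, omitted = extract_complex_pockets(cx, threshold=5.5)
p = pockets[0]
d = pocket_descriptors(p)
print(f"pocket {p.pocket_id}: {p.n_atoms} atoms over {len(p.residues)} residues")
print(f"barycenter {p.barycenter.round(2)}, dmax {p.dmax:.2f} A")
print(f"hull volume {d['volume_hull']:.1f} A^3, convexity index {d['pci']:.2f}")
print(f"hydrophobicity (Kyte-Doolittle mean) {d['hydrophobicity_kd']:.2f}, "
      f"sulfur frequency {d['freq_S']:.2f}")
# dmax is the largest barycenter-to-atom distance; the population of dmax
# values across homologous pockets sets the site-clustering cutoff.
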
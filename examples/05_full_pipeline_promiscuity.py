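"""Run the whole protocol end to end and check planted-site recovery.

The reference study plants nine binding sites on five chain families
with selective / moderately promiscuous / highly promiscuous labels.
The pipeline must recover exactly nine DBS and every label.
"""

from pathlib import Path

from promisite import PipelineConfig, evaluate_recovery, run_all
from promisite.synthetic import generate_scenario, reference_scenario

src, out = Path("scratch/example_run_in"), Path("scratch/example_run_out")
truth = generate_scenario(reference_scenario(seed=1), src)
result = run_all(src, out, PipelineConfig(seed=1))

for stage, counts in result.manifest["stages"].items():
    print(f"{stage}: {counts}")
for d in result.dbs_list:
    print(f"{d.dbs_id}: {d.p} pockets, {d.n_ligand_clusters} ligand clusters "
          f"-> {d.promiscuity} (overlap {d.overlap_stats['min']:.2f}"
          f"-{d.overlap_stats['max']:.2f})")
rec = evaluate_recovery(truth,
                        {d.dbs_id: d.promiscuity for d in result.dbs_list},
                        result.pocket_to_dbs)
print("recovery:", rec)
# partition_exact=True and label_accuracy=1.0 mean the barycenter-cutoff
# clustering reproduced the planted sites and their promiscuity exactly.
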
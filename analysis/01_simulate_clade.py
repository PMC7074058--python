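#!/usr/bin/env python
"""Build the planted two-genus study clade and export its ground truth.

Generates the documented synthetic fixture (2 genera x 3 species x 2-3
strains, 200 genes per ancestral genome), writes the sequence data under
scratch/clade/ (FASTA; regenerated on demand, not part of the results) and
the truth tables under results/.
"""

from pathlib import Path

import pandas as pd

from taxodelim.io import write_clade
from taxodelim.simulate import planted_metadata, planted_two_genus_config, simulate_clade

ROOT = Path(__file__).resolve().parent.parent
SEED = 1

clade = simulate_clade(planted_two_genus_config(seed=SEED))
write_clade(clade, ROOT / "scratch" / "clade")

results = ROOT / "results"
results.mkdir(exist_ok=True)
planted_metadata().to_csv(results / "strain_metadata.tsv", sep="\t", index=False)

rows = []
for leaf in clade.leaves():
    rows.append(
        {
            "strain_id": leaf,
            "genome_bp": len(clade.genomes[leaf]),
            "n_proteins": len(clade.proteomes[leaf]),
            "genus": clade.truth_partition["genus"][leaf],
            "species": clade.truth_partition["species"][leaf],
            "subspecies": clade.truth_partition["subspecies"][leaf],
        }
    )
summary = pd.DataFrame(rows)
summary.to_csv(results / "clade_summary.tsv", sep="\t", index=False)

print(f"simulated {len(clade.leaves())} genomes (seed {SEED})")
print(summary.to_string(index=False))
print(f"sequence data in {ROOT / 'scratch' / 'clade'}, truth in {results}")
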
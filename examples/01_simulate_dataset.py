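"""Simulate a glioblastoma-like scRNA-seq dataset with planted CNVs.

Builds the frozen default configuration (three malignant clones with
whole-chromosome gains/losses plus five diploid stromal populations),
draws the counts, and prints what was planted.
"""

import numpy as np

from sccnvlineage import default_paperlike_config, simulate_dataset

config = default_paperlike_config(seed=1)
counts, annotation, metadata, truth = simulate_dataset(config)

print(f"dataset: {counts.n_genes} genes x {counts.n_cells} cells")
print(f"chromosomes: {len(config.chromosomes)} "
      f"({next(iter(config.chromosomes.values()))} genes each)")
print("\nplanted clones (dosage 1.5 = single-copy gain, 0.5 = loss):")
for clone_id, events in truth.clone_events.items():
    desc = ", ".join(f"chr{e.chromosome}x{e.dosage}" for e in events)
    n = (truth.cells["true_clone"] == clone_id).sum()
    print(f"  clone {clone_id} ({n} cells): {desc}")
print("\ncell types:")
print(truth.cells["true_type"].value_counts().to_string())

libsizes = np.asarray(counts.counts.sum(axis=0)).ravel()
print(f"\nmedian library size: {np.median(libsizes):.0f} UMIs; "
      f"median genes detected per cell: "
      f"{np.median((counts.counts > 0).sum(axis=0)):.0f}")
# Each clone's events shift expression of whole chromosomes; the stromal
# populations stay diploid and carry 8x-enriched lineage marker genes.
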
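"""Generate a synthetic stool-like abundance table and preprocess it.

Builds a 3-cluster compositional dataset (rows on the probability simplex),
writes it to TSV with its ground truth, reads it back, normalizes, filters
rare/constant taxa, and computes a Jensen-Shannon distance matrix.
"""

from pathlib import Path
import tempfile

import numpy as np

from enteromap import (filter_taxa, generate_clustered, add_zero_inflation,
                       normalize_tss, pairwise_distances, read_abundance_table,
                       write_dataset)

ds = generate_clustered(n=400, p=60, k=3, separation=5.0, spread=1.0, seed=0)
ds = add_zero_inflation(ds, dropout=0.3, seed=1)  # microbiome-like sparsity
print(f"simulated {ds.n} samples x {ds.p} taxa, "
      f"{(ds.abundances == 0).mean():.0%} zeros, row sums all 1")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "table.tsv"
    write_dataset(ds, path)
    table = read_abundance_table(path)

table = normalize_tss(table)
table, dropped = filter_taxa(table)  # <1% prevalence or std < 0.001 removed
print(f"filter kept {table.d} taxa, dropped {len(dropped)}")

D = pairwise_distances(table, "jensenshannon")
print(f"Jensen-Shannon distances: median {np.median(D.values):.3f}, "
      f"max {D.values.max():.3f}")
# Within-cluster distances should be far smaller than between-cluster ones.
same = D.values[np.ix_(ds.labels == 0, ds.labels == 0)]
diff = D.values[np.ix_(ds.labels == 0, ds.labels == 1)]
print(f"median within-cluster {np.median(same):.3f} "
      f"vs between-cluster {np.median(diff):.3f}")
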
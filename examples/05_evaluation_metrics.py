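"""Benchmark metrics and the same-genotype doublet estimate.

Compares two labelings of the same barcodes the way pooled-library studies
compare a genotype-based assignment against an orthogonal one (hashtags,
dual indexes, another tool).
"""

import pandas as pd

from mtdemux import accuracy, ari, concordance_table, same_genotype_doublet_estimate

truth = pd.Series(
    ["d1", "d1", "d1", "d2", "d2", "doublet", "d3", "d3"],
    index=[f"bc{i}" for i in range(8)],
)
pred = pd.Series(
    ["B", "B", "B", "A", "doublet", "doublet", "C", "C"],
    index=truth.index,
)

print(f"accuracy (after optimal cluster-to-donor matching): {accuracy(truth, pred):.3f}")
print(f"adjusted Rand index: {ari(truth, pred):.3f}")
print("row-normalised concordance (%):")
print(concordance_table(truth, pred).round(1).to_string())

# With N equally mixed donors only (N-1)/N of doublets join two genotypes;
# the rest are invisible to genotype methods. From an observed count of
# cross-genotype doublets the total same-genotype burden follows directly:
n_same = same_genotype_doublet_estimate(752, n_donors=4)
print(f"752 cross-genotype doublets among 4 donors imply ~{n_same:.0f} "
      "same-genotype doublets")
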
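"""Estimate the number of pooled donors when it is unknown.

The mean silhouette score over candidate K peaks at the true number of
genotype clusters; direct mode then demultiplexes by clustering variants
instead of cells (useful for very shallow or imbalanced pools).
"""

from mtdemux import (
    classify,
    direct_mode,
    estimate_k,
    filter_germline,
    simulate_cells,
    simulate_haplotypes,
)

haps = simulate_haplotypes(5, 12, n_shared=0, seed=9)
data = simulate_cells(haps, 60, 2000, doublet_fraction=0.0, error_rate=0.002, seed=9)

freq = data.matrices.frequency()
retained = filter_germline(freq)
k = estimate_k(freq[:, retained], k_range=(2, 10))
print(f"germline variants retained: {len(retained)}")
print(f"silhouette-estimated number of donors: {k} (true: 5)")

scores, model, _ = direct_mode(data.matrices, k)
labels = classify(scores, trust_p1=True)
print(f"direct-mode variant groups: {[len(s) for s in model.variant_sets]}")
print(f"singlets: {(labels == 'Singlet').sum()} of {len(labels)}")

# Direct mode groups variants by their across-cell VAF profiles; each group
# recovers one donor's private variant set, so scoring proceeds without an
# initial cell clustering.
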
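# mtdemux

Demultiplexing of pooled single-cell genomic libraries and cross-genotype
doublet detection using mitochondrial germline variants.

## Why mitochondrial variants

Pooling cells from several donors into one single-cell library cuts cost and
batch effects, but every barcode must afterwards be assigned back to its
donor, and droplets containing two cells (doublets) must be flagged. Tools
that genotype the nuclear genome struggle on assays with sparse nuclear
coverage such as (mt)scATAC-seq, ASAP-seq or DOGMA-seq. Mitochondrial DNA is
present at hundreds of copies per cell, is deeply covered by these assays,
and each donor carries a distinct set of inherited, homoplasmic (VAF ≈ 1)
mtDNA substitutions — a compact endogenous barcode. `mtdemux` exploits only
these germline mitochondrial variants: it is fast (the search space is a
16,569 bp circle), accurate down to a few mitochondrial reads per cell, and
needs no external genotype reference. Its one intrinsic blind spot is
doublets formed by two cells of the *same* donor, which share a genotype by
definition.

## Method

1. **Pileup & calling.** Reads on the mitochondrial contig (cell barcode in
   the `CB` tag or read name) are tallied per position and barcode;
   candidate SNVs require bulk depth ≥ 8, ≥ 2 supporting reads, VAF ≥ 1%,
   and a pooled-bulk VAF strictly inside (1%, 99%).
2. **Count matrices.** Per-cell reference/alternative count matrices and the
   derived VAF matrix (zero-depth entries are *missing*, not 0).
3. **Germline selection & clustering.** A variant is a germline marker when
   > 50% of the cells with any alternate signal are homoplasmic
   (VAF > 0.99). Cells are clustered on the VAF matrix with K-means (or a
   Gaussian mixture) into K genotypes; K can be estimated by the silhouette
   score when unknown. Each cluster's own variant set is derived with the
   same homoplasmy rule, and variants shared between sets are removed so the
   surviving sets G_i are sample-specific.
4. **Beta-binomial doublet model.** For cell *c* and cluster *i*, the summed
   alternative count A₁ over G_i (A₀ reference) is binomial with success
   probability *p*; with the conjugate prior Beta(α_i, 1), where
   α_i = 1 + mean alternative count over G_i in cluster *i*, the posterior
   is Beta(α_i + A₁, 1 + A₀) and the cell's score is its mode

       p = (α + A₁ − 1) / (α + β + A₁ + A₀ − 2).

   `p1` is the score for the cell's own (first-fitted) cluster, `p2` the
   best score among the others. Singlets satisfy p1 > 0.99 (and p2 < 0.01 in
   the strict rule); cells with p1 < 0.8 or p2 > 0.2 are doublets; the rest
   are resolved by a k = 5 nearest-neighbour vote in (p1, p2) space.
   Singlets go to their argmax-p cluster.
5. **Simulator & evaluation.** A synthetic-mixture generator (donor
   haplotypes, Poisson per-site depth with 1000 reads/cell ≈ 4× coverage,
   binomial base errors, doublets as exact read-count merges) plus
   permutation-matched accuracy, ARI, doublet AUC/TPR/FDR and concordance
   tables validate every stage without external data.

## Worked example

```python
from mtdemux import RunConfig, demux_matrices, evaluate_result
from mtdemux import simulate_cells, simulate_haplotypes

haps = simulate_haplotypes(4, (8, 20), n_shared=2, seed=42)
data = simulate_cells(haps, 150, 1000, doublet_fraction=0.08,
                      error_rate=0.002, seed=42)
result, model, scores = demux_matrices(data.matrices, RunConfig(k=4))
print(evaluate_result(data.truth, result))
```

prints (see `examples/03_demultiplex_and_detect_doublets.py`):

```
label
Singlet    562
Doublet     38
specific variants per cluster: [9, 18, 13, 16]
beta prior alpha per cluster: [5.2, 5.1, 5.1, 5.2]
overall accuracy: 0.983
singlet donor-assignment accuracy: 1.000
cross-genotype doublet TPR: 1.000
doublet-score AUC: 1.000
```

600 barcodes from 4 donors at ~4× mitochondrial coverage: every singlet is
assigned to the right donor, every cross-genotype doublet is flagged, and
the residual 1.7% inaccuracy is exactly the same-donor doublets that no
genotype-based method can see.

The `examples/` directory holds one short script per capability
(simulation, pileup + calling, demultiplexing, pool-size estimation,
metrics). The same functionality is available from the shell:

```bash
mtdemux simulate --donors 4 --cells-per-donor 150 --reads-per-cell 1000 \
        --doublet-frac 0.08 --seed 42 --out-dir sim/
mtdemux demux --matrix-dir sim/ --samples 4 --out-dir out/
mtdemux evaluate --truth sim/truth.tsv --pred out/demux_result.tsv --out metrics.json
```

For real data: `mtdemux demux --bam atac.bam --reference chrM.fa
--barcodes barcodes.tsv --samples 8 --out-dir out/` (coordinate-sorted,
indexed BAM; local realignment around indels, e.g. GATK IndelRealigner, is a
recommended upstream step).

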
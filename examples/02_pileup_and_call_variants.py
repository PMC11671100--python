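"""Barcode-aware pileup and SNV calling on an alignment file.

Uses the generator's toy SAM (1 bp reads, CB tags) so the whole path runs
without external data; a real coordinate-sorted mtscATAC-seq BAM works the
same way.
"""

import tempfile
from pathlib import Path

from mtdemux import (
    call_variants,
    extract_mito_reads,
    pileup,
    simulate_cells,
    simulate_haplotypes,
    write_toy_sam,
)
from mtdemux.variants import read_reference_fasta

tmp = Path(tempfile.mkdtemp())
haps = simulate_haplotypes(2, 5, n_shared=0, seed=3)
data = simulate_cells(haps, 20, 2000, doublet_fraction=0.0, error_rate=0.0, seed=3)
write_toy_sam(data, tmp / "toy.sam", fasta_path=tmp / "ref.fa", seed=3)

reads = extract_mito_reads(tmp / "toy.sam")          # CB tag, dup/secondary filtered
counts = pileup(reads, min_base_quality=20)
reference = read_reference_fasta(tmp / "ref.fa")
table = call_variants(counts, reference)             # depth>=8, reads2>=2, 1%<VAF<99%

print(f"base observations: {len(reads)}  barcodes: {len(counts.per_barcode)}")
print(f"candidate SNVs called: {len(table)}")
print(table.head(5).to_string(index=False))

# bulk_vaf ~0.5 at every site: each variant is homoplasmic in one of the two
# pooled donors, so in the pooled "bulk" pileup half the reads carry the
# alternative allele -- exactly the signature the (1%, 99%) window selects.
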
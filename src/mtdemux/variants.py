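"""Candidate SNP calling from a bulk mitochondrial pileup.

The caller mirrors the classic pooled-sample heuristics: a substitution is
emitted when bulk depth >= 8, supporting reads >= 2 and VAF >= 1%, and —
because reads come from several pooled individuals — the bulk VAF must lie
strictly inside (1%, 99%) to be a plausible germline variant of a subset of
donors (a VAF near 0 or 1 is either noise or shared by everyone and useless
for demultiplexing). SNVs only; each (position, alt) is its own record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .pileup import BASES, BASE_INDEX, PileupCounts
from .simulate import MT_LENGTH

VARIANT_COLUMNS = ["position", "ref", "alt", "bulk_depth", "bulk_alt_count", "bulk_vaf"]


def call_variants(
    counts: PileupCounts,
    reference: str,
    min_var_freq: float = 0.01,
    min_depth: int = 8,
    min_reads2: int = 2,
    bulk_vaf_window: tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """Call candidate SNVs from bulk base counts.

    Returns a variant table sorted by position with columns
    ``position, ref, alt, bulk_depth, bulk_alt_count, bulk_vaf``.
    """
    if len(reference) != MT_LENGTH:
        raise InputError(
            f"reference length {len(reference)} != {MT_LENGTH}"
        )
    if min_depth <= 0 or min_reads2 <= 0 or min_var_freq <= 0:
        raise InputError("thresholds must be positive")
    lo, hi = bulk_vaf_window
    depth = counts.bulk.sum(axis=1)
    rows = []
    for pos0 in np.flatnonzero(depth >= min_depth):
        ref_base = reference[pos0].upper()
        if ref_base not in BASE_INDEX:
            continue
        d = depth[pos0]
        for b, base in enumerate(BASES):
            if base == ref_base:
                continue
            alt_count = counts.bulk[pos0, b]
            if alt_count < min_reads2:
                continue
            vaf = alt_count / d
            if vaf < min_var_freq or not (lo < vaf < hi):
                continue
            rows.append((pos0 + 1, ref_base, base, int(d), int(alt_count), vaf))
    table = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return table.sort_values(["position", "alt"], ignore_index=True)


def write_variant_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_vcf(table: pd.DataFrame, path: str | Path, contig: str = "chrM") -> None:
    """Write the variant table as a minimal VCF (DP and AF in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={MT_LENGTH}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Bulk depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Bulk VAF">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{contig}\t{row.position}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"DP={row.bulk_depth};AF={row.bulk_vaf:.6f}\n"
            )


def read_reference_fasta(path: str | Path) -> str:
    """Read a single-record FASTA as an uppercase sequence string."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no sequence in FASTA: {path}")
    return str(records[0].seq).upper()
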
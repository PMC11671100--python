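"""Barcode-aware mitochondrial pileup from aligned reads.

Reads are taken from an indexed SAM/BAM restricted to the mitochondrial
contig (``chrM``/``MT`` aliases accepted). Duplicate, secondary and
supplementary records are discarded, the cell barcode is read from a tag
(``CB`` by default) or extracted from the read name with a regex, and each
aligned base above the quality floor is tallied per position and barcode.
Positions are 1-based throughout (mitochondrial nomenclature convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import MT_LENGTH

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CONTIG_ALIASES = ("chrM", "MT", "chrMT", "M")


@dataclass
class ReadSet:
    """Flat per-base observations surviving the read-level filters."""

    records: pd.DataFrame  # columns: barcode, position (1-based), base, qual

    def __len__(self) -> int:
        return len(self.records)

    @property
    def barcodes(self) -> list[str]:
        return sorted(self.records["barcode"].unique()) if len(self.records) else []


@dataclass
class PileupCounts:
    """Bulk and per-barcode base counts over the mitochondrial genome."""

    bulk: np.ndarray  # (16569, 4) int
    per_barcode: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    def bulk_depth(self, position: int) -> int:
        return int(self.bulk[position - 1].sum())


def _resolve_contig(alignment, contig: str | None) -> str:
    present = set(alignment.references)
    if contig is not None:
        if contig in present:
            return contig
        raise InputError(f"contig {contig!r} not found in alignment header")
    for alias in CONTIG_ALIASES:
        if alias in present:
            return alias
    raise InputError(
        f"no mitochondrial contig among {CONTIG_ALIASES} in alignment header"
    )


def extract_mito_reads(
    alignment_path: str | Path,
    contig: str | None = None,
    barcode_tag: str = "CB",
    barcode_regex: str | None = None,
    valid_barcodes: set[str] | None = None,
) -> ReadSet:
    """Collect per-base observations from the mitochondrial contig.

    ``barcode_regex``, when given, takes the barcode from the first capture
    group matched against the read name (for pipelines that prefix barcodes
    to read names) instead of the tag. Reads with no resolvable barcode, or
    a barcode outside ``valid_barcodes`` when a whitelist is given, are
    skipped; a file where *no* read yields a barcode is a format error.
    """
    import pysam

    path = Path(alignment_path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    mode = "r" if path.suffix == ".sam" else "rb"
    pattern = re.compile(barcode_regex) if barcode_regex else None
    rows: list[tuple[str, int, str, int]] = []
    n_reads = 0
    with pysam.AlignmentFile(str(path), mode) as fh:
        name = _resolve_contig(fh, contig)
        if path.suffix != ".sam" and not fh.has_index():
            raise InputError(f"alignment file has no index: {path} (samtools index)")
        it = fh.fetch(name) if path.suffix != ".sam" else (
            r for r in fh if r.reference_name == name
        )
        for read in it:
            if read.is_unmapped or read.is_duplicate or read.is_secondary \
                    or read.is_supplementary:
                continue
            if pattern is not None:
                m = pattern.search(read.query_name)
                bc = m.group(1) if m else None
            else:
                bc = read.get_tag(barcode_tag) if read.has_tag(barcode_tag) else None
            if bc is None:
                continue
            if valid_barcodes is not None and bc not in valid_barcodes:
                continue
            n_reads += 1
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in BASE_INDEX or rpos >= MT_LENGTH:
                    continue
                q = quals[qpos] if quals is not None else 0
                rows.append((bc, rpos + 1, base, int(q)))
    if rows == [] and n_reads == 0:
        # distinguish truly empty contig from barcode-format failure
        with pysam.AlignmentFile(str(path), mode) as fh:
            any_read = any(
                not (r.is_unmapped or r.is_secondary or r.is_supplementary
                     or r.is_duplicate)
                and (r.reference_name == _resolve_contig(fh, contig))
                for r in fh
            )
        if any_read and valid_barcodes is None:
            raise InputError(
                "no cell barcode found in any read "
                f"(tag {barcode_tag!r}, regex {barcode_regex!r})"
            )
    records = pd.DataFrame(rows, columns=["barcode", "position", "base", "qual"])
    return ReadSet(records)


def read_barcode_list(path: str | Path) -> set[str]:
    """Load a barcode whitelist (one per line, optionally gzipped)."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {line.strip() for line in fh if line.strip()}


def pileup(reads: ReadSet, min_base_quality: int = 20) -> PileupCounts:
    """Tally base counts per position, bulk and per barcode.

    Bases below ``min_base_quality`` are excluded; bulk counts are by
    construction the sum of the per-barcode counts.
    """
    bulk = np.zeros((MT_LENGTH, 4), dtype=np.int64)
    per_barcode: dict[str, dict[int, np.ndarray]] = {}
    rec = reads.records
    if len(rec) == 0:
        return PileupCounts(bulk, per_barcode)
    keep = rec[rec["qual"] >= min_base_quality]
    for bc, pos, base in zip(keep["barcode"], keep["position"], keep["base"]):
        b = BASE_INDEX[base]
        bulk[pos - 1, b] += 1
        cell = per_barcode.setdefault(bc, {})
        vec = cell.get(pos)
        if vec is None:
            vec = cell[pos] = np.zeros(4, dtype=np.int64)
        vec[b] += 1
    return PileupCounts(bulk, per_barcode)
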
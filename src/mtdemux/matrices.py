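"""Per-cell reference/alternative allele count matrices.

Cells are rows, candidate variants are columns. The derived frequency matrix
is alt/(alt+ref) with NaN marking *missing* entries (zero depth): a cell that
was never sequenced at a site is not evidence of the reference allele, and
the germline filter's denominator ("cells with a non-zero VAF") must count
observed cells only. For clustering, missing entries are imputed as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import InputError


@dataclass
class AlleleCountMatrices:
    """Paired cell x variant count matrices plus the derived VAF matrix."""

    ref_counts: sp.csr_matrix
    alt_counts: sp.csr_matrix
    barcodes: list[str]
    variant_names: list[str]

    def __post_init__(self) -> None:
        if self.ref_counts.shape != self.alt_counts.shape:
            raise InputError("ref and alt matrices must share shape")
        if self.ref_counts.shape != (len(self.barcodes), len(self.variant_names)):
            raise InputError("matrix shape does not match labels")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InputError("duplicate barcodes")
        if (self.ref_counts.data < 0).any() or (self.alt_counts.data < 0).any():
            raise InputError("negative allele counts")

    @classmethod
    def from_dense(cls, ref, alt, barcodes, variant_names) -> "AlleleCountMatrices":
        return cls(
            sp.csr_matrix(np.asarray(ref)),
            sp.csr_matrix(np.asarray(alt)),
            list(barcodes),
            list(variant_names),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref_counts.shape

    def depth(self) -> np.ndarray:
        """Dense total-count matrix (ref + alt)."""
        return (self.ref_counts + self.alt_counts).toarray()

    def frequency(self) -> np.ndarray:
        """Dense VAF matrix, NaN where depth is zero."""
        depth = self.depth().astype(float)
        alt = self.alt_counts.toarray().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(depth > 0, alt / np.where(depth > 0, depth, 1), np.nan)
        return freq

    def subset_variants(self, columns) -> "AlleleCountMatrices":
        cols = np.asarray(columns)
        return AlleleCountMatrices(
            self.ref_counts[:, cols].tocsr(),
            self.alt_counts[:, cols].tocsr(),
            self.barcodes,
            [self.variant_names[j] for j in cols],
        )

    # ---- persistence -------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(out / "ref.mtx", self.ref_counts)
        scipy.io.mmwrite(out / "alt.mtx", self.alt_counts)
        pd.Series(self.barcodes).to_csv(out / "barcodes.tsv", index=False, header=False)
        pd.Series(self.variant_names).to_csv(
            out / "variants.tsv", index=False, header=False
        )
        freq = pd.DataFrame(
            self.frequency(), index=self.barcodes, columns=self.variant_names
        )
        freq.to_csv(out / "frequency.tsv.gz", sep="\t", na_rep="NA")

    @classmethod
    def read(cls, in_dir: str | Path) -> "AlleleCountMatrices":
        src = Path(in_dir)
        for name in ("ref.mtx", "alt.mtx", "barcodes.tsv", "variants.tsv"):
            if not (src / name).exists():
                raise InputError(f"missing matrix file: {src / name}")
        ref = sp.csr_matrix(scipy.io.mmread(src / "ref.mtx"))
        alt = sp.csr_matrix(scipy.io.mmread(src / "alt.mtx"))
        barcodes = pd.read_csv(src / "barcodes.tsv", header=None)[0].astype(str).tolist()
        variants = pd.read_csv(src / "variants.tsv", header=None)[0].astype(str).tolist()
        return cls(ref.astype(np.int64), alt.astype(np.int64), barcodes, variants)


def build_matrices(per_barcode_counts, variants, barcodes) -> AlleleCountMatrices:
    """Assemble count matrices from a barcode-aware pileup.

    Parameters
    ----------
    per_barcode_counts
        Mapping ``barcode -> {position (1-based) -> length-4 base-count
        array}`` as produced by :func:`mtdemux.pileup.pileup`.
    variants
        A variant table (``position``, ``ref``, ``alt`` columns) defining the
        column order.
    barcodes
        Row order; rows for barcodes absent from the pileup are zero.
    """
    from .pileup import BASE_INDEX

    if len(variants) == 0:
        raise InputError("variant table is empty")
    barcodes = list(barcodes)
    if len(set(barcodes)) != len(barcodes):
        raise InputError("duplicate barcodes")
    positions = variants["position"].to_numpy()
    ref_idx = [BASE_INDEX[b] for b in variants["ref"]]
    alt_idx = [BASE_INDEX[b] for b in variants["alt"]]
    ref = np.zeros((len(barcodes), len(variants)), dtype=np.int64)
    alt = np.zeros_like(ref)
    for i, bc in enumerate(barcodes):
        counts = per_barcode_counts.get(bc)
        if not counts:
            continue
        for j, pos in enumerate(positions):
            vec = counts.get(int(pos))
            if vec is None:
                continue
            ref[i, j] = vec[ref_idx[j]]
            alt[i, j] = vec[alt_idx[j]]
    names = [
        f"{int(p)}{r}>{a}" for p, r, a in zip(positions, variants["ref"], variants["alt"])
    ]
    return AlleleCountMatrices.from_dense(ref, alt, barcodes, names)
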
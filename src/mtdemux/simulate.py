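"""Synthetic pooled mitochondrial libraries with known donor origins.

The generator works at the allele-count level: each donor carries a private
set of homoplasmic mtDNA variants (plus optional variants shared between
donors), each cell draws an independent Poisson depth at every candidate
variant site, and sequencing noise flips a binomial share of alleles.
Doublets are formed by summing the read counts of two parent cells chosen
uniformly at random, so cross- and same-donor doublets both occur (with an
expected cross-donor share of (N-1)/N for N equally mixed donors).

Depth calibration: 1000 mitochondrial reads per cell corresponds to roughly
4x mean per-site coverage, i.e. mean per-variant depth =
``reads_per_cell * 4 / 1000``.

An optional read-level mode writes a toy SAM (1 bp reads tagged with CB)
whose pileup reproduces the count matrices exactly, plus a synthetic
reference FASTA; it exists so the alignment-facing modules can be exercised
end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError
from .matrices import AlleleCountMatrices

MT_LENGTH = 16_569
BASES = "ACGT"
COVERAGE_PER_READ = 4.0 / 1000.0  # 1000 reads/cell ~ 4x mean coverage


@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide mitochondrial variant, 1-based position."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not (1 <= self.position <= MT_LENGTH):
            raise ParameterError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.ref == self.alt:
            raise ParameterError("ref and alt base must differ")

    @property
    def name(self) -> str:
        return f"{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class DonorHaplotype:
    """A donor's homoplasmic variant complement."""

    donor_id: str
    private_variants: frozenset[Variant]
    shared_variants: frozenset[Variant]

    @property
    def variants(self) -> frozenset[Variant]:
        return self.private_variants | self.shared_variants


@dataclass
class SimulatedDataset:
    """Ground-truth pooled dataset: haplotypes, per-barcode truth and counts.

    ``truth`` has one row per output barcode with columns
    ``barcode, kind (singlet|doublet), donor1, donor2``.
    """

    haplotypes: list[DonorHaplotype]
    truth: pd.DataFrame
    matrices: AlleleCountMatrices
    params: dict = field(default_factory=dict)

    @property
    def variants(self) -> list[Variant]:
        return list(self.params["variant_objects"])

    def donor_index(self, donor_id: str) -> int:
        return [h.donor_id for h in self.haplotypes].index(donor_id)


def simulate_haplotypes(
    n_donors: int,
    n_private_per_donor: int | tuple[int, int] = (5, 30),
    n_shared: int = 0,
    seed: int = 0,
) -> list[DonorHaplotype]:
    """Draw donor haplotypes with pairwise-disjoint private variant sets.

    ``n_private_per_donor`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled per donor. Shared variants are carried by a
    random subset of >= 2 donors. Positions are sampled without replacement
    from the 16,569 bp circle, so requesting more variants than positions
    raises :class:`CapacityError`.
    """
    if n_donors < 1:
        raise ParameterError("n_donors must be >= 1")
    if n_shared and n_donors < 2:
        raise ParameterError("shared variants require at least 2 donors")
    rng = np.random.default_rng(seed)
    if isinstance(n_private_per_donor, (tuple, list)):
        low, high = n_private_per_donor
        n_private = rng.integers(low, high + 1, size=n_donors)
    else:
        n_private = np.full(n_donors, int(n_private_per_donor))
    total = int(n_private.sum()) + n_shared
    if total > MT_LENGTH:
        raise CapacityError(
            f"{total} variants requested but only {MT_LENGTH} positions exist"
        )
    positions = rng.choice(np.arange(1, MT_LENGTH + 1), size=total, replace=False)
    ref_idx = rng.integers(0, 4, size=total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=total)) % 4
    variants = [
        Variant(int(p), BASES[r], BASES[a])
        for p, r, a in zip(positions, ref_idx, alt_idx)
    ]
    shared = variants[:n_shared]
    rest = variants[n_shared:]
    shared_carriers: list[set[int]] = []
    for _ in shared:
        k = int(rng.integers(2, n_donors + 1))
        shared_carriers.append(set(rng.choice(n_donors, size=k, replace=False)))
    haplotypes = []
    offset = 0
    for d in range(n_donors):
        mine = frozenset(rest[offset : offset + int(n_private[d])])
        offset += int(n_private[d])
        sh = frozenset(v for v, carriers in zip(shared, shared_carriers) if d in carriers)
        haplotypes.append(DonorHaplotype(f"donor{d}", mine, sh))
    return haplotypes


def simulate_cells(
    haplotypes: list[DonorHaplotype],
    cells_per_donor: int,
    reads_per_cell: int,
    doublet_fraction: float = 0.0,
    error_rate: float = 0.002,
    seed: int = 0,
    keep_parents: bool = False,
) -> SimulatedDataset:
    """Simulate a pooled library of singlets and read-count-merged doublets.

    The number of output barcodes is ``n_donors * cells_per_donor``; a
    ``doublet_fraction`` share of them are doublets, each the elementwise sum
    of two parent singlets (the parents are removed from the output). Mean
    per-variant depth is ``reads_per_cell * 4/1000``, drawn Poisson per cell
    and site; ``error_rate`` flips alleles Binomial(depth, error_rate).
    """
    if not 0 <= doublet_fraction < 1:
        raise ParameterError("doublet_fraction must be in [0, 1)")
    if reads_per_cell <= 0:
        raise ParameterError("reads_per_cell must be positive")
    n_donors = len(haplotypes)
    n_out = n_donors * cells_per_donor
    n_doublets = int(round(doublet_fraction * n_out))
    if n_doublets > 0 and n_out + n_doublets < 2:
        raise ParameterError("need at least 2 cells to form a doublet")
    n_initial = n_out + n_doublets  # each doublet consumes 2 parents, yields 1

    variants = sorted({v for h in haplotypes for v in h.variants})
    var_index = {v: j for j, v in enumerate(variants)}
    n_var = len(variants)
    carries = np.zeros((n_donors, n_var), dtype=bool)
    for d, h in enumerate(haplotypes):
        for v in h.variants:
            carries[d, var_index[v]] = True

    rng = np.random.default_rng(seed)
    donor_of = np.repeat(np.arange(n_donors), cells_per_donor)
    if n_initial > n_out:
        donor_of = np.concatenate(
            [donor_of, rng.integers(0, n_donors, size=n_initial - n_out)]
        )
    donor_of = rng.permutation(donor_of)

    mean_depth = reads_per_cell * COVERAGE_PER_READ
    depth = rng.poisson(mean_depth, size=(n_initial, n_var))
    errors = rng.binomial(depth, error_rate)
    carried = carries[donor_of]
    # carried sites: true allele is alt, errors flip alt->ref; else the reverse
    alt = np.where(carried, depth - errors, errors)
    ref = depth - alt

    parent_ids = rng.choice(n_initial, size=2 * n_doublets, replace=False)
    pairs = parent_ids.reshape(n_doublets, 2)
    singlet_mask = np.ones(n_initial, dtype=bool)
    singlet_mask[parent_ids] = False

    rows_ref, rows_alt, records = [], [], []
    parent_rows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for i in np.flatnonzero(singlet_mask):
        rows_ref.append(ref[i])
        rows_alt.append(alt[i])
        records.append(("singlet", haplotypes[donor_of[i]].donor_id, ""))
    for a, b in pairs:
        rows_ref.append(ref[a] + ref[b])
        rows_alt.append(alt[a] + alt[b])
        records.append(
            ("doublet", haplotypes[donor_of[a]].donor_id, haplotypes[donor_of[b]].donor_id)
        )
        if keep_parents:
            parent_rows[f"BC{len(records) - 1:06d}"] = (
                ref[a].copy(), alt[a].copy(), ref[b].copy(), alt[b].copy()
            )
    ref_counts = np.array(rows_ref, dtype=np.int64)
    alt_counts = np.array(rows_alt, dtype=np.int64)
    barcodes = [f"BC{i:06d}" for i in range(len(records))]
    truth = pd.DataFrame(records, columns=["kind", "donor1", "donor2"])
    truth.insert(0, "barcode", barcodes)

    matrices = AlleleCountMatrices.from_dense(
        ref_counts, alt_counts, barcodes, [v.name for v in variants]
    )
    params = dict(
        n_donors=n_donors,
        cells_per_donor=cells_per_donor,
        reads_per_cell=reads_per_cell,
        doublet_fraction=doublet_fraction,
        error_rate=error_rate,
        seed=seed,
        variant_objects=variants,
    )
    if keep_parents:
        params["parent_rows"] = parent_rows
    return SimulatedDataset(list(haplotypes), truth, matrices, params)


def is_cross_genotype(truth: pd.DataFrame) -> pd.Series:
    """Boolean mask over truth rows: doublet whose two parents differ."""
    return (truth["kind"] == "doublet") & (truth["donor1"] != truth["donor2"])


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write truth table and count matrices (MatrixMarket + labels)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_truth(dataset.truth, out / "truth.tsv")
    dataset.matrices.write(out)
    return out


def toy_reference(haplotypes: list[DonorHaplotype], seed: int = 0) -> str:
    """A synthetic 16,569 bp reference with the haplotypes' ref bases planted.

    Not the real mitochondrial reference sequence: off-variant positions are
    random. Sufficient for exercising pileup and variant calling on the toy
    SAM produced by :func:`write_toy_sam`.
    """
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=MT_LENGTH)
    ref = [BASES[i] for i in seq]
    for h in haplotypes:
        for v in h.variants:
            ref[v.position - 1] = v.ref
    return "".join(ref)


def write_toy_sam(
    dataset: SimulatedDataset,
    sam_path: str | Path,
    fasta_path: str | Path | None = None,
    contig: str = "chrM",
    seed: int = 0,
) -> None:
    """Emit a toy SAM whose pileup reproduces the dataset's count matrices.

    Each read is a single aligned base (CIGAR 1M, base quality 37) carrying
    the cell barcode in the CB tag, one read per counted allele.
    """
    import pysam

    variants = dataset.variants
    ref = dataset.matrices.ref_counts.toarray()
    alt = dataset.matrices.alt_counts.toarray()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": MT_LENGTH}],
    }
    reads = []  # (pos0, barcode, base, serial)
    serial = 0
    for i, bc in enumerate(dataset.matrices.barcodes):
        for j, v in enumerate(variants):
            for base, n in ((v.ref, ref[i, j]), (v.alt, alt[i, j])):
                for _ in range(int(n)):
                    reads.append((v.position - 1, bc, base, serial))
                    serial += 1
    reads.sort()
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as fh:
        for pos0, bc, base, k in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{k:08d}"
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = "1M"
            a.query_sequence = base
            a.query_qualities = pysam.qualitystring_to_array("F")  # Q37
            a.set_tag("CB", bc)
            fh.write(a)
    if fasta_path is not None:
        seq = toy_reference(dataset.haplotypes, seed=seed)
        with open(fasta_path, "w") as fa:
            fa.write(f">{contig} synthetic\n")
            for k in range(0, MT_LENGTH, 70):
                fa.write(seq[k : k + 70] + "\n")
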
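"""End-to-end orchestration: alignment file -> demultiplexing result.

Stage order: pileup -> variant calling -> count matrices -> germline filter
-> clustering (or silhouette K estimation) -> per-cluster variant sets ->
common-variant removal -> alpha estimation -> beta-binomial scoring ->
singlet/doublet classification -> donor assignment. Every stage's timing and
output size is logged, and the effective configuration is written into the
output directory for reproducibility.

Local realignment of mitochondrial reads (e.g. with GATK IndelRealigner) is
a recommended external pre-step for aligner artifact reduction; the pipeline
consumes any coordinate-sorted, indexed BAM/SAM.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import clustering, doublet, matrices as mat, metrics, variants as var
from .pileup import extract_mito_reads, pileup as build_pileup, read_barcode_list
from .errors import InputError

log = logging.getLogger("mtdemux")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the published method values."""

    # inputs
    bam: str | None = None
    reference: str | None = None
    barcodes: str | None = None
    matrix_dir: str | None = None
    contig: str | None = None
    barcode_tag: str = "CB"
    barcode_regex: str | None = None
    # variant calling
    min_base_quality: int = 20
    min_var_freq: float = 0.01
    min_depth: int = 8
    min_reads2: int = 2
    bulk_vaf_low: float = 0.01
    bulk_vaf_high: float = 0.99
    # clustering
    k: int | None = None           # None -> estimate via silhouette
    k_range: tuple[int, int] = (2, 12)
    method: str = "kmeans"
    seed: int = clustering.DEFAULT_SEED
    max_occurrence: int = 1
    vaf_high: float = 0.99
    vaf_low: float = 0.0
    min_carrier_fraction: float = 0.25
    # doublet model
    direct: bool = False
    first_fit: str = "label"
    singlet_p1: float = 0.99
    singlet_p2: float = 0.01
    doublet_p1: float = 0.8
    doublet_p2: float = 0.2
    knn_k: int = 5
    trust_p1: bool = True
    # output
    out_dir: str = "mtdemux_out"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["k_range"] = tuple(d.get("k_range", (2, 12)))
        return cls(**d)


def _stage(name: str, t0: float, detail: str = "") -> float:
    t1 = time.perf_counter()
    log.info("stage %-18s %6.2fs  %s", name, t1 - t0, detail)
    return t1


def demux_matrices(counts: mat.AlleleCountMatrices, config: RunConfig):
    """Clustering + doublet stages on prebuilt count matrices.

    Returns (result DataFrame, ClusterModel, PosteriorScoreTable).
    """
    t0 = time.perf_counter()
    if config.direct:
        if config.k is None:
            freq = counts.frequency()
            retained = clustering.filter_germline(
                freq, vaf_high=config.vaf_high, vaf_low=config.vaf_low
            )
            k = clustering.estimate_k(
                freq[:, retained], k_range=config.k_range,
                method=config.method, seed=config.seed,
            )
            log.info("silhouette-estimated K = %d", k)
        else:
            k = config.k
        scores, model, _ = doublet.direct_mode(
            counts, k, seed=config.seed,
            vaf_high=config.vaf_high, vaf_low=config.vaf_low,
        )
        t0 = _stage("direct_mode", t0, f"K={k}")
    else:
        if config.k is None:
            freq = counts.frequency()
            retained = clustering.filter_germline(
                freq, vaf_high=config.vaf_high, vaf_low=config.vaf_low
            )
            k = clustering.estimate_k(
                freq[:, retained], k_range=config.k_range,
                method=config.method, seed=config.seed,
            )
            log.info("silhouette-estimated K = %d", k)
        else:
            k = config.k
        model, retained = clustering.fit_cluster_model(
            counts, k, method=config.method, seed=config.seed,
            max_occurrence=config.max_occurrence,
            vaf_high=config.vaf_high, vaf_low=config.vaf_low,
            min_carrier_fraction=config.min_carrier_fraction,
        )
        t0 = _stage(
            "clustering", t0,
            f"K={k}, {len(retained)} germline variants, "
            f"sets={[len(s) for s in model.variant_sets]}",
        )
        scores = doublet.score_cells(
            counts.subset_variants(retained), model, first_fit=config.first_fit
        )
        t0 = _stage("scoring", t0, f"{len(scores.barcodes)} cells")
    labels = doublet.classify(
        scores,
        singlet_p1=config.singlet_p1, singlet_p2=config.singlet_p2,
        doublet_p1=config.doublet_p1, doublet_p2=config.doublet_p2,
        knn_k=config.knn_k, trust_p1=config.trust_p1,
    )
    result = doublet.assign_singlets(scores, labels)
    _stage("classification", t0, f"{(labels == 'Singlet').sum()} singlets, "
           f"{(labels == 'Doublet').sum()} doublets")
    return result, model, scores


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline and write all artifacts to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        (out / "config.json").write_text(config.to_json())
        t0 = time.perf_counter()
        if config.matrix_dir is not None:
            counts = mat.AlleleCountMatrices.read(config.matrix_dir)
            t0 = _stage("load_matrices", t0, f"{counts.shape}")
        else:
            if config.bam is None or config.reference is None:
                raise InputError("need either --matrix-dir or --bam plus --reference")
            whitelist = (
                read_barcode_list(config.barcodes) if config.barcodes else None
            )
            reads = extract_mito_reads(
                config.bam, contig=config.contig,
                barcode_tag=config.barcode_tag,
                barcode_regex=config.barcode_regex,
                valid_barcodes=whitelist,
            )
            t0 = _stage("extract_reads", t0, f"{len(reads)} base observations")
            counts_pileup = build_pileup(reads, min_base_quality=config.min_base_quality)
            t0 = _stage("pileup", t0, f"{len(counts_pileup.per_barcode)} barcodes")
            reference = var.read_reference_fasta(config.reference)
            table = var.call_variants(
                counts_pileup, reference,
                min_var_freq=config.min_var_freq,
                min_depth=config.min_depth,
                min_reads2=config.min_reads2,
                bulk_vaf_window=(config.bulk_vaf_low, config.bulk_vaf_high),
            )
            if table.empty:
                raise InputError("no candidate variant passed the calling thresholds")
            var.write_variant_table(table, out / "variants.tsv")
            var.write_vcf(table, out / "variants.vcf",
                          contig=config.contig or "chrM")
            t0 = _stage("call_variants", t0, f"{len(table)} candidate SNVs")
            barcodes = sorted(counts_pileup.per_barcode) if whitelist is None \
                else sorted(whitelist)
            counts = mat.build_matrices(counts_pileup.per_barcode, table, barcodes)
            counts.write(out / "matrices")
            t0 = _stage("build_matrices", t0, f"{counts.shape}")
        result, model, _scores = demux_matrices(counts, config)
        result.to_csv(out / "demux_result.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"barcode": counts.barcodes, "cluster": model.labels}
        ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
        rows = [
            (i, name)
            for i, s in enumerate(model.variant_sets)
            for name in (model.variant_names[j] if model.variant_names else j for j in s)
        ]
        pd.DataFrame(rows, columns=["cluster", "variant"]).to_csv(
            out / "specific_variants.tsv", sep="\t", index=False
        )
        (out / "model.json").write_text(json.dumps(model.to_dict(), indent=2))
        return out
    finally:
        log.removeHandler(fh)
        fh.close()


def evaluate_result(
    truth: pd.DataFrame, result: pd.DataFrame
) -> dict[str, float]:
    """Standard metric bundle of a run against a simulation truth table."""
    from .simulate import is_cross_genotype

    t_class = metrics.truth_class_labels(truth)
    p_class = metrics.predicted_class_labels(result)
    acc = metrics.accuracy(t_class, p_class)

    singlet_truth = truth[truth["kind"] == "singlet"]
    t_singlet = t_class.loc[singlet_truth["barcode"]]
    p_singlet = p_class.loc[singlet_truth["barcode"]]
    mapping = metrics.match_clusters(t_class, p_class)
    p_mapped = p_singlet.map(lambda x: mapping.get(x, x))
    singlet_acc = float((t_singlet.to_numpy() == p_mapped.to_numpy()).mean())

    is_doublet = pd.Series(
        (truth["kind"] == "doublet").to_numpy(), index=truth["barcode"].to_numpy()
    )
    p2 = pd.Series(result["p2"].to_numpy(), index=result["barcode"].to_numpy())
    called = pd.Series(
        (result["label"] == "Doublet").to_numpy(), index=result["barcode"].to_numpy()
    )
    # same-genotype doublets are invisible to a genotype-based method and are
    # excluded from the detection benchmark (the reference simulations pool
    # cross-genotype doublets only)
    cross = is_cross_genotype(truth)
    same = is_doublet & ~pd.Series(
        cross.to_numpy(), index=truth["barcode"].to_numpy()
    )
    keep = ~same
    dm = metrics.doublet_metrics(
        is_doublet[keep], p2.fillna(0.0)[keep], called[keep]
    )
    cross_bc = truth.loc[cross, "barcode"]
    cross_tpr = (
        float(called.loc[cross_bc].mean()) if len(cross_bc) else float("nan")
    )
    singlet_bc = singlet_truth["barcode"]
    singlet_as_doublet = float(called.loc[singlet_bc].mean())
    donor_tpr = float(
        ((t_singlet.to_numpy() == p_mapped.to_numpy())).sum() / len(singlet_bc)
    )
    truth_sing = t_class[t_class != metrics.DOUBLET_CLASS]
    pred_sing = p_class[(result.set_index("barcode")["label"] == "Singlet").reindex(p_class.index, fill_value=False)]
    shared = truth_sing.index.intersection(pred_sing.index)
    ari_val = metrics.ari(truth_sing.loc[shared], pred_sing.loc[shared]) if len(shared) else float("nan")
    return {
        "accuracy": acc,
        "singlet_accuracy": singlet_acc,
        "donor_tpr": donor_tpr,
        "doublet_tpr_cross": cross_tpr,
        "singlet_misclassified_as_doublet": singlet_as_doublet,
        "ari_singlets": ari_val,
        "auc": dm["auc"],
        "tpr_all_doublets": dm["tpr"],
        "fdr_doublets": dm["fdr"],
    }
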
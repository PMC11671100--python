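"""Beta-binomial scoring of cells against genotype clusters.

For cell *c* and cluster *i*, the alternative-allele count over cluster *i*'s
sample-specific variants observed in *c* is binomial with success probability
*p*; a conjugate Beta(alpha_i, 1) prior yields the posterior
Beta(alpha_i + A1, 1 + A0), whose mode

    p = (alpha + A1 - 1) / (alpha + beta + A1 + A0 - 2)

is the cell's score against that cluster. A singlet of donor *i* scores
p ~ 1 against cluster *i* and low elsewhere; a cross-genotype doublet scores
intermediate against both parents. ``p1`` is the posterior for the cell's
first-fitted cluster, ``p2`` the best posterior among the remaining
clusters; thresholds on (p1, p2) call Singlet / Doublet, and cells matching
neither rule are resolved by majority vote of their 5 nearest labeled
neighbours in (p1, p2) space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.cluster import KMeans
from sklearn.neighbors import KNeighborsClassifier

from .clustering import ClusterModel, DEFAULT_SEED, filter_germline
from .errors import InputError, ParameterError

MISSING = float("nan")


def binomial_likelihood(A1: int, N: int, p: float) -> float:
    """Binomial pmf C(N, A1) p^A1 (1-p)^(N-A1), computed in log space."""
    if not 0 <= A1 <= N:
        raise ParameterError(f"require 0 <= A1 <= N, got A1={A1}, N={N}")
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must lie in [0, 1]")
    return float(np.exp(binom.logpmf(A1, N, p)))


def posterior_p(A1: int, A0: int, alpha: float, beta: float = 1.0) -> float:
    """Mode of the Beta(alpha + A1, beta + A0) posterior.

    Returns NaN when the mode is undefined (uniform prior and no data).
    """
    denom = alpha + beta + A1 + A0 - 2.0
    if denom <= 0:
        return MISSING
    return (alpha + A1 - 1.0) / denom


@dataclass
class PosteriorScoreTable:
    """Per-cell posteriors against every cluster plus the (p1, p2) summary."""

    barcodes: list[str]
    p: np.ndarray  # (cells, K), NaN where the cluster's set is uncovered
    p1: np.ndarray
    p2: np.ndarray
    first_cluster: np.ndarray
    second_cluster: np.ndarray
    n_observed: np.ndarray

    @property
    def scorable(self) -> np.ndarray:
        return ~np.isnan(self.p1)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "p1": self.p1,
                "p2": self.p2,
                "first_cluster": self.first_cluster,
                "second_cluster": self.second_cluster,
                "n_variants_observed": self.n_observed,
            }
        )


def score_cells(
    matrices,
    model: ClusterModel,
    first_fit: str = "label",
) -> PosteriorScoreTable:
    """Score every cell against every cluster's specific variant set.

    ``first_fit`` selects what counts as the first-fitted cluster: the
    cell's initial clustering label (``"label"``, falling back to the best
    posterior when the label's set is uncovered in that cell) or the argmax
    posterior (``"argmax"``, used by direct mode).
    """
    ref = matrices.ref_counts.toarray()
    alt = matrices.alt_counts.toarray()
    n_cells = ref.shape[0]
    K = model.K
    p = np.full((n_cells, K), np.nan)
    union_cols = sorted({j for s in model.variant_sets for j in s})
    depth_union = (ref[:, union_cols] + alt[:, union_cols]) > 0
    n_observed = depth_union.sum(axis=1)
    for i, cols in enumerate(model.variant_sets):
        if not cols:
            raise InputError(f"cluster {i} has an empty variant set")
        A1 = alt[:, cols].sum(axis=1)
        A0 = ref[:, cols].sum(axis=1)
        covered = (A1 + A0) > 0
        ai = model.alpha[i]
        with np.errstate(invalid="ignore"):
            vals = (ai + A1 - 1.0) / (ai + model.beta + A1 + A0 - 2.0)
        p[covered, i] = vals[covered]

    first = np.full(n_cells, -1, dtype=int)
    if first_fit == "label":
        first = np.asarray(model.labels, dtype=int).copy()
        # fall back to the best-scoring cluster where the label's set is uncovered
        bad = np.isnan(p[np.arange(n_cells), first])
        if bad.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                alt_first = np.nanargmax(np.where(np.isnan(p), -np.inf, p), axis=1)
            first[bad] = alt_first[bad]
    elif first_fit == "argmax":
        filled = np.where(np.isnan(p), -np.inf, p)
        first = filled.argmax(axis=1)
    else:
        raise ParameterError(f"unknown first_fit mode: {first_fit!r}")

    p1 = p[np.arange(n_cells), first]
    others = p.copy()
    others[np.arange(n_cells), first] = np.nan
    if K == 1:
        p2 = np.zeros(n_cells)
        second = np.zeros(n_cells, dtype=int)
    else:
        filled = np.where(np.isnan(others), -np.inf, others)
        second = filled.argmax(axis=1)
        p2 = filled[np.arange(n_cells), second]
        p2[np.isinf(p2)] = np.nan
    unscorable = np.isnan(p).all(axis=1)
    p1[unscorable] = np.nan
    return PosteriorScoreTable(
        barcodes=list(matrices.barcodes),
        p=p,
        p1=p1,
        p2=p2,
        first_cluster=first,
        second_cluster=second.astype(int),
        n_observed=n_observed,
    )


SINGLET, DOUBLET, UNLABELED, UNASSIGNED = "Singlet", "Doublet", "Unlabeled", "unassigned"


def classify(
    scores: PosteriorScoreTable,
    singlet_p1: float = 0.99,
    singlet_p2: float = 0.01,
    doublet_p1: float = 0.8,
    doublet_p2: float = 0.2,
    knn_k: int = 5,
    trust_p1: bool = False,
) -> np.ndarray:
    """Threshold (p1, p2) into Singlet/Doublet, KNN-resolving the rest.

    Default rules: Singlet iff p1 > 0.99 and p2 < 0.01; Doublet iff p1 < 0.8
    or p2 > 0.2. With ``trust_p1`` any cell with p1 > 0.99 is a Singlet
    regardless of p2 (high p2 alongside a near-1 p1 is more plausibly a
    shared somatic variant than a second genotype). Cells with no coverage
    of any cluster's variants are 'unassigned'. A NaN p2 (no coverage of any
    *other* cluster) contributes no doublet evidence and is treated as 0.
    """
    if len(scores.barcodes) == 0:
        raise InputError("empty score table")
    p1 = scores.p1
    p2 = np.where(np.isnan(scores.p2), 0.0, scores.p2)
    labels = np.full(len(p1), UNLABELED, dtype=object)
    scorable = scores.scorable
    labels[~scorable] = UNASSIGNED
    if trust_p1:
        singlet = scorable & (p1 > singlet_p1)
    else:
        singlet = scorable & (p1 > singlet_p1) & (p2 < singlet_p2)
    doublet = scorable & ~singlet & ((p1 < doublet_p1) | (p2 > doublet_p2))
    labels[singlet] = SINGLET
    labels[doublet] = DOUBLET

    unlabeled = labels == UNLABELED
    if unlabeled.any():
        train = singlet | doublet
        classes = set(labels[train])
        if {SINGLET, DOUBLET} <= classes:
            X = np.column_stack([p1, p2])
            knn = KNeighborsClassifier(n_neighbors=min(knn_k, int(train.sum())))
            knn.fit(X[train], labels[train])
            labels[unlabeled] = knn.predict(X[unlabeled])
        elif classes:
            # one-class threshold labels: everything unresolved joins that class?
            # no -- keep threshold labels and warn, as promised.
            warnings.warn(
                "KNN rescue skipped: need labeled cells of both classes; "
                "returning threshold labels only"
            )
        else:
            warnings.warn("no cell passed either threshold rule; labels unresolved")
    return labels


def assign_singlets(
    scores: PosteriorScoreTable, labels: np.ndarray
) -> pd.DataFrame:
    """Final per-cell table: donor assignment for singlets, pair for doublets.

    Singlets go to the cluster with the highest posterior (ties to the lower
    index, with a warning); doublets carry (first-fitted, second) clusters.
    """
    n = len(scores.barcodes)
    donor = np.full(n, -1, dtype=int)
    second = np.full(n, -1, dtype=int)
    filled = np.where(np.isnan(scores.p), -np.inf, scores.p)
    argmax = filled.argmax(axis=1)  # numpy argmax: first (lowest) index wins ties
    ties = (filled == filled[np.arange(n), argmax][:, None]).sum(axis=1) > 1
    if np.any(ties & (labels == SINGLET)):
        warnings.warn(
            f"{int((ties & (labels == SINGLET)).sum())} singlet(s) had tied "
            "posteriors; assigned to the lower cluster index"
        )
    is_singlet = labels == SINGLET
    is_doublet = labels == DOUBLET
    donor[is_singlet] = argmax[is_singlet]
    donor[is_doublet] = scores.first_cluster[is_doublet]
    second[is_doublet] = scores.second_cluster[is_doublet]

    out = scores.frame()
    out["label"] = [UNASSIGNED if l == UNLABELED else l for l in labels]
    out["donor"] = [f"cluster{d}" if d >= 0 else UNASSIGNED for d in donor]
    out["second_donor"] = [f"cluster{d}" if d >= 0 else "" for d in second]
    out["donor_index"] = donor
    out["second_donor_index"] = second
    out["p_by_cluster"] = [
        ";".join("NA" if np.isnan(v) else f"{v:.6g}" for v in row) for row in scores.p
    ]
    cols = [
        "barcode", "label", "donor", "second_donor", "p1", "p2",
        "p_by_cluster", "n_variants_observed", "donor_index",
        "second_donor_index", "first_cluster", "second_cluster",
    ]
    return out[cols]


def direct_mode(
    matrices,
    K: int,
    seed: int = DEFAULT_SEED,
    vaf_high: float = 0.99,
    vaf_low: float = 0.0,
) -> tuple[PosteriorScoreTable, ClusterModel, np.ndarray]:
    """Variant-first scoring for hard-to-cluster cells.

    Germline-filtered variants are grouped into K clusters by their
    across-cell VAF profiles; each group plays the role of a donor's
    specific variant set, cells get provisional labels by their best mean
    observed VAF per group (used only to scale alpha), and scoring runs with
    the first-fitted cluster taken as the argmax posterior.

    Returns (scores, model, retained column indices of ``matrices``).
    """
    freq_all = matrices.frequency()
    retained = filter_germline(freq_all, vaf_high=vaf_high, vaf_low=vaf_low)
    if K > retained.size:
        raise ParameterError(
            f"K={K} exceeds the {retained.size} germline variants available"
        )
    sub = matrices.subset_variants(retained)
    freq = sub.frequency()
    X = np.nan_to_num(freq, nan=0.0).T  # variants as samples
    if K == 1:
        groups = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(
            n_clusters=K, max_iter=1000, tol=1e-5, n_init=10,
            algorithm="lloyd", random_state=seed,
        )
        groups = km.fit_predict(X)
    variant_sets = [list(np.flatnonzero(groups == k)) for k in range(K)]
    # provisional cell labels: best mean observed VAF over each group
    means = np.full((freq.shape[0], K), -np.inf)
    for k, cols in enumerate(variant_sets):
        if not cols:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(freq[:, cols], axis=1)
        means[:, k] = np.where(np.isnan(m), -np.inf, m)
    provisional = means.argmax(axis=1)
    alt = sub.alt_counts.toarray()
    alpha = np.empty(K)
    for k, cols in enumerate(variant_sets):
        cells = provisional == k
        if not cols:
            raise ParameterError(f"variant group {k} is empty; lower K")
        block = alt[np.ix_(cells, cols)] if cells.any() else alt[:, cols]
        alpha[k] = 1.0 + block.mean(axis=0).mean()
    model = ClusterModel(
        K=K, labels=provisional, variant_sets=variant_sets, alpha=alpha,
        variant_names=sub.variant_names,
    )
    scores = score_cells(sub, model, first_fit="argmax")
    return scores, model, retained
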
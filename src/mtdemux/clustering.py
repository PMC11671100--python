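"""Germline-variant selection and genotype clustering.

A variant is accepted as a high-confidence germline marker when, among cells
that show any alternate allele at all (VAF > 0, missing entries excluded),
more than half are effectively homoplasmic (VAF > 0.99). Cells are then
clustered on the VAF matrix (K-means by default, or a Gaussian mixture),
each cluster's own variant set is derived with the same homoplasmy rule
restricted to its cells, and variants appearing in several clusters' sets
are removed so that the surviving sets are sample-specific. When the number
of pooled donors is unknown it is estimated by maximising the mean
silhouette score over a candidate range.

The beta-binomial prior scale for each cluster is alpha_i = 1 + mean (over
the cluster's specific variants) of the mean alternative-allele count among
the cluster's cells, with beta fixed at 1 — i.e. the prior pseudo-counts
reflect the typical per-variant coverage of a true carrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .errors import DegenerateModelError, InputError, ParameterError

DEFAULT_SEED = 42


@dataclass
class ClusterModel:
    """Fitted genotype-clustering model.

    ``variant_sets[i]`` holds column indices (into the matrix the model was
    fitted on) of cluster *i*'s sample-specific germline variants.
    """

    K: int
    labels: np.ndarray
    variant_sets: list[list[int]]
    alpha: np.ndarray
    beta: float = 1.0
    variant_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "alpha": [float(a) for a in self.alpha],
            "beta": self.beta,
            "variant_sets": [
                [self.variant_names[j] if self.variant_names else int(j) for j in s]
                for s in self.variant_sets
            ],
        }


def _homoplasmy_keep(freq_col: np.ndarray, vaf_high: float, vaf_low: float) -> bool:
    observed = freq_col[~np.isnan(freq_col)]
    nonzero = observed[observed > vaf_low]
    if nonzero.size == 0:
        return False
    return (nonzero > vaf_high).sum() / nonzero.size > 0.5


def filter_germline(
    freq: np.ndarray, vaf_high: float = 0.99, vaf_low: float = 0.0
) -> np.ndarray:
    """Indices of columns passing the homoplasmy-majority germline rule.

    Keep variant v iff |cells with VAF > ``vaf_high``| / |cells with
    VAF > ``vaf_low``| > 0.5, counting non-missing cells only; columns with
    no non-zero cell are dropped.
    """
    freq = np.asarray(freq, dtype=float)
    if freq.size == 0:
        raise InputError("empty frequency matrix")
    keep = [
        j for j in range(freq.shape[1]) if _homoplasmy_keep(freq[:, j], vaf_high, vaf_low)
    ]
    return np.array(keep, dtype=int)


def impute_missing(freq: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Replace missing (NaN) VAF entries, default with 0 (reference-like)."""
    out = np.asarray(freq, dtype=float).copy()
    out[np.isnan(out)] = fill
    return out


def initial_cluster(
    freq: np.ndarray,
    K: int,
    method: str = "kmeans",
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """Cluster cells on the (imputed) VAF matrix into K genotypes.

    K-means runs with max_iter=1000, tol=1e-5, n_init=10, Lloyd iterations;
    the Gaussian mixture uses the same iteration budget.
    """
    X = impute_missing(freq)
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > X.shape[0]:
        raise ParameterError(f"K={K} exceeds number of cells {X.shape[0]}")
    if K == 1:
        return np.zeros(X.shape[0], dtype=int)
    if method == "kmeans":
        model = KMeans(
            n_clusters=K, max_iter=1000, tol=1e-5, n_init=10,
            algorithm="lloyd", random_state=seed,
        )
        labels = model.fit_predict(X)
    elif method == "gmm":
        model = GaussianMixture(
            n_components=K, max_iter=1000, tol=1e-5, n_init=10,
            covariance_type="diag", random_state=seed,
        )
        labels = model.fit_predict(X)
    else:
        raise ParameterError(f"unknown clustering method: {method!r}")
    if len(np.unique(labels)) < K:
        warnings.warn(f"only {len(np.unique(labels))} of {K} clusters occupied")
    return np.asarray(labels, dtype=int)


def cluster_variant_sets(
    labels: np.ndarray,
    freq: np.ndarray,
    vaf_high: float = 0.99,
    vaf_low: float = 0.0,
    min_carrier_fraction: float = 0.0,
    n_clusters: int | None = None,
) -> list[list[int]]:
    """Per-cluster raw variant sets by the homoplasmy rule within the cluster.

    ``min_carrier_fraction`` additionally requires the variant to be seen
    (VAF > ``vaf_low``) in at least that fraction of the cluster's covered
    cells. A germline variant of the cluster's donor is carried by every
    cell, so its carrier fraction among covered cells is ~1; at shallow
    depth (~1x) a handful of doublet or error cells can otherwise produce
    spurious single-cell VAF = 1 entries whose tiny denominator passes the
    homoplasmy-majority rule. The default 0 applies the bare rule.
    """
    labels = np.asarray(labels)
    freq = np.asarray(freq, dtype=float)
    K = n_clusters if n_clusters is not None else (
        int(labels.max()) + 1 if labels.size else 0
    )
    sets: list[list[int]] = []
    for k in range(K):
        cells = labels == k
        if not cells.any():
            warnings.warn(f"cluster {k} is empty; its variant set is empty")
            sets.append([])
            continue
        sub = freq[cells]
        cols = []
        for j in range(freq.shape[1]):
            col = sub[:, j]
            if not _homoplasmy_keep(col, vaf_high, vaf_low):
                continue
            if min_carrier_fraction > 0:
                observed = col[~np.isnan(col)]
                carrier = (observed > vaf_low).sum() / observed.size
                if carrier < min_carrier_fraction:
                    continue
            cols.append(j)
        sets.append(cols)
    return sets


def remove_common(
    raw_sets: list[list[int]], max_occurrence: int = 1
) -> list[list[int]]:
    """Drop variants present in more than ``max_occurrence`` cluster sets.

    The default (1) enforces strict sample-specificity: any variant shared by
    two or more clusters is removed. ``max_occurrence=2`` keeps variants
    shared by exactly two clusters. A cluster left with no variants is a
    model degeneracy — rerun with a different K or use direct mode.
    """
    from collections import Counter

    occ = Counter(j for s in raw_sets for j in set(s))
    out = [[j for j in s if occ[j] <= max_occurrence] for s in raw_sets]
    for k, s in enumerate(out):
        if not s:
            raise DegenerateModelError(
                f"cluster {k} has no sample-specific variants after removing "
                "common variants; try --direct mode or a different K"
            )
    return out


def estimate_k(
    freq: np.ndarray,
    k_range: tuple[int, int] = (2, 12),
    method: str = "kmeans",
    seed: int = DEFAULT_SEED,
) -> int:
    """Pick K maximising the mean silhouette score; ties go to smaller K."""
    X = impute_missing(freq)
    lo, hi = k_range
    if lo < 2 or hi >= X.shape[0]:
        raise ParameterError("k_range must lie within 2..cells-1")
    if np.allclose(X, X[0]):
        raise InputError("all cells identical; cluster number is undefined")
    best_k, best_score = None, -np.inf
    for k in range(lo, hi + 1):
        labels = initial_cluster(X, k, method=method, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:  # strict: ties keep the smaller k
            best_k, best_score = k, score
    if best_k is None:
        raise DegenerateModelError("silhouette scan found no valid clustering")
    return best_k


def estimate_alpha(
    alt_counts: np.ndarray,
    labels: np.ndarray,
    variant_sets: list[list[int]],
) -> np.ndarray:
    """Per-cluster beta-binomial prior: alpha_i = 1 + mean alt count over G_i.

    The inner mean is over the cluster's cells at each variant; the outer
    mean is over the cluster's specific variants. With no alternate reads at
    all, alpha collapses to 1 (uniform Beta(1, 1) prior).
    """
    alt = np.asarray(alt_counts)
    labels = np.asarray(labels)
    alphas = np.empty(len(variant_sets), dtype=float)
    for i, cols in enumerate(variant_sets):
        cells = labels == i
        if not cols or not cells.any():
            raise DegenerateModelError(f"cluster {i} has no variants or no cells")
        per_variant_mean = alt[np.ix_(cells, cols)].mean(axis=0)
        alphas[i] = 1.0 + per_variant_mean.mean()
    return alphas


def fit_cluster_model(
    matrices,
    K: int,
    method: str = "kmeans",
    seed: int = DEFAULT_SEED,
    max_occurrence: int = 1,
    vaf_high: float = 0.99,
    vaf_low: float = 0.0,
    min_carrier_fraction: float = 0.25,
) -> tuple[ClusterModel, np.ndarray]:
    """Full clustering stage on germline-filtered matrices.

    Returns the fitted model and the retained column indices of the input
    matrices (the model's variant sets index into the retained submatrix).
    """
    freq_all = matrices.frequency()
    retained = filter_germline(freq_all, vaf_high=vaf_high, vaf_low=vaf_low)
    if retained.size == 0:
        raise DegenerateModelError("no variant passed the germline filter")
    sub = matrices.subset_variants(retained)
    freq = sub.frequency()
    labels = initial_cluster(freq, K, method=method, seed=seed)
    raw_sets = cluster_variant_sets(
        labels, freq, vaf_high=vaf_high, vaf_low=vaf_low,
        min_carrier_fraction=min_carrier_fraction, n_clusters=K,
    )
    sets = remove_common(raw_sets, max_occurrence=max_occurrence)
    alpha = estimate_alpha(sub.alt_counts.toarray(), labels, sets)
    model = ClusterModel(
        K=K, labels=labels, variant_sets=sets, alpha=alpha,
        variant_names=sub.variant_names,
    )
    return model, retained
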
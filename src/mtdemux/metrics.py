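"""Benchmark metrics for demultiplexing results.

Predicted cluster indices carry no donor identity, so donor-level accuracy
first matches clusters to donors by maximum-weight bipartite matching on the
singlet contingency table; the doublet class is compared as itself. ARI and
AUC come from scikit-learn; TPR/FDR conventions are stated on the function.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .errors import InputError

DOUBLET_CLASS = "doublet"


def _align(truth: pd.Series, predicted: pd.Series) -> tuple[pd.Series, pd.Series]:
    common = truth.index.intersection(predicted.index)
    if len(common) == 0:
        raise InputError("no shared barcodes between the two label tables")
    return truth.loc[common].astype(str), predicted.loc[common].astype(str)


def match_clusters(truth: pd.Series, predicted: pd.Series) -> dict[str, str]:
    """Map predicted cluster labels to truth donor labels.

    Maximum-weight matching on the contingency table restricted to cells
    that are non-doublet in both labelings. Unmatched predicted labels map
    to themselves.
    """
    t, p = _align(truth, predicted)
    mask = (t != DOUBLET_CLASS) & (p != DOUBLET_CLASS)
    table = pd.crosstab(p[mask], t[mask])
    if table.size == 0:
        return {}
    rows, cols = linear_sum_assignment(table.to_numpy(), maximize=True)
    return {table.index[r]: table.columns[c] for r, c in zip(rows, cols)}


def accuracy(
    truth: pd.Series, predicted: pd.Series, permutation_matching: bool = True
) -> float:
    """Fraction of cells whose predicted class equals the truth class.

    Classes are donor identities plus 'doublet'. With
    ``permutation_matching`` the predicted donor labels are first optimally
    permuted onto truth donors.
    """
    t, p = _align(truth, predicted)
    if permutation_matching:
        mapping = match_clusters(t, p)
        p = p.map(lambda x: mapping.get(x, x))
    return float((t.to_numpy() == p.to_numpy()).mean())


def ari(truth: pd.Series, predicted: pd.Series) -> float:
    """Adjusted Rand index between the two partitions (pair-counting)."""
    t, p = _align(truth, predicted)
    return float(adjusted_rand_score(t, p))


def doublet_metrics(
    is_doublet_truth: pd.Series,
    p2_scores: pd.Series,
    predicted_is_doublet: pd.Series,
) -> dict[str, float]:
    """AUC (p2 as the doublet score), TPR and FDR of doublet calls.

    TPR = detected true doublets / true doublets; FDR = false doublet calls
    / all doublet calls, defined as 0 when nothing is called.
    """
    common = is_doublet_truth.index.intersection(p2_scores.index)
    if len(common) == 0:
        raise InputError("no shared barcodes")
    y = is_doublet_truth.loc[common].astype(bool).to_numpy()
    s = p2_scores.loc[common].astype(float).to_numpy()
    called = predicted_is_doublet.loc[common].astype(bool).to_numpy()
    auc = float(roc_auc_score(y, np.nan_to_num(s))) if 0 < y.sum() < len(y) else float("nan")
    n_true = int(y.sum())
    tpr = float((called & y).sum() / n_true) if n_true else float("nan")
    n_called = int(called.sum())
    fdr = float((called & ~y).sum() / n_called) if n_called else 0.0
    return {"auc": auc, "tpr": tpr, "fdr": fdr}


def concordance_table(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Row-normalised percentage matrix between two labelings.

    Rows are ``labels_a`` classes, columns ``labels_b``; each row sums to
    100 over the barcode intersection. Cells unassigned by either labeling
    are excluded from the denominators.
    """
    a, b = _align(labels_a, labels_b)
    keep = (a.str.lower() != "unassigned") & (b.str.lower() != "unassigned")
    a, b = a[keep], b[keep]
    table = pd.crosstab(a, b)
    return table.div(table.sum(axis=1), axis=0) * 100.0


def same_genotype_doublet_estimate(n_cross_doublets: int, n_donors: int) -> float:
    """Expected same-genotype doublet count given the observed cross count.

    Under uniform pairing of N equally mixed donors, a doublet is
    cross-genotype with probability (N-1)/N; the unobservable same-genotype
    doublets are therefore n_cross / ((N-1)/N) * (1/N).
    """
    if n_donors < 2:
        raise InputError("need at least 2 donors")
    cross_share = (n_donors - 1) / n_donors
    return n_cross_doublets / cross_share * (1.0 / n_donors)


def truth_class_labels(truth: pd.DataFrame) -> pd.Series:
    """Truth table -> per-barcode class labels (donor id or 'doublet')."""
    labels = truth["donor1"].where(truth["kind"] == "singlet", DOUBLET_CLASS)
    return pd.Series(labels.to_numpy(), index=truth["barcode"].to_numpy())


def predicted_class_labels(result: pd.DataFrame) -> pd.Series:
    """Demux result table -> per-barcode class labels (cluster or 'doublet')."""
    labels = result["donor"].where(result["label"] == "Singlet", result["label"])
    labels = labels.replace({"Doublet": DOUBLET_CLASS})
    return pd.Series(labels.to_numpy(), index=result["barcode"].to_numpy())
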
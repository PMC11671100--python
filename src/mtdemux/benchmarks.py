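"""Seeded simulation benchmarks of the full demultiplexing pipeline.

Each benchmark generates a pooled synthetic library (donors with 5-30
private homoplasmic variants each, per-site depth calibrated as
reads_per_cell * 4/1000, base-flip error rate 0.002, 8% read-count-merged
doublets unless stated otherwise), runs the complete clustering + doublet
pipeline with K equal to the number of donors, and evaluates against the
generator's truth table. Used by the acceptance script and the acceptance
tests; all randomness flows from the supplied seed.
"""

from __future__ import annotations

import numpy as np

from .pipeline import RunConfig, demux_matrices, evaluate_result
from .simulate import simulate_cells, simulate_haplotypes

PRIVATE_RANGE = (5, 30)
N_SHARED = 3
ERROR_RATE = 0.002
DOUBLET_FRACTION = 0.08


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_replicate(
    n_donors: int,
    cells_per_donor: int,
    reads_per_cell: int,
    seed: int,
    doublet_fraction: float = DOUBLET_FRACTION,
    error_rate: float = ERROR_RATE,
) -> dict[str, float]:
    """One simulate -> demultiplex -> evaluate cycle; returns the metric bundle."""
    hap_seed, cell_seed, fit_seed = _sub_seeds(seed, 3)
    haps = simulate_haplotypes(
        n_donors, n_private_per_donor=PRIVATE_RANGE, n_shared=N_SHARED, seed=hap_seed
    )
    data = simulate_cells(
        haps, cells_per_donor, reads_per_cell,
        doublet_fraction=doublet_fraction, error_rate=error_rate, seed=cell_seed,
    )
    config = RunConfig(k=n_donors, seed=fit_seed)
    result, _model, _scores = demux_matrices(data.matrices, config)
    return evaluate_result(data.truth, result)


def mean_metric(
    metric: str,
    n_donors: int,
    cells_per_donor: int,
    reads_per_cell: int,
    seed: int,
    n_replicates: int = 5,
    **kwargs,
) -> float:
    vals = [
        run_replicate(n_donors, cells_per_donor, reads_per_cell, s, **kwargs)[metric]
        for s in _sub_seeds(seed, n_replicates)
    ]
    return float(np.mean(vals))


def acceptance_targets(seed: int) -> dict[str, dict[str, float]]:
    """Recompute the headline simulation quantities (percent scale).

    t5: overall classification accuracy (donors + doublet class) at the
        lowest simulated depth, 250 reads/cell, mean of 5 replicates.
    t6: singlet donor-assignment accuracy at 1000 reads/cell (~4x coverage).
    t7: percent of true singlets miscalled as doublets at 2000 reads/cell,
        500 cells per donor, mean of 5 replicates.
    t8: the lower of donor-assignment TPR and cross-genotype doublet TPR at
        100 cells per donor, 2000 reads/cell.
    """
    seeds = _sub_seeds(seed, 4)
    t5 = mean_metric("accuracy", 8, 100, 250, seeds[0], n_replicates=5) * 100
    rep6 = run_replicate(8, 100, 1000, seeds[1])
    t6 = rep6["singlet_accuracy"] * 100
    t7 = mean_metric(
        "singlet_misclassified_as_doublet", 8, 500, 2000, seeds[2], n_replicates=5
    ) * 100
    rep8 = run_replicate(8, 100, 2000, seeds[3])
    t8 = min(rep8["donor_tpr"], rep8["doublet_tpr_cross"]) * 100
    return {
        "t5": {"value": t5, "n": 8 * 100 * 5},
        "t6": {"value": t6, "n": 8 * 100},
        "t7": {"value": t7, "n": 8 * 500 * 5},
        "t8": {"value": t8, "n": 8 * 100},
    }
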
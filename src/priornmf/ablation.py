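"""Exhaustive ablation over the 16 binary loss-switch subsets.

Each subset of {reconstruction, ZINB, z-score, classification} switches is
trained on the same data and seeds; the imputed matrix is clustered with
the generic k-means helper and scored by ARI against the truth labels and
by mean silhouette. Rows are keyed by the 4-bit mask (nmf, zinb, zscore,
class) in a fixed order, the all-zeros baseline first.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .imputation import impute_zeros
from .io import CountMatrix, LabelTable
from .metrics import adjusted_rand_index, kmeans_partition, silhouette_mean
from .objectives import LossWeights
from .training import TrainingConfig, fit

ALL_SUBSETS = [
    (b >> 3 & 1, b >> 2 & 1, b >> 1 & 1, b & 1) for b in range(16)
]


def score_partitioning(imputed: CountMatrix, labels: LabelTable, seed: int) -> tuple[float, float]:
    """ARI and mean silhouette of k-means (k = number of types) on the
    log1p-transformed matrix."""
    rep = np.log1p(imputed.values)
    truth = [labels.assignments[c] for c in imputed.cell_ids]
    pred = kmeans_partition(rep, n_clusters=labels.C, seed=seed)
    return adjusted_rand_index(truth, pred), silhouette_mean(rep, pred)


def ablation_table(
    X: CountMatrix,
    labels: LabelTable,
    k: int,
    base_cfg: TrainingConfig,
    seeds: list[int],
) -> list[dict]:
    """One row per switch subset with per-seed and mean ARI / silhouette."""
    rows = []
    for lam_nmf, lam_zinb, lam_zscore, lam_class in ALL_SUBSETS:
        weights = LossWeights(lam_nmf, lam_zinb, lam_zscore, lam_class)
        aris, sils = [], []
        for seed in seeds:
            cfg = replace(base_cfg, weights=weights, seed=seed)
            _, out, _ = fit(X, labels, None, k, cfg)
            result = impute_zeros(X, out)
            ari, sil = score_partitioning(result.imputed, labels, seed)
            aris.append(ari)
            sils.append(sil)
        rows.append(
            {
                "mask": f"{lam_nmf}{lam_zinb}{lam_zscore}{lam_class}",
                "lam_nmf": lam_nmf, "lam_zinb": lam_zinb,
                "lam_zscore": lam_zscore, "lam_class": lam_class,
                "ari_mean": float(np.mean(aris)),
                "silhouette_mean": float(np.mean(sils)),
                "ari_per_seed": aris,
                "silhouette_per_seed": sils,
            }
        )
    return rows
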
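"""Score an imputation with the evaluation suite.

k-means on the log1p matrix gives a predicted partition; external metrics
(ARI, Hungarian-matched accuracy, macro-F1) compare it with the true cell
types, silhouette measures cluster geometry, the per-gene Pearson summary
measures how much the imputation distorted observed expression, and the
leakage ratio asks whether marker genes of one type were spuriously
activated in the others (lower is better).
"""

import numpy as np

from priornmf import (
    DropoutSpec, SimulationConfig, TrainingConfig,
    adjusted_rand_index, clustering_accuracy, fit, gene_pearson, impute_zeros,
    kmeans_partition, leakage_ratio, macro_f1, silhouette_mean, simulate_counts,
)

ds = simulate_counts(SimulationConfig(dropout=DropoutSpec(rate=0.5), seed=0))
_, out, _ = fit(ds.X, ds.labels, None, 3, TrainingConfig(seed=0))
imputed = impute_zeros(ds.X, out).imputed

truth = [ds.labels.assignments[c] for c in ds.X.cell_ids]
for name, M in (("raw", ds.X.values), ("imputed", imputed.values)):
    rep = np.log1p(M)
    pred = kmeans_partition(rep, n_clusters=3, seed=0)
    print(f"{name:8s} ARI={adjusted_rand_index(truth, pred):.3f} "
          f"ACC={clustering_accuracy(truth, pred):.3f} "
          f"F1={macro_f1(truth, pred):.3f} "
          f"silhouette={silhouette_mean(rep, pred):.3f}")

print(f"gene-level Pearson (raw vs imputed): {gene_pearson(ds.X, imputed).mean:.3f}")

markers = ds.marker_genes("type0")
correct = [i for i, c in enumerate(ds.X.cell_ids) if truth[i] == "type0"]
wrong = [i for i, c in enumerate(ds.X.cell_ids) if truth[i] != "type0"]
for name, M in (("raw", ds.X), ("imputed", imputed)):
    lr = leakage_ratio(M, ds.X.gene_ids, markers, correct, wrong)
    print(f"{name:8s} type0-marker leakage ratio = {lr:.3f}")
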
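"""Label-degradation protocols: how much prior quality matters.

A1 keeps only a fraction of the labels (stratified); A2 keeps all labels
but reassigns a fraction of cells to a wrong type. Both feed the degraded
table to the supervised fit and score k-means ARI on the imputed matrix
against the *original* truth — so the curves show how gracefully the
prior-guided model degrades, and that clean labels are never worse than
noisy ones.
"""

import numpy as np

from priornmf import (
    DropoutSpec, SimulationConfig, TrainingConfig, adjusted_rand_index,
    fit, impute_zeros, kmeans_partition, perturb_labels, simulate_counts,
    subsample_labels,
)

ds = simulate_counts(SimulationConfig(
    n_cells=200, n_genes=100, k_types=3, dropout=DropoutSpec(rate=0.5), seed=0))
truth = [ds.labels.assignments[c] for c in ds.X.cell_ids]


def score(labels, lam_class):
    from priornmf import LossWeights
    weights = LossWeights(1, 1, 1, lam_class)
    _, out, _ = fit(ds.X, labels if labels.n_labeled else None, None, 3,
                    TrainingConfig(weights=weights, max_epochs=300, seed=0))
    imputed = impute_zeros(ds.X, out).imputed
    pred = kmeans_partition(np.log1p(imputed.values), 3, seed=0)
    return adjusted_rand_index(truth, pred)


print("A1: label fraction -> imputed k-means ARI vs truth")
for fraction in (0.0, 0.05, 0.10, 0.25, 0.50, 1.0):
    kept = subsample_labels(ds.labels, fraction, seed=0)
    ari = score(kept, lam_class=1 if kept.n_labeled else 0)
    print(f"  {fraction:5.0%} labels ({kept.n_labeled:3d} cells): ARI {ari:.3f}")

print("A2: label noise -> imputed k-means ARI vs truth")
for noise in (0.0, 0.10, 0.20, 0.30, 0.40):
    noisy = perturb_labels(ds.labels, noise, seed=0)
    print(f"  {noise:5.0%} noise: ARI {score(noisy, 1):.3f}")
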
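"""Evaluation suite for imputation quality.

External clustering agreement (ARI, Hungarian-matched accuracy, macro-F1,
macro one-vs-rest AUC), internal geometry (mean silhouette), RNA-velocity
direction correctness at cluster boundaries (CBDir), per-gene raw/imputed
Pearson correlation, marker-leakage ratio, and the subsampled agreement of
gene-gene correlation structure against a reference matrix.

Partitions are plain sequences of hashable cluster ids; standard metrics
delegate to scikit-learn / scipy. CBDir and the matrix-structure metrics are
implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm
from sklearn.cluster import KMeans

from .io import CountMatrix


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)


def _codes(labels) -> np.ndarray:
    labels = list(labels)
    lut: dict = {}
    return np.array([lut.setdefault(x, len(lut)) for x in labels], dtype=int)


def _check_lengths(a, b):
    if len(a) != len(b):
        raise ValueError(f"partition length mismatch: {len(a)} vs {len(b)}")


def adjusted_rand_index(a, b) -> float:
    """Pair-counting Rand agreement corrected for chance; 1 for identical
    partitions, ~0 for independent ones."""
    _check_lengths(a, b)
    return float(skm.adjusted_rand_score(_codes(a), _codes(b)))


def contingency(truth, pred) -> np.ndarray:
    t, p = _codes(truth), _codes(pred)
    table = np.zeros((t.max() + 1, p.max() + 1), dtype=int)
    np.add.at(table, (t, p), 1)
    return table


def hungarian_mapping(truth, pred) -> dict[int, int]:
    """Optimal cluster->class assignment (max total matches) on the
    contingency table; rectangular tables are handled."""
    table = contingency(truth, pred)
    rows, cols = linear_sum_assignment(-table.T)  # rows: pred clusters
    return {int(r): int(c) for r, c in zip(rows, cols)}


def clustering_accuracy(truth, pred) -> float:
    """Fraction of cells correct after the optimal one-to-one
    cluster-to-class matching (Hungarian algorithm)."""
    _check_lengths(truth, pred)
    table = contingency(truth, pred)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(list(truth)))


def macro_f1(truth, pred, mapping: str = "hungarian") -> float:
    """Macro-averaged F1 after mapping predicted clusters to classes.

    mapping='hungarian' relabels clusters optimally first; 'identity'
    assumes cluster ids already are class codes. Classes with an empty
    precision or recall denominator contribute F1 = 0.
    """
    _check_lengths(truth, pred)
    t, p = _codes(truth), _codes(pred)
    if mapping == "hungarian":
        mp = hungarian_mapping(truth, pred)
        p = np.array([mp.get(int(c), -1) for c in p])
    elif mapping != "identity":
        raise ValueError(f"unknown mapping {mapping!r}")
    classes = np.unique(t)
    return float(skm.f1_score(t, p, labels=classes, average="macro", zero_division=0))


def macro_auc_ovr(truth, scores) -> float:
    """Macro mean of per-class one-vs-rest ROC AUC (rank statistic, ties
    averaged). Classes with no positives or no negatives are skipped."""
    t = _codes(truth)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != t.shape[0]:
        raise ValueError("scores and truth length mismatch")
    if scores.shape[1] < t.max() + 1:
        raise ValueError("score columns do not cover all truth classes")
    aucs = []
    for c in np.unique(t):
        pos = t == c
        if pos.all() or not pos.any():
            continue
        aucs.append(skm.roc_auc_score(pos.astype(int), scores[:, c]))
    if not aucs:
        raise ValueError("no class had both positives and negatives")
    return float(np.mean(aucs))


def silhouette_mean(X, labels, metric: str = "euclidean") -> float:
    """Mean silhouette s(i) = (b-a)/max(a,b) over all cells; singleton
    clusters score 0. Requires >= 2 clusters."""
    Xv = _values(X)
    codes = _codes(labels)
    if np.unique(codes).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(skm.silhouette_score(Xv, codes, metric=metric))


@dataclass
class Embedding:
    """Low-dimensional positions with optional velocities and a neighbor
    graph (list/dict of neighbor index sets, self excluded)."""

    coords: np.ndarray
    velocity: np.ndarray | None = None
    neighbor_graph: dict[int, set[int]] | None = None


def knn_graph(coords: np.ndarray, n_neighbors: int) -> dict[int, set[int]]:
    """Euclidean k-nearest-neighbor sets (self excluded); plain plumbing for
    CBDir when no graph is supplied."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1)[:, :n_neighbors]
    return {i: set(map(int, order[i])) for i in range(coords.shape[0])}


def cbdir(emb: Embedding, truth, source, target) -> float | None:
    """Cross-boundary direction correctness for the transition source->target.

    Boundary cells are source-cluster cells with at least one neighbor in
    the target cluster. For each boundary cell c the cosine between its
    velocity v_c and the displacement x_c' - x_c is averaged over target
    neighbors c'; the score is the mean over boundary cells. Returns None
    when the clusters share no boundary (the score is undefined, not 0).
    """
    if emb.velocity is None or emb.neighbor_graph is None:
        raise ValueError("CBDir requires velocities and a neighbor graph")
    labels = np.asarray(list(truth), dtype=object)
    src_cells = np.where(labels == source)[0]
    tgt_set = set(np.where(labels == target)[0].tolist())
    per_cell = []
    for c in src_cells:
        nbrs = emb.neighbor_graph.get(int(c), set()) & tgt_set
        if not nbrs:
            continue
        v = emb.velocity[c]
        cosines = []
        for c2 in sorted(nbrs):
            disp = emb.coords[c2] - emb.coords[c]
            denom = np.linalg.norm(v) * np.linalg.norm(disp)
            cosines.append(float(v @ disp / denom) if denom > 0 else 0.0)
        per_cell.append(float(np.mean(cosines)))
    if not per_cell:
        return None
    return float(np.mean(per_cell))


@dataclass
class GenePearsonResult:
    r: np.ndarray            # per-gene correlation, NaN where undefined
    mean: float              # mean over defined genes
    n_undefined: int


def gene_pearson(raw, imputed) -> GenePearsonResult:
    """Per-gene Pearson correlation between raw and imputed expression
    vectors; zero-variance genes are excluded from the summary."""
    R, I = _values(raw), _values(imputed)
    if R.shape != I.shape:
        raise ValueError(f"shape mismatch {R.shape} vs {I.shape}")
    Rc = R - R.mean(axis=0)
    Ic = I - I.mean(axis=0)
    sr = np.sqrt((Rc ** 2).sum(axis=0))
    si = np.sqrt((Ic ** 2).sum(axis=0))
    defined = (sr > 0) & (si > 0)
    r = np.full(R.shape[1], np.nan)
    r[defined] = (Rc * Ic).sum(axis=0)[defined] / (sr * si)[defined]
    if not defined.any():
        raise ValueError("no gene has nonzero variance in both matrices")
    return GenePearsonResult(r, float(r[defined].mean()), int((~defined).sum()))


def leakage_ratio(M, gene_ids, markers, correct_cells, wrong_cells) -> float:
    """Mean marker expression in the wrong cell group divided by the mean in
    the correct group; lower means less spurious cross-type signal."""
    Mv = _values(M)
    gidx = [gene_ids.index(g) for g in markers]
    if not gidx:
        raise ValueError("empty marker set")
    correct_cells, wrong_cells = list(correct_cells), list(wrong_cells)
    if not correct_cells or not wrong_cells:
        raise ValueError("cell sets must be nonempty")
    if set(correct_cells) & set(wrong_cells):
        raise ValueError("cell sets must be disjoint")
    num = Mv[np.ix_(wrong_cells, gidx)].mean()
    den = Mv[np.ix_(correct_cells, gidx)].mean()
    if den == 0:
        raise ValueError("zero marker expression in the correct cell type")
    return float(num / den)


def _gene_corr(M: np.ndarray) -> np.ndarray:
    """Gene-gene Pearson matrix; zero-variance genes get zero off-diagonal
    correlations and a unit diagonal."""
    C = M - M.mean(axis=0)
    sd = C.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(C)
    Z[:, ok] = C[:, ok] / sd[ok]
    corr = (Z.T @ Z) / M.shape[0]
    np.fill_diagonal(corr, 1.0)
    return corr


def correlation_structure_agreement(
    ref_corr: np.ndarray,
    M,
    subsample_fraction: float = 0.2,
    iterations: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stability of the gene-gene correlation structure against a reference.

    Per iteration: subsample the given fraction of cells without
    replacement, compute the subsample's gene-gene Pearson matrix, and
    record (a) the Pearson correlation between the upper-triangle entries of
    the two matrices and (b) the Frobenius norm of their difference.
    """
    Mv = _values(M)
    ref_corr = np.asarray(ref_corr, dtype=float)
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    n = Mv.shape[0]
    size = max(int(round(subsample_fraction * n)), 1)
    if size < 3:
        raise ValueError(f"subsample of {size} cells is too small for correlations")
    iu = np.triu_indices(ref_corr.shape[0], k=1)
    ref_ut = ref_corr[iu]
    rng = np.random.default_rng(seed)
    sims, dists = np.empty(iterations), np.empty(iterations)
    for it in range(iterations):
        idx = rng.choice(n, size=size, replace=False)
        corr = _gene_corr(Mv[idx])
        ut = corr[iu]
        sims[it] = np.corrcoef(ref_ut, ut)[0, 1]
        dists[it] = np.linalg.norm(corr - ref_corr)
    return sims, dists


def kmeans_partition(M, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Generic k-means helper for turning a matrix into a partition before
    external metrics (plumbing, not part of the model)."""
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(_values(M))
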
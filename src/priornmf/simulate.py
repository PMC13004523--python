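"""Synthetic clustered count data with known ground truth.

Counts follow the assumed generative process for single-cell expression:
each cell belongs to one of k types, each type has a gene-expression
profile, library depths vary log-normally across cells, transcriptional
bursting makes counts negative-binomial (a Gamma-Poisson mixture with
shared dispersion theta), and technical dropout zeroes entries with a
per-entry Bernoulli whose rate is either constant or decreasing in the
log mean — lowly expressed genes drop out more, the feature that makes
technical zeros distinguishable from biological ones.

Type profiles carry exclusive marker blocks (a contiguous run of up-
regulated genes per type) so leakage and recovery have unambiguous truth.
Everything is fully determined by the seed.

Also provides the two label-degradation protocols used in robustness
studies: retaining a fraction of labels (stratified subsampling) and
injecting label noise (reassigning a fraction of cells to a random wrong
type).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import CountMatrix, LabelTable


@dataclass
class DropoutSpec:
    """Constant-rate dropout (``rate``) or a logistic rate decreasing in
    log1p of the true mean: p = sigmoid(intercept - slope * log1p(mu))."""

    rate: float | None = None
    intercept: float = 1.0
    slope: float = 1.0

    def probabilities(self, mu_true: np.ndarray) -> np.ndarray:
        if self.rate is not None:
            if not (0.0 <= self.rate < 1.0):
                raise ValueError("dropout rate must be in [0, 1)")
            return np.full_like(mu_true, self.rate)
        z = self.intercept - self.slope * np.log1p(mu_true)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SimulationConfig:
    n_cells: int = 300
    n_genes: int = 150
    k_types: int = 3
    type_proportions: list[float] | None = None
    theta_true: float = 2.0
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    depth_spread: float = 0.3      # log-normal sigma of per-cell depths
    base_mean_log_mu: float = 0.0  # log-normal base gene means (median 1)
    base_mean_log_sigma: float = 1.0
    marker_fraction: float = 0.2   # genes per type reserved as markers
    marker_fold: float = 8.0       # fold change of a type's marker block
    seed: int = 0

    def __post_init__(self):
        if self.type_proportions is None:
            self.type_proportions = [1.0 / self.k_types] * self.k_types
        props = np.asarray(self.type_proportions, dtype=float)
        if props.size != self.k_types or np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("type_proportions must be k positive weights summing to 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    X: CountMatrix
    X_complete: CountMatrix
    mu_true: np.ndarray
    labels: LabelTable
    dropout_mask: np.ndarray
    config: SimulationConfig

    def marker_genes(self, type_name: str) -> list[str]:
        """Gene ids of the exclusive marker block of ``type_name``."""
        cfg = self.config
        l = self.labels.types.index(type_name)
        block = max(int(cfg.marker_fraction * cfg.n_genes / cfg.k_types), 1)
        start = l * block
        return self.X.gene_ids[start:start + block]


def _profiles(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    base = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sigma, size=cfg.n_genes)
    profiles = np.tile(base, (cfg.k_types, 1))
    block = max(int(cfg.marker_fraction * cfg.n_genes / cfg.k_types), 1)
    for l in range(cfg.k_types):
        start = l * block
        profiles[l, start:start + block] *= cfg.marker_fold
    return profiles


def simulate_counts(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw a full dataset: types, depths, NB counts, then dropout."""
    rng = np.random.default_rng(cfg.seed)
    types = rng.choice(cfg.k_types, size=cfg.n_cells, p=cfg.type_proportions)
    if np.unique(types).size < cfg.k_types:
        raise ValueError("a cell type received no cells; increase n_cells or proportions")
    profiles = _profiles(cfg, rng)
    depths = rng.lognormal(0.0, cfg.depth_spread, size=cfg.n_cells)
    mu_true = depths[:, None] * profiles[types]
    # Gamma-Poisson mixture: counts are NB(mean=mu, dispersion=theta)
    lam = rng.gamma(shape=cfg.theta_true, scale=mu_true / cfg.theta_true)
    complete = rng.poisson(lam).astype(float)
    p_drop = cfg.dropout.probabilities(mu_true)
    mask = rng.uniform(size=mu_true.shape) < p_drop
    observed = np.where(mask, 0.0, complete)
    # a cell fully zeroed by dropout has no usable signal; resurrect its
    # largest true entry so size factors stay defined
    dead = observed.sum(axis=1) == 0
    for i in np.where(dead)[0]:
        j = int(np.argmax(complete[i])) if complete[i].max() > 0 else int(np.argmax(mu_true[i]))
        observed[i, j] = max(complete[i, j], 1.0)
        mask[i, j] = False
    cell_ids = [f"cell{i:04d}" for i in range(cfg.n_cells)]
    gene_ids = [f"gene{j:04d}" for j in range(cfg.n_genes)]
    type_names = [f"type{l}" for l in range(cfg.k_types)]
    labels = LabelTable({cell_ids[i]: type_names[types[i]] for i in range(cfg.n_cells)},
                        types=type_names)
    return SimulatedDataset(
        X=CountMatrix(observed, cell_ids, gene_ids),
        X_complete=CountMatrix(complete, list(cell_ids), list(gene_ids)),
        mu_true=mu_true,
        labels=labels,
        dropout_mask=mask,
        config=cfg,
    )


def subsample_labels(labels: LabelTable, fraction: float, seed: int) -> LabelTable:
    """Retain round(fraction * n_labeled) labels, stratified by type via
    largest-remainder allocation so the total is exact."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    cells = list(labels.assignments)
    total_keep = int(round(fraction * len(cells)))
    if total_keep == 0:
        return LabelTable({}, types=list(labels.types))
    if total_keep == len(cells):
        return LabelTable(dict(labels.assignments), types=list(labels.types))
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[str]] = {}
    for c in cells:
        by_type.setdefault(labels.assignments[c], []).append(c)
    names = list(by_type)
    sizes = np.array([len(by_type[t]) for t in names], dtype=float)
    exact = total_keep * sizes / sizes.sum()
    keep = np.floor(exact).astype(int)
    remainder_order = np.argsort(-(exact - keep), kind="stable")
    for idx in remainder_order[: total_keep - keep.sum()]:
        keep[idx] += 1
    kept: dict[str, str] = {}
    for t, n_keep in zip(names, keep):
        chosen = rng.choice(len(by_type[t]), size=int(n_keep), replace=False)
        for i in sorted(chosen):
            kept[by_type[t][i]] = t
    return LabelTable(kept, types=list(labels.types))


def perturb_labels(labels: LabelTable, noise: float, seed: int) -> LabelTable:
    """Reassign round(noise * n_labeled) uniformly chosen cells to a
    uniformly random *different* type; everything else unchanged."""
    if not (0.0 <= noise <= 1.0):
        raise ValueError("noise must be in [0, 1]")
    if labels.C < 2 and noise > 0:
        raise ValueError("label perturbation needs at least 2 types")
    cells = list(labels.assignments)
    n_flip = int(round(noise * len(cells)))
    out = dict(labels.assignments)
    if n_flip == 0:
        return LabelTable(out, types=list(labels.types))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cells), size=n_flip, replace=False)
    for i in chosen:
        cid = cells[i]
        others = [t for t in labels.types if t != out[cid]]
        out[cid] = others[int(rng.integers(len(others)))]
    return LabelTable(out, types=list(labels.types))
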
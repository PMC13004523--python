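"""Factorization model: trainable parameters, priors and the forward pass.

The count matrix X (cells x genes) is modeled through two factors: a
row-stochastic cell-to-module matrix W+ and a nonnegative module-by-gene
expression matrix H+. The biological mean is mu = W+ H+; it is projected to
the observation layer as mu_adjusted[i,j] = s_i * kappa[j, b(i)] * mu[i,j],
where s is the per-cell size factor and kappa an optional per-(gene, batch)
multiplicative correction. Dropout is a per-gene structural-zero probability
pi_j = sigmoid(rho_j) shared across cells, and a single dispersion theta =
softplus(theta_raw) + 1e-4 governs overdispersion.

When cell-type labels are supplied, the supervised ("prior") mode shrinks
the trainable factors toward label-derived anchors: W+ rows of labeled cells
are the equal-weight average of the one-hot encoding P and the row softmax
of ReLU(W), and H+ is the average of the cell-type prototype means H_prior
and ReLU(H). Unlabeled cells and the unsupervised mode use the pure softmax
row and ReLU(H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BatchTable, CountMatrix, LabelTable

THETA_FLOOR = 1e-4


class ConfigurationError(ValueError):
    pass


@dataclass
class SizeFactors:
    s: np.ndarray  # positive, median 1 for odd n


@dataclass
class PriorEncoding:
    P: np.ndarray           # n x k; labeled rows one-hot, unlabeled rows zero
    H_prior: np.ndarray     # k x m nonnegative prototype means
    labeled_mask: np.ndarray  # n bool
    label_index: np.ndarray   # n int, -1 for unlabeled
    types: list[str]


@dataclass
class FactorParams:
    """The trainable set: cell factor, gene factor, dropout logits,
    dispersion pre-parameter and the linear probe."""

    W: np.ndarray           # n x k, unconstrained
    H: np.ndarray           # k x m, unconstrained
    rho: np.ndarray         # m dropout logits
    theta_raw: float
    probe_weights: np.ndarray  # k x C
    probe_bias: np.ndarray     # C

    def copy(self) -> "FactorParams":
        return FactorParams(
            self.W.copy(), self.H.copy(), self.rho.copy(), float(self.theta_raw),
            self.probe_weights.copy(), self.probe_bias.copy(),
        )


@dataclass
class BatchCorrection:
    """Fixed multiplicative per-(gene, batch) correction, zero-mean in log
    space across batches for identifiability."""

    log_kappa: np.ndarray   # m x B
    batch_index: np.ndarray  # n int

    @property
    def kappa(self) -> np.ndarray:
        return np.exp(self.log_kappa)

    def per_entry(self) -> np.ndarray:
        """n x m matrix kappa[j, b(i)]."""
        return self.kappa[:, self.batch_index].T


@dataclass
class ModelOutput:
    W_plus: np.ndarray
    H_plus: np.ndarray
    mu: np.ndarray
    mu_adjusted: np.ndarray
    pi: np.ndarray          # n x m dropout probabilities
    theta: float


def compute_size_factors(X: CountMatrix) -> SizeFactors:
    """s_i = rowsum_i / median(rowsums); requires every cell total > 0."""
    totals = X.values.sum(axis=1)
    med = float(np.median(totals))
    if med <= 0:
        raise RuntimeError("median library size is zero; load validation should prevent this")
    return SizeFactors(totals / med)


def build_prior_encoding(labels: LabelTable, X: CountMatrix, k: int) -> PriorEncoding:
    """One-hot encoding P and prototype means H_prior from raw counts.

    H_prior row l is the arithmetic mean over raw count rows of cells labeled
    with type l. Types without labeled cells — and the extra "anonymous"
    modules when k > C — fall back to the global mean row. Requires k >= C.
    """
    C = labels.C
    if k < C:
        raise ConfigurationError(f"k={k} is smaller than the number of label types C={C}")
    n, m = X.n, X.m
    idx = labels.indices(X)
    labeled = idx >= 0
    P = np.zeros((n, k))
    P[np.where(labeled)[0], idx[labeled]] = 1.0
    global_mean = X.values.mean(axis=0)
    H_prior = np.tile(global_mean, (k, 1))
    for l in range(C):
        members = idx == l
        if members.any():
            H_prior[l] = X.values[members].mean(axis=0)
    return PriorEncoding(P, H_prior, labeled, idx, list(labels.types))


def estimate_batch_correction(
    X: CountMatrix, batches: BatchTable, s: SizeFactors, pseudocount: float = 1.0
) -> BatchCorrection:
    """Moment estimate of log kappa: per-(gene, batch) log mean of
    depth-normalized counts, centered per gene across batches."""
    bidx = batches.indices(X)
    B = len(batches.batches)
    norm = X.values / s.s[:, None]
    log_means = np.zeros((X.m, B))
    for b in range(B):
        members = bidx == b
        if not members.any():
            raise ConfigurationError(f"batch {batches.batches[b]!r} has no cells")
        log_means[:, b] = np.log(norm[members].mean(axis=0) + pseudocount)
    log_kappa = log_means - log_means.mean(axis=1, keepdims=True)
    return BatchCorrection(log_kappa, bidx)


def init_params(
    n: int, m: int, k: int, C: int, seed: int, scale: float = 0.1
) -> FactorParams:
    """Small nonnegative uniform init keeps ReLU active; probe starts at zero."""
    rng = np.random.default_rng(seed)
    return FactorParams(
        W=rng.uniform(0.0, scale, size=(n, k)),
        H=rng.uniform(0.0, scale, size=(k, m)),
        rho=np.zeros(m),
        theta_raw=0.0,
        probe_weights=np.zeros((k, max(C, 1))),
        probe_bias=np.zeros(max(C, 1)),
    )


def softplus(x):
    return np.logaddexp(0.0, x)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def row_softmax(A: np.ndarray) -> np.ndarray:
    Z = A - A.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def forward(
    params: FactorParams,
    prior: PriorEncoding | None,
    s: SizeFactors,
    batch: BatchCorrection | None = None,
) -> ModelOutput:
    """Deterministic forward pass producing the mean layers and dropout map.

    The stochastic observation noise of the reconstruction is not sampled:
    imputation uses the conditional mean, and dispersion is carried by the
    ZINB likelihood.
    """
    W_hat = np.maximum(params.W, 0.0)
    H_hat = np.maximum(params.H, 0.0)
    S = row_softmax(W_hat)
    if prior is not None:
        W_plus = S.copy()
        lab = prior.labeled_mask
        W_plus[lab] = 0.5 * (prior.P[lab] + S[lab])
        H_plus = 0.5 * (prior.H_prior + H_hat)
    else:
        W_plus = S
        H_plus = H_hat
    mu = W_plus @ H_plus
    mu_adjusted = s.s[:, None] * mu
    if batch is not None:
        mu_adjusted = mu_adjusted * batch.per_entry()
    n = params.W.shape[0]
    pi = np.broadcast_to(sigmoid(params.rho), (n, params.H.shape[1])).copy()
    theta = float(softplus(params.theta_raw) + THETA_FLOOR)
    out = ModelOutput(W_plus, H_plus, mu, mu_adjusted, pi, theta)
    for name, arr in (("W_plus", W_plus), ("H_plus", H_plus), ("mu_adjusted", mu_adjusted)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite values in forward output {name}")
    return out
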
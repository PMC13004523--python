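"""The four regularization terms and the switched total objective.

Terms (all averaged over the n*m entries unless noted):

* reconstruction — the Frobenius norm (not its square) of X - mu_adjusted,
  divided by the entry count;
* ZINB negative log-likelihood — a zero-inflated negative binomial on the
  observed counts with mean mu_adjusted, per-gene dropout probability
  pi_j = sigmoid(rho_j) and a shared dispersion theta; the likelihood mean
  is the depth-adjusted reconstruction because capture/thinning acts at the
  observation layer;
* z-score consistency — mean squared difference between per-cell
  standardized rows of X and of the reconstruction (population standard
  deviation, divisor m), which preserves each cell's relative expression
  shape and is invariant to per-cell scaling, so size factors cancel;
* classification — cross-entropy of a linear probe on the W+ embedding,
  averaged over labeled cells.

Each term carries a binary switch weight in {0, 1}; the total objective is
the weighted sum. ``loss_and_grads`` additionally returns analytic gradients
of the total with respect to every trainable parameter, derived by hand and
verified against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .io import CountMatrix
from .model import (
    BatchCorrection,
    FactorParams,
    ModelOutput,
    PriorEncoding,
    SizeFactors,
    THETA_FLOOR,
    forward,
    row_softmax,
    sigmoid,
)

MU_CLIP = 1e-8
ZSCORE_EPS = 1e-8


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class LossWeights:
    """Binary switches for the four terms."""

    lam_nmf: int = 1
    lam_zinb: int = 1
    lam_zscore: int = 1
    lam_class: int = 1

    def __post_init__(self):
        for name in ("lam_nmf", "lam_zinb", "lam_zscore", "lam_class"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ConfigurationError(f"{name} must be 0 or 1, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.lam_nmf, self.lam_zinb, self.lam_zscore, self.lam_class)


@dataclass
class LossBreakdown:
    nmf: float
    zinb: float
    zscore: float
    class_: float
    total: float
    disabled: tuple[str, ...] = field(default_factory=tuple)


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)


def nmf_loss(X, mu_adjusted: np.ndarray) -> float:
    """||X - mu_adjusted||_F / (n*m)."""
    Xv = _values(X)
    if Xv.shape != mu_adjusted.shape:
        raise ValueError(f"shape mismatch {Xv.shape} vs {mu_adjusted.shape}")
    n, m = Xv.shape
    return float(np.linalg.norm(Xv - mu_adjusted) / (n * m))


def zinb_log_pmf(x, mu, theta, pi):
    """Log PMF of the zero-inflated negative binomial, elementwise.

    Zero branch uses a log-sum-exp of the inflation mass and the NB zero
    probability; the positive branch uses log-Gamma functions throughout.
    pi = 1 is admitted only at x = 0 (log P = 0); at x > 0 it yields -inf.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    pi = np.asarray(pi, dtype=float)
    x, mu, pi = np.broadcast_arrays(x, mu, pi)
    theta = float(theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    log_nb_zero = log_1mpi + theta * (np.log(theta) - np.log(mu + theta))
    zero_branch = np.logaddexp(log_pi, log_nb_zero)
    pos_branch = (
        log_1mpi
        + gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
        + x * (np.log(mu) - np.log(mu + theta))
        + theta * (np.log(theta) - np.log(mu + theta))
    )
    out = np.where(x == 0, zero_branch, pos_branch)
    return out if out.ndim else float(out)


def zinb_nll(X, out: ModelOutput) -> float:
    """Mean negative ZINB log-likelihood over all entries, with the mean
    clipped below at MU_CLIP (ReLU can output exact zeros)."""
    Xv = _values(X)
    if Xv.shape != out.mu_adjusted.shape:
        raise ValueError("shape mismatch between counts and reconstruction")
    mean = np.maximum(out.mu_adjusted, MU_CLIP)
    lp = zinb_log_pmf(Xv, mean, out.theta, out.pi)
    if not np.all(np.isfinite(lp)):
        i, j = np.argwhere(~np.isfinite(lp))[0]
        raise FloatingPointError(f"non-finite ZINB log-likelihood at entry ({i}, {j})")
    return float(-lp.mean())


def zscore_rows(M: np.ndarray) -> np.ndarray:
    """Per-row standardization with population sigma (divisor m) + epsilon."""
    M = np.asarray(M, dtype=float)
    if M.shape[1] < 2:
        raise ValueError("z-scores need at least 2 genes per row")
    mean = M.mean(axis=1, keepdims=True)
    sigma = np.sqrt(((M - mean) ** 2).mean(axis=1, keepdims=True))
    return (M - mean) / (sigma + ZSCORE_EPS)


def zscore_loss(X, mu: np.ndarray) -> float:
    """Mean squared difference of per-cell z-scores; depth-invariant."""
    Xv = _values(X)
    if Xv.shape != mu.shape:
        raise ValueError(f"shape mismatch {Xv.shape} vs {mu.shape}")
    return float(((zscore_rows(Xv) - zscore_rows(mu)) ** 2).mean())


def classification_loss(
    W_plus: np.ndarray,
    label_index: np.ndarray,
    probe_weights: np.ndarray,
    probe_bias: np.ndarray,
) -> float:
    """Cross-entropy of the linear probe, averaged over labeled cells
    (label_index >= 0)."""
    lab = np.asarray(label_index) >= 0
    if not lab.any():
        raise ConfigurationError("classification loss requires at least one labeled cell")
    logits = W_plus[lab] @ probe_weights + probe_bias
    logp = logits - np.log(np.exp(logits - logits.max(axis=1, keepdims=True)).sum(axis=1, keepdims=True)) - logits.max(axis=1, keepdims=True)
    picked = logp[np.arange(lab.sum()), np.asarray(label_index)[lab]]
    return float(-picked.mean())


def total_loss(
    X,
    out: ModelOutput,
    prior: PriorEncoding | None,
    params: FactorParams,
    weights: LossWeights,
) -> LossBreakdown:
    """Evaluate every computable term once and form the switched sum."""
    l_nmf = nmf_loss(X, out.mu_adjusted)
    l_zinb = zinb_nll(X, out)
    l_zscore = zscore_loss(X, out.mu_adjusted)
    disabled: tuple[str, ...] = ()
    has_labels = prior is not None and bool(prior.labeled_mask.any())
    if weights.lam_class and not has_labels:
        raise ConfigurationError("lam_class=1 requires labeled cells")
    if has_labels:
        l_class = classification_loss(
            out.W_plus, prior.label_index, params.probe_weights, params.probe_bias
        )
    else:
        l_class = 0.0
        disabled = ("class",)
    total = (
        weights.lam_nmf * l_nmf
        + weights.lam_zinb * l_zinb
        + weights.lam_zscore * l_zscore
        + weights.lam_class * l_class
    )
    return LossBreakdown(l_nmf, l_zinb, l_zscore, l_class, float(total), disabled)


# ---------------------------------------------------------------------------
# analytic gradients


def _zinb_grads(Xv, mean, theta, pi):
    """Per-entry d log P / d(mean, theta, pi) for the ZINB log PMF."""
    zero = Xv == 0
    log_1mpi = np.log1p(-pi)
    log_nb_zero = log_1mpi + theta * (np.log(theta) - np.log(mean + theta))
    with np.errstate(divide="ignore"):
        logP0 = np.logaddexp(np.log(pi), log_nb_zero)
    w_nb = np.exp(log_nb_zero - logP0)          # share of the NB component at x=0
    mt = mean + theta
    d_mean0 = w_nb * (-theta / mt)
    d_theta0 = w_nb * (np.log(theta) + 1.0 - np.log(mt) - theta / mt)
    d_pi0 = np.exp(-logP0) - w_nb / (1.0 - pi)
    d_mean_pos = Xv / mean - (Xv + theta) / mt
    d_theta_pos = (
        digamma(Xv + theta) - digamma(theta)
        + np.log(theta) + 1.0 - np.log(mt) - (Xv + theta) / mt
    )
    d_pi_pos = -1.0 / (1.0 - pi)
    d_mean = np.where(zero, d_mean0, d_mean_pos)
    d_theta = np.where(zero, d_theta0, d_theta_pos)
    d_pi = np.where(zero, d_pi0, d_pi_pos)
    return d_mean, d_theta, d_pi


def _zscore_grad(Xv, M):
    """Gradient of the z-score loss with respect to the reconstruction M."""
    n, m = M.shape
    zx = zscore_rows(Xv)
    mean = M.mean(axis=1, keepdims=True)
    c = M - mean
    sigma = np.sqrt((c ** 2).mean(axis=1, keepdims=True))
    d = sigma + ZSCORE_EPS
    z = c / d
    g = 2.0 * (z - zx) / (n * m)                # dL/dz
    gc = (g * c).sum(axis=1, keepdims=True)
    # rows that are exactly constant have sigma = 0; the curvature term is
    # then 0/0 and its true limit is 0
    with np.errstate(invalid="ignore", divide="ignore"):
        curv = np.where(sigma > 0, gc / (m * sigma * d ** 2), 0.0)
    return (g - g.mean(axis=1, keepdims=True)) / d - c * curv


def loss_and_grads(
    params: FactorParams,
    X,
    prior: PriorEncoding | None,
    s: SizeFactors,
    weights: LossWeights,
    batch: BatchCorrection | None = None,
):
    """Total objective and its analytic gradient over the trainable set.

    Returns ``(breakdown, grads)`` where ``grads`` maps parameter names
    ('W', 'H', 'rho', 'theta_raw', 'probe_weights', 'probe_bias') to arrays
    matching the parameter shapes. Gradients of switched-off terms are not
    accumulated, so disabling a term leaves parameters unique to it
    untouched during optimization.
    """
    Xv = _values(X)
    out = forward(params, prior, s, batch)
    bd = total_loss(X, out, prior, params, weights)
    n, m = Xv.shape
    k = params.W.shape[1]

    scale = s.s[:, None] * (batch.per_entry() if batch is not None else 1.0)
    d_mu_adj = np.zeros((n, m))
    d_rho = np.zeros(m)
    d_theta_raw = 0.0
    d_probe_w = np.zeros_like(params.probe_weights)
    d_probe_b = np.zeros_like(params.probe_bias)
    dW_plus = np.zeros((n, k))

    if weights.lam_nmf:
        R = Xv - out.mu_adjusted
        fro = np.linalg.norm(R)
        if fro > 0:
            d_mu_adj += -R / (n * m * fro)

    if weights.lam_zinb:
        mean = np.maximum(out.mu_adjusted, MU_CLIP)
        d_mean, d_theta, d_pi = _zinb_grads(Xv, mean, out.theta, out.pi)
        coef = -1.0 / (n * m)
        d_mu_adj += coef * d_mean * (out.mu_adjusted > MU_CLIP)
        pi_g = out.pi[0]  # per-gene, broadcast over cells
        d_rho += coef * d_pi.sum(axis=0) * pi_g * (1.0 - pi_g)
        d_theta_raw += coef * d_theta.sum() * sigmoid(params.theta_raw)

    if weights.lam_zscore:
        d_mu_adj += _zscore_grad(Xv, out.mu_adjusted)

    if weights.lam_class:
        lab = prior.labeled_mask
        n_lab = int(lab.sum())
        logits = out.W_plus[lab] @ params.probe_weights + params.probe_bias
        Y = row_softmax(logits)
        onehot = np.zeros_like(Y)
        onehot[np.arange(n_lab), prior.label_index[lab]] = 1.0
        G = (Y - onehot) / n_lab
        d_probe_w += out.W_plus[lab].T @ G
        d_probe_b += G.sum(axis=0)
        dW_plus[lab] += G @ params.probe_weights.T

    # observation layer -> biological mean -> factors
    d_mu = d_mu_adj * scale
    dW_plus += d_mu @ out.H_plus.T
    dH_plus = out.W_plus.T @ d_mu

    if prior is not None:
        dS = dW_plus.copy()
        dS[prior.labeled_mask] *= 0.5
        dH_hat = 0.5 * dH_plus
    else:
        dS = dW_plus
        dH_hat = dH_plus
    S = row_softmax(np.maximum(params.W, 0.0))
    dW_hat = S * (dS - (dS * S).sum(axis=1, keepdims=True))
    grads = {
        "W": dW_hat * (params.W > 0),
        "H": dH_hat * (params.H > 0),
        "rho": d_rho,
        "theta_raw": float(d_theta_raw),
        "probe_weights": d_probe_w,
        "probe_bias": d_probe_b,
    }
    return bd, grads
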
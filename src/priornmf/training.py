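"""Full-batch Adam training with step-decayed learning rate and
plateau-based stopping.

The learning rate follows eta_t = eta0 * gamma^floor(t / T_decay). Training
stops when the relative change of the total objective stays below
``eps_loss`` for ``patience`` consecutive epochs, or at ``max_epochs``.
The optimizer state is fully determined by the inputs and the seed, so a
repeated run reproduces the loss trace bitwise on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import BatchTable, CountMatrix, LabelTable
from .model import (
    BatchCorrection,
    ConfigurationError,
    FactorParams,
    ModelOutput,
    PriorEncoding,
    build_prior_encoding,
    compute_size_factors,
    estimate_batch_correction,
    forward,
    init_params,
)
from .objectives import LossBreakdown, LossWeights, loss_and_grads


@dataclass
class TrainingConfig:
    weights: LossWeights = field(default_factory=LossWeights)
    eta0: float = 0.01
    gamma: float = 0.95
    T_decay: int = 200
    eps_adam: float = 1e-8
    eps_loss: float = 0.001
    patience: int = 10
    max_epochs: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ConfigurationError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.patience < 1 or self.max_epochs < 1 or self.eps_loss <= 0:
            raise ConfigurationError("patience >= 1, max_epochs >= 1 and eps_loss > 0 required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = asdict(self.weights) if not isinstance(self.weights, dict) else self.weights
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        w = d.pop("weights", {})
        return cls(weights=LossWeights(**w), **d)


@dataclass
class TrainingTrace:
    epochs: list[LossBreakdown]
    stop_epoch: int
    stop_reason: str  # plateau | max_epochs | numerical

    @property
    def totals(self) -> list[float]:
        return [e.total for e in self.epochs]


def lr_at(t: int, cfg: TrainingConfig) -> float:
    """Step-decayed learning rate eta0 * gamma^floor(t / T_decay)."""
    if t < 0:
        raise ValueError("epoch index must be >= 0")
    return cfg.eta0 * cfg.gamma ** (t // cfg.T_decay)


def plateau_reached(totals, cfg: TrainingConfig) -> bool:
    """True iff the relative change was below eps_loss for the last
    ``patience`` consecutive epochs. Needs at least patience+1 totals; a
    near-zero previous loss (|L| < 1e-12) counts as zero change."""
    totals = list(totals)
    if len(totals) < cfg.patience + 1:
        return False
    recent = totals[-(cfg.patience + 1):]
    for prev, cur in zip(recent[:-1], recent[1:]):
        rel = 0.0 if abs(prev) < 1e-12 else abs(cur - prev) / abs(prev)
        if rel >= cfg.eps_loss:
            return False
    return True


class _Adam:
    """Bias-corrected Adam over a dict of named arrays/scalars."""

    def __init__(self, shapes: dict, eps: float):
        self.m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in shapes.items()}
        self.t = 0
        self.eps = eps
        self.beta1, self.beta2 = 0.9, 0.999

    def step(self, params: dict, grads: dict, lr: float) -> dict:
        self.t += 1
        out = {}
        for key, g in grads.items():
            g = np.asarray(g, dtype=float)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1 ** self.t)
            v_hat = self.v[key] / (1 - self.beta2 ** self.t)
            out[key] = params[key] - lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return out


def _params_to_dict(p: FactorParams) -> dict:
    return {
        "W": p.W, "H": p.H, "rho": p.rho, "theta_raw": p.theta_raw,
        "probe_weights": p.probe_weights, "probe_bias": p.probe_bias,
    }


def _dict_to_params(d: dict) -> FactorParams:
    return FactorParams(
        W=np.asarray(d["W"]), H=np.asarray(d["H"]), rho=np.asarray(d["rho"]),
        theta_raw=float(d["theta_raw"]),
        probe_weights=np.asarray(d["probe_weights"]), probe_bias=np.asarray(d["probe_bias"]),
    )


def fit(
    X: CountMatrix,
    labels: LabelTable | None,
    batches: BatchTable | None,
    k: int,
    cfg: TrainingConfig,
) -> tuple[FactorParams, ModelOutput, TrainingTrace]:
    """Fit the factorization on the full batch and return the final state.

    With labels the prior-guided (supervised) forward is used; without them
    the model runs unsupervised, in which case lam_class must be 0.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    has_labels = labels is not None and labels.n_labeled > 0
    if not has_labels and cfg.weights.lam_class:
        raise ConfigurationError("lam_class=1 requires labels; pass labels or set lam_class=0")
    s = compute_size_factors(X)
    prior: PriorEncoding | None = None
    C = 1
    if has_labels:
        prior = build_prior_encoding(labels, X, k)
        C = labels.C
    batch: BatchCorrection | None = None
    if batches is not None:
        batch = estimate_batch_correction(X, batches, s)
    params = init_params(X.n, X.m, k, C, cfg.seed)
    pdict = _params_to_dict(params)
    adam = _Adam(pdict, cfg.eps_adam)
    epochs: list[LossBreakdown] = []
    stop_reason = "max_epochs"
    for t in range(cfg.max_epochs):
        try:
            bd, grads = loss_and_grads(_dict_to_params(pdict), X, prior, s, cfg.weights, batch)
        except FloatingPointError as exc:
            raise FloatingPointError(f"epoch {t}: {exc}") from exc
        if not np.isfinite(bd.total):
            raise FloatingPointError(
                f"epoch {t}: non-finite total loss "
                f"(nmf={bd.nmf}, zinb={bd.zinb}, zscore={bd.zscore}, class={bd.class_})"
            )
        epochs.append(bd)
        if plateau_reached([e.total for e in epochs], cfg):
            stop_reason = "plateau"
            break
        pdict = adam.step(pdict, grads, lr_at(t, cfg))
    final = _dict_to_params(pdict)
    out = forward(final, prior, s, batch)
    trace = TrainingTrace(epochs, stop_epoch=len(epochs), stop_reason=stop_reason)
    return final, out, trace


def trace_to_rows(trace: TrainingTrace, cfg: TrainingConfig) -> list[dict]:
    """Flat per-epoch rows (for the trace CSV)."""
    return [
        {
            "epoch": i + 1, "nmf": e.nmf, "zinb": e.zinb, "zscore": e.zscore,
            "class": e.class_, "total": e.total, "lr": lr_at(i, cfg),
        }
        for i, e in enumerate(trace.epochs)
    ]
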
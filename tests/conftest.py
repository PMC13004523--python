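import numpy as np
import pytest

from priornmf import (
    CountMatrix,
    DropoutSpec,
    LabelTable,
    SimulationConfig,
    simulate_counts,
)


@pytest.fixture
def tiny_counts():
    """5 cells x 4 genes with zeros, two alternating labels."""
    rng = np.random.default_rng(42)
    vals = np.floor(rng.integers(0, 6, size=(5, 4)).astype(float))
    vals[0, 0] = 0.0
    vals[:, 1] = np.maximum(vals[:, 1], 1.0)  # keep every row total > 0
    X = CountMatrix(vals, [f"c{i}" for i in range(5)], [f"g{j}" for j in range(4)])
    labels = LabelTable({f"c{i}": f"t{i % 2}" for i in range(5)})
    return X, labels


@pytest.fixture(scope="session")
def small_sim():
    """Quick clustered dataset for optimizer and pipeline tests."""
    cfg = SimulationConfig(
        n_cells=90, n_genes=50, k_types=3, theta_true=2.0,
        dropout=DropoutSpec(rate=0.4), seed=7,
    )
    return simulate_counts(cfg)


def grad_check_instance(seed: int = 42):
    """5 cells x 4 genes, k=2 instance with parameters away from the ReLU
    and clipping kinks, for finite-difference gradient comparisons."""
    from priornmf import FactorParams, build_prior_encoding, compute_size_factors

    rng = np.random.default_rng(seed)
    vals = np.floor(rng.integers(0, 6, size=(5, 4)).astype(float))
    vals[0, 0] = 0.0
    vals[:, 1] = np.maximum(vals[:, 1], 1.0)
    X = CountMatrix(vals, [f"c{i}" for i in range(5)], [f"g{j}" for j in range(4)])
    labels = LabelTable({f"c{i}": f"t{i % 2}" for i in range(5)})
    s = compute_size_factors(X)
    prior = build_prior_encoding(labels, X, 2)
    params = FactorParams(
        W=rng.uniform(0.3, 1.0, (5, 2)),
        H=rng.uniform(0.3, 1.0, (2, 4)),
        rho=rng.normal(0.0, 0.5, 4),
        theta_raw=0.3,
        probe_weights=rng.normal(0.0, 0.5, (2, 2)),
        probe_bias=rng.normal(0.0, 0.5, 2),
    )
    return params, X, prior, s


def flatten_params(p):
    return np.concatenate([
        p.W.ravel(), p.H.ravel(), p.rho, [p.theta_raw],
        p.probe_weights.ravel(), p.probe_bias,
    ])


def unflatten_params(v, shape):
    from priornmf import FactorParams

    n, m, k, C = shape
    i = 0
    W = v[i:i + n * k].reshape(n, k); i += n * k
    H = v[i:i + k * m].reshape(k, m); i += k * m
    rho = v[i:i + m]; i += m
    tr = float(v[i]); i += 1
    pw = v[i:i + k * C].reshape(k, C); i += k * C
    pb = v[i:i + C]
    return FactorParams(W, H, rho, tr, pw, pb)
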
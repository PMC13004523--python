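"""Zeros-only imputation and the end-to-end pipeline.

Only zero entries are replaced — observed nonzero counts are reliable
measurements and are preserved bit-for-bit. A zero entry receives the
model's depth-adjusted conditional mean, so imputed values are commensurate
with the retained raw counts of the same cell.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np

from . import __version__
from .io import CountMatrix, read_batches, read_counts, read_labels, write_matrix
from .model import ConfigurationError, ModelOutput
from .training import TrainingConfig, TrainingTrace, fit, trace_to_rows


@dataclass
class ImputationResult:
    imputed: CountMatrix
    replaced_mask: np.ndarray
    model: ModelOutput


def impute_zeros(X: CountMatrix, out: ModelOutput) -> ImputationResult:
    """imputed[i,j] = X[i,j] if X[i,j] > 0 else mu_adjusted[i,j]."""
    if X.values.shape != out.mu_adjusted.shape:
        raise ValueError("shape mismatch between counts and model output")
    mask = X.values == 0
    vals = np.where(mask, out.mu_adjusted, X.values)
    return ImputationResult(
        CountMatrix(vals, list(X.cell_ids), list(X.gene_ids)), mask, out
    )


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    counts_path: str,
    labels_path: str | None,
    batches_path: str | None,
    cfg: TrainingConfig,
    out_dir: str,
    k: int | None = None,
    dialect: str = "dense",
    orientation: str = "cells-as-rows",
    mode: str = "auto",
) -> tuple[ImputationResult, TrainingTrace, dict]:
    """Load inputs, fit, impute zeros and write outputs plus a run manifest.

    ``mode`` is 'prior' (require labels), 'unsup' (ignore labels even if
    supplied) or 'auto' (label presence decides). With labels, k defaults to
    the number of distinct label types.
    """
    X = read_counts(counts_path, orientation)
    labels = read_labels(labels_path, X) if labels_path else None
    if mode == "unsup":
        labels = None
    elif mode == "prior" and (labels is None or labels.n_labeled == 0):
        raise ConfigurationError("mode 'prior' requires a label table")
    elif mode not in ("auto", "prior", "unsup"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    batches = read_batches(batches_path, X) if batches_path else None
    if labels is None and cfg.weights.lam_class:
        raise ConfigurationError("lam_class=1 without labels: supply labels or set lam_class=0")
    if k is None:
        if labels is None or labels.C == 0:
            raise ConfigurationError("k is required in unsupervised mode")
        k = labels.C
    params, out, trace = fit(X, labels, batches, k, cfg)
    result = impute_zeros(X, out)

    os.makedirs(out_dir, exist_ok=True)
    imputed_path = os.path.join(
        out_dir, "imputed.mtx" if dialect == "matrix-market" else "imputed.csv"
    )
    write_matrix(result.imputed, imputed_path, dialect)
    trace_path = os.path.join(out_dir, "trace.csv")
    rows = trace_to_rows(trace, cfg)
    with open(trace_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    manifest = {
        "tool_version": __version__,
        "command": "impute",
        "mode": "prior" if labels is not None else "unsup",
        "k": k,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {
            "counts": {"path": counts_path, "sha256": _digest(counts_path)},
            **({"labels": {"path": labels_path, "sha256": _digest(labels_path)}} if labels_path else {}),
            **({"batches": {"path": batches_path, "sha256": _digest(batches_path)}} if batches_path else {}),
        },
        "outputs": {"imputed": imputed_path, "trace": trace_path},
        "stop_epoch": trace.stop_epoch,
        "stop_reason": trace.stop_reason,
        "n_replaced": int(result.replaced_mask.sum()),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result, trace, manifest
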
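"""Shared builders for planted-structure expression fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from adiponet import ExpressionMatrix


def make_expr(values, feature_ids=None, sample_ids=None, kind="gene") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), feature_kind=kind
    )


def planted_expression(
    rng: np.random.Generator,
    n_samples: int,
    module_sizes: tuple[int, ...],
    loading: float | tuple[float, float],
    n_noise: int,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Factor-model expression with planted modules; returns (expr, truth labels).

    Truth labels are module indices for members and -1 for noise genes.
    """
    blocks, truth = [], []
    for k, size in enumerate(module_sizes):
        f = rng.standard_normal(n_samples)
        if isinstance(loading, tuple):
            lam = rng.uniform(loading[0], loading[1], size)
        else:
            lam = np.full(size, float(loading))
        blocks.append(lam[:, None] * f[None, :]
                      + np.sqrt(1 - lam**2)[:, None] * rng.standard_normal((size, n_samples)))
        truth += [k] * size
    if n_noise:
        blocks.append(rng.standard_normal((n_noise, n_samples)))
        truth += [-1] * n_noise
    X = np.vstack(blocks)
    return make_expr(X), np.array(truth)
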
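"""Permutation-based module preservation between two cohorts.

For each module defined in a reference cohort, a set of density and
connectivity statistics is computed in an independent test cohort and
compared with a permutation null obtained by evaluating the same
statistics on random gene sets of identical size drawn from the genes
shared between the cohorts.  Each component statistic yields

    Z = (observed − null mean) / null sd,

Zdensity and Zconnectivity are the medians of their component Z scores,
and Zsummary is the median of the two.  By the usual decision rule,
Zsummary > 10 is strong evidence of preservation and Zsummary < 2 is no
evidence; the interval between is moderate.

Density components (how tightly the module hangs together in the test
data): mean intra-module |cor|, mean adjacency |cor|^beta, eigengene
variance explained, and mean |kME| of members.  Connectivity components
(whether the same genes are hubs in both cohorts): correlation of
intramodular connectivity vectors, of kME vectors, and of the vectorized
intra-module correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GREY, ExpressionMatrix, PipelineError
from .network import ModulePartition

DENSITY_STATS = ("mean_abs_cor", "mean_adjacency", "var_explained", "mean_abs_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")


@dataclass
class ModulePreservation:
    """Observed statistics and Z scores for one reference module."""

    module: str
    size: int
    observed: dict[str, float]
    z_scores: dict[str, float]
    z_density: float
    z_connectivity: float
    z_summary: float

    @property
    def flag(self) -> str:
        if self.z_summary > 10:
            return "strong"
        if self.z_summary >= 2:
            return "moderate"
        return "none"


@dataclass
class PreservationResult:
    """Per-module preservation Z statistics between a reference and a test cohort."""

    modules: list[ModulePreservation]
    n_permutations: int
    seed: int
    shared_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.modules:
            row = {"module": m.module, "size": m.size}
            row.update({f"obs_{k}": v for k, v in m.observed.items()})
            row.update({f"Z_{k}": v for k, v in m.z_scores.items()})
            row.update({"Zdensity": m.z_density, "Zconnectivity": m.z_connectivity,
                        "Zsummary": m.z_summary, "flag": m.flag})
            rows.append(row)
        return pd.DataFrame(rows)

    def zsummary(self, module: str) -> float:
        for m in self.modules:
            if m.module == module:
                return m.z_summary
        raise PipelineError(f"module {module!r} not evaluated")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Z = X - X.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=1)
    sd[sd == 0] = np.nan
    return Z / sd[:, None]


def _module_stats(
    ref_X: np.ndarray, test_X: np.ndarray, beta: int
) -> dict[str, float]:
    """All component statistics for one gene set (rows = genes, cols = samples)."""
    m = ref_X.shape[0]
    iu = np.triu_indices(m, k=1)

    cor_test = np.corrcoef(test_X)
    cor_ref = np.corrcoef(ref_X)
    abs_cor = np.abs(cor_test[iu])
    adj_test = np.abs(cor_test) ** beta
    np.fill_diagonal(adj_test, 0.0)
    adj_ref = np.abs(cor_ref) ** beta
    np.fill_diagonal(adj_ref, 0.0)

    def _kme(Z: np.ndarray, me: np.ndarray) -> np.ndarray:
        sd = me.std(ddof=1)
        if sd == 0:
            return np.zeros(Z.shape[0])
        zme = (me - me.mean()) / sd
        return Z @ zme / (Z.shape[1] - 1)

    # eigengene of the set in the test data
    Z = _standardize_rows(test_X)
    U, S, _ = np.linalg.svd(Z.T, full_matrices=False)
    me = U[:, 0] * S[0]
    var_explained = float(S[0] ** 2 / (S ** 2).sum())
    kme_test = _kme(Z, me)

    Zr = _standardize_rows(ref_X)
    Ur, Sr, _ = np.linalg.svd(Zr.T, full_matrices=False)
    me_r = Ur[:, 0] * Sr[0]
    kme_ref = _kme(Zr, me_r)

    kim_test = adj_test.sum(axis=1)
    kim_ref = adj_ref.sum(axis=1)

    def _cor(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "mean_abs_cor": float(abs_cor.mean()),
        "mean_adjacency": float(adj_test[iu].mean()),
        "var_explained": var_explained,
        "mean_abs_kme": float(np.abs(kme_test).mean()),
        "cor_kim": _cor(kim_ref, kim_test),
        "cor_kme": _cor(np.abs(kme_ref), np.abs(kme_test)),
        "cor_cor": _cor(cor_ref[iu], cor_test[iu]),
    }


def _median_z(zs: dict[str, float], names: tuple[str, ...], module: str) -> float:
    vals = []
    for name in names:
        z = zs[name]
        if np.isinf(z):
            warnings.warn(
                f"module {module!r}: component {name} has zero null sd; "
                "excluded from the median", stacklevel=3,
            )
            continue
        vals.append(z)
    if not vals:
        return float("inf")
    return float(np.median(vals))


def module_preservation(
    ref_expr: ExpressionMatrix,
    ref_partition: ModulePartition,
    test_expr: ExpressionMatrix,
    n_permutations: int = 200,
    seed: int = 0,
    beta: int = 6,
    min_module_size: int = 3,
) -> PreservationResult:
    """Zsummary preservation of each non-grey reference module in the test data.

    Features are matched by identifier (gene symbol after harmonization);
    modules with fewer than ``min_module_size`` shared genes are skipped
    with a warning.  Deterministic given ``seed``.
    """
    if n_permutations < 20:
        raise PipelineError("n_permutations must be >= 20")
    shared = [f for f in ref_expr.feature_ids if f in set(test_expr.feature_ids)]
    if len(shared) < min_module_size:
        raise PipelineError("fewer shared genes than the minimum module size")
    ref_vals = ref_expr.values.loc[shared]
    # sort test samples by id so results do not depend on their ordering
    test_vals = test_expr.values.loc[shared].sort_index(axis=1)
    ref_arr = ref_vals.to_numpy(dtype=float)
    test_arr = test_vals.to_numpy(dtype=float)
    index_of = {g: i for i, g in enumerate(shared)}

    rng = np.random.default_rng(seed)
    labels = ref_partition.labels
    modules = [m for m in ref_partition.module_names if m != GREY]
    results: list[ModulePreservation] = []
    all_stat_names = DENSITY_STATS + CONNECTIVITY_STATS
    for mod in modules:
        members = [g for g in ref_partition.members(mod) if g in index_of]
        size = len(members)
        if size < min_module_size:
            warnings.warn(f"module {mod!r}: only {size} shared genes; skipped", stacklevel=2)
            continue
        idx = np.array([index_of[g] for g in members])
        observed = _module_stats(ref_arr[idx], test_arr[idx], beta)
        null = {name: np.empty(n_permutations) for name in all_stat_names}
        for p in range(n_permutations):
            ridx = rng.choice(len(shared), size=size, replace=False)
            stats_p = _module_stats(ref_arr[ridx], test_arr[ridx], beta)
            for name in all_stat_names:
                null[name][p] = stats_p[name]
        zs = {}
        for name in all_stat_names:
            sd = null[name].std(ddof=1)
            if sd == 0:
                zs[name] = float("inf")
            else:
                zs[name] = float((observed[name] - null[name].mean()) / sd)
        z_density = _median_z(zs, DENSITY_STATS, mod)
        z_connectivity = _median_z(zs, CONNECTIVITY_STATS, mod)
        z_summary = float(np.median([z_density, z_connectivity]))
        results.append(ModulePreservation(
            module=mod, size=size, observed=observed, z_scores=zs,
            z_density=z_density, z_connectivity=z_connectivity, z_summary=z_summary,
        ))
    return PreservationResult(modules=results, n_permutations=n_permutations,
                              seed=seed, shared_genes=shared)
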
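"""Weighted co-expression network construction and module detection.

The network is unsigned: adjacency between features i and j is
``a_ij = |cor(x_i, x_j)|^beta`` with Pearson correlation and a
soft-threshold power ``beta`` chosen for approximate scale-free
connectivity.  The clustering distance is one minus the topological
overlap

    ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

which credits shared network neighbors.  Modules are branches of an
average-linkage tree cut at a fixed height quantile, filtered by a minimum
size, and merged when their eigengenes are nearly collinear.  Each module
is summarized by its eigengene (first principal component of the
standardized member expression), and every feature is annotated with its
module membership kME = cor(feature, eigengene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import (
    GREY,
    AlignmentError,
    ExpressionMatrix,
    PhenotypeTable,
    PipelineError,
    module_color_sequence,
)


@dataclass
class NetworkConfig:
    """Tuning constants for unsigned network construction.

    beta
        Soft-threshold power applied to |correlation|; 6 is the
        conventional unsigned default.
    min_module_size
        Branches smaller than this are assigned to grey.
    cut_height_quantile
        The static tree cut is placed at this quantile of the linkage merge
        heights.
    merge_cut_height
        Modules with eigengene dissimilarity 1 − cor(ME_a, ME_b) below this
        are merged.
    """

    beta: int = 6
    network_sign: str = "unsigned"
    min_module_size: int = 30
    cut_height_quantile: float = 0.9
    merge_cut_height: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise PipelineError(f"beta must be >= 1, got {self.beta}")
        if self.min_module_size < 2:
            raise PipelineError(f"min_module_size must be >= 2, got {self.min_module_size}")
        if not 0.0 < self.cut_height_quantile < 1.0:
            raise PipelineError("cut_height_quantile must be in (0, 1)")
        if not 0.0 <= self.merge_cut_height <= 1.0:
            raise PipelineError("merge_cut_height must be in [0, 1]")
        if self.network_sign != "unsigned":
            raise PipelineError("only unsigned networks are supported")


@dataclass
class ModulePartition:
    """Feature→module assignment with eigengenes and membership.

    ``labels`` maps each feature to a module color (grey = unassigned);
    ``eigengenes`` is samples × modules (columns ``ME<color>``); ``kme`` is
    features × modules (all features against all module eigengenes);
    ``var_explained`` is the per-module proportion of member variance
    captured by the eigengene.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame
    var_explained: pd.Series

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.labels.index]

    @property
    def module_names(self) -> list[str]:
        """Module colors in size order, grey (if present) last."""
        return [c.removeprefix("ME") for c in self.eigengenes.columns]

    def members(self, module: str) -> list[str]:
        return [str(i) for i in self.labels.index[self.labels == module]]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def _check_variances(expr: ExpressionMatrix) -> np.ndarray:
    X = expr.values.to_numpy(dtype=float)
    constant = X.max(axis=1) == X.min(axis=1)
    if constant.any():
        bad = [expr.feature_ids[i] for i in np.flatnonzero(constant)[:10]]
        raise PipelineError(f"zero-variance features: {bad}")
    return X


def adjacency_matrix(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    X = _check_variances(expr)
    a = np.abs(np.corrcoef(X)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_dissimilarity(expr: ExpressionMatrix, config: NetworkConfig) -> pd.DataFrame:
    """Topological-overlap dissimilarity d = 1 − ω, symmetric, zero diagonal."""
    if expr.n_features < 2:
        raise PipelineError("need at least 2 features for a network")
    a = adjacency_matrix(expr, config.beta)
    k = a.sum(axis=1)
    shared = a @ a  # Σ_u a_iu a_uj (diag of a is 0, so u ≠ i, j contributions plus i/j terms vanish)
    denom = np.minimum.outer(k, k) + 1.0 - a
    omega = (shared + a) / denom
    np.fill_diagonal(omega, 1.0)
    d = 1.0 - omega
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.values.index, columns=expr.values.index)


@dataclass
class SoftThresholdResult:
    beta: int
    fit_table: pd.DataFrame  # beta, signed_r2, slope, mean_k
    used_fallback: bool


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit R² of the connectivity distribution.

    Bins log10(k) into ``n_bins`` equal-width bins, regresses log10 of the
    per-bin frequency on log10 of the per-bin mean connectivity, and
    returns (−sign(slope)·R², slope).
    """
    k = np.asarray(k, dtype=float)
    k = np.maximum(k, 1e-12)
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    r2 = res.rvalue ** 2
    return float(-np.sign(res.slope) * r2), float(res.slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidate_betas: list[int] | None = None,
    r2_target: float = 0.8,
    fallback: int = 6,
) -> SoftThresholdResult:
    """Choose the smallest power whose signed scale-free fit R² meets ``r2_target``.

    Falls back to ``fallback`` (with a warning) when no candidate reaches
    the target — e.g. on pure-noise data with no scale-free structure.
    """
    if candidate_betas is None:
        candidate_betas = list(range(1, 13))
    if len(candidate_betas) < 1:
        raise PipelineError("candidate_betas must be non-empty")
    if expr.n_features < 10:
        raise PipelineError("fewer features than connectivity bins")
    X = _check_variances(expr)
    acorr = np.abs(np.corrcoef(X))
    np.fill_diagonal(acorr, 0.0)
    rows = []
    for beta in candidate_betas:
        k = (acorr ** beta).sum(axis=1)
        signed_r2, slope = scale_free_fit(k)
        rows.append({"beta": beta, "signed_r2": signed_r2, "slope": slope,
                     "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    passing = table[table["signed_r2"] >= r2_target]
    if len(passing):
        beta = int(passing["beta"].iloc[0])
        return SoftThresholdResult(beta=beta, fit_table=table, used_fallback=False)
    warnings.warn(
        f"no candidate beta reached signed R² {r2_target}; using fallback {fallback}",
        stacklevel=2,
    )
    return SoftThresholdResult(beta=fallback, fit_table=table, used_fallback=True)


def module_eigengenes(
    expr: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component eigengene and variance explained per module.

    Member features are standardized across samples; the eigengene is the
    leading right-singular-vector score scaled to unit variance, with sign
    oriented so the mean correlation with member features is positive (ties
    broken by the first member's correlation sign).  Grey is summarized too
    when it has ≥ 2 features, and is ordered last.
    """
    modules = _ordered_modules(labels)
    me_cols: dict[str, np.ndarray] = {}
    var_exp: dict[str, float] = {}
    for mod in modules:
        members = labels.index[labels == mod]
        if len(members) < 2:
            if mod == GREY:
                continue
            raise PipelineError(f"module {mod!r} has fewer than 2 features")
        X = expr.values.loc[members].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=1)
        if (sd == 0).any():
            bad = [str(members[i]) for i in np.flatnonzero(sd == 0)[:5]]
            raise PipelineError(f"constant features in module {mod!r}: {bad}")
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        # samples × features SVD; leading left-singular score of Z.T
        U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
        me = U[:, 0] * S[0]
        me = me / me.std(ddof=1)
        member_cor = np.array([np.corrcoef(me, z)[0, 1] for z in Z])
        mean_cor = member_cor.mean()
        if mean_cor < 0 or (mean_cor == 0 and member_cor[0] < 0):
            me = -me
        me_cols[f"ME{mod}"] = me
        var_exp[mod] = float(S[0] ** 2 / (S ** 2).sum())
    eigengenes = pd.DataFrame(me_cols, index=expr.values.columns)
    return eigengenes, pd.Series(var_exp, name="var_explained")


def kme_matrix(expr: ExpressionMatrix, me: pd.DataFrame) -> pd.DataFrame:
    """kME[f, m] = Pearson cor(feature f, eigengene m), for all features."""
    if list(me.index) != list(expr.values.columns):
        raise AlignmentError("eigengene samples do not align with expression samples")
    X = expr.values.to_numpy(dtype=float)
    Zx = (X - X.mean(axis=1, keepdims=True))
    sx = Zx.std(axis=1, ddof=1)
    if (sx == 0).any():
        bad = [expr.feature_ids[i] for i in np.flatnonzero(sx == 0)[:5]]
        raise PipelineError(f"constant features: {bad}")
    M = me.to_numpy(dtype=float)
    Zm = M - M.mean(axis=0, keepdims=True)
    sm_ = Zm.std(axis=0, ddof=1)
    n = X.shape[1]
    kme = (Zx @ Zm) / ((n - 1) * np.outer(sx, sm_))
    return pd.DataFrame(np.clip(kme, -1, 1), index=expr.values.index, columns=me.columns)


def _ordered_modules(labels: pd.Series) -> list[str]:
    """Modules by decreasing size (stable), grey always last."""
    sizes = labels.value_counts()
    mods = [m for m in sizes.index if m != GREY]
    mods.sort(key=lambda m: (-sizes[m], str(m)))
    if (labels == GREY).any():
        mods.append(GREY)
    return mods


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Assign canonical colors in decreasing-size order; grey stays grey."""
    sizes = labels.value_counts()
    mods = [m for m in sizes.index if m != GREY]
    # deterministic: size desc, then current label for ties
    mods.sort(key=lambda m: (-sizes[m], str(m)))
    colors = module_color_sequence(len(mods))
    mapping = {old: new for old, new in zip(mods, colors)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def detect_modules(expr: ExpressionMatrix, config: NetworkConfig) -> ModulePartition:
    """Cluster the TOM dissimilarity into labeled modules.

    Average-linkage hierarchical clustering; a static cut at the
    ``cut_height_quantile`` of merge heights defines candidate branches;
    branches below ``min_module_size`` go to grey; surviving modules are
    colored in size order; modules whose eigengenes are closer than
    ``merge_cut_height`` (dissimilarity 1 − cor) are merged iteratively,
    largest combined size first, then everything is relabeled and
    recomputed.
    """
    d = tom_dissimilarity(expr, config)
    Z = linkage(squareform(d.to_numpy(), checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, config.cut_height_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw.astype(object), index=d.index)
    sizes = labels.value_counts()
    small = sizes.index[sizes < config.min_module_size]
    labels[labels.isin(small)] = GREY
    if (labels == GREY).all():
        warnings.warn("all features assigned to grey (no module passed the size filter)",
                      stacklevel=2)
        eigengenes, var_exp = module_eigengenes(expr, labels)
        kme = kme_matrix(expr, eigengenes) if len(eigengenes.columns) else \
            pd.DataFrame(index=expr.values.index)
        return ModulePartition(labels=labels, eigengenes=eigengenes, kme=kme,
                               var_explained=var_exp)
    labels = _relabel_by_size(labels)
    labels = _merge_close_modules(expr, labels, config.merge_cut_height)
    labels = _relabel_by_size(labels)
    eigengenes, var_exp = module_eigengenes(expr, labels)
    kme = kme_matrix(expr, eigengenes)
    return ModulePartition(labels=labels, eigengenes=eigengenes, kme=kme,
                           var_explained=var_exp)


def _merge_close_modules(
    expr: ExpressionMatrix, labels: pd.Series, merge_cut_height: float
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < threshold."""
    labels = labels.copy()
    while True:
        mods = [m for m in _ordered_modules(labels) if m != GREY]
        if len(mods) < 2:
            return labels
        me, _ = module_eigengenes(expr, labels)
        cols = [f"ME{m}" for m in mods]
        cor = np.corrcoef(me[cols].to_numpy().T)
        sizes = labels.value_counts()
        best = None  # (combined_size, -dissim, a, b)
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                dissim = 1.0 - cor[i, j]
                if dissim < merge_cut_height:
                    key = (sizes[mods[i]] + sizes[mods[j]], -dissim)
                    if best is None or key > best[0]:
                        best = (key, mods[i], mods[j])
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


@dataclass
class ModuleTraitResult:
    """Module-eigengene ↔ trait correlations with Bonferroni flags.

    ``table`` has one row per (module, trait): Pearson r, two-sided p from
    the exact t transform with n−2 df, the Bonferroni threshold
    0.05 / (n_modules × n_traits), a significance flag, and the percentage
    of member genes whose expression correlates with the trait at p < 0.05.
    """

    table: pd.DataFrame
    bonferroni_threshold: float
    n_modules: int
    n_traits: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def top_module(self, trait: str) -> str:
        """Most significant non-grey module for ``trait`` (min p, ties by larger |r|)."""
        sub = self.table[(self.table["trait"] == trait) & (self.table["module"] != GREY)]
        if sub.empty:
            raise PipelineError(f"no modules tested for trait {trait!r}")
        sub = sub.sort_values(["p_value", "abs_r"], ascending=[True, False])
        return str(sub["module"].iloc[0])


def module_trait_correlation(
    partition: ModulePartition,
    pheno: PhenotypeTable,
    traits: list[str],
    expr: ExpressionMatrix | None = None,
    alpha: float = 0.05,
    gene_alpha: float = 0.05,
) -> ModuleTraitResult:
    """Correlate each module eigengene (grey included) with each trait.

    ``expr`` (the matrix the partition was built from) enables the
    per-module percentage of trait-correlated member genes.
    """
    me = partition.eigengenes
    ph = pheno.data.loc[me.index]
    n = len(me.index)
    if n < 3:
        raise PipelineError("need at least 3 samples for correlation tests")
    modules = partition.module_names
    n_tests = len(modules) * len(traits)
    threshold = alpha / n_tests
    rows = []
    for trait in traits:
        t = pd.to_numeric(ph[trait]).to_numpy(dtype=float)
        if np.std(t) == 0:
            raise PipelineError(f"trait {trait!r} is constant")
        pct = _pct_trait_correlated(partition, expr, t, gene_alpha) if expr is not None else {}
        for mod in modules:
            r, p = stats.pearsonr(me[f"ME{mod}"].to_numpy(), t)
            rows.append({
                "module": mod, "trait": trait, "pearson_r": float(r),
                "abs_r": float(abs(r)), "p_value": float(p),
                "significant": bool(p < threshold),
                "pct_trait_correlated": pct.get(mod, np.nan),
            })
    table = pd.DataFrame(rows)
    return ModuleTraitResult(table=table, bonferroni_threshold=threshold,
                             n_modules=len(modules), n_traits=len(traits))


def _pct_trait_correlated(
    partition: ModulePartition,
    expr: ExpressionMatrix,
    trait: np.ndarray,
    gene_alpha: float,
) -> dict[str, float]:
    X = expr.values.to_numpy(dtype=float)
    n = X.shape[1]
    Zx = X - X.mean(axis=1, keepdims=True)
    sx = Zx.std(axis=1, ddof=1)
    zt = trait - trait.mean()
    st = zt.std(ddof=1)
    r = (Zx @ zt) / ((n - 1) * sx * st)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p_series = pd.Series(p, index=expr.values.index)
    out = {}
    for mod in partition.module_names:
        members = partition.members(mod)
        if members:
            out[mod] = float(100.0 * (p_series.loc[members] < gene_alpha).mean())
    return out
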
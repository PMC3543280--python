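"""Cross-cohort comparison: gene harmonization, overlap tests, hub analysis.

Module memberships from different cohorts are compared over a shared
gene-symbol background: a 2×2 cross-tabulation with Fisher's exact test
for module overlap, a Monte-Carlo empirical null for the joint hub-gene
overlap across several cohorts, Pearson comparison of kME profiles,
Welch-t differential expression with top-N list overlap, hypergeometric
over-representation against gene-set collections, and additive-dosage
SNP association with eigengenes or single genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EmptyResultError, ExpressionMatrix, FeatureAnnotation, PipelineError
from .preprocess import collapse_probes


# ---------------------------------------------------------------------------
# harmonization


def harmonize_genes(
    cohort_exprs: list[ExpressionMatrix],
    anns: list[FeatureAnnotation | None],
) -> tuple[list[ExpressionMatrix], list[str]]:
    """Collapse each cohort to gene symbols and align on the shared symbols.

    Cohorts already at gene level (``feature_kind == "gene"``) pass through
    the collapse untouched.  Returns the row-aligned matrices (sorted
    shared-symbol order) and the shared list, which serves as the default
    background for overlap tests.
    """
    if len(cohort_exprs) != len(anns):
        raise PipelineError("one annotation (or None) required per cohort")
    collapsed = []
    for expr, ann in zip(cohort_exprs, anns):
        if expr.feature_kind == "gene":
            collapsed.append(expr)
        else:
            if ann is None:
                raise PipelineError("probe-level cohort requires an annotation")
            collapsed.append(collapse_probes(expr, ann))
    shared: set[str] = set(collapsed[0].feature_ids)
    for expr in collapsed[1:]:
        shared &= set(expr.feature_ids)
    if not shared:
        raise EmptyResultError("no gene symbols shared across cohorts")
    order = sorted(shared)
    aligned = [
        ExpressionMatrix(e.values.loc[order], feature_kind="gene") for e in collapsed
    ]
    return aligned, order


# ---------------------------------------------------------------------------
# Fisher overlap


@dataclass
class OverlapResult:
    """2×2 cross-tabulation of two gene sets over a background.

    ``percentage`` is defined relative to set B (``100·shared/|B|``);
    ``fisher_p`` is the exact test p-value at the requested sidedness.
    """

    background_size: int
    set_a_size: int
    set_b_size: int
    shared_count: int
    shared_ids: list[str]
    percentage: float
    fisher_p: float
    sidedness: str

    def contingency(self) -> np.ndarray:
        both = self.shared_count
        only_a = self.set_a_size - both
        only_b = self.set_b_size - both
        neither = self.background_size - both - only_a - only_b
        return np.array([[both, only_a], [only_b, neither]])


def fisher_module_overlap(
    set_a: set[str] | list[str],
    set_b: set[str] | list[str],
    background: list[str],
    sidedness: str = "two_sided",
) -> OverlapResult:
    """Fisher's exact test of gene-set overlap over a shared background."""
    if sidedness not in ("two_sided", "greater"):
        raise PipelineError(f"sidedness must be 'two_sided' or 'greater', got {sidedness!r}")
    bg = set(background)
    a, b = set(set_a), set(set_b)
    stray = (a | b) - bg
    if stray:
        raise PipelineError(f"set elements outside background: {sorted(stray)[:10]}")
    shared = sorted(a & b)
    table = np.array([
        [len(shared), len(a) - len(shared)],
        [len(b) - len(shared), len(bg) - len(a | b)],
    ])
    alternative = "two-sided" if sidedness == "two_sided" else "greater"
    _, p = stats.fisher_exact(table, alternative=alternative)
    pct = 100.0 * len(shared) / len(b) if b else 0.0
    return OverlapResult(
        background_size=len(bg), set_a_size=len(a), set_b_size=len(b),
        shared_count=len(shared), shared_ids=shared, percentage=pct,
        fisher_p=float(p), sidedness=sidedness,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo hub overlap


@dataclass
class HubOverlapSpec:
    """Hub-selection criterion for the empirical joint-overlap null.

    ``criterion`` is one of ``kme_above`` (threshold on |kME|), ``top_rank``
    (the k highest-kME members) or ``top_fraction`` (the top fraction q of
    members, size ⌈q·module size⌉); ``trials`` Monte-Carlo draws with
    ``seed``.
    """

    criterion: str
    parameter: float
    trials: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in ("kme_above", "top_rank", "top_fraction"):
            raise PipelineError(f"unknown criterion {self.criterion!r}")
        if self.trials < 10_000:
            raise PipelineError("trials must be >= 10,000")
        if self.criterion == "top_fraction" and not 0 < self.parameter <= 1:
            raise PipelineError("top_fraction parameter must be in (0, 1]")
        if self.criterion == "top_rank" and (self.parameter < 1 or self.parameter != int(self.parameter)):
            raise PipelineError("top_rank parameter must be a positive integer")
        if self.criterion == "kme_above" and not 0 <= self.parameter <= 1:
            raise PipelineError("kme_above threshold must be in [0, 1]")


@dataclass
class HubOverlapResult:
    spec: HubOverlapSpec
    observed_count: int
    draw_sizes: list[int]
    module_sizes: list[int]
    empirical_p: float
    trials: int
    n_exceeding: int


def _draw_size(kme: pd.Series, spec: HubOverlapSpec) -> int:
    m = len(kme)
    if spec.criterion == "kme_above":
        return int((kme.abs() > spec.parameter).sum())
    if spec.criterion == "top_rank":
        size = int(spec.parameter)
        if size > m:
            raise PipelineError(f"top_rank {size} exceeds module size {m}")
        return size
    return int(math.ceil(spec.parameter * m))


def empirical_hub_overlap(
    kme_per_dataset: list[pd.Series],
    spec: HubOverlapSpec,
    candidate_genes: set[str] | list[str],
    observed_count: int,
    chunk: int = 20_000,
) -> HubOverlapResult:
    """Monte-Carlo p-value for a joint hub overlap across datasets.

    Each entry of ``kme_per_dataset`` holds the kME values of one cohort's
    TG-module members (indexed by gene).  Per trial a uniform random
    member subset of the criterion-implied size is drawn independently in
    each dataset; the trial statistic is the number of candidate genes
    present in every dataset's draw.  The returned estimate uses the
    add-one rule p = (1 + #{stat ≥ observed}) / (trials + 1), so it is
    never zero.  Deterministic given ``spec.seed``.
    """
    if observed_count < 0:
        raise PipelineError("observed_count must be >= 0")
    candidates = sorted(set(candidate_genes))
    if not candidates:
        raise PipelineError("candidate gene set is empty")
    module_sizes = [len(k) for k in kme_per_dataset]
    draw_sizes = [_draw_size(k, spec) for k in kme_per_dataset]
    for size, m in zip(draw_sizes, module_sizes):
        if size > m:
            raise PipelineError(f"criterion size {size} exceeds module size {m}")
    # a candidate can only score if it is a member everywhere
    member_masks = []
    for kme in kme_per_dataset:
        members = set(kme.index)
        member_masks.append(np.array([g in members for g in candidates]))
    eligible = np.logical_and.reduce(member_masks)
    max_attainable = min([int(e) for e in [eligible.sum()] + draw_sizes])
    if observed_count > max_attainable:
        raise PipelineError(
            f"observed_count {observed_count} exceeds the maximum attainable {max_attainable}"
        )
    # only jointly-eligible candidates can contribute to the joint count
    joint_candidates = [g for g, e in zip(candidates, eligible) if e]
    n_joint = len(joint_candidates)
    cand_cols = []
    for kme in kme_per_dataset:
        pos = {g: i for i, g in enumerate(kme.index)}
        cand_cols.append(np.array([pos[g] for g in joint_candidates], dtype=int))

    rng = np.random.default_rng(spec.seed)
    n_exceeding = 0
    done = 0
    while done < spec.trials:
        t = min(chunk, spec.trials - done)
        inside = np.ones((t, n_joint), dtype=bool)
        for cols, size, m in zip(cand_cols, draw_sizes, module_sizes):
            if size == 0:
                inside[:] = False
                continue
            u = rng.random((t, m))
            kth = np.partition(u, size - 1, axis=1)[:, size - 1:size]
            mask = u <= kth  # exactly `size` members in the draw per trial
            inside &= mask[:, cols]
        stat = inside.sum(axis=1)
        n_exceeding += int((stat >= observed_count).sum())
        done += t
    p = (1 + n_exceeding) / (spec.trials + 1)
    return HubOverlapResult(
        spec=spec, observed_count=observed_count, draw_sizes=draw_sizes,
        module_sizes=module_sizes, empirical_p=float(p), trials=spec.trials,
        n_exceeding=n_exceeding,
    )


# ---------------------------------------------------------------------------
# kME cross-correlation


def kme_cross_correlation(
    kme_a: pd.Series, kme_b: pd.Series, shared: list[str]
) -> tuple[float, float]:
    """Pearson correlation of two cohorts' kME over shared TG-module genes."""
    if len(shared) < 3:
        raise PipelineError("need at least 3 shared genes")
    a = kme_a.loc[shared].to_numpy(dtype=float)
    b = kme_b.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise PipelineError("constant kME vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# differential expression and top-N overlap


def rank_differential_expression(
    expr: ExpressionMatrix, labels: pd.Series
) -> pd.DataFrame:
    """Welch two-sample t-test per gene, ranked by ascending p.

    ``labels`` maps samples to exactly two classes; ties in p break by
    larger |t|, then by gene symbol.  Returns columns gene, t, p, rank.
    """
    lab = labels.loc[expr.sample_ids]
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise PipelineError(f"need exactly 2 classes, got {list(classes)}")
    g1 = expr.values.loc[:, (lab == classes[0]).to_numpy()]
    g2 = expr.values.loc[:, (lab == classes[1]).to_numpy()]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise PipelineError(
            f"each class needs >= 2 samples (got {g1.shape[1]} and {g2.shape[1]})"
        )
    t, p = stats.ttest_ind(g1.to_numpy(), g2.to_numpy(), axis=1, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    out = pd.DataFrame({"gene": expr.feature_ids, "t": t, "p": p})
    out["abs_t"] = out["t"].abs()
    out = out.sort_values(["p", "abs_t", "gene"], ascending=[True, False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns="abs_t").reset_index(drop=True)


def top_n(ranked: pd.DataFrame, n: int) -> list[str]:
    if n > len(ranked):
        raise PipelineError(f"n={n} exceeds ranking length {len(ranked)}")
    return ranked["gene"].iloc[:n].tolist()


def top_n_overlap(
    ranked_a: pd.DataFrame,
    ranked_b: pd.DataFrame,
    n: int,
    background: list[str],
    sidedness: str = "two_sided",
) -> OverlapResult:
    """Fisher overlap of the top-``n`` genes of two differential-expression rankings."""
    return fisher_module_overlap(top_n(ranked_a, n), top_n(ranked_b, n),
                                 background, sidedness=sidedness)


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric over-representation per gene set."""

    table: pd.DataFrame  # set_name, set_size_in_background, query_size, overlap, p, bonferroni_p
    background_size: int
    n_sets_tested: int


def ora_enrichment(
    query: set[str] | list[str],
    gene_sets: dict[str, list[str]],
    background: list[str],
) -> EnrichmentResult:
    """Hypergeometric over-representation of a query set against a collection.

    Each gene set is intersected with the background before testing; the
    p-value is the upper tail P(X ≥ overlap) with X hypergeometric, and
    Bonferroni correction runs over the sets with nonzero background
    intersection.
    """
    q = set(query)
    if not q:
        raise PipelineError("query gene set is empty")
    bg = set(background)
    stray = q - bg
    if stray:
        raise PipelineError(f"query genes outside background: {sorted(stray)[:10]}")
    N = len(bg)
    n_query = len(q)
    rows = []
    for name, genes in gene_sets.items():
        in_bg = set(genes) & bg
        K = len(in_bg)
        if K == 0:
            continue
        overlap = len(q & in_bg)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n_query))
        rows.append({"set_name": name, "set_size_in_background": K,
                     "query_size": n_query, "overlap": overlap, "p": p})
    if not rows:
        raise EmptyResultError("no gene set intersects the background")
    table = pd.DataFrame(rows)
    n_sets = len(table)
    table["bonferroni_p"] = np.minimum(1.0, table["p"] * n_sets)
    table = table.sort_values("p").reset_index(drop=True)
    return EnrichmentResult(table=table, background_size=N, n_sets_tested=n_sets)


# ---------------------------------------------------------------------------
# SNP association


def snp_association(genotypes: pd.Series, target: pd.Series) -> tuple[float, float]:
    """Pearson correlation of additive SNP dosage (0/1/2 or imputed [0,2]) with a target.

    The target is a module eigengene column or a single gene's expression
    over the same samples.
    """
    common = [s for s in genotypes.index if s in set(target.index)]
    if len(common) < 3:
        raise PipelineError("need at least 3 samples with both genotype and target")
    g = pd.to_numeric(genotypes.loc[common]).to_numpy(dtype=float)
    t = pd.to_numeric(target.loc[common]).to_numpy(dtype=float)
    if np.std(g) == 0:
        raise PipelineError("constant genotype")
    if np.std(t) == 0:
        raise PipelineError("constant target vector")
    r, p = stats.pearsonr(g, t)
    return float(r), float(p)
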
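"""Multi-cohort synthetic expression studies with planted module structure.

The generator emulates the study design the pipeline targets: three
cohorts of adipose expression (two microarray-like with multiple probes
per gene, one smaller RNA-seq-like), a latent-factor module structure
partially shared across cohorts, one module whose factor drives serum
triglycerides log-linearly, and twin-pair correlation in one cohort.

Per cohort and module m, the latent factor f_m is standard normal across
samples.  A member gene g has expression

    x_g = λ_g f_m + sqrt(1 − λ_g²) ε,      ε ~ N(0, 1),

so λ_g is both the planted loading and (asymptotically) the gene's kME.
Background genes are pure noise.  Triglycerides follow
log TG = μ + b f_tg + σ e, i.e. a log-normal marginal whose location is
set so the median is ≈1.2 mmol/L and roughly a third of samples exceed
the 1.5 mmol/L case cutoff.  Probe-level matrices expand each gene into
1–3 probes with per-probe sensitivity a ~ U(0.5, 1.5) and independent
probe noise, so the most variable probe is also the most signal-rich —
the property the max-variance collapse rule relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, FeatureAnnotation, PhenotypeTable, PipelineError


@dataclass
class SyntheticStudyConfig:
    """Study-design parameters for the generator.

    Defaults mirror the target design: cohorts of 53 (twins), 70 and 20
    samples, 2000 genes with planted modules of 150/100/60, loadings
    uniform on (0.5, 0.9), the first module driving log-TG with
    standardized slope 0.6, and twin pairs (intra-pair noise correlation
    0.5) in the first cohort.
    """

    n_cohorts: int = 3
    samples_per_cohort: tuple[int, ...] = (53, 70, 20)
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (150, 100, 60)
    loading_range: tuple[float, float] = (0.5, 0.9)
    preserved_flags: tuple[tuple[bool, ...], ...] | None = None  # [module][cohort]
    tg_module_index: int = 0
    tg_effect: float = 0.6
    tg_noise_sd: float = 0.3
    tg_log_median: float = math.log(1.2)
    noise_sd: float = 1.0
    inter_module_cor: float = 0.0
    twin_pair_cohort: int | None = 0
    twin_pair_cor: float = 0.5
    probes_per_gene_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) probes
    probe_noise_sd: float = 0.3
    rnaseq_cohort: int | None = 2  # emitted at gene level (no probe expansion)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise PipelineError("samples_per_cohort length must equal n_cohorts")
        if sum(self.module_sizes) > self.n_genes:
            raise PipelineError("module sizes exceed the number of genes")
        lo, hi = self.loading_range
        if not (0 < lo < hi < 1):
            raise PipelineError("loading_range must be inside (0, 1)")
        if not 0 <= self.tg_module_index < len(self.module_sizes):
            raise PipelineError("tg_module_index out of range")
        if self.preserved_flags is not None:
            if len(self.preserved_flags) != len(self.module_sizes):
                raise PipelineError("preserved_flags needs one row per module")
            for row in self.preserved_flags:
                if len(row) != self.n_cohorts:
                    raise PipelineError("preserved_flags rows need one entry per cohort")
        if abs(self.inter_module_cor) >= 1:
            raise PipelineError("inter_module_cor must be in (-1, 1)")


@dataclass
class SyntheticCohort:
    """One cohort's emitted data plus its cohort-specific ground truth."""

    name: str
    expression: ExpressionMatrix       # probe-level (or gene-level for RNA-seq cohorts)
    gene_expression: ExpressionMatrix  # gene-level signal before probe expansion
    phenotypes: PhenotypeTable
    annotation: FeatureAnnotation
    factors: pd.DataFrame              # samples × modules latent factors
    module_members: dict[int, list[str]]  # module index → member genes in THIS cohort


@dataclass
class SyntheticStudy:
    """Generated cohorts plus global ground truth."""

    config: SyntheticStudyConfig
    cohorts: list[SyntheticCohort]
    gene_ids: list[str]
    loadings: pd.Series                # per-gene planted loading (module members only)
    gene_module: pd.Series             # per-gene planted module index (-1 = background)

    def truth_dict(self) -> dict:
        return {
            "gene_module": {g: int(m) for g, m in self.gene_module.items()},
            "loadings": {g: float(l) for g, l in self.loadings.items()},
            "tg_module_index": self.config.tg_module_index,
            "tg_effect": self.config.tg_effect,
            "per_cohort_members": {
                c.name: {str(m): genes for m, genes in c.module_members.items()}
                for c in self.cohorts
            },
            "seed": self.config.seed,
        }


def generate_multi_cohort_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a reproducible multi-cohort study from ``config``.

    All randomness flows through a single ``numpy.random.default_rng``
    (PCG64) stream seeded by ``config.seed``, so the same seed yields an
    identical study on any platform.
    """
    rng = np.random.default_rng(config.seed)
    n_modules = len(config.module_sizes)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    # planted membership: first modules' worth of genes, then background
    gene_module = np.full(config.n_genes, -1, dtype=int)
    start = 0
    members_global: dict[int, np.ndarray] = {}
    for m, size in enumerate(config.module_sizes):
        members_global[m] = np.arange(start, start + size)
        gene_module[start:start + size] = m
        start += size
    background = np.arange(start, config.n_genes)

    lo, hi = config.loading_range
    loadings = np.zeros(config.n_genes)
    member_mask = gene_module >= 0
    loadings[member_mask] = rng.uniform(lo, hi, size=int(member_mask.sum()))

    preserved = config.preserved_flags
    if preserved is None:
        preserved = tuple(tuple(True for _ in range(config.n_cohorts))
                          for _ in range(n_modules))

    cohorts: list[SyntheticCohort] = []
    for c in range(config.n_cohorts):
        n = config.samples_per_cohort[c]
        sample_ids = [f"C{c + 1}S{j:03d}" for j in range(n)]

        # latent module factors, optionally equicorrelated
        F = rng.standard_normal((n, n_modules))
        if config.inter_module_cor != 0 and n_modules > 1:
            shared = rng.standard_normal((n, 1))
            rho = config.inter_module_cor
            F = math.sqrt(abs(rho)) * np.sign(rho) * shared + math.sqrt(1 - abs(rho)) * F

        # per-cohort membership: non-preserved modules relocate their
        # loadings onto random background genes; original members go to noise
        cohort_members: dict[int, np.ndarray] = {}
        free_background = list(background)
        for m in range(n_modules):
            if preserved[m][c]:
                cohort_members[m] = members_global[m]
            else:
                size = len(members_global[m])
                if size > len(free_background):
                    raise PipelineError(
                        f"not enough background genes to relocate module {m} in cohort {c}"
                    )
                pick = rng.choice(len(free_background), size=size, replace=False)
                chosen = np.array([free_background[i] for i in sorted(pick)])
                free_background = [g for i, g in enumerate(free_background)
                                   if i not in set(pick)]
                cohort_members[m] = chosen

        # noise, with a shared pair component in the twin cohort
        if config.twin_pair_cohort == c:
            pair_ids, pair_index = _twin_pairs(n)
            rho = config.twin_pair_cor
            pair_noise = rng.standard_normal((config.n_genes, len(set(pair_index))))
            ind_noise = rng.standard_normal((config.n_genes, n))
            eps = (math.sqrt(rho) * pair_noise[:, pair_index]
                   + math.sqrt(1 - rho) * ind_noise)
        else:
            pair_ids = [""] * n
            eps = rng.standard_normal((config.n_genes, n))

        X = config.noise_sd * eps
        for m, members in cohort_members.items():
            lam = loadings[members_global[m]]  # loadings travel with the module
            fm = F[:, m]
            X[members] = (lam[:, None] * fm[None, :]
                          + np.sqrt(1 - lam ** 2)[:, None]
                          * config.noise_sd * eps[members])

        gene_df = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
        gene_expr = ExpressionMatrix(gene_df, feature_kind="gene")

        pheno = _phenotypes(rng, config, F, sample_ids, pair_ids)
        if config.rnaseq_cohort == c:
            expr = gene_expr
            ann = FeatureAnnotation(pd.DataFrame({
                "gene_symbol": gene_ids,
                "gene_length_kb": rng.uniform(0.5, 10.0, size=config.n_genes),
            }, index=pd.Index(gene_ids, name="feature_id")))
        else:
            expr, ann = _expand_probes(rng, gene_df, config)

        cohorts.append(SyntheticCohort(
            name=f"cohort{c + 1}",
            expression=expr,
            gene_expression=gene_expr,
            phenotypes=pheno,
            annotation=ann,
            factors=pd.DataFrame(F, index=sample_ids,
                                 columns=[f"factor{m}" for m in range(n_modules)]),
            module_members={m: [gene_ids[g] for g in mem]
                            for m, mem in cohort_members.items()},
        ))

    return SyntheticStudy(
        config=config,
        cohorts=cohorts,
        gene_ids=gene_ids,
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        gene_module=pd.Series(gene_module, index=gene_ids, name="module"),
    )


def _twin_pairs(n: int) -> tuple[list[str], np.ndarray]:
    """Pair ids for a twin cohort: consecutive pairs, a trailing singleton if n is odd."""
    pair_ids = []
    pair_index = []
    for j in range(n):
        pair = j // 2
        pair_ids.append(f"pair{pair + 1:02d}")
        pair_index.append(pair)
    return pair_ids, np.array(pair_index)


def _phenotypes(
    rng: np.random.Generator,
    config: SyntheticStudyConfig,
    F: np.ndarray,
    sample_ids: list[str],
    pair_ids: list[str],
) -> PhenotypeTable:
    n = len(sample_ids)
    f_tg = F[:, config.tg_module_index]
    log_tg = (config.tg_log_median + config.tg_effect * f_tg
              + config.tg_noise_sd * rng.standard_normal(n))
    tg = np.exp(log_tg)
    bmi = 26.0 + 1.0 * f_tg + 3.0 * rng.standard_normal(n)
    bmi = np.maximum(bmi, 16.0)
    paired = any(p for p in pair_ids)
    if paired:
        # twins share age and sex
        ages = rng.uniform(25, 65, size=(n + 1) // 2)
        sexes = rng.integers(0, 2, size=(n + 1) // 2)
        age = np.array([ages[j // 2] for j in range(n)])
        sex = np.array([sexes[j // 2] for j in range(n)])
    else:
        age = rng.uniform(25, 65, size=n)
        sex = rng.integers(0, 2, size=n)
    df = pd.DataFrame({
        "tg": tg, "bmi": bmi, "age": np.round(age, 1), "sex": sex,
        "pair_id": [p if p else None for p in pair_ids],
        "group": np.where(tg > 1.5, "case", "control"),
    }, index=pd.Index(sample_ids, name="sample_id"))
    return PhenotypeTable(df)


def _expand_probes(
    rng: np.random.Generator,
    gene_df: pd.DataFrame,
    config: SyntheticStudyConfig,
) -> tuple[ExpressionMatrix, FeatureAnnotation]:
    probs = np.asarray(config.probes_per_gene_probs, dtype=float)
    probs = probs / probs.sum()
    n_probes = rng.choice(np.arange(1, len(probs) + 1), size=len(gene_df), p=probs)
    rows, probe_ids, symbols = [], [], []
    G = gene_df.to_numpy()
    n = gene_df.shape[1]
    for i, gene in enumerate(gene_df.index):
        for k in range(n_probes[i]):
            a = rng.uniform(0.5, 1.5)
            noise = config.probe_noise_sd * rng.standard_normal(n)
            rows.append(a * G[i] + noise)
            probe_ids.append(f"{gene}_p{k + 1}")
            symbols.append(gene)
    expr = ExpressionMatrix(
        pd.DataFrame(np.asarray(rows), index=probe_ids, columns=gene_df.columns),
        feature_kind="probe",
    )
    ann = FeatureAnnotation(pd.DataFrame({
        "gene_symbol": symbols,
        "gene_length_kb": rng.uniform(0.5, 10.0, size=len(probe_ids)),
    }, index=pd.Index(probe_ids, name="feature_id")))
    return expr, ann


def generate_dosages(
    n_samples: int,
    n_snps: int = 1,
    maf: float = 0.3,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Independent Hardy-Weinberg SNP dosages (0/1/2), samples × SNPs."""
    if not 0 < maf <= 0.5:
        raise PipelineError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, maf, size=(n_samples, n_snps))
    if sample_ids is None:
        sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    return pd.DataFrame(dos, index=pd.Index(sample_ids, name="sample_id"),
                        columns=[f"rs{k + 1:06d}" for k in range(n_snps)])
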
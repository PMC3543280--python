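"""End-to-end orchestration: preprocess → network → preservation → compare.

``run_all`` takes two or more cohorts (expression + phenotypes +
annotation), prepares each one, infers its co-expression modules,
correlates eigengenes with the adjusted TG trait, quantifies pairwise
module preservation against the first cohort, selects each cohort's TG
module, and tests the cross-cohort overlap of TG-module genes and hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GREY, ExpressionMatrix, FeatureAnnotation, PhenotypeTable, PipelineError
from .preprocess import (
    collapse_probes,
    default_detection_mask,
    filter_expressed,
    residualize_expression,
    stepwise_adjust_trait,
)
from .network import (
    ModulePartition,
    ModuleTraitResult,
    NetworkConfig,
    detect_modules,
    module_trait_correlation,
)
from .preservation import PreservationResult, module_preservation
from .compare import (
    HubOverlapSpec,
    OverlapResult,
    empirical_hub_overlap,
    fisher_module_overlap,
    harmonize_genes,
    kme_cross_correlation,
)


@dataclass
class CohortInput:
    name: str
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    annotation: FeatureAnnotation | None = None


@dataclass
class CohortResult:
    name: str
    expression: ExpressionMatrix          # preprocessed, gene-level
    partition: ModulePartition
    trait_result: ModuleTraitResult
    tg_module: str
    tg_module_genes: list[str]
    adjusted_tg: pd.Series
    selected_covariates: list[str]


@dataclass
class RunAllResult:
    cohorts: list[CohortResult]
    preservation: dict[str, PreservationResult]   # "ref_vs_<name>"
    tg_overlaps: dict[str, OverlapResult]          # "<a>_vs_<b>"
    shared_tg_genes: list[str]
    hub_overlap: dict | None
    kme_cross: dict[str, tuple[float, float]]
    background: list[str]

    def summary(self) -> dict:
        out = {
            "cohorts": {
                c.name: {
                    "n_genes": c.expression.n_features,
                    "n_samples": c.expression.n_samples,
                    "n_modules": len([m for m in c.partition.module_names if m != GREY]),
                    "tg_module": c.tg_module,
                    "tg_module_size": len(c.tg_module_genes),
                    "selected_covariates": c.selected_covariates,
                }
                for c in self.cohorts
            },
            "preservation": {
                key: res.to_frame()[["module", "size", "Zsummary", "flag"]]
                        .to_dict(orient="records")
                for key, res in self.preservation.items()
            },
            "tg_overlaps": {
                key: {
                    "background_size": r.background_size,
                    "set_a_size": r.set_a_size,
                    "set_b_size": r.set_b_size,
                    "shared_count": r.shared_count,
                    "percentage": r.percentage,
                    "fisher_p": r.fisher_p,
                }
                for key, r in self.tg_overlaps.items()
            },
            "n_shared_tg_genes": len(self.shared_tg_genes),
            "shared_tg_genes": self.shared_tg_genes,
            "kme_cross_correlation": {k: {"r": v[0], "p": v[1]}
                                      for k, v in self.kme_cross.items()},
        }
        if self.hub_overlap is not None:
            out["hub_overlap"] = self.hub_overlap
        return out


def prepare_cohort(
    cohort: CohortInput,
    min_fraction: float = 0.5,
    covariates: tuple[str, ...] = ("age", "sex"),
    pair_center: bool | None = None,
    stepwise_candidates: tuple[str, ...] = ("age", "sex", "bmi"),
    alpha: float = 0.05,
) -> tuple[ExpressionMatrix, pd.Series, list[str]]:
    """Filter, collapse, residualize one cohort; adjust log-TG by stepwise OLS.

    ``pair_center`` defaults to True exactly when the phenotype table
    carries pair labels.
    """
    expr = cohort.expression
    mask = default_detection_mask(expr)
    expr = filter_expressed(expr, mask, min_fraction=min_fraction)
    if expr.feature_kind == "probe":
        if cohort.annotation is None:
            raise PipelineError(f"cohort {cohort.name}: probe-level data needs an annotation")
        expr = collapse_probes(expr, cohort.annotation)
    pheno = cohort.phenotypes.aligned_to(expr)
    if pair_center is None:
        pair_center = ("pair_id" in pheno.data.columns
                       and pheno.data["pair_id"].notna().any())
    expr = residualize_expression(expr, pheno, list(covariates), pair_center=pair_center)
    adj = stepwise_adjust_trait(pheno, "tg", list(stepwise_candidates),
                                log_transform=True, alpha=alpha)
    return expr, adj.residuals, adj.selected


def run_all(
    cohorts: list[CohortInput],
    network_config: NetworkConfig | None = None,
    n_permutations: int = 200,
    hub_spec: HubOverlapSpec | None = None,
    seed: int = 0,
    min_fraction: float = 0.5,
) -> RunAllResult:
    """Run the full multi-cohort analysis with cohort 1 as the preservation reference."""
    if len(cohorts) < 2:
        raise PipelineError(">= 2 cohorts required")
    config = network_config or NetworkConfig(seed=seed)

    stage = "preprocess"
    try:
        prepared: list[CohortResult] = []
        gene_exprs: list[ExpressionMatrix] = []
        for cohort in cohorts:
            expr, tg_adj, selected = prepare_cohort(cohort, min_fraction=min_fraction)
            gene_exprs.append(expr)
            prepared.append(CohortResult(
                name=cohort.name, expression=expr, partition=None,  # filled below
                trait_result=None, tg_module="", tg_module_genes=[],
                adjusted_tg=tg_adj, selected_covariates=selected,
            ))

        stage = "harmonize"
        aligned, background = harmonize_genes(gene_exprs, [None] * len(gene_exprs))

        stage = "network"
        for res, expr, cohort in zip(prepared, aligned, cohorts):
            partition = detect_modules(expr, config)
            pheno = cohort.phenotypes.aligned_to(expr)
            ph = pheno.data.copy()
            ph["tg_adj"] = res.adjusted_tg.loc[ph.index]
            pheno2 = PhenotypeTable(ph)
            traits = ["tg_adj"]
            trait_result = module_trait_correlation(partition, pheno2, traits, expr=expr)
            non_grey = [m for m in partition.module_names if m != GREY]
            if not non_grey:
                raise PipelineError(f"cohort {res.name}: no modules detected")
            tg_module = trait_result.top_module("tg_adj")
            res.expression = expr
            res.partition = partition
            res.trait_result = trait_result
            res.tg_module = tg_module
            res.tg_module_genes = partition.members(tg_module)

        stage = "preservation"
        preservation: dict[str, PreservationResult] = {}
        ref = prepared[0]
        for other in prepared[1:]:
            key = f"{ref.name}_vs_{other.name}"
            preservation[key] = module_preservation(
                ref.expression, ref.partition, other.expression,
                n_permutations=n_permutations, seed=seed, beta=config.beta,
            )

        stage = "compare"
        tg_overlaps: dict[str, OverlapResult] = {}
        for i in range(len(prepared)):
            for j in range(i + 1, len(prepared)):
                a, b = prepared[i], prepared[j]
                tg_overlaps[f"{a.name}_vs_{b.name}"] = fisher_module_overlap(
                    a.tg_module_genes, b.tg_module_genes, background,
                )
        shared = set(prepared[0].tg_module_genes)
        for res in prepared[1:]:
            shared &= set(res.tg_module_genes)
        shared_tg_genes = sorted(shared)

        kme_cross: dict[str, tuple[float, float]] = {}
        for i in range(len(prepared)):
            for j in range(i + 1, len(prepared)):
                a, b = prepared[i], prepared[j]
                pair_shared = sorted(set(a.tg_module_genes) & set(b.tg_module_genes))
                if len(pair_shared) >= 3:
                    ka = a.partition.kme[f"ME{a.tg_module}"]
                    kb = b.partition.kme[f"ME{b.tg_module}"]
                    kme_cross[f"{a.name}_vs_{b.name}"] = kme_cross_correlation(
                        ka, kb, pair_shared)

        hub_result = None
        if shared_tg_genes:
            spec = hub_spec or HubOverlapSpec(criterion="top_fraction", parameter=0.5,
                                              trials=100_000, seed=seed)
            kmes = []
            for res in prepared:
                col = f"ME{res.tg_module}"
                kmes.append(res.partition.kme.loc[res.tg_module_genes, col])
            # observed: shared genes ranking in the top fraction everywhere
            observed = _observed_hub_count(kmes, spec, shared_tg_genes)
            hub = empirical_hub_overlap(kmes, spec, shared_tg_genes, observed)
            hub_result = {
                "criterion": spec.criterion, "parameter": spec.parameter,
                "trials": spec.trials, "seed": spec.seed,
                "observed_count": observed, "empirical_p": hub.empirical_p,
                "draw_sizes": hub.draw_sizes, "module_sizes": hub.module_sizes,
            }
    except PipelineError as exc:
        raise PipelineError(f"[stage: {stage}] {exc}") from exc

    return RunAllResult(
        cohorts=prepared, preservation=preservation, tg_overlaps=tg_overlaps,
        shared_tg_genes=shared_tg_genes, hub_overlap=hub_result,
        kme_cross=kme_cross, background=background,
    )


def _observed_hub_count(
    kmes: list[pd.Series], spec: HubOverlapSpec, candidates: list[str]
) -> int:
    """Candidates meeting the hub criterion in every dataset."""
    qualifying = None
    for kme in kmes:
        absk = kme.abs()
        if spec.criterion == "kme_above":
            sel = set(absk.index[absk > spec.parameter])
        elif spec.criterion == "top_rank":
            sel = set(absk.sort_values(ascending=False).index[: int(spec.parameter)])
        else:
            k = int(np.ceil(spec.parameter * len(absk)))
            sel = set(absk.sort_values(ascending=False).index[:k])
        qualifying = sel if qualifying is None else (qualifying & sel)
    return len(qualifying & set(candidates))
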
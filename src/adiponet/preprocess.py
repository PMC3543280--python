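"""Per-cohort preparation of expression and trait data.

Covers the steps applied to each cohort before network construction:
background-detection filtering, collapsing multiple probes per gene to the
most variable probe, removing covariate and twin-pair effects from
expression by least squares, adjusting a trait for significant covariates
by bidirectional stepwise regression, dichotomizing triglycerides at a
clinical cutoff, and FPKM normalization for RNA-seq counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    AlignmentError,
    EmptyResultError,
    ExpressionMatrix,
    FeatureAnnotation,
    PhenotypeTable,
    PipelineError,
)

logger = logging.getLogger(__name__)


def default_detection_mask(expr: ExpressionMatrix, quantile: float = 0.10) -> pd.DataFrame:
    """Boolean detection mask: value strictly above the per-sample ``quantile``.

    Stands in for platform "expressed above background" calls when none are
    supplied.
    """
    if not 0.0 <= quantile < 1.0:
        raise PipelineError(f"quantile must be in [0, 1), got {quantile}")
    thresholds = expr.values.quantile(quantile, axis=0)
    return expr.values.gt(thresholds, axis=1)


def filter_expressed(
    expr: ExpressionMatrix, mask: pd.DataFrame, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep features detected in at least ``ceil(min_fraction * n_samples)`` samples.

    ``mask`` is a boolean DataFrame aligned to ``expr`` (same feature and
    sample identifiers).  Feature order is preserved; the sample set is
    unchanged.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise PipelineError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if mask.shape != expr.values.shape or list(mask.index) != list(expr.values.index) \
            or list(mask.columns) != list(expr.values.columns):
        raise AlignmentError(
            f"detection mask shape/ids {mask.shape} do not align with expression {expr.values.shape}"
        )
    required = math.ceil(min_fraction * expr.n_samples)
    keep = mask.to_numpy(dtype=bool).sum(axis=1) >= required
    if not keep.any():
        raise EmptyResultError(
            f"no features detected in >= {required} of {expr.n_samples} samples"
        )
    return ExpressionMatrix(expr.values.loc[keep], feature_kind=expr.feature_kind)


def collapse_probes(expr: ExpressionMatrix, ann: FeatureAnnotation) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    The representative probe for a gene is the one with maximal sample
    variance; ties break to the lexicographically smallest probe id.
    Probes without an annotation row are dropped (count logged).
    """
    if expr.feature_kind != "probe":
        raise PipelineError("collapse_probes expects a probe-level matrix")
    symbols = ann.symbol_map()
    mapped = [f for f in expr.feature_ids if f in symbols.index and pd.notna(symbols.loc[f])]
    n_dropped = expr.n_features - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise EmptyResultError("no probes map to a gene symbol")
    sub = expr.values.loc[mapped]
    variances = sub.var(axis=1, ddof=1)
    table = pd.DataFrame({
        "probe": mapped,
        "symbol": symbols.loc[mapped].astype(str).to_numpy(),
        "var": variances.to_numpy(),
    })
    # max variance wins; ties resolved by smallest probe id
    table = table.sort_values(["symbol", "var", "probe"], ascending=[True, False, True])
    reps = table.drop_duplicates("symbol", keep="first")
    out = sub.loc[reps["probe"]]
    out.index = reps["symbol"].to_numpy()
    return ExpressionMatrix(out.sort_index(), feature_kind="gene")


def _rank_deficient_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that are (numerically) linear combinations of the others."""
    collinear = []
    for j in range(design.shape[1]):
        others = np.delete(design, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
        resid = design[:, j] - others @ coef
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(design[:, j])):
            collinear.append(names[j])
    return collinear


def residualize_expression(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    covariates: list[str],
    pair_center: bool = False,
) -> ExpressionMatrix:
    """Replace each feature by residuals of a least-squares fit on covariates.

    The design always contains an intercept.  With ``pair_center``, residuals
    are additionally centered within each ``pair_id`` group, removing a fixed
    pair (twin/family) effect.
    """
    ph = pheno.aligned_to(expr).data
    for c in covariates:
        if c not in ph.columns:
            raise PipelineError(f"covariate {c!r} not in phenotype table")
        if ph[c].isna().any():
            bad = ph.index[ph[c].isna()].tolist()
            raise PipelineError(f"covariate {c!r} has missing values for samples {bad[:10]}")
    Y = expr.values.to_numpy(dtype=float).T  # samples x features
    if covariates:
        X = np.column_stack(
            [np.ones(len(ph))] + [pd.to_numeric(ph[c]).to_numpy(dtype=float) for c in covariates]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            collinear = _rank_deficient_columns(X[:, 1:], list(covariates))
            raise PipelineError(f"rank-deficient design; collinear covariates: {collinear}")
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
    else:
        resid = Y - Y.mean(axis=0, keepdims=True)
    out = pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns)
    if pair_center:
        if "pair_id" not in ph.columns or ph["pair_id"].isna().all():
            raise PipelineError("pair_center requested but pair_id is absent")
        pair = ph["pair_id"].astype(str)
        means = out.T.groupby(pair).transform("mean").T
        out = out - means
        # samples without a pair label keep their covariate residual minus
        # the global mean so feature means stay ~0
    out = out.sub(out.mean(axis=1), axis=0)
    return ExpressionMatrix(out, feature_kind=expr.feature_kind)


@dataclass
class StepwiseResult:
    """Adjusted trait plus the covariates retained by stepwise selection."""

    residuals: pd.Series
    selected: list[str]
    response_name: str
    log_transformed: bool


def stepwise_adjust_trait(
    pheno: PhenotypeTable,
    response: str,
    candidates: list[str],
    log_transform: bool = True,
    alpha: float = 0.05,
) -> StepwiseResult:
    """Adjust a trait for significant covariates by bidirectional stepwise OLS.

    Forward steps add the candidate with the smallest partial p-value if
    p ≤ ``alpha``; backward steps drop the retained covariate with the
    largest p-value if p > ``alpha``; iteration stops at a fixed point.
    Returns residuals from the final model (just the centered response when
    nothing is selected).
    """
    df = pheno.data
    if response not in df.columns:
        raise PipelineError(f"response {response!r} not in phenotype table")
    y = pd.to_numeric(df[response]).astype(float)
    if y.isna().any():
        raise PipelineError(f"response {response!r} has missing values")
    if log_transform:
        if (y <= 0).any():
            bad = df.index[y <= 0].tolist()
            raise PipelineError(
                f"log transform requires strictly positive response; offending samples: {bad[:10]}"
            )
        y = np.log(y)
    for c in candidates:
        if c not in df.columns:
            raise PipelineError(f"candidate covariate {c!r} not in phenotype table")
        if df[c].isna().any():
            raise PipelineError(f"candidate covariate {c!r} has missing values")

    yv = y.to_numpy()
    cols = {c: pd.to_numeric(df[c]).to_numpy(dtype=float) for c in candidates}

    def fit(selected: list[str]):
        X = np.column_stack([np.ones(len(yv))] + [cols[c] for c in selected])
        return sm.OLS(yv, X).fit()

    selected: list[str] = []
    while True:
        changed = False
        # forward
        remaining = [c for c in candidates if c not in selected]
        best_p, best_c = None, None
        for c in remaining:
            res = fit(selected + [c])
            p = res.pvalues[-1]
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p <= alpha:
            selected.append(best_c)
            changed = True
        # backward
        while selected:
            res = fit(selected)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        res = fit(selected)
        residuals = pd.Series(res.resid, index=df.index, name=f"{response}_adj")
    else:
        residuals = pd.Series(yv - yv.mean(), index=df.index, name=f"{response}_adj")
    return StepwiseResult(residuals=residuals, selected=selected,
                          response_name=response, log_transformed=log_transform)


def dichotomize_binary_trait(
    pheno: PhenotypeTable, threshold: float = 1.5
) -> tuple[pd.Series, dict[str, int]]:
    """Label samples case/control by serum TG strictly above ``threshold`` mmol/L.

    Returns the per-sample labels and the class counts.  1.5 mmol/L is the
    average fasting serum TG for European-origin male adults, the cutoff
    used to define high-TG cases.
    """
    tg = pd.to_numeric(pheno.data["tg"], errors="coerce")
    if tg.isna().any():
        bad = pheno.data.index[tg.isna()].tolist()
        raise PipelineError(f"tg missing for samples: {bad[:10]}")
    labels = pd.Series(
        np.where(tg.to_numpy() > threshold, "case", "control"),
        index=pheno.data.index, name="tg_group",
    )
    counts = {"case": int((labels == "case").sum()), "control": int((labels == "control").sum())}
    return labels, counts


def fpkm(
    counts: pd.DataFrame,
    gene_length_kb: pd.Series,
    mapped_reads: pd.Series,
) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million mapped reads.

    ``value = count / (length_kb × mapped_reads / 10⁶)`` — read counts
    normalized by gene length in kilobases and by the per-sample total of
    mapped reads in millions.
    """
    cvals = counts.to_numpy(dtype=float)
    if (cvals < 0).any():
        raise PipelineError("counts must be nonnegative")
    lengths = pd.to_numeric(gene_length_kb).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = counts.index[lengths.isna() | (lengths <= 0)].tolist()
        raise PipelineError(f"gene_length_kb must be present and > 0; offending genes: {bad[:10]}")
    lib = pd.to_numeric(mapped_reads).reindex(counts.columns)
    if lib.isna().any() or (lib <= 0).any():
        bad = counts.columns[lib.isna() | (lib <= 0)].tolist()
        raise PipelineError(f"mapped_reads must be present and > 0; offending samples: {bad[:10]}")
    vals = cvals / lengths.to_numpy()[:, None] / (lib.to_numpy()[None, :] / 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        feature_kind="gene",
    )
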
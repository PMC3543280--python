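"""Core data containers and exceptions shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a features × samples table of
continuous expression (log-intensities for microarrays, log(FPKM+1) for
RNA-seq) carried as a :class:`pandas.DataFrame` so that feature and sample
identifiers travel with the values.  Phenotypes and feature annotation are
thin validated wrappers around DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GREY = "grey"

#: Canonical module color sequence, assigned in order of decreasing module
#: size.  Grey is reserved for unassigned background features and never
#: appears in this list.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


class PipelineError(ValueError):
    """Base class for validation and computation errors in this package."""


class AlignmentError(PipelineError):
    """Inputs that must share identifiers or shape do not."""


class EmptyResultError(PipelineError):
    """An operation produced an empty result where at least one row/feature is required."""


def module_color_sequence(n: int) -> list[str]:
    """Return ``n`` module labels: the canonical colors, then ``module<k>``."""
    labels = list(MODULE_COLORS[:n])
    for k in range(len(labels), n):
        labels.append(f"module{k + 1}")
    return labels


@dataclass
class ExpressionMatrix:
    """Features × samples continuous expression with identifiers.

    Parameters
    ----------
    values
        DataFrame with one row per feature and one column per sample.
    feature_kind
        ``"probe"`` for platform-level features, ``"gene"`` after collapsing
        probes to gene symbols.
    """

    values: pd.DataFrame
    feature_kind: str = "probe"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("probe", "gene"):
            raise PipelineError(f"feature_kind must be 'probe' or 'gene', got {self.feature_kind!r}")
        vals = np.asarray(self.values.to_numpy(), dtype=float)
        if not np.all(np.isfinite(vals)):
            n_bad = int((~np.isfinite(vals)).sum())
            raise PipelineError(f"expression matrix contains {n_bad} non-finite values")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate feature ids: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate sample ids: {dups[:10]}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes: TG (mmol/L), BMI, age, sex, pair and group labels.

    ``data`` is indexed by sample id.  ``tg`` must be strictly positive
    wherever present (it is a serum concentration and is later
    log-transformed).  ``pair_id`` marks twin pairs / families; ``group`` is
    an optional case/control label.  Missing optional values are NaN/None.
    """

    data: pd.DataFrame

    REQUIRED = ("tg", "bmi", "age", "sex")
    OPTIONAL = ("pair_id", "group")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate sample ids in phenotype table: {dups[:10]}")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise PipelineError(f"phenotype table missing required columns: {missing}")
        tg = pd.to_numeric(self.data["tg"], errors="coerce")
        bad = self.data.index[(tg <= 0) & tg.notna()].tolist()
        if bad:
            raise PipelineError(f"tg must be > 0 mmol/L; offending samples: {bad[:10]}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def aligned_to(self, expr: ExpressionMatrix) -> "PhenotypeTable":
        """Return the phenotype rows for ``expr``'s samples, in expression order."""
        missing = [s for s in expr.sample_ids if s not in self.data.index]
        if missing:
            raise AlignmentError(f"samples absent from phenotype table: {missing[:10]}")
        return PhenotypeTable(self.data.loc[expr.sample_ids])


@dataclass
class FeatureAnnotation:
    """Probe/gene annotation: feature id → gene symbol (+ optional length in kb)."""

    data: pd.DataFrame  # indexed by feature_id; columns: gene_symbol [, gene_length_kb]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate feature ids in annotation: {dups[:10]}")
        if "gene_symbol" not in self.data.columns:
            raise PipelineError("annotation must contain a 'gene_symbol' column")
        if "gene_length_kb" in self.data.columns:
            lengths = pd.to_numeric(self.data["gene_length_kb"], errors="coerce")
            bad = self.data.index[(lengths <= 0) & lengths.notna()].tolist()
            if bad:
                raise PipelineError(f"gene_length_kb must be > 0; offending features: {bad[:10]}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def symbol_map(self) -> pd.Series:
        return self.data["gene_symbol"]
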
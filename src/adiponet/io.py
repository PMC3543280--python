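"""Readers/writers for the pipeline's tab-delimited formats, plus run logging.

Expression TSV: first column ``feature_id``, one column per sample,
header row of sample ids.  Phenotype TSV: ``sample_id, tg, bmi, age, sex,
pair_id, group`` with ``NA`` for missing optional fields.  Annotation
TSV: ``feature_id, gene_symbol, gene_length_kb``.  GMT: standard
``set_name<TAB>description<TAB>gene…`` lines.  Genotypes: long-format
``sample_id, snp_id, dosage``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, FeatureAnnotation, PhenotypeTable, PipelineError

FLOAT_FORMAT = "%.10g"


def read_expression(path: str | Path, feature_kind: str = "probe") -> ExpressionMatrix:
    """Read a features × samples expression TSV.

    Duplicate feature or sample identifiers and non-numeric cells are
    rejected with the offending ids/coordinates.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = [c for c in header if header.count(c) > 1]  # pandas would mangle these
    if dups:
        raise PipelineError(f"{path}: duplicate sample ids in header: {sorted(set(dups))[:10]}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup_f = df.index[df.index.duplicated()].unique().tolist()
        raise PipelineError(f"{path}: duplicate feature ids: {dup_f[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise PipelineError(
            f"{path}: non-numeric cell at feature {df.index[i]!r}, sample {df.columns[j]!r}: "
            f"{df.iloc[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise PipelineError(f"{path}: missing value at feature {df.index[i]!r}, "
                            f"sample {df.columns[j]!r}")
    # numpy's strtod is correctly-rounded, so repr-written values read back
    # bit-exactly (pandas' fast parser is not)
    exact = df.to_numpy(dtype=str).astype(np.float64)
    out = pd.DataFrame(exact, index=df.index.astype(str), columns=df.columns.astype(str))
    out.index.name = None
    out.columns.name = None
    return ExpressionMatrix(out, feature_kind=feature_kind)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV that reads back bit-exactly (repr round-trip)."""
    df = expr.values.copy()
    df.index.name = "feature_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(str(c) for c in df.columns) + "\n")
        for fid, row in zip(df.index, df.to_numpy()):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     na_values=["NA"], keep_default_na=True)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path: str | Path) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="feature_id", na_values=["NA"])
    return FeatureAnnotation(df)


def write_annotation(ann: FeatureAnnotation, path: str | Path) -> None:
    df = ann.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (set name, description, genes…)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PipelineError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise PipelineError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    if not sets:
        raise PipelineError(f"{path}: empty GMT file")
    return sets


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read long-format dosages into a samples × SNPs DataFrame."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "snp_id", "dosage"}
    if not required.issubset(df.columns):
        raise PipelineError(f"{path}: genotype TSV needs columns {sorted(required)}")
    dosage = pd.to_numeric(df["dosage"], errors="coerce")
    if dosage.isna().any() or (dosage < 0).any() or (dosage > 2).any():
        raise PipelineError(f"{path}: dosages must be numeric in [0, 2]")
    wide = df.pivot(index="sample_id", columns="snp_id", values="dosage")
    return wide.astype(float)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunLog:
    """Provenance record written next to every command's outputs."""

    command: str
    config: dict
    seeds: dict[str, int]
    input_digests: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.version:
            from . import __version__
            self.version = __version__

    def write(self, path: str | Path) -> None:
        payload = {
            "timestamp": self.timestamp,
            "command": self.command,
            "version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "input_digests": self.input_digests,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
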
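"""Domain types and tabular I/O for the reversal-analysis pipeline.

All tabular files are TSV. Files written by this package carry a commented
header block of ``#key=value`` lines recording provenance (stage, parameters,
seed) so that every output is self-describing and byte-reproducible.

Gene and sample identifiers are matched exactly and case-sensitively
throughout; no symbol aliasing is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("reverseq")

__all__ = [
    "ValidationError",
    "CountMatrix",
    "SampleDesign",
    "GeneSet",
    "PhenotypeTable",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_phenotypes",
    "write_phenotypes",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_unique(values: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen[v] = 1
    if dups:
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer gene x sample count matrix.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns.
    Counts must be raw (unnormalized) integers: any non-integral value is
    rejected rather than silently accepted, since normalization is owned by
    the differential-expression stage.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(list(df.index), "gene")
        _check_unique(list(df.columns), "sample")
        if df.shape[1] < 2:
            raise ValidationError("a CountMatrix needs at least 2 samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"counts must be non-negative integers; offending entry at "
                f"gene {df.index[g]!r}, sample {df.columns[s]!r}: {values[g, s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample design: an arm label, an optional timepoint, covariates.

    ``table`` is indexed by sample id with an ``arm`` column (categorical
    label such as control / disease / treated), an optional numeric
    ``timepoint`` column (hours), and any further numeric covariate columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "sample")
        if "arm" not in self.table.columns:
            raise ValidationError("design table must have an 'arm' column")
        if "timepoint" in self.table.columns:
            tp = pd.to_numeric(self.table["timepoint"], errors="coerce")
            if (tp.dropna() < 0).any():
                raise ValidationError("timepoints must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def arm(self, sample: str) -> str:
        return str(self.table.loc[sample, "arm"])

    def samples_in_arm(self, arm: str, timepoint: float | None = None) -> list[str]:
        mask = self.table["arm"] == arm
        if timepoint is not None:
            mask &= self.table["timepoint"] == timepoint
        return list(self.table.index[mask])

    def check_matches(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (GMT semantics)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PhenotypeTable:
    """Samples x numeric phenotypes; missing values allowed (NaN)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "sample")
        coerced = self.table.apply(pd.to_numeric, errors="coerce")
        n_new_na = int(coerced.isna().sum().sum() - self.table.isna().sum().sum())
        if n_new_na > 0:
            raise ValidationError("phenotype columns must be numeric")
        object.__setattr__(self, "table", coerced.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def phenotype_names(self) -> list[str]:
        return list(self.table.columns)


# ---------------------------------------------------------------------------
# TSV with commented provenance header
# ---------------------------------------------------------------------------

def _format_header(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"#{k}={v}\n" for k, v in meta.items())


def read_table(path: str | Path, index_col: int | None = 0) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].rstrip("\n")
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    return df, meta


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None,
                index_label: str | None = None, float_format: str = "%.10g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_format_header(meta))
        df.to_csv(fh, sep="\t", index_label=index_label, float_format=float_format,
                  lineterminator="\n")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample TSV count matrix (first column gene ids).

    Row and column order are preserved from the file. Duplicated gene or
    sample ids, negative entries, and non-integral entries are rejected with
    an error naming the offender.
    """
    df, _ = read_table(path, index_col=None)
    gene_col = df.columns[0]
    _check_unique(list(df[gene_col].astype(str)), "gene")
    df = df.set_index(gene_col)
    df.index.name = "gene"
    df.index = df.index.astype(str)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    write_table(cm.counts, path, meta=meta, index_label="gene")


def read_design(path: str | Path) -> SampleDesign:
    df, _ = read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    write_table(design.table, path, meta=meta, index_label="sample")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df, _ = read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return PhenotypeTable(df)


def write_phenotypes(pt: PhenotypeTable, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    write_table(pt.table, path, meta=meta, index_label="sample")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated name/description/members.

    Duplicate members within a line are deduplicated with a logged warning;
    a line with fewer than three fields is a parse error naming the line.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT lines need name, description and >=1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                log.warning("gene set %r (line %d): duplicate members deduplicated", name, lineno)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")
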
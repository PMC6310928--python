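"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices and clinical tables are plain TSV; gene-set collections
use the Broad GMT dialect (set name, description, then member genes, all
tab-separated, one set per line).  Expression values are assumed to arrive
already log-scaled and preprocessed; no normalization happens on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale gene-by-sample expression.

    ``data`` is a genes x samples DataFrame; gene and sample identifiers are
    unique and every value is finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        return cls(name=name, genes=frozenset(genes), description=description)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered list of gene sets with unique names."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            seen, dups = set(), []
            for n in names:
                if n in seen:
                    dups.append(n)
                seen.add(n)
            raise ValueError(f"duplicate gene-set names: {dups[:5]}")

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        return cls(sets=tuple(sets))

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival records: time-to-event and a 0/1 event indicator.

    ``endpoint`` is an optional tag naming what the time measures (OS, DFS,
    MFS); it is carried through but never interpreted.
    """

    data: pd.DataFrame = field(repr=False)
    endpoint: str | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival times")
        bad = ~self.data["event"].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"event indicator outside {{0,1}} for samples "
                f"{self.data.loc[bad, 'sample_id'].tolist()[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV.

    First column holds gene ids, the header row holds sample ids.  Duplicate
    gene rows are collapsed to the row with the highest mean expression (a
    warning reports how many were dropped).  Any non-numeric cell is an
    error naming the offending row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = samples  # undo pandas' mangling of any odd header names
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() | df.isna()
    if bad.to_numpy().any():
        gene_idx, col_idx = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[gene_idx]!r}, "
            f"sample {df.columns[col_idx]!r}"
        )
    if numeric.index.has_duplicates:
        n_before = len(numeric)
        means = numeric.mean(axis=1)
        # keep, per gene id, the row with the highest mean expression
        order = np.argsort(-means.to_numpy(), kind="stable")
        ranked = numeric.iloc[order]
        deduped = ranked[~ranked.index.duplicated(keep="first")]
        # restore original first-occurrence order of gene ids
        first_order = numeric.index.drop_duplicates()
        numeric = deduped.loc[first_order]
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept max-mean row per gene)",
            path,
            n_before - len(numeric),
        )
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into an ordered gene-set collection.

    Each line: set name, description, then one or more genes, tab-separated.
    Duplicate genes within a line are deduplicated silently (set semantics);
    duplicate set names are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet.from_genes(name, genes, description))
    if not sets:
        logger.warning("%s: empty GMT file, returning empty collection", path)
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


def read_clinical(path: str | Path, endpoint: str | None = None) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time, event.

    Rows with a missing time or event are dropped with a logged count; an
    event value outside {0, 1} is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    n_before = len(df)
    df = df.dropna(subset=["time", "event"]).copy()
    if len(df) < n_before:
        logger.warning("%s: dropped %d rows with missing time/event", path, n_before - len(df))
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return ClinicalTable(df.reset_index(drop=True), endpoint=endpoint)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index=False)
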
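"""Count tables, taxonomy lineages, sample metadata and normalisations.

The central container is :class:`TaxonCountTable`, a thin wrapper around a
dense ``pandas.DataFrame`` of non-negative integer counts with samples as
rows and taxa as columns.  All on-disk formats are plain tab-separated text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("species", "genus", "class", "phylum")

LIBRARY_LEVELS = ("Seq", "PCR/Seq", "Ext/PCR/Seq")
SAMPLE_TYPES = ("soil", "mock", "ext_control", "pcr_control")


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class TaxonCountTable:
    """Samples x taxa table of non-negative integer counts.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id with taxon ids as columns.
    rank :
        Taxonomic rank of the columns, one of ``species``, ``genus``,
        ``class``, ``phylum``.
    """

    data: pd.DataFrame
    rank: str = "species"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {RANKS}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate taxon ids: {dups}")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableFormatError("counts must be numeric")
        if (arr < 0).any():
            raise TableFormatError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise TableFormatError("counts must be integers")
        self.data = self.data.astype(np.int64)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts (row sums)."""
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonCountTable":
        return TaxonCountTable(self.data.loc[list(sample_ids)].copy(), rank=self.rank)


@dataclass
class AbundanceTable:
    """Samples x taxa table of non-negative real values.

    ``kind`` records the normalisation applied: ``relative`` (rows sum to 1),
    ``cpm`` (rows sum to 1e6) or ``hellinger`` (squared rows sum to 1).
    """

    data: pd.DataFrame
    rank: str = "species"
    kind: str = "relative"
    warnings: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class TaxonomyLineage:
    """Maps species-level taxon ids to (genus, class, phylum) labels."""

    data: pd.DataFrame  # index taxon_id, columns genus, class, phylum

    def __post_init__(self) -> None:
        missing = [c for c in ("genus", "class", "phylum") if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"lineage missing columns: {missing}")
        if self.data.index.duplicated().any():
            raise TableFormatError("lineage has duplicate taxon ids (lineage must be a function)")

    def labels_at(self, rank: str) -> pd.Series:
        if rank not in ("genus", "class", "phylum"):
            raise ValueError(f"cannot aggregate to rank {rank!r}")
        return self.data[rank]


@dataclass
class SampleMetadata:
    """Per-sample design labels: run, library, site, plot, replicate, type."""

    data: pd.DataFrame  # index sample_id

    REQUIRED = ("run", "library", "site", "plot", "replicate", "sample_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"metadata missing columns: {missing}")
        if self.data.index.duplicated().any():
            raise TableFormatError("duplicate sample ids in metadata")
        bad = set(self.data["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise TableFormatError(f"unknown sample_type values: {sorted(bad)}")
        soil = self.data[self.data["sample_type"] == "soil"]
        key = soil[["run", "library", "site", "plot", "replicate"]]
        if key.duplicated().any():
            raise TableFormatError("(run, library, site, plot, replicate) must be unique per soil sample")

    def samples_of_type(self, sample_type: str) -> pd.Index:
        return self.data.index[self.data["sample_type"] == sample_type]

    def for_samples(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        return self.data.loc[list(sample_ids)]


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated text)
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    labels = header[1:]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise TableFormatError(f"{path.name}: duplicate labels in header: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_count_table(path: str | Path, dialect: str = "taxa_rows",
                     rank: str = "species") -> TaxonCountTable:
    """Read a TSV count table.

    ``dialect`` is ``taxa_rows`` (taxa in the first column, samples across;
    the default, matching classifier output) or ``samples_rows``.
    """
    if dialect not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise TableFormatError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    if dialect == "taxa_rows":
        body = body.T
    return TaxonCountTable(body, rank=rank)


def write_count_table(table: TaxonCountTable, path: str | Path,
                      dialect: str = "taxa_rows") -> None:
    df = table.data.T if dialect == "taxa_rows" else table.data
    df.to_csv(path, sep="\t", index_label="taxon_id" if dialect == "taxa_rows" else "sample_id")


def read_lineage(path: str | Path) -> TaxonomyLineage:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TaxonomyLineage(df)


def write_lineage(lineage: TaxonomyLineage, path: str | Path) -> None:
    lineage.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_emu_relative_abundance(path: str | Path,
                                sample_reads: Mapping[str, int]) -> TaxonCountTable:
    """Read a merged classifier-style relative-abundance TSV as pseudo-counts.

    Relative abundances are multiplied by the supplied per-sample read count
    and rounded to the nearest integer.  This is lossy: rounded pseudo-counts
    do not exactly recover the original read assignments.
    """
    df = _read_tsv(path).T  # taxa rows on disk
    missing = sorted(set(df.index) - set(sample_reads))
    if missing:
        raise TableFormatError(f"no read count supplied for samples: {missing}")
    counts = df.mul(pd.Series(sample_reads), axis=0).round()
    return TaxonCountTable(counts, rank="species")


# ---------------------------------------------------------------------------
# Aggregation, pooling and normalisation
# ---------------------------------------------------------------------------

def aggregate_to_rank(table: TaxonCountTable, lineage: TaxonomyLineage,
                      rank: str) -> TaxonCountTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Row sums are preserved exactly (integer arithmetic).
    """
    if rank == table.rank:
        return table
    if RANKS.index(rank) <= RANKS.index(table.rank):
        raise ValueError(f"cannot aggregate {table.rank} table to finer rank {rank}")
    if table.rank == "species":
        orphans = sorted(set(table.taxon_ids) - set(lineage.data.index))
        if orphans:
            raise TableFormatError(f"taxa missing from lineage: {orphans}")
        labels = lineage.labels_at(rank).loc[table.taxon_ids]
    else:
        # parent map derived from the species-level lineage (child -> parent)
        pairs = lineage.data[[table.rank, rank]].drop_duplicates()
        if pairs[table.rank].duplicated().any():
            bad = sorted(pairs.loc[pairs[table.rank].duplicated(), table.rank])
            raise TableFormatError(f"lineage is not a function at {table.rank}: {bad}")
        parent = pairs.set_index(table.rank)[rank]
        orphans = sorted(set(table.taxon_ids) - set(parent.index))
        if orphans:
            raise TableFormatError(f"taxa missing from lineage: {orphans}")
        labels = parent.loc[table.taxon_ids]
    agg = table.data.T.groupby(labels.values).sum().T
    agg.columns = [str(c) for c in agg.columns]
    return TaxonCountTable(agg, rank=rank)


def pool_tables(tables: Sequence[TaxonCountTable]) -> TaxonCountTable:
    """Pool per-run tables into one, zero-filling on the union of taxa."""
    if not tables:
        raise ValueError("no tables to pool")
    rank = tables[0].rank
    if any(t.rank != rank for t in tables):
        raise ValueError("cannot pool tables at different ranks")
    pooled = pd.concat([t.data for t in tables], axis=0).fillna(0)
    return TaxonCountTable(pooled, rank=rank)


def to_relative_abundance(table: TaxonCountTable | AbundanceTable) -> AbundanceTable:
    """Divide each row by its row sum; zero-sum rows stay zero with a warning."""
    df = table.data.astype(float)
    sums = df.sum(axis=1)
    zero = sums == 0
    notes = []
    if zero.any():
        names = list(df.index[zero])
        notes.append(f"zero-sum samples left as zeros: {names}")
        warnings.warn(notes[-1])
        sums = sums.replace(0, 1)
    rel = df.div(sums, axis=0)
    return AbundanceTable(rel, rank=table.rank, kind="relative", warnings=notes)


def cpm_normalize(table: TaxonCountTable) -> AbundanceTable:
    """Counts-per-million: count / row_sum * 1e6.  Zero-sum rows are an error."""
    df = table.data.astype(float)
    sums = df.sum(axis=1)
    if (sums == 0).any():
        names = list(df.index[sums == 0])
        raise ValueError(f"cannot CPM-normalize zero-count samples: {names}")
    cpm = df.div(sums, axis=0) * 1e6
    return AbundanceTable(cpm, rank=table.rank, kind="cpm")
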
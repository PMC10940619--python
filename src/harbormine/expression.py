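"""Per-library gene read counts: loading, ranking, RPKM.

The selection of neutral loci ranks genes by raw mapped-read counts within
each library (depth differs between libraries, so no single count cutoff is
meaningful and only within-library ranks are compared); core-promoter
selection instead uses RPKM.  Ties are always broken lexicographically by
gene id so that every ranking is deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CountTableError

#: featureCounts emits these positional columns between Geneid and the
#: per-library count columns; all but Length are dropped on load.
_FEATURECOUNTS_META = ("Chr", "Start", "End", "Strand")
_GENE_ID_NAMES = ("Geneid", "gene_id", "GeneID", "gene", "id", "ID")
_LENGTH_NAMES = ("Length", "length", "length_bp", "gene_length")


@dataclass
class CountMatrix:
    """Nonnegative integer read counts, genes x libraries, plus gene lengths."""

    counts: pd.DataFrame  # index: gene_id, columns: library_id, dtype int64
    gene_length_bp: Optional[pd.Series] = None  # index: gene_id

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise CountTableError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise CountTableError("duplicate library ids in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise CountTableError("counts must be integers")
        if (arr < 0).any():
            raise CountTableError("counts must be nonnegative")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> List[str]:
        return list(self.counts.columns)

    def count(self, gene_id: str, library: str) -> int:
        return int(self.counts.at[gene_id, library])

    def library_total(self, library: str) -> int:
        return int(self.counts[library].sum())


@dataclass
class RankTable:
    """Genes of one library ordered from most to fewest reads (rank 1 = top)."""

    library_id: str
    ordered_gene_ids: List[str]
    rank: Dict[str, int]

    def __post_init__(self) -> None:
        assert sorted(self.rank.values()) == list(range(1, len(self.ordered_gene_ids) + 1))

    def to_frame(self, m: "CountMatrix") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.ordered_gene_ids,
                "count": [m.count(g, self.library_id) for g in self.ordered_gene_ids],
                "rank": range(1, len(self.ordered_gene_ids) + 1),
            }
        )


def load_counts(path) -> CountMatrix:
    """Load a featureCounts-style TSV into a :class:`CountMatrix`.

    Expects a gene-id column (``Geneid``/``gene_id``/first column), an
    optional ``Length`` column, and one numeric column per library.  Lines
    starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise CountTableError("count table needs a gene-id column and >=1 library column")
    id_col = next((c for c in _GENE_ID_NAMES if c in df.columns), None)
    if id_col is None:
        # fall back to the first column if it is non-numeric
        first = df.columns[0]
        if pd.api.types.is_numeric_dtype(df[first]):
            raise CountTableError("cannot locate a gene-id column")
        id_col = first
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df = df.drop(columns=[c for c in _FEATURECOUNTS_META if c in df.columns])
    length_col = next((c for c in _LENGTH_NAMES if c in df.columns), None)
    lengths = None
    if length_col is not None:
        lengths = df[length_col].astype(int)
        lengths.name = "length_bp"
        df = df.drop(columns=[length_col])
    if df.shape[1] == 0:
        raise CountTableError("no library columns found")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise CountTableError(f"library {col!r}: non-numeric cell")
        if ((vals % 1) != 0).any():
            raise CountTableError(f"library {col!r}: non-integer cell")
        if (vals < 0).any():
            raise CountTableError(f"library {col!r}: negative cell")
        df[col] = vals.astype(np.int64)
    return CountMatrix(counts=df, gene_length_bp=lengths)


def rank_genes(m: CountMatrix, library: str) -> RankTable:
    """Rank genes from most to fewest reads in one library.

    Descending by count, ties broken by gene id ascending; the result is
    invariant to the row order of the input matrix.
    """
    if library not in m.counts.columns:
        raise KeyError(f"unknown library {library!r}")
    col = m.counts[library]
    order = sorted(col.index, key=lambda g: (-int(col[g]), g))
    return RankTable(
        library_id=library,
        ordered_gene_ids=order,
        rank={g: i + 1 for i, g in enumerate(order)},
    )


def compute_rpkm(m: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, genes x libraries.

    ``rpkm[g, l] = counts[g, l] / ((length[g] / 1e3) * (total[l] / 1e6))``
    with ``total[l]`` the column sum over genes in the matrix.
    """
    if m.gene_length_bp is None:
        raise CountTableError("RPKM requires gene lengths")
    lengths = m.gene_length_bp.reindex(m.counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:3])
        raise CountTableError(f"missing gene length for {missing}")
    if (lengths < 1).any():
        raise CountTableError("gene lengths must be >= 1 bp")
    totals = m.counts.sum(axis=0)
    zero = [c for c in totals.index if totals[c] == 0]
    if zero:
        raise CountTableError(f"library total is zero for {zero}; RPKM undefined")
    kb = lengths.to_numpy(dtype=float) / 1e3
    per_million = totals.to_numpy(dtype=float) / 1e6
    vals = m.counts.to_numpy(dtype=float) / np.outer(kb, per_million)
    return pd.DataFrame(vals, index=m.counts.index, columns=m.counts.columns)


def write_rank_table(rt: RankTable, m: CountMatrix, handle) -> None:
    """Write a RankTable as TSV (gene_id, count, rank)."""
    rt.to_frame(m).to_csv(handle, sep="\t", index=False)


def counts_from_arrays(
    gene_ids: Sequence[str],
    library_ids: Sequence[str],
    counts,
    gene_length_bp: Optional[Mapping[str, int]] = None,
) -> CountMatrix:
    """Build a CountMatrix from in-memory arrays (used by the simulator)."""
    df = pd.DataFrame(
        np.asarray(counts, dtype=np.int64), index=list(gene_ids), columns=list(library_ids)
    )
    lengths = None
    if gene_length_bp is not None:
        lengths = pd.Series(gene_length_bp, name="length_bp").reindex(df.index).astype(int)
    return CountMatrix(counts=df, gene_length_bp=lengths)
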
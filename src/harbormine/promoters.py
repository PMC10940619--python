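"""Bidirectional-promoter mining and core-promoter extraction.

A divergent (head-to-head) pair is two adjacent genes whose start codons
point away from each other: the left gene on the minus strand, the right
gene on the plus strand.  The interval between them is shared upstream
sequence for both genes and is a candidate bidirectional promoter.
Adjacency reuses the gene-coverage sweep, so a third gene nested between
two genes blocks a pair — a promoter interval containing another gene is
not a clean bidirectional promoter.

"Highly expressed in most conditions" is operationalised as: a pair is
kept iff BOTH genes rank within the top ``q`` quantile of their library
(rank <= ceil(q * n_genes)) in at least ``min_libraries`` libraries,
counting only libraries where both genes pass together.  Both knobs are
configurable; the defaults are q = 0.10 and a strict majority of libraries.

Core promoters are the ``core_len`` (default 200) bases immediately
upstream of a gene's start codon, taken for the top ``top_n`` (default 8)
unique genes ranked by RPKM (raw counts optional) in a chosen library.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .errors import EmptyPromoterError, OutOfBoundsError
from .expression import CountMatrix, compute_rpkm, rank_genes
from .genome_model import (
    GeneRecord,
    GenomeAnnotation,
    GenomeSequence,
    upstream_window,
)
from .intergenic import _adjacent_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivergentPair:
    """Adjacent minus/plus gene pair with the shared upstream interval."""

    left_gene: GeneRecord   # strand '-'
    right_gene: GeneRecord  # strand '+'

    @property
    def chrom(self) -> str:
        return self.left_gene.chrom

    @property
    def promoter_start0(self) -> int:
        return self.left_gene.end0

    @property
    def promoter_end0(self) -> int:
        return self.right_gene.start0

    @property
    def length_bp(self) -> int:
        return self.promoter_end0 - self.promoter_start0

    @property
    def pair_id(self) -> str:
        return f"{self.left_gene.gene_id}|{self.right_gene.gene_id}"


@dataclass
class PromoterConfig:
    core_len: int = 200
    top_n: int = 8
    metric: str = "rpkm"  # or "raw_counts"
    expr_quantile: float = 0.10
    min_libraries: Optional[int] = None  # None -> strict majority

    def __post_init__(self) -> None:
        if self.core_len < 1 or self.top_n < 1:
            raise ValueError("core_len and top_n must be >= 1")
        if not (0 < self.expr_quantile <= 1):
            raise ValueError("expr_quantile must be in (0, 1]")
        if self.metric not in ("rpkm", "raw_counts"):
            raise ValueError("metric must be 'rpkm' or 'raw_counts'")

    def resolve_min_libraries(self, n_libraries: int) -> int:
        m = self.min_libraries if self.min_libraries is not None else n_libraries // 2 + 1
        if not (1 <= m <= n_libraries):
            raise ValueError(f"min_libraries must be in [1, {n_libraries}]")
        return m


def classify_adjacent_pairs(
    ann: GenomeAnnotation,
) -> Dict[str, List[Tuple[GeneRecord, GeneRecord]]]:
    """Partition all adjacent gene pairs into divergent/tandem/convergent.

    Divergent: left '-', right '+'.  Convergent: left '+', right '-'.
    Tandem: both on the same strand.
    """
    out: Dict[str, List[Tuple[GeneRecord, GeneRecord]]] = {
        "divergent": [],
        "tandem": [],
        "convergent": [],
    }
    for chrom in ann.chromosomes():
        for left, right in _adjacent_pairs(ann.genes_on(chrom)):
            if left.strand == right.strand:
                out["tandem"].append((left, right))
            elif left.strand == "-" and right.strand == "+":
                out["divergent"].append((left, right))
            else:
                out["convergent"].append((left, right))
    return out


def find_divergent_pairs(ann: GenomeAnnotation) -> List[DivergentPair]:
    """All adjacent head-to-head pairs, ordered by chromosome then coordinate."""
    return [
        DivergentPair(left_gene=left, right_gene=right)
        for left, right in classify_adjacent_pairs(ann)["divergent"]
    ]


def filter_pairs_by_expression(
    pairs: List[DivergentPair], m: CountMatrix, cfg: Optional[PromoterConfig] = None
) -> List[DivergentPair]:
    """Keep pairs whose two genes are jointly top-quantile in enough libraries."""
    cfg = cfg or PromoterConfig()
    libs = m.library_ids
    need = cfg.resolve_min_libraries(len(libs))
    n_genes = len(m.gene_ids)
    cutoff = max(1, math.ceil(cfg.expr_quantile * n_genes))
    ranks = {lib: rank_genes(m, lib).rank for lib in libs}
    kept = []
    for p in pairs:
        for gid in (p.left_gene.gene_id, p.right_gene.gene_id):
            if gid not in m.counts.index:
                raise KeyError(f"gene {gid!r} missing from count matrix")
        n_pass = sum(
            1
            for lib in libs
            if ranks[lib][p.left_gene.gene_id] <= cutoff
            and ranks[lib][p.right_gene.gene_id] <= cutoff
        )
        if n_pass >= need:
            kept.append(p)
    return kept


def extract_bidirectional_promoter(pair: DivergentPair, seq: GenomeSequence) -> Tuple[str, str]:
    """(record name, plus-strand promoter sequence) for a divergent pair.

    The reverse complement of the returned sequence is the same promoter as
    seen by the left (minus-strand) gene.
    """
    if pair.length_bp <= 0:
        raise EmptyPromoterError(
            f"pair {pair.pair_id}: genes abut; no promoter interval"
        )
    chrom_seq = seq[pair.chrom]
    if pair.promoter_end0 > len(chrom_seq):
        raise OutOfBoundsError(f"pair {pair.pair_id}: interval beyond {pair.chrom}")
    s = chrom_seq[pair.promoter_start0 : pair.promoter_end0]
    return pair.pair_id, s


def extract_core_promoters(
    ann: GenomeAnnotation,
    seq: GenomeSequence,
    m: CountMatrix,
    cfg: Optional[PromoterConfig] = None,
    library: Optional[str] = None,
) -> List[Tuple[str, str]]:
    """Core promoter windows for the top expressed genes of one library.

    Genes are ranked by RPKM (or raw counts) in ``library``; the first
    ``top_n`` unique genes with an in-bounds upstream window are emitted as
    (gene_id, sequence).  A gene whose window would cross a chromosome end
    is skipped with a warning and replaced by the next-ranked gene; if the
    ranking is exhausted first, the output is partial (with a warning).
    """
    cfg = cfg or PromoterConfig()
    if library is None:
        library = m.library_ids[0]
    if cfg.metric == "rpkm":
        col = compute_rpkm(m)[library]
        order = sorted(col.index, key=lambda g: (-float(col[g]), g))
    else:
        order = rank_genes(m, library).ordered_gene_ids
    genes = {g.gene_id: g for g in ann.genes}
    out: List[Tuple[str, str]] = []
    seen = set()
    for gid in order:
        if len(out) >= cfg.top_n:
            break
        if gid in seen or gid not in genes:
            continue
        seen.add(gid)
        try:
            window = upstream_window(genes[gid], cfg.core_len, seq)
        except OutOfBoundsError:
            logger.warning(
                "gene %s: %d bp upstream window out of bounds; taking next-ranked gene",
                gid, cfg.core_len,
            )
            continue
        out.append((gid, window))
    if len(out) < cfg.top_n:
        logger.warning(
            "only %d of %d requested core promoters could be extracted",
            len(out), cfg.top_n,
        )
    return out


def write_fasta(records: List[Tuple[str, str]], handle, width: int = 70) -> None:
    for name, s in records:
        handle.write(f">{name}\n")
        for i in range(0, len(s), width):
            handle.write(s[i : i + width] + "\n")
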
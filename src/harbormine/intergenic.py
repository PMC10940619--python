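"""Intergenic region extraction and flanking-expression scoring.

An intergenic region is a maximal interval not covered by any annotated
gene, bounded by a gene on each side.  Extraction is a running-maximum
sweep over the genes of a chromosome sorted by start: overlapping or nested
genes extend a single covered block, and a region is emitted only where
coverage truly breaks.  Terminal (telomere-side) gaps are not regions —
the downstream score needs two flanking genes.  Strand plays no role in
adjacency.

Each region is scored, per RNA-seq library, by the arithmetic mean of its
two flanking genes' read counts; constitutively high flanking expression is
the evidence that the locus is transcriptionally active yet dispensable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .expression import CountMatrix
from .genome_model import GenomeAnnotation, GeneRecord


@dataclass(frozen=True)
class IntergenicRegion:
    """A gap between adjacent gene spans (0-based half-open), with flanks."""

    chrom: str
    start0: int
    end0: int
    left_gene_id: str
    right_gene_id: str

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start0}-{self.end0}"

    @property
    def length_bp(self) -> int:
        return self.end0 - self.start0


@dataclass(frozen=True)
class RegionScore:
    region_id: str
    library_id: str
    score: float


def _adjacent_pairs(
    genes: List[GeneRecord],
) -> List[Tuple[GeneRecord, GeneRecord]]:
    """(left, right) gene pairs adjacent under the running-maximum sweep.

    ``genes`` must be sorted by (start0, end0, gene_id).  The left gene of a
    pair is the gene achieving the running maximum end (ties broken by gene
    id ascending); the right gene is the first gene starting at or after
    that maximum.  Gap length may be zero (abutting genes).
    """
    pairs: List[Tuple[GeneRecord, GeneRecord]] = []
    if not genes:
        return pairs
    cov_end = genes[0].end0
    left = genes[0]
    for g in genes[1:]:
        if g.start0 >= cov_end:
            pairs.append((left, g))
            cov_end = g.end0
            left = g
        else:
            if g.end0 > cov_end or (g.end0 == cov_end and g.gene_id < left.gene_id):
                cov_end = g.end0
                left = g
    return pairs


def extract_intergenic(ann: GenomeAnnotation) -> List[IntergenicRegion]:
    """All intergenic regions of the genome, in (chrom, start) order.

    A region is emitted wherever gene coverage breaks between two genes;
    zero-length breaks (abutting genes) produce no region, and the gaps
    before the first and after the last gene of a chromosome are excluded.
    """
    regions: List[IntergenicRegion] = []
    for chrom in ann.chromosomes():
        for left, right in _adjacent_pairs(ann.genes_on(chrom)):
            if right.start0 > left.end0:
                regions.append(
                    IntergenicRegion(
                        chrom=chrom,
                        start0=left.end0,
                        end0=right.start0,
                        left_gene_id=left.gene_id,
                        right_gene_id=right.gene_id,
                    )
                )
    return regions


def score_region(r: IntergenicRegion, m: CountMatrix, library: str) -> RegionScore:
    """Mean of the two flanking genes' read counts in one library."""
    for gid in (r.left_gene_id, r.right_gene_id):
        if gid not in m.counts.index:
            raise KeyError(f"flanking gene {gid!r} missing from count matrix")
    score = (m.count(r.left_gene_id, library) + m.count(r.right_gene_id, library)) / 2.0
    return RegionScore(region_id=r.region_id, library_id=library, score=score)


def score_table(
    regions: List[IntergenicRegion], m: CountMatrix, libraries: Optional[List[str]] = None
) -> pd.DataFrame:
    """Region x library matrix of mean flanking-gene counts."""
    libs = libraries if libraries is not None else m.library_ids
    rows = {}
    for r in regions:
        left = m.counts.loc[r.left_gene_id, libs].to_numpy(dtype=float)
        right = m.counts.loc[r.right_gene_id, libs].to_numpy(dtype=float)
        rows[r.region_id] = (left + right) / 2.0
    return pd.DataFrame.from_dict(rows, orient="index", columns=libs)


def write_bed(
    regions: List[IntergenicRegion],
    handle,
    scores: Optional[Dict[str, float]] = None,
) -> None:
    """BED6 output; the score column is clamped/scaled to 0-1000."""
    max_score = max(scores.values()) if scores else 0.0
    for r in regions:
        if scores and max_score > 0:
            bed_score = int(round(1000 * min(scores.get(r.region_id, 0.0), max_score) / max_score))
        else:
            bed_score = 0
        handle.write(
            f"{r.chrom}\t{r.start0}\t{r.end0}\t{r.region_id}\t{bed_score}\t.\n"
        )


def write_score_table(scores: List[RegionScore], handle) -> None:
    """Long-format TSV of per-region, per-library scores."""
    handle.write("region_id\tlibrary_id\tscore\n")
    for s in scores:
        handle.write(f"{s.region_id}\t{s.library_id}\t{s.score:g}\n")
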
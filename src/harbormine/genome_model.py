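"""Genome annotation and sequence primitives.

Gene models are read from GFF3 (1-based inclusive coordinates, as written)
and converted once, at the parser boundary, to 0-based half-open intervals;
every downstream module works in the half-open convention, which is native
for BED output and interval arithmetic.  The 1-based view remains available
through ``GeneRecord.start1`` / ``GeneRecord.end1``.

The "start codon" of a gene is approximated by the 5' end of its gene
feature (``start1`` on the plus strand, ``end1`` on the minus strand); CDS
sub-features are not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional

from Bio import SeqIO
from gffutils.feature import feature_from_line

from .errors import (
    AnnotationValidationError,
    GFF3ParseError,
    OutOfBoundsError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over A/C/G/T/N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GeneRecord:
    """A stranded gene span on one chromosome.

    Internally 0-based half-open (``start0``, ``end0``); the 1-based
    inclusive coordinates from the source GFF3 are exposed as ``start1`` /
    ``end1``.
    """

    chrom: str
    start0: int
    end0: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start0 < self.end0):
            raise AnnotationValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start0}, {self.end0})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def start1(self) -> int:
        return self.start0 + 1

    @property
    def end1(self) -> int:
        return self.end0

    @property
    def length_bp(self) -> int:
        return self.end0 - self.start0

    @property
    def five_prime_pos0(self) -> int:
        """0-based position of the approximated start codon's first base."""
        return self.start0 if self.strand == "+" else self.end0 - 1


@dataclass
class GenomeAnnotation:
    """A validated set of gene records plus chromosome lengths."""

    genes: List[GeneRecord]
    chrom_lengths: Dict[str, int]
    _by_chrom: Dict[str, List[GeneRecord]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_lengths:
                raise AnnotationValidationError(
                    f"gene {g.gene_id}: chromosome {g.chrom!r} has no recorded length"
                )
            if g.end0 > self.chrom_lengths[g.chrom]:
                raise AnnotationValidationError(
                    f"gene {g.gene_id}: end {g.end1} exceeds length of {g.chrom} "
                    f"({self.chrom_lengths[g.chrom]})"
                )
        self._by_chrom = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self._by_chrom:
            # stable, reproducible sort: by start, then end, then id
            self._by_chrom[chrom].sort(key=lambda g: (g.start0, g.end0, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def by_id(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def chromosomes(self) -> List[str]:
        return sorted(self.chrom_lengths)

    def genes_on(self, chrom: str) -> List[GeneRecord]:
        """Genes on a chromosome sorted by (start0, end0, gene_id)."""
        return list(self._by_chrom.get(chrom, []))

    def to_gff3(self, handle) -> None:
        """Serialize back to GFF3 (gene features only), preserving coordinates."""
        handle.write("##gff-version 3\n")
        for chrom in self.chromosomes():
            handle.write(f"##sequence-region {chrom} 1 {self.chrom_lengths[chrom]}\n")
        for chrom in self.chromosomes():
            for g in self.genes_on(chrom):
                handle.write(
                    f"{chrom}\tharbormine\tgene\t{g.start1}\t{g.end1}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )


class GenomeSequence:
    """Chromosome name -> nucleotide string (A/C/G/T/N, case preserved)."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = dict(seqs)

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, handle, width: int = 70) -> None:
        for chrom in sorted(self._seqs):
            handle.write(f">{chrom}\n")
            s = self._seqs[chrom]
            for i in range(0, len(s), width):
                handle.write(s[i : i + width] + "\n")

    def validate_against(self, ann: GenomeAnnotation) -> None:
        """Check sequence lengths agree with the annotation's chrom_lengths."""
        for chrom, L in ann.chrom_lengths.items():
            if chrom in self._seqs and len(self._seqs[chrom]) != L:
                raise AnnotationValidationError(
                    f"{chrom}: sequence length {len(self._seqs[chrom])} != "
                    f"annotated length {L}"
                )


def parse_gff3(
    path,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Parse gene features from a GFF3 file into a :class:`GenomeAnnotation`.

    Coordinates are taken as written (1-based inclusive) and converted to the
    internal 0-based half-open convention.  Chromosome lengths come from
    ``##sequence-region`` pragmas, from the ``chrom_lengths`` argument, or —
    as a last resort — from the maximum gene end per chromosome.

    Raises
    ------
    GFF3ParseError
        A data line is malformed (message includes the line number).
    AnnotationValidationError
        Duplicate gene IDs, or a gene extending past a declared chromosome
        length.
    """
    genes: List[GeneRecord] = []
    declared: Dict[str, int] = dict(chrom_lengths or {})
    seen_ids = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    declared.setdefault(parts[1], int(parts[3]))
                continue
            if line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GFF3ParseError(
                    f"line {lineno}: expected 9 tab-separated GFF3 columns, "
                    f"got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GFF3ParseError(f"line {lineno}: cannot parse GFF3 line: {exc}") from exc
            if feat.featuretype != feature_type:
                continue
            ids = feat.attributes.get(id_attribute, [])
            if not ids:
                raise GFF3ParseError(
                    f"line {lineno}: {feature_type} feature lacks {id_attribute!r} attribute"
                )
            gene_id = ids[0]
            if gene_id in seen_ids:
                raise AnnotationValidationError(
                    f"line {lineno}: duplicate gene_id {gene_id!r}"
                )
            seen_ids.add(gene_id)
            if feat.strand not in ("+", "-"):
                raise GFF3ParseError(
                    f"line {lineno}: gene {gene_id!r} has strand {feat.strand!r}; "
                    "expected '+' or '-'"
                )
            if feat.start < 1 or feat.end < feat.start:
                raise GFF3ParseError(
                    f"line {lineno}: invalid coordinates {feat.start}..{feat.end}"
                )
            genes.append(
                GeneRecord(
                    chrom=feat.seqid,
                    start0=feat.start - 1,
                    end0=feat.end,
                    gene_id=gene_id,
                    strand=feat.strand,
                )
            )
    if not declared:
        for g in genes:
            declared[g.chrom] = max(declared.get(g.chrom, 0), g.end0)
    else:
        for g in genes:
            declared.setdefault(g.chrom, g.end0)
            declared[g.chrom] = max(declared[g.chrom], declared[g.chrom])
    return GenomeAnnotation(genes=genes, chrom_lengths=declared)


def upstream_window(gene: GeneRecord, n: int, seq: GenomeSequence) -> str:
    """The ``n`` bases immediately upstream of a gene's start codon,
    oriented so the window reads 5'->3' toward the gene.

    For a plus-strand gene this is the genomic slice ``[start1-n, start1-1]``
    (1-based inclusive); for a minus-strand gene it is the reverse complement
    of ``[end1+1, end1+n]``.  A window that would run past either chromosome
    end raises :class:`OutOfBoundsError` — there is no silent truncation.
    """
    if n < 1:
        raise ValueError("window length must be >= 1")
    if gene.chrom not in seq:
        raise KeyError(f"chromosome {gene.chrom!r} not in sequence")
    chrom_seq = seq[gene.chrom]
    if gene.strand == "+":
        lo, hi = gene.start0 - n, gene.start0
        if lo < 0:
            raise OutOfBoundsError(
                f"gene {gene.gene_id}: {n} bp upstream window starts before {gene.chrom}"
            )
        return chrom_seq[lo:hi]
    lo, hi = gene.end0, gene.end0 + n
    if hi > len(chrom_seq):
        raise OutOfBoundsError(
            f"gene {gene.gene_id}: {n} bp upstream window runs past the end of {gene.chrom}"
        )
    return reverse_complement(chrom_seq[lo:hi])
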
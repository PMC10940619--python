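"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's sweep/sort code paths: intervals are
checked base by base, selections by full sorts and Python set operations.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np

from harbormine.genome_model import GenomeAnnotation


def per_base_intergenic(ann: GenomeAnnotation) -> List[Tuple[str, int, int, str, str]]:
    """Mark every base gene-covered or not; take maximal uncovered runs
    strictly between covered runs.  Returns (chrom, start0, end0, left, right).

    Left flank = among genes ending exactly at the run start, the one with
    the smallest gene_id; right flank = the gene starting at the run end
    (the first such by (end, id) order among genes at that start).
    """
    out = []
    for chrom in ann.chromosomes():
        genes = ann.genes_on(chrom)
        if not genes:
            continue
        L = ann.chrom_lengths[chrom]
        covered = np.zeros(L, dtype=bool)
        for g in genes:
            covered[g.start0 : g.end0] = True
        first_cov = int(np.argmax(covered))
        last_cov = L - 1 - int(np.argmax(covered[::-1]))
        i = first_cov
        while i <= last_cov:
            if not covered[i]:
                j = i
                while j <= last_cov and not covered[j]:
                    j += 1
                start0, end0 = i, j
                lefts = [g for g in genes if g.end0 == start0]
                # the sweep's left flank is the id-smallest gene achieving
                # the running maximum end
                left = min(lefts, key=lambda g: g.gene_id)
                rights = [g for g in genes if g.start0 == end0]
                right = min(rights, key=lambda g: (g.end0, g.gene_id))
                out.append((chrom, start0, end0, left.gene_id, right.gene_id))
                i = j
            else:
                i += 1
    return out


def brute_force_selection(
    scores: Dict[str, Dict[str, float]],
    lengths: Dict[str, int],
    k: int,
    min_length_bp: int,
) -> Set[str]:
    """Full-sort top-K per library, set intersection, strict length filter."""
    libs = sorted({lib for per in scores.values() for lib in per})
    per_lib_sets = []
    for lib in libs:
        ranked = sorted(scores, key=lambda r: (-scores[r][lib], r))
        per_lib_sets.append(set(ranked[:k]))
    consensus = set.intersection(*per_lib_sets) if per_lib_sets else set()
    return {r for r in consensus if lengths[r] > min_length_bp}


def brute_force_adjacent_pairs(ann: GenomeAnnotation) -> List[Tuple[str, str, str]]:
    """(left_id, right_id, class) for every adjacent pair, via the per-base
    coverage map.

    Coverage blocks are maximal covered runs, additionally split at any
    position not strictly interior to a gene where one gene ends and
    another starts (abutting genes are adjacent with a zero-length gap).
    The pair is (id-smallest gene ending the left block, (end,id)-smallest
    gene starting the right block).
    """
    pairs = []
    for chrom in ann.chromosomes():
        genes = ann.genes_on(chrom)
        if len(genes) < 2:
            continue
        L = ann.chrom_lengths[chrom]
        covered = np.zeros(L, dtype=bool)
        interior = np.zeros(L + 1, dtype=bool)
        for g in genes:
            covered[g.start0 : g.end0] = True
            interior[g.start0 + 1 : g.end0] = True
        blocks = []  # (start, end) of covered blocks after splitting
        in_block = False
        for i in range(L + 1):
            c = covered[i] if i < L else False
            if c and not in_block:
                block_start = i
                in_block = True
            elif in_block and (not c):
                blocks.append((block_start, i))
                in_block = False
            elif in_block and c and not interior[i] and any(
                g.end0 == i for g in genes
            ) and any(g.start0 == i for g in genes):
                blocks.append((block_start, i))
                block_start = i
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            lefts = [g for g in genes if g.end0 == e1]
            left = min(lefts, key=lambda g: g.gene_id)
            rights = [g for g in genes if g.start0 == s2]
            right = min(rights, key=lambda g: (g.end0, g.gene_id))
            if left.strand == right.strand:
                cls = "tandem"
            elif left.strand == "-" and right.strand == "+":
                cls = "divergent"
            else:
                cls = "convergent"
            pairs.append((left.gene_id, right.gene_id, cls))
    return pairs
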
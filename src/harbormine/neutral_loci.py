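"""Selection of candidate neutral ("safe-harbor") integration loci.

The funnel: score every intergenic region per library by mean flanking-gene
read count; keep the top-K regions of each library; intersect across all
libraries (a region must be top-K in *every* condition to count as flanked
by constitutive, highly expressed genes); finally keep only regions whose
length strictly exceeds a minimum (default 4800 bp), so a cassette can be
integrated far from either flanking gene.  Survivors are ranked by mean
per-library score.  The last manual step of picking a handful of loci
spread across chromosomes is deliberately not automated; the report carries
the chromosome so a user can reproduce that spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .expression import CountMatrix
from .genome_model import GenomeAnnotation
from .intergenic import IntergenicRegion, extract_intergenic, score_table

logger = logging.getLogger(__name__)

#: Default per-library cutoff and length filter.
DEFAULT_TOP_K = 500
DEFAULT_MIN_LENGTH_BP = 4800


@dataclass
class SelectionConfig:
    """Parameters of the selection funnel.

    ``min_length_bp`` is compared strictly: a region of exactly this length
    is excluded.
    """

    top_k: int = DEFAULT_TOP_K
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP
    libraries: Optional[List[str]] = None  # None -> all libraries in the matrix

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_length_bp < 0:
            raise ValueError("min_length_bp must be >= 0")


@dataclass
class NeutralLocusCandidate:
    """A region surviving every filter, with its scores and final rank."""

    region: IntergenicRegion
    per_library_score: Dict[str, float]
    mean_score: float
    consensus_rank: int


@dataclass
class SelectionResult:
    """Candidates plus the per-stage survivor counts of the funnel."""

    candidates: List[NeutralLocusCandidate]
    funnel: Dict[str, int] = field(default_factory=dict)

    @property
    def region_ids(self) -> List[str]:
        return [c.region.region_id for c in self.candidates]

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "region_id": c.region.region_id,
                "chrom": c.region.chrom,
                "start0": c.region.start0,
                "end0": c.region.end0,
                "length_bp": c.region.length_bp,
                "left_gene_id": c.region.left_gene_id,
                "right_gene_id": c.region.right_gene_id,
            }
            for lib, s in c.per_library_score.items():
                row[f"score_{lib}"] = s
            row["mean_score"] = c.mean_score
            row["rank"] = c.consensus_rank
            rows.append(row)
        return pd.DataFrame(rows)


def top_regions_per_library(scores: pd.DataFrame, library: str, k: int) -> List[str]:
    """Region ids of the top-``k`` regions of one library.

    Sorted descending by score, ties broken by region id ascending; returns
    ``min(k, n_regions)`` ids.
    """
    col = scores[library]
    order = sorted(col.index, key=lambda r: (-float(col[r]), r))
    return order[:k]


def consensus_intersection(per_library: Dict[str, Iterable[str]]) -> List[str]:
    """Regions present in the top set of *every* library, sorted by id."""
    if not per_library:
        raise ValueError("need at least one library")
    sets = [set(v) for v in per_library.values()]
    out = set.intersection(*sets)
    return sorted(out)


def length_filter(
    region_ids: Iterable[str],
    regions_by_id: Dict[str, IntergenicRegion],
    min_length_bp: int,
) -> List[str]:
    """Keep regions strictly longer than ``min_length_bp`` bp."""
    return sorted(
        r for r in region_ids if regions_by_id[r].length_bp > min_length_bp
    )


def discover_neutral_loci(
    ann: GenomeAnnotation, m: CountMatrix, cfg: Optional[SelectionConfig] = None
) -> SelectionResult:
    """Run the full funnel and rank survivors by mean per-library score."""
    cfg = cfg or SelectionConfig()
    libs = cfg.libraries if cfg.libraries is not None else m.library_ids
    unknown = [l for l in libs if l not in m.library_ids]
    if unknown:
        raise KeyError(f"libraries not in count matrix: {unknown}")

    regions = extract_intergenic(ann)
    by_id = {r.region_id: r for r in regions}
    funnel = {"regions_extracted": len(regions)}
    logger.info("intergenic regions extracted: %d", len(regions))

    scores = score_table(regions, m, libraries=list(libs))
    funnel["regions_scored"] = len(scores)

    per_library = {
        lib: top_regions_per_library(scores, lib, cfg.top_k) for lib in libs
    }
    for lib in libs:
        logger.info("library %s: top %d regions retained", lib, len(per_library[lib]))
    funnel["top_k_per_library"] = min(len(v) for v in per_library.values())

    consensus = consensus_intersection(per_library)
    funnel["consensus"] = len(consensus)
    logger.info("regions in the top %d of all %d libraries: %d",
                cfg.top_k, len(libs), len(consensus))

    survivors = length_filter(consensus, by_id, cfg.min_length_bp)
    funnel["length_filtered"] = len(survivors)
    logger.info("regions longer than %d bp: %d", cfg.min_length_bp, len(survivors))

    ranked = sorted(
        survivors, key=lambda r: (-float(scores.loc[r].mean()), r)
    )
    candidates = [
        NeutralLocusCandidate(
            region=by_id[rid],
            per_library_score={lib: float(scores.at[rid, lib]) for lib in libs},
            mean_score=float(scores.loc[rid].mean()),
            consensus_rank=i + 1,
        )
        for i, rid in enumerate(ranked)
    ]
    return SelectionResult(candidates=candidates, funnel=funnel)
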
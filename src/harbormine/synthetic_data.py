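"""Synthetic genomes, annotations and RNA-seq count tables with planted truth.

The generator emulates the real inputs of the pipeline — a multi-chromosome
fungal annotation with stranded genes and intergenic gaps of controlled
length, plus per-library overdispersed read counts — at a scale where every
stage can be tested in seconds.  Truth is planted by construction:

* **planted neutral loci** — long gaps (strictly above the length filter)
  whose two flanking genes are "constitutive high": drawn from a high-mean
  negative binomial in *every* library;
* **planted divergent pairs** — adjacent minus/plus gene pairs whose genes
  are constitutive high, separated by a modest gap (the bidirectional
  promoter);
* **decoys**, each violating exactly one defining predicate of a neutral
  locus: ``high_flank_short_gap`` (constitutive flanks, gap below the
  length filter), ``long_gap_low_flank`` (long gap, background flanks) and
  ``high_in_some_libraries`` (long gap, flanks high only in a strict
  minority of libraries — non-constitutive expression).

Counts follow a negative binomial (gamma-Poisson) model with a per-library
sequencing-depth factor, emulating RNA-seq overdispersion.  All randomness
derives from a single seed; identical configs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import SimulationConfigError
from .expression import CountMatrix, counts_from_arrays
from .genome_model import GeneRecord, GenomeAnnotation, GenomeSequence
from .neutral_loci import SelectionConfig

CLASS_HIGH = "high"
CLASS_BACKGROUND = "background"
CLASS_SOME_LIBS = "some_libs"

DECOY_SHORT_GAP = "high_flank_short_gap"
DECOY_LOW_FLANK = "long_gap_low_flank"
DECOY_SOME_LIBS = "high_in_some_libraries"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults give 2 chromosomes x 200 genes, 6 libraries, 8 planted neutral
    loci, 4 planted divergent pairs and 3 decoys per decoy class.  A wider
    18-library profile (matching the number of real libraries the selection
    was designed around) is available via :func:`eighteen_library_profile`.
    """

    seed: int = 42
    n_chroms: int = 2
    genes_per_chrom: int = 200
    gene_length_range: Tuple[int, int] = (500, 3000)
    gap_length_range: Tuple[int, int] = (200, 2000)       # background gaps
    long_gap_range: Tuple[int, int] = (5000, 8000)        # above the length filter
    short_gap_range: Tuple[int, int] = (800, 2000)
    divergent_gap_range: Tuple[int, int] = (300, 1000)
    n_libraries: int = 6
    n_planted_neutral: int = 8
    n_planted_divergent: int = 4
    n_decoys_per_class: int = 3
    high_mean_range: Tuple[float, float] = (6000.0, 12000.0)
    background_mean_range: Tuple[float, float] = (5.0, 300.0)
    some_libs_fraction: float = 1 / 3   # fraction of libraries that are high (< 1/2)
    depth_factor_range: Tuple[float, float] = (0.6, 1.4)
    nb_dispersion: float = 10.0         # NB size parameter; smaller = noisier
    selection_top_k: int = 50           # region top-K matched to this genome scale
    min_length_bp: int = 4800

    def selection_config(self, libraries: Optional[List[str]] = None) -> SelectionConfig:
        """The selection funnel scaled to this genome (top-K ~ 1/8 of regions)."""
        return SelectionConfig(
            top_k=self.selection_top_k,
            min_length_bp=self.min_length_bp,
            libraries=libraries,
        )

    @property
    def library_ids(self) -> List[str]:
        return [f"lib{i + 1:02d}" for i in range(self.n_libraries)]


def eighteen_library_profile(seed: int = 42) -> SimulationConfig:
    """A fidelity profile with 18 libraries, as in the real RNA-seq design."""
    return SimulationConfig(seed=seed, n_libraries=18)


@dataclass
class TruthTable:
    """Planted features, keyed the same way the pipeline keys its output."""

    planted_neutral: List[str] = field(default_factory=list)       # region ids
    planted_divergent: List[str] = field(default_factory=list)     # "left|right"
    decoys: Dict[str, str] = field(default_factory=dict)           # region id -> class
    gene_class: Dict[str, str] = field(default_factory=dict)       # gene id -> class
    high_library_idx: Dict[str, List[int]] = field(default_factory=dict)

    def to_tsv(self, handle) -> None:
        handle.write("id\tkind\tlabel\n")
        for rid in self.planted_neutral:
            handle.write(f"{rid}\tplanted_neutral\t.\n")
        for pid in self.planted_divergent:
            handle.write(f"{pid}\tplanted_divergent\t.\n")
        for rid, label in sorted(self.decoys.items()):
            handle.write(f"{rid}\tdecoy\t{label}\n")


# ----------------------------------------------------------------- genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _pick_special_slots(
    rng: np.random.Generator, n_slots: int, n_needed: int
) -> List[int]:
    """Slot indices at pairwise distance >= 3.

    Distance >= 2 would already keep flanking genes disjoint; >= 3 also
    guarantees that the forced-strand genes of two different planted
    features are never adjacent to each other, so no unplanned
    head-to-head pair of constitutive-high genes can arise.
    """
    chosen: List[int] = []
    candidates = set(range(n_slots))
    for _ in range(n_needed):
        if not candidates:
            raise SimulationConfigError(
                "not enough intergenic slots for the requested planted features; "
                "increase genes_per_chrom or reduce the planted counts"
            )
        pick = int(rng.choice(sorted(candidates)))
        chosen.append(pick)
        candidates -= {pick - 2, pick - 1, pick, pick + 1, pick + 2}
    return sorted(chosen)


def simulate_genome(
    cfg: SimulationConfig,
) -> Tuple[GenomeAnnotation, GenomeSequence, TruthTable]:
    """Build the annotation, the random sequence, and the truth table.

    All planted neutral gaps strictly exceed ``cfg.min_length_bp``; planted
    divergent pairs are adjacent minus/plus genes.  Deterministic in
    ``cfg.seed``.
    """
    if cfg.long_gap_range[0] <= cfg.min_length_bp:
        raise SimulationConfigError(
            "long_gap_range must lie strictly above min_length_bp so planted "
            "loci satisfy the length filter by construction"
        )
    rng = np.random.default_rng([cfg.seed, 0])
    # one entry per planted feature, spread round-robin over chromosomes
    specials = (
        ["neutral"] * cfg.n_planted_neutral
        + ["divergent"] * cfg.n_planted_divergent
        + [DECOY_SHORT_GAP] * cfg.n_decoys_per_class
        + [DECOY_LOW_FLANK] * cfg.n_decoys_per_class
        + [DECOY_SOME_LIBS] * cfg.n_decoys_per_class
    )
    rng.shuffle(specials)
    per_chrom: List[List[str]] = [[] for _ in range(cfg.n_chroms)]
    for i, kind in enumerate(specials):
        per_chrom[i % cfg.n_chroms].append(kind)

    genes: List[GeneRecord] = []
    chrom_lengths: Dict[str, int] = {}
    truth = TruthTable()
    seqs: Dict[str, str] = {}

    n_some_high = max(1, int(round(cfg.n_libraries * cfg.some_libs_fraction)))
    if n_some_high * 2 >= cfg.n_libraries and cfg.n_libraries > 1:
        n_some_high = (cfg.n_libraries - 1) // 2  # enforce strict minority
    n_some_high = max(1, n_some_high)

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n_genes = cfg.genes_per_chrom
        n_slots = n_genes - 1
        slot_kind: Dict[int, str] = {}
        slots = _pick_special_slots(rng, n_slots, len(per_chrom[ci]))
        for slot, kind in zip(slots, per_chrom[ci]):
            slot_kind[slot] = kind

        # forced strands for the two genes flanking a special slot: kept
        # convergent (+,-) except for planted divergent pairs (-,+), so no
        # unplanned head-to-head pair involves constitutive-high genes
        forced_strand: Dict[int, str] = {}
        for slot, kind in slot_kind.items():
            if kind == "divergent":
                forced_strand[slot], forced_strand[slot + 1] = "-", "+"
            else:
                forced_strand[slot], forced_strand[slot + 1] = "+", "-"

        pos = int(rng.integers(*cfg.gap_length_range, endpoint=True))
        for gi in range(n_genes):
            glen = int(rng.integers(*cfg.gene_length_range, endpoint=True))
            strand = forced_strand.get(
                gi, "+" if rng.random() < 0.5 else "-"
            )
            gene_id = f"{chrom}_g{gi + 1:04d}"
            gene = GeneRecord(
                chrom=chrom, start0=pos, end0=pos + glen, gene_id=gene_id, strand=strand
            )
            genes.append(gene)
            truth.gene_class[gene_id] = CLASS_BACKGROUND
            pos += glen
            if gi < n_slots:
                kind = slot_kind.get(gi)
                if kind == "neutral" or kind == DECOY_LOW_FLANK or kind == DECOY_SOME_LIBS:
                    gap = int(rng.integers(*cfg.long_gap_range, endpoint=True))
                elif kind == DECOY_SHORT_GAP:
                    gap = int(rng.integers(*cfg.short_gap_range, endpoint=True))
                elif kind == "divergent":
                    gap = int(rng.integers(*cfg.divergent_gap_range, endpoint=True))
                else:
                    gap = int(rng.integers(*cfg.gap_length_range, endpoint=True))
                pos += gap
        chrom_len = pos + int(rng.integers(*cfg.gap_length_range, endpoint=True))
        chrom_lengths[chrom] = chrom_len
        seqs[chrom] = _random_sequence(rng, chrom_len)

        # second pass over this chromosome's slots to register truth entries
        chrom_genes = [g for g in genes if g.chrom == chrom]
        for slot, kind in sorted(slot_kind.items()):
            left, right = chrom_genes[slot], chrom_genes[slot + 1]
            region_id = f"{chrom}:{left.end0}-{right.start0}"
            if kind == "neutral":
                truth.planted_neutral.append(region_id)
                truth.gene_class[left.gene_id] = CLASS_HIGH
                truth.gene_class[right.gene_id] = CLASS_HIGH
            elif kind == "divergent":
                truth.planted_divergent.append(f"{left.gene_id}|{right.gene_id}")
                truth.gene_class[left.gene_id] = CLASS_HIGH
                truth.gene_class[right.gene_id] = CLASS_HIGH
            elif kind == DECOY_SHORT_GAP:
                truth.decoys[region_id] = DECOY_SHORT_GAP
                truth.gene_class[left.gene_id] = CLASS_HIGH
                truth.gene_class[right.gene_id] = CLASS_HIGH
            elif kind == DECOY_LOW_FLANK:
                truth.decoys[region_id] = DECOY_LOW_FLANK
            elif kind == DECOY_SOME_LIBS:
                truth.decoys[region_id] = DECOY_SOME_LIBS
                libs = sorted(
                    int(x)
                    for x in rng.choice(cfg.n_libraries, size=n_some_high, replace=False)
                )
                for g in (left, right):
                    truth.gene_class[g.gene_id] = CLASS_SOME_LIBS
                    truth.high_library_idx[g.gene_id] = libs

    ann = GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)
    return ann, GenomeSequence(seqs), truth


# ----------------------------------------------------------------- counts

def simulate_counts(
    ann: GenomeAnnotation, truth: TruthTable, cfg: SimulationConfig
) -> CountMatrix:
    """Negative-binomial read counts per gene per library.

    Constitutive-high genes draw from a high-mean NB in every library;
    background genes from a low-mean NB; ``some_libs`` genes are high only
    in their assigned minority of libraries.  Each library has its own
    depth factor.  Deterministic in ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    gene_ids = [g.gene_id for g in ann.genes]
    lengths = {g.gene_id: g.length_bp for g in ann.genes}
    depth = rng.uniform(*cfg.depth_factor_range, size=cfg.n_libraries)
    base_mean = np.empty(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        cls = truth.gene_class.get(gid, CLASS_BACKGROUND)
        if cls == CLASS_BACKGROUND:
            base_mean[i] = rng.uniform(*cfg.background_mean_range)
        else:  # high and some_libs share the high-mean scale
            base_mean[i] = rng.uniform(*cfg.high_mean_range)
    low_mean = {
        gid: rng.uniform(*cfg.background_mean_range)
        for gid in gene_ids
        if truth.gene_class.get(gid) == CLASS_SOME_LIBS
    }

    r = cfg.nb_dispersion
    counts = np.zeros((len(gene_ids), cfg.n_libraries), dtype=np.int64)
    for li in range(cfg.n_libraries):
        means = base_mean * depth[li]
        for i, gid in enumerate(gene_ids):
            if truth.gene_class.get(gid) == CLASS_SOME_LIBS:
                if li not in truth.high_library_idx[gid]:
                    means[i] = low_mean[gid] * depth[li]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(means > 0, r / (r + means), 1.0)
        counts[:, li] = rng.negative_binomial(r, p)
    return counts_from_arrays(gene_ids, cfg.library_ids, counts, gene_length_bp=lengths)


# ----------------------------------------------------------------- dataset

@dataclass
class SyntheticDataset:
    annotation: GenomeAnnotation
    sequence: GenomeSequence
    counts: CountMatrix
    truth: TruthTable
    config: SimulationConfig


def simulate_dataset(cfg: Optional[SimulationConfig] = None) -> SyntheticDataset:
    """Genome + counts + truth in one call (in-memory)."""
    cfg = cfg or SimulationConfig()
    ann, seq, truth = simulate_genome(cfg)
    counts = simulate_counts(ann, truth, cfg)
    return SyntheticDataset(ann, seq, counts, truth, cfg)


def write_dataset(cfg: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Emit genome.fa, genes.gff3, counts.tsv and truth.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        ds.sequence.to_fasta(fh)
    with open(paths["gff3"], "w") as fh:
        ds.annotation.to_gff3(fh)
    with open(paths["counts"], "w") as fh:
        df = ds.counts.counts.copy()
        df.insert(0, "Length", [ds.counts.gene_length_bp[g] for g in df.index])
        df.index.name = "Geneid"
        df.to_csv(fh, sep="\t")
    with open(paths["truth"], "w") as fh:
        ds.truth.to_tsv(fh)
    return paths


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping of field overrides."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - valid
    if unknown:
        raise SimulationConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in (
        "gene_length_range", "gap_length_range", "long_gap_range",
        "short_gap_range", "divergent_gap_range", "high_mean_range",
        "background_mean_range", "depth_factor_range",
    ):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)
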
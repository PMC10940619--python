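# harbormine

Computational discovery of **neutral, highly transcribed integration loci**
("genomic safe harbors"), **bidirectional and core promoters** in a fungal
genome, and string-level simulation of **direct-repeat marker-recycling
donor templates** for CRISPR/HDR engineering.

## Who this is for

Strain engineers working in filamentous fungi (e.g. *Aspergillus oryzae*)
need genomic sites where a transgene can be integrated and strongly
expressed without disrupting host genes, promoters to drive it, and donor
constructs whose selection marker can be excised and reused. `harbormine`
implements the computational side of that workflow from two standard
inputs: a GFF3 gene annotation (plus genome FASTA) and featureCounts-style
per-library RNA-seq read-count tables.

## The methods

**Neutral loci.** Every intergenic region — a maximal interval not covered
by any annotated gene, found by a running-maximum coverage sweep — is
scored per library by the arithmetic mean of its two flanking genes' read
counts, `s(r, l) = (c_left,l + c_right,l) / 2`. Because library depth
varies, no absolute cutoff is used; instead the top *K* regions of each
library (default *K* = 500) are intersected across **all** libraries, so
survivors are flanked by *constitutively* highly expressed genes. A strict
length filter (default > 4800 bp) then keeps regions large enough to
integrate into far from either flanking gene. Survivors are ranked by mean
per-library score.

**Bidirectional promoters.** Adjacent gene pairs with the left gene on the
minus strand and the right gene on the plus strand (start codons pointing
apart) share their intergenic interval as upstream sequence. Pairs whose
two genes are both in the top expression quantile (default top 10 % of
ranked genes) in a majority of libraries are candidate endogenous
bidirectional promoters.

**Core promoters.** For the top *n* (default 8) unique genes ranked by
RPKM — `counts / (length/10³ · total/10⁶)` — the 200 bp immediately
upstream of the start codon is extracted strand-aware as a minimal core
promoter for synthetic expression systems.

**Marker recycling.** A fixing template is assembled as
`5′arm | payload | 300-bp repeat | pyrG marker | 3′arm`, where the repeat
duplicates the first 300 bp of the genomic 3′ flank. After exact-match HDR
integration the marker sits between two identical direct repeats;
intramolecular recombination under 5-FOA counter-selection excises the
marker plus one repeat copy, leaving the payload seamlessly in place. An
ectopic insertion without a flanking genomic repeat cannot loop out — the
simulator models this as an explicit error.

## Worked example

```bash
harbormine simulate --out-dir demo --seed 42
harbormine neutral-loci --gff demo/genes.gff3 --counts demo/counts.tsv \
    --top-k 50 --min-length 4800 --out-prefix demo/loci
```

The second command prints the selection funnel:

```
regions_extracted   398
regions_scored      398
top_k_per_library   50
consensus           44
length_filtered     8
```

398 intergenic regions were extracted from the simulated 2-chromosome,
400-gene annotation; 44 were in the top-50 of every one of the 6
libraries; 8 survived the > 4.8 kb length filter. `demo/loci.report.tsv`
ranks them by mean flanking expression:

```
region_id            chrom  start0  end0    length_bp  mean_score  rank
chr2:165279-170698   chr2   165279  170698  5419       12134.3     1
chr1:315923-323093   chr1   315923  323093  7170       11728.8     2
chr1:509280-515842   chr1   509280  515842  6562       11368.0     3
...
```

These 8 regions are exactly the loci the simulator planted (long gaps with
constitutive-high flanking genes); the 9 decoys — high flanks with a short
gap, long gaps with background flanks, and flanks high in only a minority
of libraries — are all rejected. Other subcommands: `bidirectional`,
`core-promoters`, `design-template`, `integrate-simulate` (see
`harbormine --help`).

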
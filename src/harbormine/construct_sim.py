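"""String-level simulation of direct-repeat marker-recycling donor design.

A fixing template targets a genomic locus for homology-directed repair
(HDR) and carries, in order:

    5' homology arm | payload | direct repeat | pyrG marker | 3' homology arm

The direct repeat duplicates the first ``repeat_len`` (default 300) bases
of the genomic 3' flank of the locus.  After correct on-target integration
the marker therefore sits between two identical copies of that sequence —
one from the template, one the native start of the 3' flank — and
counter-selection with 5-FOA selects recombinants that have looped the
marker out between the repeats, leaving the payload seamlessly inserted in
otherwise wild-type sequence.  Ectopic (NHEJ) integrations at a random
site lack a second genomic repeat copy and cannot loop out; 5-FOA kills
them, which is what makes the repeat locus-specific.

HDR here is an exact-match contract: a single mismatch between an arm and
the genome aborts integration.  Mismatch tolerance and repair biochemistry
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from .errors import IntegrationError, LoopOutImpossibleError, TemplateDesignError
from .genome_model import GenomeSequence

DEFAULT_REPEAT_LEN = 300
MIN_ARM_LEN = 25
MAX_ARM_LEN = 950


@dataclass(frozen=True)
class IntegrationLocus:
    """A target site: replace ``[del_start0, del_end0)`` on ``chrom``.

    A pure insertion is the degenerate case ``del_start0 == del_end0``
    (insertion between positions ``del_start0 - 1`` and ``del_start0``).
    """

    chrom: str
    del_start0: int
    del_end0: int

    def __post_init__(self) -> None:
        if not (0 <= self.del_start0 <= self.del_end0):
            raise ValueError("invalid locus interval")


@dataclass(frozen=True)
class FixingTemplate:
    """Ordered parts of a marker-recycling donor."""

    five_prime_arm: str
    payload: str
    repeat_seq: str
    marker: str
    three_prime_arm: str

    def __post_init__(self) -> None:
        for name in ("five_prime_arm", "repeat_seq", "marker", "three_prime_arm"):
            if not getattr(self, name):
                raise TemplateDesignError(f"{name} must be non-empty")

    @property
    def sequence(self) -> str:
        return (
            self.five_prime_arm
            + self.payload
            + self.repeat_seq
            + self.marker
            + self.three_prime_arm
        )

    def part_map(self) -> str:
        """Plain-text, GenBank-style coordinate map of the template parts."""
        lines = ["part\tstart1\tend1\tlength_bp"]
        pos = 0
        for name, part in (
            ("five_prime_arm", self.five_prime_arm),
            ("payload", self.payload),
            ("repeat", self.repeat_seq),
            ("marker", self.marker),
            ("three_prime_arm", self.three_prime_arm),
        ):
            if part:
                lines.append(f"{name}\t{pos + 1}\t{pos + len(part)}\t{len(part)}")
            pos += len(part)
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IntegratedChromosome:
    """A chromosome string after HDR, with tracked marker coordinates."""

    sequence: str
    marker_start0: int
    marker_end0: int


def design_fixing_template(
    seq: GenomeSequence,
    locus: IntegrationLocus,
    payload: str,
    marker: str,
    arm_len: int,
    repeat_len: int = DEFAULT_REPEAT_LEN,
    repeat_side: str = "three_prime",
) -> FixingTemplate:
    """Build the donor for a locus from its genomic flanks.

    The homology arms are the ``arm_len`` bases on either side of the
    replaced interval; the direct repeat duplicates the first
    ``repeat_len`` bases of the 3' flank (or, with
    ``repeat_side='five_prime'``, the last ``repeat_len`` bases of the 5'
    flank, in which case it is placed between marker and payload so the
    marker is still bracketed by the two copies).
    """
    chrom_seq = seq[locus.chrom]
    if locus.del_end0 > len(chrom_seq):
        raise TemplateDesignError("locus extends past the chromosome end")
    if locus.del_start0 - arm_len < 0:
        raise TemplateDesignError(
            f"5' flank shorter than arm length {arm_len}"
        )
    if locus.del_end0 + max(arm_len, repeat_len if repeat_side == "three_prime" else arm_len) > len(chrom_seq):
        raise TemplateDesignError(
            f"3' flank shorter than required {max(arm_len, repeat_len)} bp"
        )
    five_arm = chrom_seq[locus.del_start0 - arm_len : locus.del_start0]
    three_arm = chrom_seq[locus.del_end0 : locus.del_end0 + arm_len]
    if repeat_side == "three_prime":
        repeat = chrom_seq[locus.del_end0 : locus.del_end0 + repeat_len]
    elif repeat_side == "five_prime":
        if locus.del_start0 - repeat_len < 0:
            raise TemplateDesignError(f"5' flank shorter than repeat length {repeat_len}")
        repeat = chrom_seq[locus.del_start0 - repeat_len : locus.del_start0]
    else:
        raise ValueError("repeat_side must be 'three_prime' or 'five_prime'")
    return FixingTemplate(
        five_prime_arm=five_arm,
        payload=payload,
        repeat_seq=repeat,
        marker=marker,
        three_prime_arm=three_arm,
    )


def simulate_hdr_integration(
    seq: GenomeSequence, locus: IntegrationLocus, t: FixingTemplate
) -> IntegratedChromosome:
    """On-target HDR: replace the locus interval with payload|repeat|marker.

    Both arms must match the genome exactly at the locus; any mismatch
    raises :class:`IntegrationError` (a failed HDR event).
    """
    chrom_seq = seq[locus.chrom]
    arm5, arm3 = t.five_prime_arm, t.three_prime_arm
    if chrom_seq[locus.del_start0 - len(arm5) : locus.del_start0] != arm5:
        raise IntegrationError("5' homology arm does not match the genome at the locus")
    if chrom_seq[locus.del_end0 : locus.del_end0 + len(arm3)] != arm3:
        raise IntegrationError("3' homology arm does not match the genome at the locus")
    insert = t.payload + t.repeat_seq + t.marker
    new_seq = chrom_seq[: locus.del_start0] + insert + chrom_seq[locus.del_end0 :]
    marker_start = locus.del_start0 + len(t.payload) + len(t.repeat_seq)
    return IntegratedChromosome(
        sequence=new_seq,
        marker_start0=marker_start,
        marker_end0=marker_start + len(t.marker),
    )


def simulate_marker_loopout(
    chrom_with_insert: IntegratedChromosome,
    repeat_len_min: int = DEFAULT_REPEAT_LEN,
    max_offset: int = 10_000,
) -> str:
    """5-FOA-selected excision between identical direct repeats.

    Searches for the nearest pair of identical ``repeat_len_min``-mers
    flanking the marker (offsets scanned outward from the marker edges) and
    returns the chromosome after recombination deletes the marker plus one
    repeat copy.  If no such pair exists within ``max_offset`` bases the
    configuration cannot loop out — the modelled outcome of an ectopic
    integration under counter-selection — and
    :class:`LoopOutImpossibleError` is raised.
    """
    s = chrom_with_insert.sequence
    ms, me = chrom_with_insert.marker_start0, chrom_with_insert.marker_end0
    L = repeat_len_min
    if L < 1:
        raise ValueError("repeat_len_min must be >= 1")
    max_a = min(max_offset, ms - L)
    max_b = min(max_offset, len(s) - me - L)
    for d in range(0, max(max_a, 0) + max(max_b, 0) + 1):
        for a in range(0, d + 1):
            b = d - a
            if a > max_a or b > max_b or max_a < 0 or max_b < 0:
                continue
            up = s[ms - a - L : ms - a]
            down = s[me + b : me + b + L]
            if up == down:
                # crossover between the repeats removes [upstream copy, marker]
                return s[: ms - a - L] + s[me + b :]
    raise LoopOutImpossibleError(
        f"no identical direct repeats of >= {L} bp flank the marker; "
        "the strain cannot survive 5-FOA counter-selection"
    )
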
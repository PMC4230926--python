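"""Core domain records shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package (VCF
convention); BED input is converted at the I/O boundary.  Variant allele
frequencies (VAFs) are stored as percent in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_TIERS = frozenset({1, 2, 3})
BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset({"C", "T"})
PURINES = frozenset({"A", "G"})
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call in one sample.

    ``pos`` is the 1-based position of the reference allele's first base.
    ``tier`` follows the annotation tiering convention (1 = coding/splice/RNA,
    2 = conserved/regulatory, 3 = non-repetitive); ``None`` means unknown.
    ``transcript_aa_pos`` carries the amino-acid coordinate used by the
    proximity analysis when the variant is coding.
    """

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tier: int | None = None
    gene: str = ""
    transcript_aa_pos: int | None = None
    clone_id: str = ""  # ground-truth label, populated by the simulator

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.tier is not None and self.tier not in VALID_TIERS:
            raise ValueError(f"tier must be 1-3 or None, got {self.tier}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in BASES and self.alt in BASES

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.sample_id, self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class ReadcountEntry:
    """Per-sample sequencing depth and variant support at one mutation."""

    sample_id: str
    chrom: str
    pos: int
    alt: str
    depth: int
    var_reads: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive at {self.chrom}:{self.pos}, got {self.depth}")
        if not 0 <= self.var_reads <= self.depth:
            raise ValueError(
                f"var_reads {self.var_reads} outside [0, depth={self.depth}] at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele frequency in percent."""
        return 100.0 * self.var_reads / self.depth

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.sample_id, self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment, 1-based inclusive coordinates.

    ``cn_state`` is the segmented tumor copy number (2 = diploid/neutral);
    ``loh`` marks loss-of-heterozygosity segments, which are excluded from
    clonality analysis because allele loss distorts VAFs.
    """

    chrom: str
    start: int
    end: int
    cn_state: float
    loh: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad segment interval {self.chrom}:{self.start}-{self.end}")
        if self.cn_state <= 0:
            raise ValueError(f"cn_state must be positive, got {self.cn_state}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class HetSnpSite:
    """A germline heterozygous SNP with paired normal/tumor VAFs (percent)."""

    chrom: str
    pos: int
    normal_vaf: float
    tumor_vaf: float


@dataclass(frozen=True)
class ReadAlignmentStat:
    """Summary of one read's alignment to an SV contig or to the reference.

    ``unaligned_end_bases`` is the larger of the two unaligned end lengths;
    ``flank_left``/``flank_right`` count aligned bases on each side of the
    breakpoint (contig alignments only).
    """

    read_id: str
    sv_id: str
    target: str  # "contig" | "reference"
    unaligned_end_bases: int
    pct_substitutions: float
    pct_indels: float
    score: float
    spans_breakpoint: bool = False
    flank_left: int = 0
    flank_right: int = 0
    sample: str = "tumor"  # "tumor" | "normal"
    source: str = "capture"  # "capture" | "wgs"

    def __post_init__(self) -> None:
        if self.pct_substitutions < 0 or self.pct_indels < 0:
            raise ValueError("percent fields must be nonnegative")
        if self.flank_left < 0 or self.flank_right < 0:
            raise ValueError("flank lengths must be nonnegative")
        if self.target not in ("contig", "reference"):
            raise ValueError(f"target must be contig|reference, got {self.target}")


@dataclass
class StableRegionSet:
    """Copy-number-neutral, non-LOH regions retained for clonality analysis."""

    regions_by_cn: dict[float, list[CNSegment]] = field(default_factory=dict)
    excluded_chromosomes: dict[str, str] = field(default_factory=dict)  # chrom -> reason

    def covering_segment(self, chrom: str, pos: int) -> CNSegment | None:
        """Segment containing (chrom, pos), or None.

        Boundary positions resolve to the leftmost (lowest-start) covering
        segment.
        """
        hits = [
            seg
            for segs in self.regions_by_cn.values()
            for seg in segs
            if seg.contains(chrom, pos)
        ]
        if not hits:
            return None
        return min(hits, key=lambda s: (s.start, s.end))
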
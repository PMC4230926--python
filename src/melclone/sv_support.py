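"""Structural-variant validation from per-read realignment statistics.

Candidate SVs are validated by realigning capture reads to the assembled SV
contig and to the reference.  A read supports the SV when it aligns cleanly
to the contig across the breakpoint (with adequate flanking alignment on both
sides) and has no acceptable alignment to the reference.  Supporting reads
are tabulated in tumor and normal, a one-sided Fisher exact test calls the
somatic status, and any SV-supporting read in the normal whole-genome data
vetoes the call as germline or artifact.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .types import ReadAlignmentStat

MAX_UNALIGNED_END_BASES = 1
MAX_PCT_SUBSTITUTIONS = 1.0
MAX_PCT_INDELS = 1.0
MIN_SCORE = 50.0
MIN_FLANK = 10
DEFAULT_ALPHA = 0.05


@dataclass
class SVSupportResult:
    """Tabulated support and somatic verdict for one SV."""

    sv_id: str
    tumor_support: int
    tumor_total: int
    normal_support: int
    normal_total: int
    fisher_p: float
    verdict: str  # "somatic" | "germline_or_artifact" | "unsupported"


def acceptable_alignment(stat: ReadAlignmentStat) -> bool:
    """Alignment-quality gate: <=1 unaligned end base, <=1% substitutions,
    <=1% indels, score >= 50."""
    return (
        stat.unaligned_end_bases <= MAX_UNALIGNED_END_BASES
        and stat.pct_substitutions <= MAX_PCT_SUBSTITUTIONS
        and stat.pct_indels <= MAX_PCT_INDELS
        and stat.score >= MIN_SCORE
    )


def is_sv_supporting(
    contig_stat: ReadAlignmentStat, reference_stats: Sequence[ReadAlignmentStat] = ()
) -> bool:
    """True when the read supports the SV breakpoint.

    Requires an acceptable contig alignment that spans the breakpoint with at
    least 10 aligned bases of flank on each side, and no acceptable alignment
    of the same read to the reference.
    """
    if contig_stat.target != "contig":
        raise ValueError("contig_stat must target the SV contig")
    if not acceptable_alignment(contig_stat):
        return False
    if not contig_stat.spans_breakpoint:
        return False
    if contig_stat.flank_left < MIN_FLANK or contig_stat.flank_right < MIN_FLANK:
        return False
    return not any(acceptable_alignment(r) for r in reference_stats if r.target == "reference")


def tabulate_support(records: Iterable[ReadAlignmentStat]) -> dict[str, tuple[int, int]]:
    """Per-sample (supporting, total) read counts from mixed-target records.

    Reads are grouped by id; the total counts every read with a contig
    alignment evaluated against the SV.
    """
    by_read: dict[tuple[str, str], dict[str, list[ReadAlignmentStat]]] = defaultdict(
        lambda: {"contig": [], "reference": []}
    )
    for r in records:
        by_read[(r.sample, r.read_id)][r.target].append(r)
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for (sample, _), targets in by_read.items():
        if not targets["contig"]:
            continue
        counts[sample][1] += 1
        if any(is_sv_supporting(c, targets["reference"]) for c in targets["contig"]):
            counts[sample][0] += 1
    return {s: (c[0], c[1]) for s, c in counts.items()}


def somatic_sv_test(
    sv_id: str,
    capture_records: Iterable[ReadAlignmentStat],
    wgs_normal_records: Iterable[ReadAlignmentStat] = (),
    alpha: float = DEFAULT_ALPHA,
) -> SVSupportResult:
    """Fisher-based somatic status call for one SV.

    One-sided Fisher exact test (tumor-enriched) on the capture support
    table.  Verdicts: ``unsupported`` when the tumor has no supporting read;
    ``germline_or_artifact`` when the normal WGS data contains any
    SV-supporting read (regardless of p); ``somatic`` when p < alpha and the
    WGS veto does not fire.
    """
    counts = tabulate_support(capture_records)
    t_sup, t_tot = counts.get("tumor", (0, 0))
    n_sup, n_tot = counts.get("normal", (0, 0))
    if t_tot == 0 or n_tot == 0:
        raise ValueError(f"{sv_id}: no evaluated reads in tumor or normal capture data")
    _, p = stats.fisher_exact(
        [[t_sup, t_tot - t_sup], [n_sup, n_tot - n_sup]], alternative="greater"
    )
    wgs_counts = tabulate_support(wgs_normal_records)
    wgs_normal_support = wgs_counts.get("normal", (0, 0))[0]
    if t_sup == 0:
        verdict = "unsupported"
    elif wgs_normal_support > 0:
        verdict = "germline_or_artifact"
    elif p < alpha:
        verdict = "somatic"
    else:
        verdict = "germline_or_artifact"
    return SVSupportResult(
        sv_id=sv_id,
        tumor_support=t_sup,
        tumor_total=t_tot,
        normal_support=n_sup,
        normal_total=n_tot,
        fisher_p=float(p),
        verdict=verdict,
    )
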
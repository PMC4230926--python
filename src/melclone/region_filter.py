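"""Selection of "stable" genomic regions and deep-coverage mutation filtering.

Clonality inference needs VAFs that map cleanly onto cellular prevalence, so
the analysis is restricted to copy-number-neutral, non-LOH regions on
chromosomes whose germline heterozygous SNPs behave diploid in the tumor
(tumor VAF near 50%), and to mutations covered deeper than ``min_depth``
reads in both the tumor and the matched normal.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .types import CNSegment, HetSnpSite, MutationRecord, ReadcountEntry, StableRegionSet

# A het SNP qualifies as informative when the *normal* VAF is in this window.
NORMAL_HET_WINDOW = (40.0, 60.0)
# A tumor VAF "deviates" when more than this many points away from 50.
TUMOR_VAF_DEVIATION = 10.0
# Chromosome excluded when the deviating fraction exceeds this.
MAX_DEVIANT_FRACTION = 0.25

DEFAULT_MIN_DEPTH = 100


def build_stable_regions(
    segments: Sequence[CNSegment],
    het_snp_vafs: Sequence[HetSnpSite],
    normal_het_window: tuple[float, float] = NORMAL_HET_WINDOW,
    tumor_vaf_deviation: float = TUMOR_VAF_DEVIATION,
    max_deviant_fraction: float = MAX_DEVIANT_FRACTION,
) -> StableRegionSet:
    """Retain non-LOH segments on chromosomes with diploid-behaving het SNPs.

    Heterozygous-SNP evidence is restricted to sites whose normal VAF lies in
    ``normal_het_window`` (default 40-60%).  A chromosome is excluded with
    reason ``variable_vaf`` when more than ``max_deviant_fraction`` of its
    qualifying sites have tumor VAF deviating from 50 by more than
    ``tumor_vaf_deviation`` points, and with reason ``no_evidence`` when it
    has no qualifying site at all.  Retained segments are grouped by copy
    number state, sorted and non-overlap-checked per chromosome.
    """
    lo, hi = normal_het_window
    qualifying: dict[str, list[float]] = defaultdict(list)
    for site in het_snp_vafs:
        if lo <= site.normal_vaf <= hi:
            qualifying[site.chrom].append(site.tumor_vaf)

    chroms = {seg.chrom for seg in segments}
    excluded: dict[str, str] = {}
    for chrom in sorted(chroms):
        tumor_vafs = qualifying.get(chrom, [])
        if not tumor_vafs:
            excluded[chrom] = "no_evidence"
            continue
        deviant = sum(1 for v in tumor_vafs if abs(v - 50.0) > tumor_vaf_deviation)
        if deviant / len(tumor_vafs) > max_deviant_fraction:
            excluded[chrom] = "variable_vaf"

    by_cn: dict[float, list[CNSegment]] = defaultdict(list)
    for seg in segments:
        if seg.loh or seg.chrom in excluded:
            continue
        by_cn[seg.cn_state].append(seg)
    for cn, segs in by_cn.items():
        segs.sort(key=lambda s: (s.chrom, s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(f"overlapping segments on {a.chrom}: {a} / {b}")
    return StableRegionSet(regions_by_cn=dict(by_cn), excluded_chromosomes=excluded)


def filter_mutations(
    mutations: Sequence[MutationRecord],
    tumor_readcounts: Mapping[tuple[str, int], ReadcountEntry] | Iterable[ReadcountEntry],
    normal_readcounts: Mapping[tuple[str, int], ReadcountEntry] | Iterable[ReadcountEntry],
    regions: StableRegionSet,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[dict[float, list[MutationRecord]], dict[str, list[MutationRecord]]]:
    """Keep mutations covered > ``min_depth`` in tumor AND normal inside
    retained stable regions, grouped by the covering segment's copy number.

    Depth comparison is strict (``depth > min_depth``), mirroring the
    ">100x coverage" convention.  Returns ``(kept_by_cn, dropped_by_reason)``
    with reasons ``no_readcounts``, ``low_depth`` and ``outside_regions``.
    """
    t_idx = _index(tumor_readcounts)
    n_idx = _index(normal_readcounts)
    kept: dict[float, list[MutationRecord]] = defaultdict(list)
    dropped: dict[str, list[MutationRecord]] = defaultdict(list)
    for m in mutations:
        site = (m.chrom, m.pos)
        t = t_idx.get(site)
        n = n_idx.get(site)
        if t is None or n is None:
            dropped["no_readcounts"].append(m)
            continue
        if t.depth <= min_depth or n.depth <= min_depth:
            dropped["low_depth"].append(m)
            continue
        seg = regions.covering_segment(m.chrom, m.pos)
        if seg is None:
            dropped["outside_regions"].append(m)
            continue
        kept[seg.cn_state].append(m)
    return dict(kept), dict(dropped)


def _index(
    readcounts: Mapping[tuple[str, int], ReadcountEntry] | Iterable[ReadcountEntry],
) -> Mapping[tuple[str, int], ReadcountEntry]:
    if isinstance(readcounts, Mapping):
        return readcounts
    return {(e.chrom, e.pos): e for e in readcounts}
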
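"""Mutation-spectrum and UV dipyrimidine-context statistics.

UV damage crosslinks adjacent pyrimidines, so UV-driven C->T transitions fall
disproportionately at the 3' base of a pyrimidine dinucleotide — i.e. the base
5' of the mutated cytosine (read on the pyrimidine strand) is itself a C or T.
This module computes the six strand-collapsed substitution classes, merges
adjacent SNVs into dinucleotide mutations (CC->TT being the UV hallmark),
measures 5'/3' pyrimidine-context fractions for C->T mutations against a
reference-wide chance baseline, and dissects all of this per VAF cluster so a
UV founding clone can be told apart from a non-UV subclone within one tumor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import COMPLEMENT, MutationRecord, PYRIMIDINES

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class DNPCall:
    """Two adjacent same-sample SNVs merged into one dinucleotide mutation."""

    sample_id: str
    chrom: str
    pos: int  # first base, 1-based
    ref: str  # dinucleotide
    alt: str

    @property
    def is_CCtoTT(self) -> bool:
        """True for CC->TT (or its strand equivalent GG->AA)."""
        return (self.ref, self.alt) in {("CC", "TT"), ("GG", "AA")}


@dataclass
class SignatureSummary:
    """Substitution spectrum and dipyrimidine-context statistics.

    ``frac_prev_pyrimidine`` is the fraction of C->T mutations whose 5'
    neighbor (pyrimidine orientation) is C or T; ``frac_next_pyrimidine`` the
    3'-side analogue.  Baselines are the corresponding chance fractions over
    all C/G positions of the reference; p-values test the observed fraction
    against that baseline.  Fractions are ``None`` when no C->T context was
    available.
    """

    label: str
    class_counts: dict[str, int]
    n_CtoT: int
    frac_prev_pyrimidine: float | None
    frac_next_pyrimidine: float | None
    baseline_prev: float
    baseline_next: float
    p_prev: float | None
    p_next: float | None


def substitution_class(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution.

    Purine references are complemented so the mutated base reads C or T.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"substitution_class needs single-base SNV alleles, got {ref}>{alt}")
    if ref in PYRIMIDINES:
        cls = f"{ref}>{alt}"
    else:
        cls = f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
    if cls not in SUBSTITUTION_CLASSES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    return cls


def mutation_context(
    record: MutationRecord, reference: str | Mapping[str, str]
) -> tuple[str, str] | None:
    """5' and 3' neighbors of the mutated base in pyrimidine orientation.

    For a C or T reference allele the neighbors are read directly; for G or A
    the opposite strand carries the mutated pyrimidine, so the neighbors are
    the complements of the flanks, swapped.  Returns None when the position
    sits at a contig edge (context unavailable).
    """
    seq = reference[record.chrom] if isinstance(reference, Mapping) else reference
    i = record.pos - 1  # to 0-based
    if i - 1 < 0 or i + 1 >= len(seq):
        return None
    if not record.is_snv:
        raise ValueError("mutation_context is defined for SNVs only")
    left, right = seq[i - 1], seq[i + 1]
    if record.ref in PYRIMIDINES:
        return (left, right)
    return (COMPLEMENT[right], COMPLEMENT[left])


def detect_dinucleotide_mutations(
    mutations: Sequence[MutationRecord],
) -> tuple[list[DNPCall], list[MutationRecord]]:
    """Merge adjacent same-sample SNVs into dinucleotide calls.

    SNVs at (pos, pos+1) on one chromosome of one sample merge into a DNP and
    leave the SNV set; runs of three or more adjacent SNVs merge greedily
    left-to-right (pairs first, an odd remainder stays an SNV).
    """
    snvs = sorted(
        (m for m in mutations if m.is_snv), key=lambda m: (m.sample_id, m.chrom, m.pos)
    )
    non_snvs = [m for m in mutations if not m.is_snv]
    dnps: list[DNPCall] = []
    remaining: list[MutationRecord] = []
    i = 0
    while i < len(snvs):
        a = snvs[i]
        if (
            i + 1 < len(snvs)
            and snvs[i + 1].sample_id == a.sample_id
            and snvs[i + 1].chrom == a.chrom
            and snvs[i + 1].pos == a.pos + 1
        ):
            b = snvs[i + 1]
            dnps.append(
                DNPCall(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    pos=a.pos,
                    ref=a.ref + b.ref,
                    alt=a.alt + b.alt,
                )
            )
            i += 2
        else:
            remaining.append(a)
            i += 1
    return dnps, remaining + non_snvs


def context_fraction(
    mutations: Sequence[MutationRecord],
    reference: str | Mapping[str, str],
    side: str = "prev",
) -> tuple[int, int, float | None]:
    """Pyrimidine-context fraction among C>T mutations.

    Returns ``(k, n, k/n)`` where ``n`` counts C>T (including strand-collapsed
    G>A) mutations with available context and ``k`` those whose neighbor on
    ``side`` ("prev" = 5', "next" = 3') is a pyrimidine.  The fraction is
    None when no context is available.
    """
    if side not in ("prev", "next"):
        raise ValueError("side must be 'prev' or 'next'")
    k = n = 0
    for m in mutations:
        if not m.is_snv or substitution_class(m.ref, m.alt) != "C>T":
            continue
        ctx = mutation_context(m, reference)
        if ctx is None:
            continue
        n += 1
        neighbor = ctx[0] if side == "prev" else ctx[1]
        if neighbor in PYRIMIDINES:
            k += 1
    return k, n, (k / n if n else None)


def expected_context_fraction(reference: str | Mapping[str, str], side: str = "prev") -> float:
    """Chance pyrimidine-context fraction over all C/G reference positions.

    Every interior C contributes its literal neighbor; every interior G
    contributes the complemented opposite-strand neighbor (strand collapse).
    This is the "expected by chance" baseline the observed C->T context
    fractions are tested against.
    """
    if side not in ("prev", "next"):
        raise ValueError("side must be 'prev' or 'next'")
    seqs = reference.values() if isinstance(reference, Mapping) else [reference]
    k = n = 0
    for seq in seqs:
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        if arr.size < 3:
            continue
        base = arr[1:-1]
        prev_b, next_b = arr[:-2], arr[2:]
        is_c, is_g = base == b"C", base == b"G"
        pyr = lambda x: (x == b"C") | (x == b"T")
        pur = lambda x: (x == b"A") | (x == b"G")
        if side == "prev":
            hits = (is_c & pyr(prev_b)) | (is_g & pur(next_b))
        else:
            hits = (is_c & pyr(next_b)) | (is_g & pur(prev_b))
        n += int((is_c | is_g).sum())
        k += int(hits.sum())
    if n == 0:
        raise ValueError("reference contains no C/G positions with context")
    return k / n


def proportion_test(k: int, n: int, p0: float) -> float:
    """Two-sided one-sample proportion test of k/n against p0.

    Chi-square with Yates continuity correction (the conventional one-sample
    prop.test); falls back to the exact binomial test when the expected
    counts ``n*p0`` or ``n*(1-p0)`` drop below 5.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if n * p0 < 5 or n * (1 - p0) < 5:
        return float(stats.binomtest(k, n, p0).pvalue)
    dev = abs(k - n * p0)
    correction = min(0.5, dev)
    chi2 = (dev - correction) ** 2 / (n * p0 * (1 - p0))
    return float(stats.chi2.sf(chi2, df=1))


def summarize(
    mutations: Sequence[MutationRecord],
    reference: str | Mapping[str, str],
    label: str = "pooled",
) -> SignatureSummary:
    """Full signature summary (spectrum + context statistics) for one set."""
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    for m in mutations:
        if m.is_snv:
            counts[substitution_class(m.ref, m.alt)] += 1
    k_prev, n_prev, f_prev = context_fraction(mutations, reference, "prev")
    k_next, n_next, f_next = context_fraction(mutations, reference, "next")
    b_prev = expected_context_fraction(reference, "prev")
    b_next = expected_context_fraction(reference, "next")
    return SignatureSummary(
        label=label,
        class_counts=counts,
        n_CtoT=counts["C>T"],
        frac_prev_pyrimidine=f_prev,
        frac_next_pyrimidine=f_next,
        baseline_prev=b_prev,
        baseline_next=b_next,
        p_prev=proportion_test(k_prev, n_prev, b_prev) if n_prev else None,
        p_next=proportion_test(k_next, n_next, b_next) if n_next else None,
    )


def per_cluster_signature(
    mutations: Sequence[MutationRecord],
    cluster_members: Sequence[Sequence[int]],
    reference: str | Mapping[str, str],
    cluster_labels: Sequence[str] | None = None,
) -> list[SignatureSummary]:
    """One signature summary per VAF cluster, plus the pooled sample.

    ``cluster_members`` holds index lists into ``mutations`` (as produced by
    :func:`melclone.clonality.assign_clusters`); the pooled summary comes
    last with label "pooled".  Clusters without C>T context report ``None``
    fractions.
    """
    labels = (
        list(cluster_labels)
        if cluster_labels is not None
        else [f"cluster{i}" for i in range(len(cluster_members))]
    )
    summaries = [
        summarize([mutations[i] for i in members], reference, label)
        for members, label in zip(cluster_members, labels)
    ]
    summaries.append(summarize(mutations, reference, "pooled"))
    return summaries
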
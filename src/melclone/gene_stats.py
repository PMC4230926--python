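"""Gene-level mutation statistics for the discovery cohort.

Covers per-gene mutation-rate summaries (mutations per Mbp of covered
sequence), a simplified significantly-mutated-gene (SMG) test that handles
hypermutator samples by subgrouping, expression-based gene filtering,
amino-acid proximity clustering of recurrent mutations, and Fisher exact
tests of co-occurrence / mutual exclusivity between gene pairs.

The SMG test here is deliberately simple: within each case subgroup the
per-gene mutation count is tested against an upper-tail binomial at the
subgroup's background rate, subgroup p-values are combined by Fisher's
method, and the combined p-values are FDR-adjusted by Benjamini-Hochberg.
It ranks genes against the background reliably but is not the convolution
statistic of full SMG suites, so published per-gene p-values from those
tools are not expected to match.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MutationRecord

HYPERMUTATOR_MEDIAN_FACTOR = 3.0
DEFAULT_PROXIMITY_WINDOW = 10  # amino acids


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2k degrees of freedom."""
    p = np.clip(np.asarray(pvalues, dtype=float), np.finfo(float).tiny, 1.0)
    chi2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(chi2, df=2 * len(p)))


def mutation_rate_per_mbp(total: int, covered_bps: int) -> float:
    """Mutations per megabase of covered sequence, to 2 decimals."""
    if covered_bps <= 0:
        raise ValueError("covered_bps must be positive")
    return round(1e6 * total / covered_bps, 2)


@dataclass
class GeneMutSummary:
    """One row of the per-gene summary table."""

    gene: str
    indels: int
    snvs: int
    total: int
    mutated_cases: int
    mutation_frequency: float
    covered_bps: int
    rate_per_mbp: float
    p_value: float | None = None
    fdr: float | None = None


def summarize_genes(
    mutations: Sequence[MutationRecord],
    covered_bps: Mapping[str, int],
    cohort_size: int,
) -> list[GeneMutSummary]:
    """Per-gene counts, case frequency and mutation rate per Mbp.

    ``mutation_frequency`` uses the number of paired cases in the cohort as
    its denominator.
    """
    by_gene: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        if m.gene:
            by_gene.setdefault(m.gene, []).append(m)
    out = []
    for gene in sorted(by_gene):
        muts = by_gene[gene]
        snvs = sum(1 for m in muts if m.is_snv)
        indels = len(muts) - snvs
        cases = len({m.patient_id for m in muts})
        bps = covered_bps.get(gene)
        out.append(
            GeneMutSummary(
                gene=gene,
                indels=indels,
                snvs=snvs,
                total=len(muts),
                mutated_cases=cases,
                mutation_frequency=round(cases / cohort_size, 4),
                covered_bps=bps if bps is not None else 0,
                rate_per_mbp=mutation_rate_per_mbp(len(muts), bps) if bps else float("nan"),
            )
        )
    return out


def declare_hypermutators(
    case_totals: Mapping[str, int], median_factor: float = HYPERMUTATOR_MEDIAN_FACTOR
) -> set[str]:
    """Default hypermutator rule: total burden > ``median_factor`` x cohort median."""
    totals = np.array(list(case_totals.values()), dtype=float)
    cutoff = median_factor * float(np.median(totals))
    return {case for case, t in case_totals.items() if t > cutoff}


def smg_test(
    gene_case_counts: pd.DataFrame,
    covered_bps: Mapping[str, int],
    hypermutators: set[str] | None = None,
    expressed_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Simplified significantly-mutated-gene test with hypermutator subgrouping.

    Parameters
    ----------
    gene_case_counts:
        genes x cases matrix of mutation counts.
    covered_bps:
        per-gene covered base pairs (per case); genes without coverage are
        skipped.
    hypermutators:
        case ids forming the hypermutant subgroup; defaults to the
        3x-median-burden rule.
    expressed_genes:
        if given, genes outside this set are excluded before testing.

    Within each subgroup the background rate is (subgroup total mutations) /
    (subgroup total covered bases); a gene's subgroup p-value is the
    upper-tail binomial P(X >= observed) over ``covered_bps * n_cases``
    trials at that rate.  Subgroup p-values are combined by Fisher's method
    and BH-adjusted across tested genes.
    """
    counts = gene_case_counts
    if expressed_genes is not None:
        counts = counts.loc[[g for g in counts.index if g in expressed_genes]]
    genes = [g for g in counts.index if covered_bps.get(g, 0) > 0]
    counts = counts.loc[genes]
    if hypermutators is None:
        hypermutators = declare_hypermutators(counts.sum(axis=0).to_dict())
    groups = [
        [c for c in counts.columns if c in hypermutators],
        [c for c in counts.columns if c not in hypermutators],
    ]
    groups = [g for g in groups if g]

    bps = np.array([covered_bps[g] for g in genes], dtype=float)
    pvals = np.ones(len(genes))
    group_ps = []
    for cases in groups:
        sub = counts[cases]
        gene_totals = sub.sum(axis=1).to_numpy(dtype=float)
        trials = bps * len(cases)
        background = gene_totals.sum() / trials.sum()
        if background <= 0:
            group_ps.append(np.ones(len(genes)))
            continue
        p = stats.binom.sf(gene_totals - 1, trials.astype(int), background)
        group_ps.append(np.clip(p, np.finfo(float).tiny, 1.0))
    if len(group_ps) == 1:
        pvals = group_ps[0]
    else:
        chi2 = -2.0 * sum(np.log(p) for p in group_ps)
        pvals = stats.chi2.sf(chi2, df=2 * len(group_ps))
    fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    return pd.DataFrame(
        {
            "gene": genes,
            "total": counts.sum(axis=1).to_numpy(),
            "covered_bps": bps.astype(int),
            "p_value": pvals,
            "fdr": fdr,
        }
    ).set_index("gene")


def expression_filter(
    expression: pd.DataFrame,
    min_rpkm: float = 0.5,
    min_reads: int = 3,
    min_sample_frac: float = 0.70,
    rule: str = "rpkm",
) -> set[str]:
    """Genes considered expressed in the reference expression table.

    ``rule='rpkm'`` keeps genes with average expression > ``min_rpkm``;
    ``rule='reads'`` keeps genes with at least ``min_reads`` in at least
    ``min_sample_frac`` of samples; ``rule='either'`` keeps the union.
    """
    avg_ok = expression.mean(axis=1) > min_rpkm
    reads_ok = (expression >= min_reads).mean(axis=1) >= min_sample_frac
    if rule == "rpkm":
        keep = avg_ok
    elif rule == "reads":
        keep = reads_ok
    elif rule == "either":
        keep = avg_ok | reads_ok
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return set(expression.index[keep])


def proximity_clusters(
    mutations: Sequence[MutationRecord], window: int = DEFAULT_PROXIMITY_WINDOW
) -> tuple[list[tuple[MutationRecord, MutationRecord]], list[list[MutationRecord]]]:
    """Mutation pairs within ``window`` amino acids on the same gene transcript.

    Pairs require different cases (recurrence across patients is the signal);
    connected components of the pair graph are reported as clusters.
    """
    eligible = [m for m in mutations if m.transcript_aa_pos is not None and m.gene]
    pairs = [
        (a, b)
        for a, b in combinations(eligible, 2)
        if a.gene == b.gene
        and a.patient_id != b.patient_id
        and abs(a.transcript_aa_pos - b.transcript_aa_pos) <= window
    ]
    # union-find over mutations appearing in pairs
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ids = {id(m): m for ab in pairs for m in ab}
    for key in ids:
        parent[key] = key
    for a, b in pairs:
        ra, rb = find(id(a)), find(id(b))
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[MutationRecord]] = {}
    for key, m in ids.items():
        comps.setdefault(find(key), []).append(m)
    clusters = [
        sorted(ms, key=lambda m: (m.gene, m.transcript_aa_pos, m.patient_id))
        for ms in comps.values()
    ]
    clusters.sort(key=lambda ms: (ms[0].gene, ms[0].transcript_aa_pos))
    return pairs, clusters


def cooccurrence_test(
    status_a: Sequence[bool], status_b: Sequence[bool], direction: str = "cooccur"
) -> tuple[float, tuple[int, int, int, int]]:
    """One-sided Fisher exact test for co-occurrence or mutual exclusivity.

    Returns ``(p, (both, a_only, b_only, neither))``.  ``cooccur`` tests the
    upper hypergeometric tail (more double-mutants than chance), ``exclude``
    the lower tail.
    """
    if len(status_a) != len(status_b):
        raise ValueError("status vectors must have equal length")
    if len(status_a) == 0:
        raise ValueError("empty status vectors")
    a = np.asarray(status_a, dtype=bool)
    b = np.asarray(status_b, dtype=bool)
    table = (
        int((a & b).sum()),
        int((a & ~b).sum()),
        int((~a & b).sum()),
        int((~a & ~b).sum()),
    )
    if direction == "cooccur":
        alternative = "greater"
    elif direction == "exclude":
        alternative = "less"
    else:
        raise ValueError(f"direction must be cooccur|exclude, got {direction!r}")
    _, p = stats.fisher_exact(
        [[table[0], table[1]], [table[2], table[3]]], alternative=alternative
    )
    return float(p), table
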
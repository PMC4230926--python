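# Methods

This note records the models, parameter choices and numerical conventions
behind melclone, and what the synthetic-data generator does and does not
emulate.

## VAF model and purity

All VAFs are percents in [0, 100]; all genomic coordinates are 1-based
inclusive (BED input is converted at the I/O boundary). For a mutation
carried by a clone at cellular prevalence *f* in a specimen of purity *ρ*,
on a segment of tumor copy number *c* with *m* mutant copies,

    E[VAF] = 100 · f · ρ · m / (ρ·c + (1−ρ)·2).

Clonality analysis is restricted to copy-number-neutral (c = 2), non-LOH
regions with m = 1, where E[VAF] = 50·f·ρ, so the founding clone (f = 1)
marks 50·ρ and purity = 2 × founding-peak VAF, capped at 100 and reported to
one decimal. VAFs above 50 in neutral regions are retained through
clustering; only the purity cap intervenes. Purity correction of a VAF is
100·VAF/purity, capped at 100.

## Stable-region selection

Segments flagged LOH are dropped outright. Chromosome-level screening uses
germline heterozygous SNPs whose **normal** VAF lies in [40, 60]: a
chromosome is excluded (reason `variable_vaf`) when more than 25% of those
sites have **tumor** VAF deviating from 50 by more than 10 points, and
excluded with reason `no_evidence` when it has no qualifying site. The
deviation/fraction thresholds operationalize what is otherwise a manual
"does this chromosome look diploid" judgement; both are configurable, and
the defaults were fixed before any recovery testing. Mutation filtering then
keeps sites covered strictly deeper than 100 reads in *both* tumor and
normal (a strict `>` mirroring the ">100x" convention) inside retained
segments, grouped by the covering segment's copy-number state; a mutation on
a segment boundary takes the leftmost covering segment. Only the c = 2 group
feeds default clustering; other states are reported separately, never pooled.

## KDE clustering

The density is a Gaussian KDE on a fixed 512-point grid over [0, 100] with
Silverman's rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)
(falling back through sd when the IQR vanishes). The curve is renormalized
to integrate to exactly 1 over the grid: kernels near 0 or 100 leak mass
outside the support, and renormalization restores the unit integral without
moving any peak. Significant peaks are local maxima with topographic
prominence ≥ 10% of the global density maximum; peaks closer than 5 VAF
points are merged keeping the denser one, and results are ordered by
descending VAF. The prominence fraction and separation are exposed in
configuration; they are a deterministic stand-in for interactive peak
calling, chosen so that well-separated two-clone mixtures at realistic depth
(≥ 500×) are resolved while shoulder wiggles are not. Cluster assignment
sends each mutation to the peak whose valley boundaries (density minima
between adjacent peaks; midpoints when no curve is available) contain its
VAF; a VAF exactly on a valley goes to the higher-VAF cluster. The founding
clone is the highest-VAF cluster even when a subclone holds more mutations.

## Mutation-context statistics

Substitutions are strand-collapsed into six classes (mutated base reported
as C or T). For context, a C or T reference base reads its literal 5′/3′
neighbors; a G or A base contributes the complemented, swapped flanks so
"prev" always means 5′ of the mutated pyrimidine. Positions at contig edges
are excluded from fractions. Adjacent same-sample SNVs merge greedily
left-to-right into dinucleotide mutations and leave the SNV set before
context analysis (avoiding double counting); CC→TT status includes the GG→AA
strand equivalent. The chance baseline is the pyrimidine-neighbor fraction
over **all** C/G positions of the supplied reference — it is always computed,
never hard-coded, since it depends on the sequence analyzed. The proportion
test is a two-sided one-sample chi-square with Yates continuity correction,
falling back to the exact binomial test when n·p₀ < 5 or n·(1−p₀) < 5; the
two-sided continuity-corrected flavor matches common statistical-package
defaults and is documented here because the choice is otherwise arbitrary.

## Multisample comparison and trees

Shared/private analysis partitions mutations by the subset of samples
carrying them; pairwise sharing is Jaccard (|A∩B|/|A∪B|). The VAF matrix
holds purity-corrected percents with mutations absent from a sample entered
as 0 (absence); a presence mask is kept so callers can instead exclude
low-coverage sites. Distances are the mean absolute VAF difference
("manhattan"; the root-mean-square option stays on the same [0, 100] scale).
Neighbor joining is implemented in the package (Saitou–Nei agglomeration,
final trifurcation, deterministic tie-breaking by lowest index); negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling branch so the joined pair's path length is preserved. An artificial
all-zero "normal" taxon provides rooting. scikit-bio's NJ is used in the
test suite as an independent cross-check, never as the implementation.

## Gene-level statistics

Mutation rate is 10⁶·total/covered bps, reported to two decimals; case
frequency uses the number of paired cases in the cohort as denominator. The
SMG test is deliberately simplified: cases are split into a hypermutant
subgroup (user-declared, defaulting to total burden > 3× the cohort median)
and the rest; within each subgroup a gene's count is tested against an
upper-tail binomial over covered_bps × n_cases trials at the subgroup
background rate (subgroup total mutations / subgroup total covered bases);
subgroup p-values are Fisher-combined (χ² on 2k df) and BH-adjusted. This
ranks genes against background reliably but is *not* a convolution test over
mutation categories, so p-values/FDRs from full SMG suites are not expected
to be reproduced. Genes can be pre-filtered by expression (average RPKM
> 0.5, or ≥ 3 reads in ≥ 70% of samples, or either). Proximity clustering
pairs mutations on the same gene within 10 amino acids across different
cases and reports connected components. Co-occurrence/exclusion tests are
one-sided Fisher exact (upper/lower hypergeometric tail); one-sidedness
matches the directional hypotheses these tests encode.

## SV support rules

Acceptable alignment: ≤ 1 unaligned base at either end, ≤ 1% substitutions,
≤ 1% indels, score ≥ 50. An SV-supporting read must align acceptably to the
contig, span the breakpoint with ≥ 10 aligned flanking bases on each side,
and have no acceptable reference alignment. Tabulated totals count every
read evaluated against the contig for that sample. The somatic call is a
one-sided (tumor-enriched) Fisher exact test at α = 0.05, with an absolute
veto: any SV-supporting read in normal WGS data makes the verdict
`germline_or_artifact` regardless of p. Zero tumor support is `unsupported`.
Repeat-sequence filtering and manual review are consumed as input flags, not
recomputed — they are not algorithmic steps.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: clones on
a prevalence tree (children ≤ parents per sample, siblings summing within the
parent), i.i.d. reference sequence at a target GC (default 0.4, with
symmetric base frequencies so a random neighbor is a pyrimidine with
probability 0.5), C→T/G→A mutations placed with a controllable 5′- or
3′-pyrimidine context bias, Poisson depths (zeros raised to 1) with binomial
or beta-binomial read sampling (ρ = 0.01 by default — the paperless noise
parameter; VAF scatter in real deep validation data motivates mild
overdispersion, and ρ = 0 recovers the pure binomial), and per-read SV
records built to satisfy or violate exactly one named rule each. One global
seed feeds a splittable generator per operation, so outputs are
byte-identical under a fixed seed and adding an operation does not perturb
others.

It does **not** emulate: mapping artifacts, strand bias, germline
contamination of somatic calls, copy-number change *within* a segment,
mutation clustering along the genome (kataegis), or sequencing error in the
reads themselves. Passing recovery tests therefore demonstrates the
statistical machinery is correct under the stated model, not robustness to
every artifact of real data.

Default study-scale conditions used by the tests: two-clone tumors with
cluster centers 46.8/19.81 VAF (subclone 4× the mutations), depth 500×,
n = 2000 mutations, 200 kb reference; SMG calibration with 30 cases (5
hypermutant at 150 mutations/Mbp, 25 at 30/Mbp) and per-gene footprints of
15–90 kb, matching the covered-base range of real capture panels.

## Degenerate inputs and tie-breaks

KDE requires ≥ 2 values; a flat or monotone density yields its global
maximum as the single peak. Readcount rows with var_reads > depth or
depth ≤ 0 are rejected at parse time. Neighbor joining requires ≥ 3 taxa and
a symmetric, NaN-free matrix. Proportion tests reject n = 0; context
fractions with no eligible C→T mutations are reported as undefined (None)
rather than 0. Valley ties in cluster assignment go to the higher-VAF
cluster; equal-prominence peak merges keep the denser peak, with grid order
breaking exact ties.

## Known limitations

Purity estimation assumes a diploid heterozygous founding clone; focal
amplification of the mutant allele (configurable in the simulator) biases
the estimate upward. Single-sample KDE clustering cannot separate clones
closer than about one bandwidth. The NJ tree is a sample tree, not a clone
tree, and carries no bootstrap support. The SMG simplification above is the
largest intentional departure from full-suite behavior.
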
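"""Gene-level mutation rates, co-occurrence and proximity clustering.

Reproduces the rate arithmetic of a discovery-cohort summary table (mutations
per Mbp of covered sequence), tests co-occurrence of truncations in one gene
with point mutations in another by a one-sided Fisher exact test, and finds
recurrent mutations clustering within 10 amino acids across patients.
"""

from melclone import (
    MutationRecord,
    cooccurrence_test,
    mutation_rate_per_mbp,
    proximity_clusters,
)

print("mutation rates per Mbp (total mutations / covered bps):")
for gene, total, bps in [
    ("BRAF", 22, 62_953),
    ("NRAS", 4, 16_408),
    ("CDKN2A", 4, 16_864),
    ("EPHA3", 10, 89_708),
]:
    print(f"  {gene:>7}: {total:3d} / {bps:6d} bp = {mutation_rate_per_mbp(total, bps):7.2f}")

# co-occurrence: 3 patients carry truncations in gene A, all 3 also carry a
# gene-B mutation; 16 further patients carry only B, 77 carry neither
status_a = [True] * 3 + [False] * 93
status_b = [True] * 3 + [True] * 16 + [False] * 77
p, table = cooccurrence_test(status_a, status_b, direction="cooccur")
print(f"\nco-occurrence table (both, A only, B only, neither): {table}")
print(f"one-sided Fisher exact p = {p:.4f}")

# proximity: recurrent mutations within 10 amino acids on one transcript
muts = [
    MutationRecord(f"P{i}", f"P{i}", "chr3", 100 + i, "C", "T", gene="EPHA3",
                   transcript_aa_pos=aa)
    for i, aa in enumerate([114, 118, 136, 317, 325, 600])
]
pairs, clusters = proximity_clusters(muts, window=10)
print(f"\nproximity pairs (<=10 aa apart, different patients): {len(pairs)}")
for cluster in clusters:
    print("  cluster:", [(m.gene, m.transcript_aa_pos) for m in cluster])
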
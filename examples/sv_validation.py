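"""Validate a structural variant from per-read realignment statistics.

A read supports an SV when it aligns cleanly to the assembled breakpoint
contig (<=1 unaligned end base, <=1% substitutions, <=1% indels, score >=50),
spans the breakpoint with >=10 aligned bases of flank on each side, and has no
acceptable alignment to the reference.  Tumor/normal support counts feed a
one-sided Fisher exact test; any supporting read in the normal whole-genome
data vetoes the call as germline or artifact.
"""

from melclone import simulate_sv_read_records, somatic_sv_test

# 12 supporting reads among 120 evaluated in the tumor, none among 110 in the
# matched normal, and a clean normal whole-genome check
capture = simulate_sv_read_records(
    n_support_tumor=12, n_nonsupport_tumor=108,
    n_support_normal=0, n_nonsupport_normal=110,
    seed=5,
)
wgs_normal = simulate_sv_read_records(0, 0, 0, 200, seed=6, source="wgs")

result = somatic_sv_test("sv_del_chr3", capture, wgs_normal)
print(f"SV {result.sv_id}:")
print(f"  tumor support : {result.tumor_support}/{result.tumor_total} reads")
print(f"  normal support: {result.normal_support}/{result.normal_total} reads")
print(f"  Fisher p      : {result.fisher_p:.3e}")
print(f"  verdict       : {result.verdict}")

# one supporting read in the normal WGS data is enough to veto
wgs_contaminated = simulate_sv_read_records(0, 0, 1, 199, seed=8, source="wgs")
vetoed = somatic_sv_test("sv_del_chr3", capture, wgs_contaminated)
print(f"  with 1 normal-WGS supporting read -> verdict: {vetoed.verdict}")
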
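"""Readers and writers for the external formats the pipeline touches.

Dialect contracts
-----------------
* VCF 4.x for mutations (positions kept 1-based; INFO keys ``TIER``, ``GENE``,
  ``AAPOS`` and ``PATIENT`` are parsed when present; one
  :class:`~melclone.types.MutationRecord` is emitted per variant-sample with a
  non-reference genotype).
* Readcounts are tab-separated with columns
  ``sample  chrom  pos  alt  depth  var_reads`` (1-based positions).
* Copy-number segments are BED-dialect: 0-based half-open on disk with two
  extra columns ``cn_state`` and ``loh``; converted to 1-based inclusive
  coordinates on read.
* FASTA via Biopython (sequences case-folded to upper); Newick via scikit-bio.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF
from skbio import TreeNode

from .types import CNSegment, HetSnpSite, MutationRecord, ReadAlignmentStat, ReadcountEntry

READCOUNT_COLUMNS = ["sample", "chrom", "pos", "alt", "depth", "var_reads"]
HET_SNP_COLUMNS = ["chrom", "pos", "normal_vaf", "tumor_vaf"]
SV_RECORD_COLUMNS = [
    "read_id",
    "sv_id",
    "target",
    "unaligned_end_bases",
    "pct_substitutions",
    "pct_indels",
    "score",
    "spans_breakpoint",
    "flank_left",
    "flank_right",
    "sample",
    "source",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> list[MutationRecord]:
    """Read somatic SNV/indel calls from a VCF 4.x file.

    Emits one record per variant-sample carrying a non-reference genotype;
    for sites-only VCFs (no sample columns) a single record with empty
    ``sample_id`` is emitted per variant.  Raises :class:`ParseError` (naming
    the offending line) on malformed headers or non-monotone contig order.
    """
    path = os.fspath(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exception subclasses
        raise ParseError(f"{path}: malformed VCF header (line 1): {exc}") from exc

    n_header_lines = vcf.raw_header.count("\n")
    samples = list(vcf.samples)
    records: list[MutationRecord] = []
    seen_contigs: list[str] = []
    last_pos = 0
    for idx, v in enumerate(vcf):
        line_no = n_header_lines + idx + 1
        if not seen_contigs or v.CHROM != seen_contigs[-1]:
            if v.CHROM in seen_contigs:
                raise ParseError(
                    f"{path}: non-monotone contig order, contig {v.CHROM} revisited (line {line_no})"
                )
            seen_contigs.append(v.CHROM)
            last_pos = 0
        if v.POS < last_pos:
            raise ParseError(
                f"{path}: positions out of order on {v.CHROM} (line {line_no})"
            )
        last_pos = v.POS

        tier = v.INFO.get("TIER")
        gene = v.INFO.get("GENE") or ""
        aa_pos = v.INFO.get("AAPOS")
        patient = v.INFO.get("PATIENT") or ""
        for alt in v.ALT:
            common = dict(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                tier=int(tier) if tier is not None else None,
                gene=str(gene),
                transcript_aa_pos=int(aa_pos) if aa_pos is not None else None,
            )
            if samples:
                for sample, gt_type in zip(samples, v.gt_types):
                    if gt_type in (1, 3):  # HET or HOM_ALT
                        records.append(
                            MutationRecord(
                                patient_id=patient or sample,
                                sample_id=sample,
                                **common,
                            )
                        )
            else:
                records.append(MutationRecord(patient_id=patient, sample_id="", **common))
    return records


def write_vcf(records: Iterable[MutationRecord], path: str | os.PathLike) -> None:
    """Write mutation records as a multi-sample VCF 4.2 file.

    Variants sharing (chrom, pos, ref, alt) collapse onto one line with 0/1
    genotypes marking the samples that carry them.  All records are assumed to
    belong to one patient (the first record's ``patient_id`` is written).
    """
    records = list(records)
    samples = sorted({r.sample_id for r in records if r.sample_id})
    by_site: dict[tuple, dict] = {}
    order: list[tuple] = []
    for r in records:
        site = (r.chrom, r.pos, r.ref, r.alt)
        if site not in by_site:
            by_site[site] = {"rec": r, "samples": set()}
            order.append(site)
        if r.sample_id:
            by_site[site]["samples"].add(r.sample_id)

    def contig_rank(site: tuple) -> tuple:
        return (site[0], site[1])

    order.sort(key=contig_rank)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=TIER,Number=1,Type=Integer,Description="Annotation tier (1-3)">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AAPOS,Number=1,Type=Integer,Description="Amino-acid position on transcript">',
        '##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(site[0] for site in order):
        lines.append(f"##contig=<ID={chrom}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header_cols += ["FORMAT"] + samples
    lines.append("\t".join(header_cols))

    for site in order:
        r: MutationRecord = by_site[site]["rec"]
        info = []
        if r.tier is not None:
            info.append(f"TIER={r.tier}")
        if r.gene:
            info.append(f"GENE={r.gene}")
        if r.transcript_aa_pos is not None:
            info.append(f"AAPOS={r.transcript_aa_pos}")
        if r.patient_id:
            info.append(f"PATIENT={r.patient_id}")
        row = [r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS", ";".join(info) or "."]
        if samples:
            row.append("GT")
            carriers = by_site[site]["samples"]
            row += ["0/1" if s in carriers else "0/0" for s in samples]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Readcount tables
# ---------------------------------------------------------------------------

def read_readcounts(path: str | os.PathLike) -> list[ReadcountEntry]:
    """Read a tab-separated readcount table.

    VAF is recomputed as ``100 * var_reads / depth``; rows with
    ``var_reads > depth`` or non-positive depth raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in READCOUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing readcount columns {missing}")
    return [
        ReadcountEntry(
            sample_id=str(row.sample),
            chrom=str(row.chrom),
            pos=int(row.pos),
            alt=str(row.alt),
            depth=int(row.depth),
            var_reads=int(row.var_reads),
        )
        for row in df.itertuples()
    ]


def write_readcounts(entries: Iterable[ReadcountEntry], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            dict(
                sample=e.sample_id,
                chrom=e.chrom,
                pos=e.pos,
                alt=e.alt,
                depth=e.depth,
                var_reads=e.var_reads,
                vaf=round(e.vaf, 4),
            )
            for e in entries
        ],
        columns=READCOUNT_COLUMNS + ["vaf"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_het_snps(path: str | os.PathLike) -> list[HetSnpSite]:
    """Read paired normal/tumor VAFs (percent) at germline het SNP sites."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in HET_SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing het-SNP columns {missing}")
    return [
        HetSnpSite(
            chrom=str(r.chrom),
            pos=int(r.pos),
            normal_vaf=float(r.normal_vaf),
            tumor_vaf=float(r.tumor_vaf),
        )
        for r in df.itertuples()
    ]


def write_het_snps(sites: Iterable[HetSnpSite], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [dict(chrom=s.chrom, pos=s.pos, normal_vaf=s.normal_vaf, tumor_vaf=s.tumor_vaf) for s in sites],
        columns=HET_SNP_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_sv_records(path: str | os.PathLike) -> list[ReadAlignmentStat]:
    """Read per-read SV alignment statistics keyed by sv_id."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SV_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing SV record columns {missing}")
    return [
        ReadAlignmentStat(
            read_id=str(r.read_id),
            sv_id=str(r.sv_id),
            target=str(r.target),
            unaligned_end_bases=int(r.unaligned_end_bases),
            pct_substitutions=float(r.pct_substitutions),
            pct_indels=float(r.pct_indels),
            score=float(r.score),
            spans_breakpoint=bool(r.spans_breakpoint),
            flank_left=int(r.flank_left),
            flank_right=int(r.flank_right),
            sample=str(r.sample),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]


def write_sv_records(records: Iterable[ReadAlignmentStat], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            dict(
                read_id=r.read_id,
                sv_id=r.sv_id,
                target=r.target,
                unaligned_end_bases=r.unaligned_end_bases,
                pct_substitutions=r.pct_substitutions,
                pct_indels=r.pct_indels,
                score=r.score,
                spans_breakpoint=r.spans_breakpoint,
                flank_left=r.flank_left,
                flank_right=r.flank_right,
                sample=r.sample,
                source=r.source,
            )
            for r in records
        ],
        columns=SV_RECORD_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Copy-number segments (BED dialect)
# ---------------------------------------------------------------------------

def read_segments(path: str | os.PathLike) -> list[CNSegment]:
    """Read BED-dialect segments (0-based half-open) into 1-based inclusive
    :class:`CNSegment` objects.

    Columns: chrom, start, end[, cn_state[, loh]]; cn_state defaults to 2 and
    loh to false.  Comment lines start with ``#`` or ``track``.
    """
    segments = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {i}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end < start:
                raise ParseError(f"{path}: line {i}: bad interval {start}-{end}")
            cn_state = float(fields[3]) if len(fields) > 3 else 2.0
            loh = fields[4].lower() in ("1", "true", "t", "yes") if len(fields) > 4 else False
            segments.append(CNSegment(chrom=chrom, start=start + 1, end=end, cn_state=cn_state, loh=loh))
    return segments


def write_segments(segments: Iterable[CNSegment], path: str | os.PathLike) -> None:
    """Write segments back out in BED dialect (0-based half-open)."""
    with open(path, "w") as fh:
        for s in segments:
            cn = int(s.cn_state) if float(s.cn_state).is_integer() else s.cn_state
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{cn}\t{int(s.loh)}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into {name: upper-case sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | os.PathLike | None = None) -> str:
    """Serialize a tree to Newick text (terminated with ';'); optionally to a file."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if not text.endswith(";"):
        text += ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick(source: str | os.PathLike) -> TreeNode:
    """Parse Newick text or a Newick file into a scikit-bio TreeNode."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        handle: io.StringIO | str = io.StringIO(source)
    else:
        handle = os.fspath(source)
    try:
        return TreeNode.read(handle, format="newick")
    except Exception as exc:
        raise ParseError(f"malformed Newick input: {exc}") from exc
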
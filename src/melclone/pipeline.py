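"""End-to-end orchestration: simulate (optionally), filter, cluster, dissect.

A :class:`PipelineConfig` names the inputs, toggles the stages and carries
every tunable.  :func:`run_pipeline` executes the enabled stages in order —
region filtering -> clonality -> signature -> multisample comparison ->
gene statistics -> SV support — and writes a JSON manifest recording the
parameters, seed and per-stage output paths.  Deterministic stages re-run
byte-identically under the same config and inputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clonality, io_formats, multisample, region_filter
from . import signature as sig
from . import sv_support, synthetic
from .types import MutationRecord

STAGES = ("region_filter", "clonality", "signature", "multisample", "gene_stats", "sv_support")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected on load)."""

    outdir: str
    seed: int = 0
    simulate: dict | None = None  # inline SimConfig mapping; generates inputs
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    min_depth: int = 100
    bandwidth: float | str = "auto"
    min_prominence_frac: float = 0.10
    min_separation: float = 5.0
    proximity_window: int = 10
    fdr_threshold: float = 0.05
    fisher_direction: str = "cooccur"
    normal_het_window: tuple[float, float] = (40.0, 60.0)
    per_cluster_signature: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        enabled = {s for s in STAGES if self.stages.get(s, False)}
        if self.per_cluster_signature and "signature" in enabled and "clonality" not in enabled:
            raise ValueError(
                "per-cluster signature dissection requires the clonality stage to be enabled"
            )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "normal_het_window" in raw:
            raw["normal_het_window"] = tuple(raw["normal_het_window"])
        return cls(**raw)


def _require(cfg: PipelineConfig, stage: str, *keys: str) -> None:
    missing = [k for k in keys if k not in cfg.inputs]
    if missing:
        raise FileNotFoundError(f"stage {stage}: missing required inputs {missing}")


def _simulate_inputs(cfg: PipelineConfig, outdir: Path) -> None:
    """Materialize synthetic inputs into outdir/inputs and register them."""
    sim_raw = dict(cfg.simulate or {})
    sim_raw.setdefault("seed", cfg.seed)
    clones = [synthetic.CloneSpec(**c) for c in sim_raw.pop("clones")]
    sim = synthetic.SimConfig(clones=clones, **sim_raw)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    result = synthetic.simulate_patient(sim)
    io_formats.write_fasta({"chr1": result.reference}, indir / "reference.fa")
    io_formats.write_readcounts(result.readcounts, indir / "tumor_readcounts.tsv")
    # matched normal: same depth model, no variant reads
    rng = np.random.default_rng(np.random.SeedSequence(sim.seed, spawn_key=(99,)))
    normals = [
        type(e)(
            sample_id="normal",
            chrom=e.chrom,
            pos=e.pos,
            alt=e.alt,
            depth=max(1, int(rng.poisson(sim.depth_mean))),
            var_reads=0,
        )
        for e in result.readcounts
        if e.sample_id == sim.samples[0]
    ]
    io_formats.write_readcounts(normals, indir / "normal_readcounts.tsv")
    all_records = [m for ms in result.mutations_by_sample.values() for m in ms]
    io_formats.write_vcf(all_records, indir / "mutations.vcf")
    if result.true_tree_newick:
        io_formats.write_newick(
            io_formats.read_newick(result.true_tree_newick), indir / "true_tree.nwk"
        )
    cfg.inputs.setdefault("reference_fasta", str(indir / "reference.fa"))
    cfg.inputs.setdefault("tumor_readcounts", str(indir / "tumor_readcounts.tsv"))
    cfg.inputs.setdefault("normal_readcounts", str(indir / "normal_readcounts.tsv"))
    cfg.inputs.setdefault("vcf", str(indir / "mutations.vcf"))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        _simulate_inputs(cfg, outdir)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("inputs", "stages", "simulate", "outdir")
        },
        "stages": {},
    }
    enabled = {s for s in STAGES if cfg.stages.get(s, False)}

    mutations: list[MutationRecord] = []
    if "vcf" in cfg.inputs:
        mutations = io_formats.read_vcf(cfg.inputs["vcf"])
    reference = (
        io_formats.read_fasta(cfg.inputs["reference_fasta"])
        if "reference_fasta" in cfg.inputs
        else None
    )

    regions = None
    if "region_filter" in enabled:
        _require(cfg, "region_filter", "segments", "het_snps")
        segments = io_formats.read_segments(cfg.inputs["segments"])
        het = io_formats.read_het_snps(cfg.inputs["het_snps"])
        regions = region_filter.build_stable_regions(
            segments, het, normal_het_window=cfg.normal_het_window
        )
        out = outdir / "stable_regions.json"
        out.write_text(
            json.dumps(
                {
                    "excluded_chromosomes": regions.excluded_chromosomes,
                    "regions_by_cn": {
                        str(cn): [[s.chrom, s.start, s.end] for s in segs]
                        for cn, segs in regions.regions_by_cn.items()
                    },
                },
                indent=2,
            )
        )
        manifest["stages"]["region_filter"] = {"output": str(out)}

    architectures: dict[str, clonality.ClonalArchitecture] = {}
    readcounts_by_sample: dict[str, list] = {}
    if "clonality" in enabled:
        _require(cfg, "clonality", "tumor_readcounts")
        entries = io_formats.read_readcounts(cfg.inputs["tumor_readcounts"])
        for e in entries:
            readcounts_by_sample.setdefault(e.sample_id, []).append(e)
        report = {}
        for sample, rcs in sorted(readcounts_by_sample.items()):
            if regions is not None and "normal_readcounts" in cfg.inputs:
                normals = io_formats.read_readcounts(cfg.inputs["normal_readcounts"])
                kept, _ = region_filter.filter_mutations(
                    [m for m in mutations if m.sample_id == sample],
                    {(e.chrom, e.pos): e for e in rcs},
                    {(e.chrom, e.pos): e for e in normals},
                    regions,
                    min_depth=cfg.min_depth,
                )
                neutral = {(m.chrom, m.pos) for m in kept.get(2.0, [])}
                rcs = [e for e in rcs if (e.chrom, e.pos) in neutral]
            vafs = [e.vaf for e in rcs]
            if len(vafs) < 2:
                continue
            arch = clonality.infer_architecture(
                vafs,
                bandwidth=cfg.bandwidth,
                min_prominence_frac=cfg.min_prominence_frac,
                min_separation=cfg.min_separation,
            )
            architectures[sample] = arch
            report[sample] = {
                "founding_cluster_vaf": arch.founding_peak_vaf,
                "subclone_cluster_vafs": arch.peak_vafs[1:],
                "n_subclones": arch.n_subclones,
                "purity_percent": arch.purity,
                "cluster_sizes": [len(m) for m in arch.cluster_members],
            }
        out = outdir / "clonal_architecture.json"
        out.write_text(json.dumps(report, indent=2))
        manifest["stages"]["clonality"] = {"output": str(out)}

    if "signature" in enabled:
        _require(cfg, "signature", "vcf", "reference_fasta")
        assert reference is not None
        rows = []
        for sample in sorted({m.sample_id for m in mutations}):
            sample_muts = [m for m in mutations if m.sample_id == sample]
            _, snvs = sig.detect_dinucleotide_mutations(sample_muts)
            summaries = [sig.summarize(snvs, reference, label="sample")]
            if cfg.per_cluster_signature and sample in architectures:
                arch = architectures[sample]
                rc_keyed = {
                    (e.chrom, e.pos): i
                    for i, e in enumerate(readcounts_by_sample.get(sample, []))
                }
                idx_of_rc = {}
                for mi, m in enumerate(snvs):
                    ri = rc_keyed.get((m.chrom, m.pos))
                    if ri is not None:
                        idx_of_rc[ri] = mi
                members = [
                    [idx_of_rc[ri] for ri in cluster if ri in idx_of_rc]
                    for cluster in arch.cluster_members
                ]
                labels = [f"cluster@{v:.1f}" for v in arch.peak_vafs]
                summaries = sig.per_cluster_signature(snvs, members, reference, labels)
            for s in summaries:
                rows.append(
                    dict(
                        sample=sample,
                        label=s.label,
                        n_CtoT=s.n_CtoT,
                        frac_prev_pyrimidine=s.frac_prev_pyrimidine,
                        frac_next_pyrimidine=s.frac_next_pyrimidine,
                        baseline_prev=s.baseline_prev,
                        baseline_next=s.baseline_next,
                        p_prev=s.p_prev,
                        p_next=s.p_next,
                        **s.class_counts,
                    )
                )
        out = outdir / "signature_report.tsv"
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
        manifest["stages"]["signature"] = {"output": str(out)}

    if "multisample" in enabled and len(readcounts_by_sample) >= 2:
        purities = {
            s: architectures[s].purity for s in readcounts_by_sample if s in architectures
        }
        matrix = multisample.build_vaf_matrix(readcounts_by_sample, purities)
        names, dist = multisample.distance_matrix(matrix)
        tree = multisample.build_tree(dist, names)
        out = outdir / "sample_tree.nwk"
        io_formats.write_newick(tree, out)
        muts_by_sample = {
            s: [m for m in mutations if m.sample_id == s] for s in readcounts_by_sample
        }
        _, pairwise = multisample.shared_private(muts_by_sample)
        shared_out = outdir / "shared_fractions.json"
        shared_out.write_text(
            json.dumps({f"{a}|{b}": v for (a, b), v in pairwise.items()}, indent=2)
        )
        manifest["stages"]["multisample"] = {
            "tree": str(out),
            "shared_fractions": str(shared_out),
        }

    if "gene_stats" in enabled and "covered_bps" in cfg.inputs:
        from . import gene_stats

        covered = (
            pd.read_csv(cfg.inputs["covered_bps"], sep="\t")
            .set_index("gene")["covered_bps"]
            .to_dict()
        )
        cohort = len({m.patient_id for m in mutations}) or 1
        summaries = gene_stats.summarize_genes(mutations, covered, cohort)
        out = outdir / "gene_summary.tsv"
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(out, sep="\t", index=False)
        manifest["stages"]["gene_stats"] = {"output": str(out)}

    if "sv_support" in enabled and "sv_records" in cfg.inputs:
        records = io_formats.read_sv_records(cfg.inputs["sv_records"])
        by_sv: dict[str, list] = {}
        for r in records:
            by_sv.setdefault(r.sv_id, []).append(r)
        results = []
        for sv_id, recs in sorted(by_sv.items()):
            capture = [r for r in recs if r.source == "capture"]
            wgs = [r for r in recs if r.source == "wgs"]
            res = sv_support.somatic_sv_test(sv_id, capture, wgs)
            results.append(asdict(res))
        out = outdir / "sv_support.tsv"
        pd.DataFrame(results).to_csv(out, sep="\t", index=False)
        manifest["stages"]["sv_support"] = {"output": str(out)}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
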
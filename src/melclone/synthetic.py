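"""Synthetic tumor-sequencing data with known clonal structure.

The generator emulates the statistical structure the downstream analysis
assumes: a small set of clones with fixed cellular prevalences per sample,
binomial (or beta-binomial) read sampling at a target depth and tumor purity,
UV-type versus context-free trinucleotide contexts for C->T mutations, shared
and private mutations across metastases of one patient, and copy-number
neutral versus altered segments.

The expected VAF of a mutation at cellular prevalence ``f`` in a tumor of
purity ``rho`` on a segment of copy number ``c`` with ``m`` mutant copies is

    E[VAF] = 100 * f * rho * m / (rho * c + (1 - rho) * 2)

which reduces to ``50 * f * rho`` in the diploid heterozygous case — the model
under which purity is estimated as twice the founding-clone VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .types import CNSegment, MutationRecord, ReadAlignmentStat, ReadcountEntry

SIGNATURES = ("uv_5prime", "pyr_3prime", "uniform")

# stable per-operation seed offsets for the splittable generator
_OP_KEYS = {"reference": 1, "mutations": 2, "readcounts": 3, "sv": 4}


def _rng(seed: int, op: str) -> np.random.Generator:
    """Operation-specific generator derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_OP_KEYS[op],)))


@dataclass
class CloneSpec:
    """One clonal population: its prevalence per sample, size and signature."""

    clone_id: str
    prevalence_per_sample: dict[str, float]
    n_mutations: int
    signature: str = "uniform"
    signature_strength: float = 0.9
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.signature not in SIGNATURES:
            raise ValueError(f"unknown signature {self.signature!r}")
        if not 0.5 <= self.signature_strength <= 1.0:
            raise ValueError("signature_strength must be in [0.5, 1]")
        for s, f in self.prevalence_per_sample.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"prevalence for {s} outside [0,1]: {f}")


@dataclass
class SimConfig:
    """Full description of one simulated patient."""

    clones: list[CloneSpec]
    purity_per_sample: dict[str, float]
    depth_mean: float = 500.0
    overdispersion: float = 0.01  # beta-binomial rho; 0 = pure binomial
    genome_length: int = 100_000
    gc_content: float = 0.4
    seed: int = 0
    cn_segments: list[CNSegment] = field(default_factory=list)
    mutant_copies: int = 1

    def __post_init__(self) -> None:
        for s, p in self.purity_per_sample.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"purity for {s} outside [0,1]: {p}")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        self._check_tree()

    def _check_tree(self) -> None:
        by_id = {c.clone_id: c for c in self.clones}
        children: dict[str | None, list[CloneSpec]] = {}
        for c in self.clones:
            if c.parent_id is not None and c.parent_id not in by_id:
                raise ValueError(f"clone {c.clone_id} has unknown parent {c.parent_id}")
            children.setdefault(c.parent_id, []).append(c)
        for c in self.clones:
            if c.parent_id is None:
                continue
            parent = by_id[c.parent_id]
            for s, f in c.prevalence_per_sample.items():
                if f > parent.prevalence_per_sample.get(s, 0.0) + 1e-12:
                    raise ValueError(
                        f"clone {c.clone_id} prevalence exceeds parent {c.parent_id} in sample {s}"
                    )
        for parent_id, sibs in children.items():
            if parent_id is None:
                continue
            parent = by_id[parent_id]
            samples = {s for c in sibs for s in c.prevalence_per_sample}
            for s in samples:
                total = sum(c.prevalence_per_sample.get(s, 0.0) for c in sibs)
                if total > parent.prevalence_per_sample.get(s, 0.0) + 1e-9:
                    raise ValueError(
                        f"sibling prevalences under {parent_id} exceed parent in sample {s}"
                    )

    @property
    def samples(self) -> list[str]:
        return sorted(self.purity_per_sample)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {
            "clones",
            "purity_per_sample",
            "depth_mean",
            "overdispersion",
            "genome_length",
            "gc_content",
            "seed",
            "cn_segments",
            "mutant_copies",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        clones = [CloneSpec(**c) for c in raw.pop("clones")]
        segs = [CNSegment(**s) for s in raw.pop("cn_segments", [])]
        return cls(clones=clones, cn_segments=segs, **raw)


def expected_vaf(
    prevalence: float, purity: float, cn_state: float = 2.0, mutant_copies: int = 1
) -> float:
    """Closed-form expected VAF (percent) of a clonal mutation."""
    denom = purity * cn_state + (1.0 - purity) * 2.0
    if denom <= 0:
        raise ValueError("degenerate purity/copy-number combination")
    return 100.0 * prevalence * purity * mutant_copies / denom


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

def simulate_reference(length: int, gc: float = 0.4, seed: int = 0) -> str:
    """I.i.d. random DNA with P(G)+P(C)=gc, deterministic under ``seed``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0,1], got {gc}")
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = _rng(seed, "reference")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    return "".join(np.array(["A", "C", "G", "T"])[idx])


# ---------------------------------------------------------------------------
# Mutations with signature-aware site selection
# ---------------------------------------------------------------------------

def _context_pools(ref: np.ndarray) -> dict[str, np.ndarray]:
    """0-based interior site indices, split by base and neighbor context.

    Strand collapse: a G>A change is the C>T change on the opposite strand, so
    the 5' neighbor of its mutated pyrimidine is the complement of the
    reference base 3' of the G (pyrimidine iff that base is a purine), and
    vice versa for the 3' neighbor.
    """
    interior = np.arange(1, len(ref) - 1)
    base = ref[interior]
    prev = ref[interior - 1]
    nxt = ref[interior + 1]
    is_c = base == "C"
    is_g = base == "G"
    pyr_prev = np.isin(prev, ["C", "T"])
    pur_next = np.isin(nxt, ["A", "G"])
    pyr_next = np.isin(nxt, ["C", "T"])
    pur_prev = np.isin(prev, ["A", "G"])
    return {
        # 5' neighbor of the mutated pyrimidine is a pyrimidine
        "prev_pyr": interior[(is_c & pyr_prev) | (is_g & pur_next)],
        "prev_not": interior[(is_c & ~pyr_prev) | (is_g & ~pur_next)],
        # 3' neighbor of the mutated pyrimidine is a pyrimidine
        "next_pyr": interior[(is_c & pyr_next) | (is_g & pur_prev)],
        "next_not": interior[(is_c & ~pyr_next) | (is_g & ~pur_prev)],
        "any": interior[is_c | is_g],
    }


def simulate_mutations(
    config: SimConfig, reference: str, chrom: str = "chr1", patient_id: str = "SIM"
) -> list[MutationRecord]:
    """Draw C>T (and strand-equivalent G>A) mutations for every clone.

    ``uv_5prime`` clones place a fraction ``signature_strength`` of their
    mutations at sites whose 5' neighbor (in pyrimidine orientation) is a
    pyrimidine; ``pyr_3prime`` clones constrain the 3' neighbor instead;
    ``uniform`` clones draw C/G sites without context preference.  No two
    mutations share a position.
    """
    rng = _rng(config.seed, "mutations")
    ref = np.frombuffer(reference.upper().encode(), dtype="S1").astype("U1")
    pools = _context_pools(ref)
    used = np.zeros(len(ref), dtype=bool)

    def draw(pool: np.ndarray, k: int, clone_id: str) -> np.ndarray:
        avail = pool[~used[pool]]
        if len(avail) < k:
            raise ValueError(
                f"clone {clone_id}: only {len(avail)} eligible context positions for {k} mutations"
            )
        chosen = rng.choice(avail, size=k, replace=False)
        used[chosen] = True
        return chosen

    records: list[MutationRecord] = []
    for clone in config.clones:
        n = clone.n_mutations
        if clone.signature == "uniform":
            sites = draw(pools["any"], n, clone.clone_id)
        else:
            side = "prev" if clone.signature == "uv_5prime" else "next"
            k_ctx = rng.binomial(n, clone.signature_strength)
            sites = np.concatenate(
                [
                    draw(pools[f"{side}_pyr"], int(k_ctx), clone.clone_id),
                    draw(pools[f"{side}_not"], n - int(k_ctx), clone.clone_id),
                ]
            )
        for i in np.sort(sites):
            base = ref[i]
            alt = "T" if base == "C" else "A"
            records.append(
                MutationRecord(
                    patient_id=patient_id,
                    sample_id="",
                    chrom=chrom,
                    pos=int(i) + 1,  # to 1-based
                    ref=str(base),
                    alt=alt,
                    tier=1,
                    clone_id=clone.clone_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Readcounts
# ---------------------------------------------------------------------------

def simulate_readcounts(
    mutations: Sequence[MutationRecord], config: SimConfig
) -> list[ReadcountEntry]:
    """Draw per-sample depths and variant read counts for every mutation.

    Depth is Poisson(depth_mean) with zeros raised to 1; variant reads are
    binomial at the closed-form expected VAF, or beta-binomial when
    ``config.overdispersion`` (rho) is positive.
    """
    rng = _rng(config.seed, "readcounts")
    clones = {c.clone_id: c for c in config.clones}
    rho = config.overdispersion
    entries: list[ReadcountEntry] = []
    for sample in config.samples:
        purity = config.purity_per_sample[sample]
        for m in mutations:
            clone = clones[m.clone_id]
            prevalence = clone.prevalence_per_sample.get(sample, 0.0)
            cn = 2.0
            for seg in config.cn_segments:
                if seg.contains(m.chrom, m.pos):
                    cn = seg.cn_state
                    break
            p = expected_vaf(prevalence, purity, cn, config.mutant_copies) / 100.0
            depth = max(1, int(rng.poisson(config.depth_mean)))
            if p <= 0.0:
                var = 0
            elif rho > 0:
                ab = (1.0 - rho) / rho
                p_draw = rng.beta(p * ab, (1.0 - p) * ab)
                var = int(rng.binomial(depth, p_draw))
            else:
                var = int(rng.binomial(depth, min(p, 1.0)))
            entries.append(
                ReadcountEntry(
                    sample_id=sample,
                    chrom=m.chrom,
                    pos=m.pos,
                    alt=m.alt,
                    depth=depth,
                    var_reads=var,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Multi-sample patients with a known tree
# ---------------------------------------------------------------------------

@dataclass
class MultisampleSim:
    """Bundle emitted by :func:`simulate_multisample` for recovery tests."""

    mutations: list[MutationRecord]  # site-level, clone-labeled
    readcounts: list[ReadcountEntry]  # all samples
    mutations_by_sample: dict[str, list[MutationRecord]]
    true_tree_newick: str
    reference: str


def simulate_multisample(config: SimConfig) -> MultisampleSim:
    """Simulate every sample of one patient plus the noise-free truth tree.

    Trunk-clone mutations (prevalence > 0 everywhere) appear in all samples;
    private-clone mutations only where their clone's prevalence is positive.
    The truth tree is built from the noise-free expected purity-corrected VAF
    matrix (entry = 50 * prevalence), so it is fixed by construction.
    """
    if len(config.samples) < 2:
        raise ValueError("multisample simulation needs >= 2 samples")
    return _simulate_patient(config, with_tree=True)


def simulate_patient(config: SimConfig) -> MultisampleSim:
    """Like :func:`simulate_multisample` but accepts a single-sample patient
    (the truth tree is then empty: a tree needs at least two tumor taxa)."""
    return _simulate_patient(config, with_tree=len(config.samples) >= 2)


def _simulate_patient(config: SimConfig, with_tree: bool) -> MultisampleSim:
    reference = simulate_reference(config.genome_length, config.gc_content, config.seed)
    mutations = simulate_mutations(config, reference)
    readcounts = simulate_readcounts(mutations, config)
    clones = {c.clone_id: c for c in config.clones}
    by_sample: dict[str, list[MutationRecord]] = {s: [] for s in config.samples}
    for m in mutations:
        for s in config.samples:
            if clones[m.clone_id].prevalence_per_sample.get(s, 0.0) > 0:
                by_sample[s].append(
                    MutationRecord(
                        patient_id=m.patient_id,
                        sample_id=s,
                        chrom=m.chrom,
                        pos=m.pos,
                        ref=m.ref,
                        alt=m.alt,
                        tier=m.tier,
                        clone_id=m.clone_id,
                    )
                )

    newick = ""
    if with_tree:
        # truth tree from the noise-free expected corrected-VAF profiles
        from .io_formats import write_newick
        from .multisample import build_tree, distance_matrix_from_profiles

        profiles = {
            s: np.array(
                [50.0 * clones[m.clone_id].prevalence_per_sample.get(s, 0.0) for m in mutations]
            )
            for s in config.samples
        }
        profiles["normal"] = np.zeros(len(mutations))
        names, dist = distance_matrix_from_profiles(profiles)
        newick = write_newick(build_tree(dist, names))

    return MultisampleSim(
        mutations=mutations,
        readcounts=readcounts,
        mutations_by_sample=by_sample,
        true_tree_newick=newick,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# SV per-read alignment records
# ---------------------------------------------------------------------------

_SV_VIOLATIONS = (
    "ends",
    "substitutions",
    "indels",
    "score",
    "span",
    "flank_left",
    "flank_right",
    "reference_hit",
)


def simulate_sv_read_records(
    n_support_tumor: int,
    n_nonsupport_tumor: int,
    n_support_normal: int,
    n_nonsupport_normal: int,
    seed: int = 0,
    sv_id: str = "sv1",
    source: str = "capture",
) -> list[ReadAlignmentStat]:
    """Construct per-read alignment records with known support status.

    Supporting reads satisfy every acceptance threshold and span rule by
    construction; non-supporting reads violate exactly one rule each, cycling
    through the rule list so every failure mode is represented.
    """
    rng = _rng(seed, "sv")
    records: list[ReadAlignmentStat] = []
    counter = 0

    def good_contig(read_id: str, sample: str) -> ReadAlignmentStat:
        return ReadAlignmentStat(
            read_id=read_id,
            sv_id=sv_id,
            target="contig",
            unaligned_end_bases=int(rng.integers(0, 2)),
            pct_substitutions=float(rng.uniform(0, 1)),
            pct_indels=float(rng.uniform(0, 1)),
            score=float(rng.uniform(50, 90)),
            spans_breakpoint=True,
            flank_left=int(rng.integers(10, 40)),
            flank_right=int(rng.integers(10, 40)),
            sample=sample,
            source=source,
        )

    def bad_reference(read_id: str, sample: str) -> ReadAlignmentStat:
        return ReadAlignmentStat(
            read_id=read_id,
            sv_id=sv_id,
            target="reference",
            unaligned_end_bases=int(rng.integers(5, 20)),
            pct_substitutions=float(rng.uniform(3, 8)),
            pct_indels=float(rng.uniform(2, 5)),
            score=float(rng.uniform(10, 40)),
            sample=sample,
            source=source,
        )

    def emit(sample: str, n_support: int, n_nonsupport: int) -> None:
        nonlocal counter
        for _ in range(n_support):
            rid = f"{sv_id}.{sample}.r{counter}"
            counter += 1
            records.append(good_contig(rid, sample))
            records.append(bad_reference(rid, sample))
        for j in range(n_nonsupport):
            rid = f"{sv_id}.{sample}.r{counter}"
            counter += 1
            rule = _SV_VIOLATIONS[j % len(_SV_VIOLATIONS)]
            c = good_contig(rid, sample)
            if rule == "ends":
                c = replace(c, unaligned_end_bases=2)
            elif rule == "substitutions":
                c = replace(c, pct_substitutions=2.5)
            elif rule == "indels":
                c = replace(c, pct_indels=2.5)
            elif rule == "score":
                c = replace(c, score=49.0)
            elif rule == "span":
                c = replace(c, spans_breakpoint=False)
            elif rule == "flank_left":
                c = replace(c, flank_left=9)
            elif rule == "flank_right":
                c = replace(c, flank_right=9)
            records.append(c)
            if rule == "reference_hit":
                records.append(
                    ReadAlignmentStat(
                        read_id=rid,
                        sv_id=sv_id,
                        target="reference",
                        unaligned_end_bases=0,
                        pct_substitutions=0.2,
                        pct_indels=0.0,
                        score=70.0,
                        sample=sample,
                        source=source,
                    )
                )
            else:
                records.append(bad_reference(rid, sample))

    emit("tumor", n_support_tumor, n_nonsupport_tumor)
    emit("normal", n_support_normal, n_nonsupport_normal)
    return records
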
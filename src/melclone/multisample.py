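"""Shared/private mutation analysis and distance-based sample phylogenetics.

Multiple metastases from one patient are compared by (i) partitioning
mutations by the subset of samples carrying them, and (ii) building a
neighbor-joining tree over the samples plus an artificial all-zero "normal"
taxon from purity-corrected VAF profiles.  Correcting each sample's VAFs for
purity puts the profiles on a common cellular-prevalence scale before
distances are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .clonality import correct_vaf
from .types import MutationRecord, ReadcountEntry

NORMAL_TAXON = "normal"

MutKey = tuple[str, int, str]  # (chrom, pos, alt)


def _keys(muts: Iterable) -> set[MutKey]:
    out = set()
    for m in muts:
        if isinstance(m, (MutationRecord, ReadcountEntry)):
            out.add((m.chrom, m.pos, m.alt))
        else:
            out.add(tuple(m))
    return out


def shared_private(
    mutation_sets: Mapping[str, Iterable],
) -> tuple[dict[MutKey, tuple[str, ...]], dict[tuple[str, str], float]]:
    """Partition mutations by carrying samples; Jaccard shared fractions.

    Returns ``(partition, pairwise)`` where ``partition`` maps each mutation
    key to the sorted tuple of samples containing it and ``pairwise`` maps
    each sample pair to |A∩B| / |A∪B|.
    """
    if len(mutation_sets) < 2:
        raise ValueError("need >= 2 samples")
    sets = {s: _keys(muts) for s, muts in mutation_sets.items()}
    partition: dict[MutKey, tuple[str, ...]] = {}
    for key in set().union(*sets.values()):
        partition[key] = tuple(sorted(s for s, ks in sets.items() if key in ks))
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(sorted(sets), 2):
        union = sets[a] | sets[b]
        pairwise[(a, b)] = len(sets[a] & sets[b]) / len(union) if union else 1.0
    return partition, pairwise


@dataclass
class VafMatrix:
    """Mutations x samples matrix of purity-corrected VAF percents.

    The last column is always the artificial normal taxon (all zeros), which
    roots the tree.  ``present`` marks entries backed by an observed
    readcount; absent entries are 0 (mutation treated as absent from that
    sample).
    """

    keys: list[MutKey]
    samples: list[str]  # includes NORMAL_TAXON last
    values: np.ndarray  # shape (n_mutations, n_samples)
    present: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100 + 1e-9):
            raise ValueError("corrected VAFs must lie in [0, 100]")
        if np.any(self.values[:, -1] != 0):
            raise ValueError("normal column must be all zeros")


def build_vaf_matrix(
    readcounts_by_sample: Mapping[str, Iterable[ReadcountEntry]],
    purities: Mapping[str, float],
) -> VafMatrix:
    """Assemble the purity-corrected VAF matrix over all observed mutations.

    ``purities`` are percents in (0, 100].  A mutation missing from a sample
    contributes 0 (absence) with its presence mask cleared.
    """
    samples = sorted(readcounts_by_sample)
    missing = [s for s in samples if s not in purities]
    if missing:
        raise ValueError(f"purity missing for samples: {missing}")
    indexed = {
        s: {(e.chrom, e.pos, e.alt): e for e in entries}
        for s, entries in readcounts_by_sample.items()
    }
    keys = sorted(set().union(*(d.keys() for d in indexed.values())))
    values = np.zeros((len(keys), len(samples) + 1))
    present = np.zeros_like(values, dtype=bool)
    for i, key in enumerate(keys):
        for j, s in enumerate(samples):
            e = indexed[s].get(key)
            if e is not None:
                values[i, j] = correct_vaf(e.vaf, purities[s])
                present[i, j] = True
    present[:, -1] = True  # the normal is observed at 0 by definition
    return VafMatrix(keys=keys, samples=samples + [NORMAL_TAXON], values=values, present=present)


def distance_matrix(matrix: VafMatrix, metric: str = "manhattan") -> tuple[list[str], np.ndarray]:
    """Pairwise sample distances on the corrected-VAF profiles.

    ``manhattan`` is the mean absolute VAF difference; ``euclidean`` the
    root-mean-square difference.  Both stay on the [0, 100] VAF scale.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("empty VAF matrix")
    return matrix.samples, _profile_distances(matrix.values, metric)


def distance_matrix_from_profiles(
    profiles: Mapping[str, np.ndarray], metric: str = "manhattan"
) -> tuple[list[str], np.ndarray]:
    """Distance matrix from raw per-sample VAF profile vectors (same order)."""
    names = list(profiles)
    values = np.column_stack([np.asarray(profiles[n], dtype=float) for n in names])
    return names, _profile_distances(values, metric)


def _profile_distances(values: np.ndarray, metric: str) -> np.ndarray:
    k = values.shape[1]
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = values[:, i] - values[:, j]
            if metric == "manhattan":
                d = float(np.mean(np.abs(diff)))
            elif metric == "euclidean":
                d = float(np.sqrt(np.mean(diff**2)))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            dist[i, j] = dist[j, i] = d
    return dist


def neighbor_joining(dist: np.ndarray, names: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou–Nei agglomeration.  Negative branch lengths are clamped
    to zero with the deficit moved onto the sibling branch so path lengths
    between the joined pair are preserved.  The returned tree is unrooted
    (trifurcating root for >= 3 taxa).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(names):
        raise ValueError("distance matrix shape does not match taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if len(names) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=str(n)) for n in names]
    d = d.copy()
    active = list(range(len(names)))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        # clamp negatives, preserving li + lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent.extend([ni, nj])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [d.shape[0] - 1]

    # final three nodes join at one internal vertex (trifurcating root of the
    # unrooted tree); closed-form lengths l_i = (d_ij + d_ik - d_jk) / 2
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = float(max(length, 0.0))
        root.append(nodes[idx])
    return root


def build_tree(
    dist: np.ndarray, names: Sequence[str], root_on: str | None = NORMAL_TAXON
) -> TreeNode:
    """NJ tree over samples, rooted on the normal taxon when present."""
    tree = neighbor_joining(dist, names)
    if root_on is not None and root_on in [str(n) for n in names]:
        tip = tree.find(root_on)
        tree = tree.root_at(tip, above=True)
    return tree


def write_phylip_distances(
    names: Sequence[str], dist: np.ndarray, path: str, lower_triangle: bool = False
) -> None:
    """Export a distance matrix in PHYLIP format (10-character name field)."""
    with open(path, "w") as fh:
        fh.write(f"{len(names):5d}\n")
        for i, name in enumerate(names):
            field = str(name)[:10].ljust(10)
            cols = range(i) if lower_triangle else range(len(names))
            row = "  ".join(f"{dist[i, j]:.6f}" for j in cols)
            fh.write(f"{field}  {row}\n" if row else f"{field}\n")
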
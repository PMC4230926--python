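"""Shared/private partitioning, VAF matrices and neighbor-joining trees."""

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from melclone import (
    ReadcountEntry,
    build_tree,
    build_vaf_matrix,
    distance_matrix,
    neighbor_joining,
    shared_private,
)
from melclone.io_formats import read_newick, write_newick
from melclone.multisample import VafMatrix, write_phylip_distances


def rc(sample, pos, depth=100, var=25):
    return ReadcountEntry(sample, "chr1", pos, "T", depth, var)


class TestSharedPrivate:
    def test_identical_sets(self):
        sets = {"a": [rc("a", 1), rc("a", 2)], "b": [rc("b", 1), rc("b", 2)]}
        _, pairwise = shared_private(sets)
        assert pairwise[("a", "b")] == 1.0

    def test_disjoint_sets(self):
        sets = {"a": [rc("a", 1)], "b": [rc("b", 2)]}
        _, pairwise = shared_private(sets)
        assert pairwise[("a", "b")] == 0.0

    def test_jaccard_arithmetic(self):
        # |A ∩ B| = 90, |A ∪ B| = 100
        shared = [rc("a", p) for p in range(90)]
        a = shared + [rc("a", p) for p in range(1000, 1005)]
        b = [rc("b", p) for p in range(90)] + [rc("b", p) for p in range(2000, 2005)]
        partition, pairwise = shared_private({"a": a, "b": b})
        assert pairwise[("a", "b")] == pytest.approx(0.9)
        assert sum(1 for v in partition.values() if v == ("a", "b")) == 90


class TestVafMatrix:
    def test_full_purity_is_raw_vaf(self):
        m = build_vaf_matrix({"s": [rc("s", 1, 100, 25)]}, {"s": 100.0})
        assert m.values[0, 0] == pytest.approx(25.0)

    def test_purity_correction_applied(self):
        m = build_vaf_matrix({"s": [rc("s", 1, 100, 20)]}, {"s": 40.0})
        assert m.values[0, 0] == pytest.approx(50.0)

    def test_missing_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            build_vaf_matrix({"s": [rc("s", 1)]}, {})

    def test_absent_mutation_is_zero_with_mask(self):
        m = build_vaf_matrix(
            {"a": [rc("a", 1), rc("a", 2)], "b": [rc("b", 1)]}, {"a": 100.0, "b": 100.0}
        )
        i = m.keys.index(("chr1", 2, "T"))
        j = m.samples.index("b")
        assert m.values[i, j] == 0.0 and not m.present[i, j]

    def test_normal_column_zero(self):
        m = build_vaf_matrix({"a": [rc("a", 1)], "b": [rc("b", 1)]}, {"a": 80.0, "b": 60.0})
        assert m.samples[-1] == "normal" and np.all(m.values[:, -1] == 0)


class TestDistanceMatrix:
    def make(self, values):
        values = np.asarray(values, dtype=float)
        n, k = values.shape
        return VafMatrix(
            keys=[("chr1", i + 1, "T") for i in range(n)],
            samples=[f"s{j}" for j in range(k - 1)] + ["normal"],
            values=values,
            present=np.ones_like(values, dtype=bool),
        )

    def test_duplicate_columns_distance_zero(self):
        m = self.make([[30, 30, 0], [20, 20, 0]])
        _, d = distance_matrix(m)
        assert d[0, 1] == 0.0

    def test_constant_50_vs_normal(self):
        m = self.make([[50, 0], [50, 0], [50, 0]])
        _, d = distance_matrix(m)
        assert d[0, 1] == pytest.approx(50.0)

    def test_hand_computed_4x3(self):
        vals = [[40, 20, 0], [10, 30, 0], [0, 50, 0], [30, 30, 0]]
        m = self.make(vals)
        _, d = distance_matrix(m, metric="manhattan")
        # |40-20|+|10-30|+|0-50|+|30-30| = 90; /4 = 22.5
        assert d[0, 1] == pytest.approx(22.5)
        assert d[0, 2] == pytest.approx((40 + 10 + 0 + 30) / 4)
        assert d[1, 2] == pytest.approx((20 + 30 + 50 + 30) / 4)

    def test_metric_axioms_and_triangle(self, rng):
        vals = np.column_stack([rng.uniform(0, 100, 30) for _ in range(3)] + [np.zeros(30)])
        m = self.make(vals)
        _, d = distance_matrix(m)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        k = d.shape[0]
        for i, j, l in itertools.permutations(range(k), 3):
            assert d[i, j] <= d[i, l] + d[l, j] + 1e-9

    def test_empty_matrix_rejected(self):
        m = VafMatrix(keys=[], samples=["a", "normal"], values=np.zeros((0, 2)), present=np.zeros((0, 2), bool))
        with pytest.raises(ValueError):
            distance_matrix(m)


def random_additive_tree(names, rng):
    """Random binary topology with positive branch lengths; returns
    (TreeNode, distance matrix) with additive path-length distances."""
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.5, 5))
        b.length = float(rng.uniform(0.5, 5))
        parent.extend([b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    nodes[0].length = float(rng.uniform(0.5, 5))
    nodes[1].length = float(rng.uniform(0.5, 5))
    root.extend(nodes)
    tips = list(root.tips())
    dist = np.zeros((len(names), len(names)))
    idx = {t.name: k for k, t in enumerate(tips)}
    dm = root.tip_tip_distances()
    for a in names:
        for b in names:
            dist[names.index(a), names.index(b)] = dm[a, b]
    return root, dist


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(a,b)=3, d(a,c)=5, d(b,c)=6 -> La=1, Lb=2, Lc=4
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        # closed form: La = (dab + dac - dbc)/2, etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(4.0)

    def test_additive_four_taxon_recovery_vs_least_squares(self, rng):
        names = ["A", "B", "C", "D"]
        for _ in range(10):
            true, d = random_additive_tree(names, rng)
            nj = neighbor_joining(d, names)
            assert nj.compare_rfd(true, rooted=False) == 0.0
            # oracle: of the 3 possible quartet topologies, the generating one
            # minimizes the four-point condition residual
            pairings = [(("A", "B"), ("C", "D")), (("A", "C"), ("B", "D")), (("A", "D"), ("B", "C"))]
            sums = []
            for (p, q), (r, s) in pairings:
                i, j, k, l = (names.index(x) for x in (p, q, r, s))
                sums.append(d[i, j] + d[k, l])
            best = pairings[int(np.argmin(sums))]
            oracle = read_newick(f"(({best[0][0]},{best[0][1]}),({best[1][0]},{best[1][1]}));")
            assert nj.compare_rfd(oracle, rooted=False) == 0.0

    def test_additive_five_taxon_recovery(self, rng):
        names = list("ABCDE")
        for _ in range(10):
            true, d = random_additive_tree(names, rng)
            nj = neighbor_joining(d, names)
            assert nj.compare_rfd(true, rooted=False) == 0.0

    def test_agrees_with_skbio_nj(self, rng):
        """Independent implementation check against scikit-bio's NJ."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        names = list("ABCDEF")
        _, d = random_additive_tree(names, rng)
        ours = neighbor_joining(d, names)
        theirs = skbio_nj(DistanceMatrix(d, names))
        assert ours.compare_rfd(theirs, rooted=False) == 0.0

    def test_nan_and_asymmetry_rejected(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(d, list("abc"))
        d2 = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(d2, list("abc"))

    def test_no_negative_branch_lengths(self, rng):
        # noisy (non-additive) matrices can produce negative NJ estimates;
        # they must be clamped
        for _ in range(20):
            d = rng.uniform(0.1, 10, size=(5, 5))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = neighbor_joining(d, list("abcde"))
            assert all(n.length >= 0 for n in tree.traverse() if n.length is not None)

    def test_topology_invariant_to_uniform_scaling(self, rng):
        names = list("ABCD")
        _, d = random_additive_tree(names, rng)
        t1 = neighbor_joining(d, names)
        t2 = neighbor_joining(d * 7.3, names)
        assert t1.compare_rfd(t2, rooted=False) == 0.0


class TestBuildTree:
    def test_rooted_on_normal(self, rng):
        names = ["s1", "s2", "s3", "normal"]
        _, d = random_additive_tree(names, rng)
        tree = build_tree(d, names)
        # normal attaches directly at the root after outgroup rooting
        root_children_names = {c.name for c in tree.children}
        assert "normal" in root_children_names

    def test_private_clone_pair_siblings_and_divergence(self):
        """Two samples sharing a private clone come out as siblings and most
        distant from the normal."""
        from melclone import CloneSpec, SimConfig, simulate_multisample

        cfg = SimConfig(
            clones=[
                CloneSpec("trunk", {"sb1": 1.0, "sb2": 1.0, "sb3": 1.0, "ln": 1.0}, 150),
                CloneSpec(
                    "private23",
                    {"sb1": 0.0, "sb2": 0.8, "sb3": 0.8, "ln": 0.0},
                    150,
                    parent_id="trunk",
                ),
            ],
            purity_per_sample={"sb1": 0.5, "sb2": 0.7, "sb3": 0.6, "ln": 0.5},
            depth_mean=400.0,
            genome_length=60_000,
            seed=33,
        )
        sim = simulate_multisample(cfg)
        by_sample: dict[str, list] = {}
        for e in sim.readcounts:
            by_sample.setdefault(e.sample_id, []).append(e)
        purities = {s: 100.0 * p for s, p in cfg.purity_per_sample.items()}
        matrix = build_vaf_matrix(by_sample, purities)
        names, d = distance_matrix(matrix)
        tree = build_tree(d, names)
        sb2 = tree.find("sb2")
        sibling_names = {t.name for t in sb2.parent.tips()}
        assert sibling_names == {"sb2", "sb3"}
        i2, i3, inorm = names.index("sb2"), names.index("sb3"), names.index("normal")
        others = [names.index(s) for s in ("sb1", "ln")]
        assert d[i2, inorm] > max(d[o, inorm] for o in others)
        assert d[i3, inorm] > max(d[o, inorm] for o in others)


class TestPhylipExport:
    def test_ten_character_name_field(self, tmp_path, rng):
        names = ["longsamplename", "b", "normal"]
        _, d = random_additive_tree(names, rng)
        p = tmp_path / "dist.phy"
        write_phylip_distances(names, d, str(p))
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert lines[1][:10] == "longsample"
        assert len(lines[1].split()) == 4  # name + 3 distances
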
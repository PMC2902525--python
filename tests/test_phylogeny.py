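"""Distances, neighbor-joining, bootstrap, paralog discrimination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flcdna.phylogeny import (
    DistanceMatrix,
    MsaBlock,
    Relation,
    bootstrap_support,
    call_paralog,
    complete_deletion,
    distance_matrix,
    neighbor_joining,
    p_distance,
    poisson_correct,
)
from flcdna.synthetic_data import mutate


class TestCompleteDeletion:
    def test_single_gapped_column(self):
        msa = MsaBlock(["x", "y", "z"], ["AT-G", "ATAG", "ATCG"])
        out = complete_deletion(msa)
        assert out.rows == ["ATG", "ATG", "ATG"]
        assert out.n_columns_removed == 1

    def test_gap_free_block_unchanged(self):
        msa = MsaBlock(["x", "y", "z"], ["ATG", "ATA", "ATC"])
        assert complete_deletion(msa).rows == msa.rows

    def test_all_columns_gapped_rejected(self):
        with pytest.raises(ValueError):
            complete_deletion(MsaBlock(["x", "y", "z"], ["A-", "-A", "AA"]))

    def test_random_block_equals_column_filter_oracle(self, rng):
        chars = np.array(list("ACGT-"))
        rows = ["".join(chars[rng.integers(0, 5, 80)]) for _ in range(4)]
        msa = MsaBlock(list("abcd"), rows)
        keep = [i for i in range(80) if all(r[i] != "-" for r in rows)]
        expected = ["".join(r[i] for i in keep) for r in rows]
        assert complete_deletion(msa).rows == expected


class TestDistances:
    def test_p_distance_identical(self):
        assert p_distance("AAAA", "AAAA") == 0.0

    def test_p_distance_quarter(self):
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_p_distance_brute_force(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 100)])
        b = "".join(bases[rng.integers(0, 4, 100)])
        expected = sum(x != y for x, y in zip(a, b)) / 100
        assert p_distance(a, b) == expected

    @pytest.mark.parametrize(
        "p,d",
        [(0.0, 0.0), (0.5, math.log(2)), (0.1, 0.10536051565782628)],
    )
    def test_poisson_closed_forms(self, p, d):
        assert poisson_correct(p) == pytest.approx(d, abs=1e-12)

    def test_poisson_monotone_and_above_identity(self):
        grid = np.linspace(0.0, 0.95, 40)
        values = [poisson_correct(p) for p in grid]
        assert all(v2 > v1 for v1, v2 in zip(values, values[1:]))
        assert all(v >= p for v, p in zip(values, grid))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_poisson_dominates_p_everywhere(self, p):
        d = poisson_correct(p)
        assert d >= p
        assert d == pytest.approx(p, abs=1e-6) or p > 1e-4  # d ~ p for small p

    def test_saturated_distance_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            poisson_correct(1.0)


def _random_additive_tree(rng, n_leaves):
    """Random topology + branch lengths; returns (adjacency, leaf names)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    edges = {}  # node -> {node: length}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    add_edge(labels[0], labels[1], float(rng.uniform(0.1, 2)))
    internal = 0
    for leaf in labels[2:]:
        # split a random existing edge and hang the new leaf off it
        a = list(edges)[rng.integers(0, len(edges))]
        b = list(edges[a])[rng.integers(0, len(edges[a]))]
        w = edges[a].pop(b)
        edges[b].pop(a)
        mid = f"n{internal}"
        internal += 1
        cut = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * cut)
        add_edge(mid, b, w * (1 - cut))
        add_edge(mid, leaf, float(rng.uniform(0.1, 2)))
    return edges, labels


def _tree_metric(edges, labels):
    import heapq

    out = np.zeros((len(labels), len(labels)))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in edges[u].items():
                if d + w < dist.get(v, np.inf):
                    dist[v] = d + w
                    heapq.heappush(heap, (d + w, v))
        for j, dst in enumerate(labels):
            out[i, j] = dist[dst]
    np.fill_diagonal(out, 0.0)
    return out


class TestNeighborJoining:
    WORKED = DistanceMatrix(
        ["a", "b", "c", "d"],
        np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        ),
    )

    def test_worked_four_taxon_example_exact(self):
        """Additive matrix from ((a:1,b:2):1,(c:3,d:4)): NJ recovers the
        topology and every branch length."""
        tree = neighbor_joining(self.WORKED)
        assert tree.bipartitions() == {frozenset({"a", "b"})}
        ld = tree.leaf_distances()
        for i, x in enumerate(self.WORKED.taxa):
            for j, y in enumerate(self.WORKED.taxa):
                if i < j:
                    assert ld[(x, y)] == pytest.approx(
                        self.WORKED.matrix[i, j], abs=1e-12
                    )

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.root.children}
        assert lengths["a"] == pytest.approx(0.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], m)

    def test_random_additive_matrices_reproduced(self):
        """Tree-metric reproduction to 1e-9 on random additive 6-taxon
        matrices (NJ consistency)."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            edges, labels = _random_additive_tree(rng, 6)
            metric = _tree_metric(edges, labels)
            tree = neighbor_joining(DistanceMatrix(labels, metric))
            ld = tree.leaf_distances()
            for i, x in enumerate(labels):
                for j, y in enumerate(labels):
                    if i < j:
                        key = (min(x, y), max(x, y))
                        assert abs(ld[key] - metric[i, j]) < 1e-9

    def test_against_independent_nj_implementation(self):
        """Topology agreement with scikit-bio's neighbor joining on a
        generic (non-additive) matrix."""
        import skbio

        rng = np.random.default_rng(23)
        n = 6
        m = rng.uniform(0.2, 1.5, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = neighbor_joining(DistanceMatrix(labels, m)).bipartitions()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
        theirs = set()
        all_taxa = frozenset(labels)
        for node in sk_tree.non_tips(include_self=False):
            under = frozenset(t.name for t in node.tips())
            if 1 < len(under) < n - 1:
                theirs.add(min(under, all_taxa - under, key=lambda s: sorted(s)))
        assert ours == theirs


class TestBootstrap:
    def _clean_signal_msa(self):
        # columns are either constant or split ab|cd: zero homoplasy
        col_ab = "AATT"
        col_const = "GGGG"
        cols = [col_ab] * 30 + [col_const] * 30
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        return MsaBlock(list("abcd"), rows)

    def test_zero_homoplasy_gives_full_support(self):
        tree = bootstrap_support(self._clean_signal_msa(), n_reps=200, seed=4)
        supports = [n.support for n in tree.internal_nodes()]
        assert supports and all(s == 100.0 for s in supports)

    def test_seeded_reproducibility(self):
        msa = MsaBlock(
            list("abcd"),
            [
                mutate("ACGT" * 30, r, seed=i)
                for i, r in enumerate((0.0, 0.05, 0.2, 0.25))
            ],
        )
        t1 = bootstrap_support(msa, n_reps=300, seed=9)
        t2 = bootstrap_support(msa, n_reps=300, seed=9)
        s1 = [n.support for n in t1.internal_nodes()]
        s2 = [n.support for n in t2.internal_nodes()]
        assert s1 == s2

    def test_monte_carlo_stability(self):
        rng = np.random.default_rng(31)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        rows = [
            base,
            mutate(base, 0.05, rng=rng),
            mutate(base, 0.25, rng=rng),
            mutate(base, 0.30, rng=rng),
        ]
        msa = MsaBlock(list("abcd"), rows)
        t_small = bootstrap_support(msa, n_reps=1000, seed=1)
        t_big = bootstrap_support(msa, n_reps=10000, seed=2)
        s_small = sorted(n.support for n in t_small.internal_nodes())
        s_big = sorted(n.support for n in t_big.internal_nodes())
        for a, b in zip(s_small, s_big):
            assert abs(a - b) <= 2.0

    def test_invalid_rep_count(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._clean_signal_msa(), n_reps=0)


class TestParalogCalls:
    def test_allelic_direction(self, rng):
        x1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        x2 = mutate(x1, 0.002, rng=rng)  # tight within-species pair
        y = mutate(x1, 0.02, rng=rng)  # cross-species ortholog
        v = call_paralog(x1, x2, y, n_reps=500, rng=rng)
        assert v.verdict is Relation.ALLELIC_VARIANTS
        assert v.d_within < v.d_cross_min
        assert v.support >= 70

    def test_paralog_direction(self, rng):
        x1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        x2 = mutate(x1, 0.08, rng=rng)  # pre-speciation duplicate
        y = mutate(x1, 0.02, rng=rng)
        v = call_paralog(x1, x2, y, n_reps=500, rng=rng)
        assert v.verdict is Relation.PARALOGS
        assert v.d_cross_min < v.d_within

    def test_rule_antisymmetry(self, rng):
        """Swapping the within/cross roles flips the verdict."""
        x1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        dup = mutate(x1, 0.08, rng=rng)
        ortho = mutate(x1, 0.02, rng=rng)
        as_paralog = call_paralog(x1, dup, ortho, n_reps=500, seed=8)
        as_allelic = call_paralog(x1, ortho, dup, n_reps=500, seed=8)
        assert as_paralog.verdict is Relation.PARALOGS
        assert as_allelic.verdict is Relation.ALLELIC_VARIANTS

    def test_verdicts_on_simulated_triples(self, clean_sim):
        rng = np.random.default_rng(2)
        for t in clean_sim.triples:
            v = call_paralog(*t.seqs, ids=t.ids, n_reps=500, rng=rng)
            want = Relation.PARALOGS if t.relation == "paralog" else Relation.ALLELIC_VARIANTS
            assert v.verdict is want

    def test_unaligned_triple_aligned_first(self, rng):
        x1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        x2 = mutate(x1, 0.002, indel_rate=0.005, rng=rng)
        y = mutate(x1, 0.02, rng=rng)
        v = call_paralog(x1, x2, y, n_reps=500, rng=rng)
        assert v.verdict is Relation.ALLELIC_VARIANTS
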
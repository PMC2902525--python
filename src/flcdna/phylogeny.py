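"""Distance-based phylogeny: Poisson-corrected distances, neighbor-joining,
column-resampling bootstrap, and paralog-vs-allelic-variant discrimination.

The duplication analysis rests on a two-species argument: allelic variation
within one species should be smaller than the divergence between orthologs
of two (closely related) species. For a triple — two highly similar
sequences X1, X2 from one species and a putative ortholog Y from the other —
the sequences are aligned, gapped columns removed (complete deletion),
p-distances Poisson-corrected (d = -ln(1 - p)), and the pair is called
paralogous when min(d(X1,Y), d(X2,Y)) < d(X1,X2) with bootstrap support,
allelic when the inequality is reversed.

For triples, bipartition support on an unrooted 3-leaf tree is undefined
(the topology is unique), so bootstrap support is computed on the operative
statistic itself: the percentage of column-resampled replicates in which
the distance inequality holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MsaBlock",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "ParalogVerdict",
    "complete_deletion",
    "p_distance",
    "poisson_correct",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "call_paralog",
]

GAP = "-"


@dataclass
class MsaBlock:
    """An aligned block: equal-length rows over taxa (protein or DNA)."""

    taxa: list[str]
    rows: list[str]
    n_columns_removed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def complete_deletion(msa: MsaBlock) -> MsaBlock:
    """Remove every column containing a gap in any row."""
    cols = [
        i
        for i in range(msa.n_sites)
        if all(row[i] != GAP for row in msa.rows)
    ]
    if not cols:
        raise ValueError("complete deletion removed every column")
    removed = msa.n_sites - len(cols)
    return MsaBlock(
        taxa=list(msa.taxa),
        rows=["".join(row[i] for i in cols) for row in msa.rows],
        n_columns_removed=removed,
    )


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing sites between two equal-length gap-free rows."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    if not row_i:
        raise ValueError("zero-length rows")
    diff = sum(1 for a, b in zip(row_i, row_j) if a != b)
    return diff / len(row_i)


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p), defined for p < 1."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"saturated distance: p = {p} not in [0, 1)")
    return -math.log1p(-p)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        self.matrix = (m + m.T) / 2  # remove float-epsilon asymmetry


def distance_matrix(msa: MsaBlock, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise distances after complete deletion has been applied.

    ``correction`` is "poisson" (default) or "p" for the raw proportion.
    """
    n = len(msa.taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(msa.rows[i], msa.rows[j])
            d = poisson_correct(p) if correction == "poisson" else p
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=list(msa.taxa), matrix=m)


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0  # branch to parent
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root node."""

    root: TreeNode
    taxa: list[str]

    @property
    def has_negative_lengths(self) -> bool:
        def walk(node: TreeNode) -> bool:
            return any(c.length < 0 or walk(c) for c in node.children)

        return walk(self.root)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every leaf pair (tree metric)."""
        # distance from every node to every leaf below it, then combine at
        # each internal node across child subtrees
        dist: dict[tuple[str, str], float] = {}

        def below(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            per_child = []
            for c in node.children:
                d = {leaf: v + c.length for leaf, v in below(c).items()}
                per_child.append(d)
            for a in range(len(per_child)):
                for b in range(a + 1, len(per_child)):
                    for la, va in per_child[a].items():
                        for lb, vb in per_child[b].items():
                            key = (min(la, lb), max(la, lb))
                            dist[key] = va + vb
            merged: dict[str, float] = {}
            for d in per_child:
                merged.update(d)
            return merged

        below(self.root)
        return dist

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each canonicalized as the leaf set on
        the child side of the edge or its complement, whichever sorts first."""
        all_taxa = frozenset(self.taxa)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            under = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and len(under) > 1 and len(all_taxa - under) > 1:
                side = min(under, all_taxa - under, key=lambda s: sorted(s))
                parts.add(side)
            return under

        walk(self.root)
        return parts

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6g}"

        return fmt(self.root) + ";"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j;
    branch lengths from the standard NJ formulas (negative lengths are
    retained, flagged on the tree). Exact Q ties are broken by the
    lexicographic order of the joined pair's smallest leaf names, so the
    result is deterministic. Consistent on additive matrices: recovers the
    generating tree exactly.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    reps = list(dm.taxa)  # smallest leaf name under each active node

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q = np.minimum(Q, Q.T)  # symmetrize 1-ulp subtraction-order noise
        Q[np.tril_indices(m)] = np.inf  # search the upper triangle only
        qmin = Q.min()
        ties = [
            (i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] == qmin
        ]
        i, j = min(ties, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        new_rep = min(reps[i], reps[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [new_rep]

    # closing three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root, taxa=list(dm.taxa))


def _resample_msa(msa: MsaBlock, rng: np.random.Generator) -> MsaBlock:
    idx = rng.integers(0, msa.n_sites, size=msa.n_sites)
    arr = np.array([list(row) for row in msa.rows])
    return MsaBlock(taxa=list(msa.taxa), rows=["".join(r) for r in arr[:, idx]])


def bootstrap_support(
    msa: MsaBlock,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    correction: str = "poisson",
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """NJ tree with per-internal-edge bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; support for an
    internal edge is the percentage of replicate trees containing its
    bipartition. Replicates with a saturated distance (p = 1) contribute to
    the denominator but to no bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = neighbor_joining(distance_matrix(msa, correction))
    # map each internal node of the base tree to its bipartition
    all_taxa = frozenset(base.taxa)
    node_part: list[tuple[TreeNode, frozenset[str]]] = []

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        under = frozenset().union(*(walk(c) for c in node.children))
        if node is not base.root and len(under) > 1 and len(all_taxa - under) > 1:
            side = min(under, all_taxa - under, key=lambda s: sorted(s))
            node_part.append((node, side))
        return under

    walk(base.root)

    hits = {id(node): 0 for node, _ in node_part}
    for _ in range(n_reps):
        rep = _resample_msa(msa, rng)
        try:
            tree = neighbor_joining(distance_matrix(rep, correction))
        except ValueError:  # saturated replicate
            continue
        parts = tree.bipartitions()
        for node, part in node_part:
            if part in parts:
                hits[id(node)] += 1
    for node, _ in node_part:
        node.support = 100.0 * hits[id(node)] / n_reps
    return base


class Relation(str, Enum):
    PARALOGS = "paralogs"
    ALLELIC_VARIANTS = "allelic_variants"
    AMBIGUOUS = "ambiguous"


@dataclass
class ParalogVerdict:
    id_x1: str
    id_x2: str
    id_y: str
    verdict: Relation
    d_within: float
    d_cross_min: float
    support: float  # % of bootstrap replicates agreeing with the verdict
    saturated: bool = False


def _anchor_align(x1: str, x2: str, y: str) -> list[str]:
    """Quick triple alignment anchored on X1: X2 and Y are each globally
    aligned to X1 and their residues projected onto X1's coordinates
    (insertions relative to X1 are dropped; complete deletion follows)."""
    from .cross_species import _make_aligner

    aligner = _make_aligner(1.0, -1.0, -2.0)

    def project(other: str) -> str:
        aln = aligner.align(x1, other)[0]
        row_ref, row_other = aln[0], aln[1]
        out = []
        for a, b in zip(row_ref, row_other):
            if a != GAP:
                out.append(b)
        return "".join(out)

    return [x1, project(x2), project(y)]


def call_paralog(
    x1: str,
    x2: str,
    y: str,
    ids: tuple[str, str, str] = ("X1", "X2", "Y"),
    n_reps: int = 1000,
    support_threshold: float = 70.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ParalogVerdict:
    """Discriminate paralogs from allelic variants for one triple.

    X1, X2 are the two highly similar sequences from one species, Y the
    putative ortholog from the other. Equal-length inputs are taken as
    aligned; unequal lengths are aligned first (anchored on X1). Verdict:
    paralogs when min(d(X1,Y), d(X2,Y)) < d(X1,X2) and the inequality holds
    in >= ``support_threshold`` % of column-resampled bootstrap replicates;
    allelic_variants for the reverse inequality; ambiguous otherwise (or
    when distances are saturated).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len({len(x1), len(x2), len(y)}) != 1:
        rows = _anchor_align(x1, x2, y)
    else:
        rows = [x1, x2, y]
    msa = complete_deletion(MsaBlock(taxa=list(ids), rows=rows))
    arr = np.array([list(r) for r in msa.rows])
    L = arr.shape[1]
    diff12 = arr[0] != arr[1]
    diff1y = arr[0] != arr[2]
    diff2y = arr[1] != arr[2]
    p12 = diff12.mean()
    p_cross = min(diff1y.mean(), diff2y.mean())
    if p12 >= 1.0 or max(diff1y.mean(), diff2y.mean()) >= 1.0:
        return ParalogVerdict(
            *ids, Relation.AMBIGUOUS, float("inf"), float("inf"), 0.0, saturated=True
        )
    d_within = poisson_correct(float(p12))
    d_cross_min = poisson_correct(float(p_cross))

    # Poisson correction is monotone, so the d-inequality per replicate is
    # exactly the p-inequality: bootstrap on p, immune to saturation.
    idx = rng.integers(0, L, size=(n_reps, L))
    b12 = diff12[idx].mean(axis=1)
    b_cross = np.minimum(diff1y[idx].mean(axis=1), diff2y[idx].mean(axis=1))
    support_paralog = 100.0 * float(np.mean(b_cross < b12))
    support_allelic = 100.0 * float(np.mean(b12 < b_cross))

    if d_cross_min < d_within and support_paralog >= support_threshold:
        verdict, support = Relation.PARALOGS, support_paralog
    elif d_within < d_cross_min and support_allelic >= support_threshold:
        verdict, support = Relation.ALLELIC_VARIANTS, support_allelic
    else:
        verdict, support = Relation.AMBIGUOUS, max(support_paralog, support_allelic)
    return ParalogVerdict(
        ids[0], ids[1], ids[2], verdict, d_within, d_cross_min, support
    )
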
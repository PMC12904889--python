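"""Trees: newick I/O, NJ fallback, split sets, weighted Robinson-Foulds.

Maximum-likelihood inference is delegated to IQ-TREE (command construction
only, with ModelFinder left at its default and 1,000 ultrafast bootstrap
replicates).  For fixture-scale work a deterministic neighbor-joining
implementation over p-distances stands in: NJ is exact on additive
distances, which is all the test substrate requires.

Tree comparison uses the weighted Robinson-Foulds distance: the sum over
the union of bipartitions of the absolute branch-length difference, with a
split absent from one tree contributing length 0 there.  Since the raw
distance is unbounded, a transformed similarity 1 - wRF/(L1+L2) (L_i =
total branch length) is reported alongside it; it lies in [0,1], equals 1
for identical trees, and is monotone decreasing in the distance.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ParseError, ValidationError
from .supermatrix import Supermatrix

Tree = dendropy.Tree

DEFAULT_UFBOOT = 1000

#: Characters ignored when counting comparable sites for p-distances.
MISSING_CHARS = frozenset({"-", "?", "N", "n", "X", "x"})


def build_treeinference_command(aln_path: str, threads: int = 1) -> list[str]:
    """IQ-TREE 2 argument vector: automatic model selection, UFboot 1000."""
    if not str(aln_path):
        raise ValidationError("alignment path must be non-empty")
    if threads < 1:
        raise ValidationError(f"threads must be >= 1, got {threads}")
    return [
        "iqtree2",
        "-s", str(aln_path),
        "-B", str(DEFAULT_UFBOOT),
        "-T", str(threads),
    ]


def parse_newick(text: str) -> Tree:
    """Parse a newick string; internal labels and underscores preserved."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ParseError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError(f"negative branch length {edge.length}")
    return tree


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Tree) -> str:
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    return out.getvalue().strip()


def leaf_labels(tree: Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        if (self.d < 0).any():
            raise ValidationError("distances must be non-negative")


def p_distance_matrix(sm: Supermatrix) -> DistanceMatrix:
    """Pairwise mismatch fractions over comparable (non-missing) sites."""
    labels = sm.genomes
    if len(labels) < 2:
        raise ValidationError("need at least 2 rows for a distance matrix")
    arr = sm.to_array()
    ok = ~np.isin(arr, list(MISSING_CHARS))
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        comparable = int(both.sum())
        if comparable == 0:
            raise ValidationError(
                f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
            )
        mism = int((arr[i][both] != arr[j][both]).sum())
        d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(labels=list(labels), d=d)


def nj(dist: DistanceMatrix) -> Tree:
    """Neighbor-joining with deterministic tie-breaking.

    Q-criterion agglomeration; ties in Q are broken by the smallest (i, j)
    index pair in the current node ordering (new nodes append at the end).
    Negative branch-length estimates are clamped to 0.  Returns an unrooted
    tree (trifurcating root).  Exact on additive distance matrices.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValidationError(f"NJ needs at least 3 taxa, got {n}")
    d = dist.d.astype(float).copy()
    nodes = list(dist.labels)  # newick fragments

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((len(keep) + 1, len(keep) + 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [merged]

    # final trifurcation
    (a, b, c), dd = nodes, d
    la = max(0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2]), 0.0)
    lb = max(0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2]), 0.0)
    lc = max(0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1]), 0.0)
    newick = f"({a}:{la:.10g},{b}:{lb:.10g},{c}:{lc:.10g});"
    return parse_newick(newick)


def splits(tree: Tree) -> dict[frozenset, float]:
    """Canonical split set with branch lengths.

    Each edge contributes the bipartition induced by removing it, keyed by
    the side NOT containing the lexicographically smallest leaf; lengths of
    edges inducing the same split (the two root-adjacent edges of a rooted
    binary tree) are summed, so the set is invariant to rooting.  Trivial
    (pendant) splits are included with their pendant lengths.
    """
    leaves = leaf_labels(tree)
    if len(leaves) < 2:
        raise ValidationError("need at least 2 leaves")
    anchor = leaves[0]
    full = frozenset(leaves)
    out: dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below == full:
            continue
        key = frozenset(full - below) if anchor in below else below
        length = node.edge.length or 0.0
        out[key] = out.get(key, 0.0) + length
    return out


def total_branch_length(tree: Tree) -> float:
    return sum(
        (e.length or 0.0) for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )


def _check_same_leaves(t1: Tree, t2: Tree) -> None:
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise ValidationError(
            f"trees have different leaf sets; symmetric difference: "
            f"{sorted(l1 ^ l2)}"
        )


def weighted_rf(t1: Tree, t2: Tree) -> float:
    """Weighted Robinson-Foulds distance: sum of |len1(s) - len2(s)| over
    the union of splits, with absent splits contributing 0."""
    _check_same_leaves(t1, t2)
    s1, s2 = splits(t1), splits(t2)
    return sum(
        abs(s1.get(s, 0.0) - s2.get(s, 0.0)) for s in set(s1) | set(s2)
    )


def transformed_similarity(t1: Tree, t2: Tree) -> float:
    """1 - wRF / (L1 + L2); in [0,1], 1 for identical trees."""
    d = weighted_rf(t1, t2)
    total = total_branch_length(t1) + total_branch_length(t2)
    if total == 0:
        return 1.0 if d == 0 else 0.0
    return 1.0 - d / total


def rf_topology_distance(t1: Tree, t2: Tree) -> int:
    """Unweighted RF distance over non-trivial splits (topology check)."""
    _check_same_leaves(t1, t2)
    nontrivial = lambda ss: {s for s in ss if 1 < len(s) < len(leaf_labels(t1)) - 1}
    a, b = nontrivial(splits(t1)), nontrivial(splits(t2))
    return len(a ^ b)
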
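"""Concatenated-protein distance phylogenetics.

The tree deliverable is a Saitou–Nei neighbor-joining tree over Poisson- or
p-distances on a concatenated (supermatrix) alignment of the three cluster
proteins, with nonparametric bootstrap supports mapped onto the point
estimate.  Clade assignment (the seven cluster groups, and the mtrC
subfamilies MtrC/MtrF/OmcA/UndA/MtrG/MtrH) is exemplar-supervised by
nearest patristic distance.  Trees are :class:`skbio.tree.TreeNode`
objects; all tie-breaking is lexicographic on labels so every result is
deterministic.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio.tree import TreeNode

SUBFAMILIES = ("MtrC", "MtrF", "OmcA", "UndA", "MtrG", "MtrH")


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Concatenated alignment: rows are cluster ids, columns tile per-gene
    partitions without overlap."""

    leaves: list[str]
    partitions: list[tuple[str, tuple[int, int]]]  # gene -> [start, end) columns
    matrix: np.ndarray  # dtype '<U1', shape (n_leaves, n_columns)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, leaf: str) -> str:
        return "".join(self.matrix[self.leaves.index(leaf)])


def concatenate(
    alignments: dict[str, dict[str, str]],
    index: dict[str, dict[str, str]],
    gene_order: tuple[str, ...] = ("mtrA", "mtrB", "mtrC"),
) -> Supermatrix:
    """Concatenate per-gene alignments into one supermatrix.

    ``alignments`` maps gene -> {sequence id -> aligned row};
    ``index`` maps cluster id -> {gene -> sequence id}.  Clusters missing
    any gene are excluded with a warning.  Unequal row lengths within one
    gene's alignment are an error.
    """
    widths: dict[str, int] = {}
    for gene in gene_order:
        aln = alignments[gene]
        lens = {len(s) for s in aln.values()}
        if len(lens) > 1:
            raise ValueError(f"alignment for {gene} has unequal row lengths: {sorted(lens)}")
        widths[gene] = lens.pop() if lens else 0

    leaves = []
    for cid in sorted(index):
        missing = [
            g for g in gene_order
            if g not in index[cid] or index[cid][g] not in alignments[g]
        ]
        if missing:
            warnings.warn(f"cluster {cid} missing genes {missing}; excluded from supermatrix")
            continue
        leaves.append(cid)

    partitions = []
    offset = 0
    for gene in gene_order:
        partitions.append((gene, (offset, offset + widths[gene])))
        offset += widths[gene]

    rows = []
    for cid in leaves:
        rows.append("".join(alignments[g][index[cid][g]] for g in gene_order))
    matrix = np.array([list(r) for r in rows], dtype="<U1") if rows else np.empty((0, offset), dtype="<U1")
    return Supermatrix(leaves=leaves, partitions=partitions, matrix=matrix)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def protein_distance(sm: Supermatrix, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise p-distance over columns where both rows are non-gap.

    ``correction='poisson'`` applies -ln(1 - p); saturated pairs (p >= 1
    under correction) and pairs with no comparable columns are errors.
    """
    if len(sm.leaves) < 2:
        raise ValueError("need at least 2 leaves for distances")
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    n = len(sm.leaves)
    mat = sm.matrix
    nongap = mat != "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {sm.leaves[i]} and {sm.leaves[j]}"
                )
            p = float((mat[i][comparable] != mat[j][comparable]).sum()) / total
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance (p={p}) between {sm.leaves[i]} and {sm.leaves[j]}"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=list(sm.leaves), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _quote_label(label: str) -> str:
    """Newick-quote a label when it contains structural characters."""
    if any(ch in label for ch in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label, children=None):
        self.label = label  # lexicographically smallest tip underneath
        self.children = children or []  # list of (child, branch_length)

    def newick(self, top=True) -> str:
        if not self.children:
            s = _quote_label(self.label)
        else:
            s = "(" + ",".join(
                f"{c.newick(False)}:{bl:.10g}" for c, bl in self.children
            ) + ")"
        return s + ";" if top else s


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Deterministic: ties on Q broken lexicographically by the (sorted)
    labels of the joined nodes.  A negative branch length is clamped to 0
    with the deficit transferred to its sibling branch, preserving the
    joined pair's path length.  Returns an unrooted tree (trifurcating
    root) as a scikit-bio TreeNode.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes = [_Node(lbl) for lbl in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(len(nodes)))

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((nodes[i].label, nodes[j].label)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = _Node(min(nodes[i].label, nodes[j].label), [(nodes[i], li), (nodes[j], lj)])
        # reuse row i for the new node
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
            d[i, k] = d[k, i] = duk
        nodes[i] = u
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = _Node(
        min(nodes[i].label, nodes[j].label, nodes[k].label),
        [(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)), (nodes[k], max(lk, 0.0))],
    )
    tree = TreeNode.read(_io.StringIO(root.newick()), convert_underscores=False)
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, RF, monophyly
# ---------------------------------------------------------------------------

def _all_sides(tree: TreeNode) -> set[frozenset[str]]:
    """Every bipartition side of an unrooted tree, both orientations,
    including the trivial (single-tip) ones."""
    all_tips = frozenset(t.name for t in tree.tips())
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if node.children else frozenset({node.name})
        if 0 < len(side) < len(all_tips):
            sides.add(side)
            sides.add(all_tips - side)
    return sides


def nontrivial_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions, canonicalized to the side not containing
    the lexicographically smallest tip."""
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if not node.children:
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        out.add(all_tips - side if ref in side else side)
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds symmetric difference of nontrivial bipartitions."""
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    if tips1 != tips2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = nontrivial_bipartitions(t1), nontrivial_bipartitions(t2)
    return len(b1 ^ b2)


def monophyly_fraction(tree: TreeNode, taxa: dict[str, str]) -> float:
    """Fraction of rank labels (with >= 2 leaves) whose leaf set is one side
    of some bipartition of the unrooted tree."""
    groups: dict[str, set[str]] = {}
    for leaf, label in taxa.items():
        groups.setdefault(label, set()).add(leaf)
    multi = {lbl: frozenset(s) for lbl, s in groups.items() if len(s) >= 2}
    if not multi:
        raise ValueError("no rank label has >= 2 leaves; monophyly fraction undefined")
    sides = _all_sides(tree)
    n_tips = len(list(tree.tips()))
    mono = 0
    for leafset in multi.values():
        if leafset in sides or len(leafset) == n_tips:
            mono += 1
    return mono / len(multi)


def is_monophyletic(tree: TreeNode, leafset: set[str]) -> bool:
    n_tips = len(list(tree.tips()))
    fs = frozenset(leafset)
    return len(fs) == n_tips or fs in _all_sides(tree)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    sm: Supermatrix, n: int, seed: int, correction: str = "poisson"
) -> TreeNode:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    ``n`` column resamplings with replacement (over all supermatrix
    columns); the support of each internal bipartition of the point
    estimate is the percentage of replicate trees containing it.  Supports
    are stored as ``node.support`` (floats in [0, 100]) and as internal
    node names.  The point-estimate topology does not depend on the seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 bootstrap replicates")
    point = nj_tree(protein_distance(sm, correction))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in nontrivial_bipartitions(point)}
    rng = np.random.default_rng(seed)
    n_cols = sm.n_columns
    for _ in range(n):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = Supermatrix(
            leaves=list(sm.leaves),
            partitions=[("resampled", (0, n_cols))],
            matrix=sm.matrix[:, cols],
        )
        rep_bps = nontrivial_bipartitions(nj_tree(protein_distance(rep, correction)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_tips = frozenset(t.name for t in point.tips())
    ref = min(all_tips)
    for node in point.traverse(include_self=False):
        if not node.children:
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        canon = all_tips - side if ref in side else side
        support = 100.0 * counts[canon] / n
        node.support = support
        node.name = str(int(round(support)))
    return point


# ---------------------------------------------------------------------------
# Exemplar-supervised clade assignment
# ---------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    """Leaf -> group map plus per-group monophyly flags."""

    groups: dict[str, str] = field(default_factory=dict)
    monophyletic: dict[str, bool] = field(default_factory=dict)


def _nearest_label(
    tree: TreeNode, references: dict[str, str], tol: float = 1e-9
) -> dict[str, str]:
    tip_names = [t.name for t in tree.tips()]
    missing = [r for r in references if r not in tip_names]
    if missing:
        raise ValueError(f"reference leaves absent from tree: {sorted(missing)}")
    dm = tree.tip_tip_distances()
    out: dict[str, str] = {}
    for leaf in tip_names:
        if leaf in references:
            out[leaf] = references[leaf]
            continue
        best: dict[str, float] = {}
        for ref, grp in references.items():
            dist = dm[leaf, ref]
            if grp not in best or dist < best[grp]:
                best[grp] = dist
        ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) <= tol:
            out[leaf] = "unassigned"
        else:
            out[leaf] = ranked[0][0]
    return out


def assign_groups(tree: TreeNode, exemplars: dict[str, str]) -> GroupAssignment:
    """Assign every leaf the group of its nearest exemplar (patristic
    distance); ties between groups leave a leaf unassigned.  Each induced
    group is flagged for monophyly."""
    groups = _nearest_label(tree, exemplars)
    assignment = GroupAssignment(groups=groups)
    for grp in sorted(set(exemplars.values())):
        leafset = {l for l, g in groups.items() if g == grp}
        assignment.monophyletic[grp] = bool(leafset) and is_monophyletic(tree, leafset)
    return assignment


def classify_mtrC_subfamily(
    mtrC_tree: TreeNode, references: dict[str, str]
) -> tuple[dict[str, str], dict[str, bool]]:
    """Assign mtrC-family leaves to subfamilies by nearest reference.

    All six subfamilies must be represented among the references; ties
    yield 'unclassified'.  Returns (assignment, per-subfamily monophyly).
    """
    present = set(references.values())
    absent = [s for s in SUBFAMILIES if s not in present]
    if absent:
        raise ValueError(f"missing references for subfamilies: {absent}")
    raw = _nearest_label(mtrC_tree, references)
    assignment = {l: ("unclassified" if g == "unassigned" else g) for l, g in raw.items()}
    mono = {}
    for sub in SUBFAMILIES:
        leafset = {l for l, g in assignment.items() if g == sub}
        mono[sub] = bool(leafset) and is_monophyletic(mtrC_tree, leafset)
    return assignment, mono


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)
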
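"""Distance-based phylogeny stage: concatenation, K2P distances, neighbor
joining, bootstrap support, outgroup rooting.

This is deliberately a desk-scale stage: per-gene alignments are
concatenated into a supermatrix, pairwise distances are computed under
the Kimura two-parameter model (or as raw p-distances), and the tree is
built with Saitou-Nei neighbor joining, which recovers the generating
topology and branch lengths exactly on additive matrices.  Branch
support comes from nonparametric bootstrap over supermatrix columns.
All tie-breaking is deterministic (taxon-label order) and the single
integer seed governs every random draw, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

GAP_CHARS = set("-.?NX")


class SaturationError(ValueError):
    """Distance formula undefined (log argument <= 0)."""


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column_subset(self, idx: Sequence[int]) -> "Supermatrix":
        rows = {t: "".join(self.rows[t][i] for i in idx) for t in self.taxa}
        return Supermatrix(taxa=list(self.taxa), rows=rows, partitions=[])

    def partition_text(self) -> str:
        """RAxML-style partition lines."""
        return "\n".join(f"DNA, {g} = {a}-{b}" for g, a, b in self.partitions)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read one aligned FASTA into {taxon: row}; duplicate labels are errors."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"{path}: duplicate taxon label {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return rows


def concatenate(
    alignments: Mapping[str, Mapping[str, str]],
    gene_order: Optional[Sequence[str]] = None,
) -> Supermatrix:
    """Join per-gene alignments into a supermatrix.

    Genes are concatenated in ``gene_order`` if given, else in sorted
    gene-name order — never in input order, so shuffled inputs yield an
    identical matrix.  Taxa missing from a gene get gap columns there.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    order = list(gene_order) if gene_order is not None else sorted(alignments)
    taxa = sorted({t for g in alignments.values() for t in g})
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for gene in order:
        aln = alignments[gene]
        width = len(next(iter(aln.values())))
        if any(len(s) != width for s in aln.values()):
            raise ValueError(f"gene {gene}: rows have unequal lengths")
        for t in taxa:
            rows[t].append(aln.get(t, "-" * width))
        partitions.append((gene, pos, pos + width - 1))
        pos += width
    return Supermatrix(
        taxa=taxa, rows={t: "".join(parts) for t, parts in rows.items()}, partitions=partitions
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _comparable_sites(a: str, b: str):
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        yield x, y


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites (pairwise deletion of gaps/ambiguity)."""
    if len(a) != len(b):
        raise ValueError("rows must be aligned to equal length")
    n = diff = 0
    for x, y in _comparable_sites(a, b):
        n += 1
        diff += x != y
    if n == 0:
        raise ValueError("no comparable sites")
    return diff / n


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance, d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are the transition and transversion proportions over sites
    with unambiguous bases in both rows.  Raises
    :class:`SaturationError` when the log argument is non-positive.
    """
    if len(a) != len(b):
        raise ValueError("rows must be aligned to equal length")
    n = ts = tv = 0
    for x, y in _comparable_sites(a, b):
        n += 1
        if x == y:
            continue
        same_class = ({x, y} <= _PURINES) or ({x, y} <= _PYRIMIDINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    arg = (1 - 2 * P - Q) * math.sqrt(max(0.0, 1 - 2 * Q))
    if arg <= 0:
        raise SaturationError(f"K2P undefined at P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(arg)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def to_phylip(self) -> str:
        lines = [str(len(self.taxa))]
        for i, t in enumerate(self.taxa):
            lines.append(
                t + "  " + "  ".join(f"{x:.6f}" for x in self.matrix[i])
            )
        return "\n".join(lines) + "\n"


SATURATION_FALLBACK = 5.0  # substitutions/site stand-in for saturated pairs


def distance_matrix(m: Supermatrix, method: str = "k2p") -> DistanceMatrix:
    """All pairwise distances over a supermatrix (pairwise gap deletion)."""
    fn = {"k2p": k2p_distance, "p": p_distance}[method]
    taxa = sorted(m.taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = fn(m.rows[taxa[i]], m.rows[taxa[j]])
            except SaturationError:
                dij = SATURATION_FALLBACK
                saturated.append((taxa[i], taxa[j]))
            d[i, j] = d[j, i] = dij
    if saturated:
        warnings.warn(f"{len(saturated)} saturated pair(s) set to {SATURATION_FALLBACK}")
    return DistanceMatrix(taxa=taxa, matrix=d, saturated_pairs=saturated)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    label: Optional[str] = None  # taxon name for leaves
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode
    rooted: bool = False
    clamped_negative_branches: int = 0
    outgroup_monophyletic: Optional[bool] = None

    def taxa(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, blen: Optional[float]) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                lab = ""
                if include_support and node.support is not None:
                    lab = f"{node.support:g}"
                s = f"({inner}){lab}"
            if blen is not None:
                s += f":{blen:.6f}"
            return s

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as the leaf set on one side of each
        internal edge, canonicalized to the side without the smallest taxon."""
        all_taxa = frozenset(self.root.leaves())
        ref = min(all_taxa)
        out = set()
        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_taxa) - (0 if self.rooted else 1):
                    canon = side if ref not in side else all_taxa - side
                    if 1 < len(canon) < len(all_taxa):
                        out.add(canon)
                walk(child)
        walk(self.root)
        return out


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Exact on additive matrices.  Ties in the Q criterion are broken by
    the lexicographically smallest (label, label) pair, where an internal
    node inherits the smallest label beneath it; negative branch lengths
    are clamped to zero and counted on the returned tree.  The result is
    unrooted, represented with a trifurcating root for n >= 3.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(d.taxa)  # tie-break keys
    nodes = [TreeNode(label=t) for t in d.taxa]
    dist = {
        (i, j): float(d.matrix[i, j])
        for i in range(n)
        for j in range(n)
        if i != j
    }
    active = list(range(n))
    next_id = n
    clamped = 0

    def D(i, j):
        return dist[(i, j)] if i != j else 0.0

    blen_of: dict[int, float] = {}
    parent_children: dict[int, list[int]] = {}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        u = next_id
        next_id += 1
        labels.append(min(labels[i], labels[j]))
        nodes.append(None)  # placeholder; built at the end
        parent_children[u] = [i, j]
        blen_of[i], blen_of[j] = li, lj
        for k in active:
            if k in (i, j):
                continue
            duk = (D(i, k) + D(j, k) - dij) / 2
            dist[(u, k)] = dist[(k, u)] = max(0.0, duk)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = (D(i, j) + D(i, k) - D(j, k)) / 2
    lj = (D(i, j) + D(j, k) - D(i, k)) / 2
    lk = (D(i, k) + D(j, k) - D(i, j)) / 2
    for idx, l in ((i, li), (j, lj), (k, lk)):
        if l < 0:
            clamped += 1
            l = 0.0
        blen_of[idx] = l
    root_id = next_id
    parent_children[root_id] = [i, j, k]

    def build(idx: int) -> TreeNode:
        if idx < n:
            return nodes[idx]
        node = TreeNode()
        for c in parent_children[idx]:
            node.children.append((build(c), blen_of[c]))
        return node

    return Tree(root=build(root_id), rooted=False, clamped_negative_branches=clamped)


def root_with_outgroup(t: Tree, outgroup_taxa: Sequence[str]) -> Tree:
    """Root an unrooted tree on the edge separating the outgroup.

    If the outgroup is not monophyletic in the unrooted tree, the root is
    placed (deterministically) on the edge whose split contains all
    outgroup taxa on one side with the fewest extra taxa, and the result
    is flagged via ``outgroup_monophyletic=False``.
    """
    import copy

    t = Tree(
        root=copy.deepcopy(t.root),
        rooted=t.rooted,
        clamped_negative_branches=t.clamped_negative_branches,
    )
    og = frozenset(outgroup_taxa)
    all_taxa = frozenset(t.root.leaves())
    if not og:
        raise ValueError("empty outgroup")
    missing = og - all_taxa
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if og == all_taxa:
        raise ValueError("outgroup cannot be all taxa")

    # collect candidate edges: (extra taxa count, tiebreak, parent, child index)
    best = None

    def walk(node: TreeNode, path):
        nonlocal best
        for ci, (child, blen) in enumerate(node.children):
            side = frozenset(child.leaves())
            for candidate in (side, all_taxa - side):
                if og <= candidate:
                    extra = len(candidate) - len(og)
                    on_child_side = og <= side
                    key = (extra, tuple(sorted(side)), len(path))
                    if best is None or key < best[0]:
                        best = (key, node, ci, on_child_side)
            walk(child, path + [ci])

    walk(t.root, [])
    assert best is not None
    key, parent, ci, on_child_side = best
    monophyletic = key[0] == 0
    child, blen = parent.children[ci]

    # re-hang the tree so the chosen edge carries the root
    new_root = TreeNode()
    # detach child from parent
    parent.children = [c for idx, c in enumerate(parent.children) if idx != ci]
    rest = _reattach_upward(t.root, parent)
    og_side, in_side = (child, rest) if on_child_side else (rest, child)
    new_root.children = [(og_side, blen / 2), (in_side, blen / 2)]
    return Tree(
        root=new_root,
        rooted=True,
        clamped_negative_branches=t.clamped_negative_branches,
        outgroup_monophyletic=monophyletic,
    )


def _reattach_upward(root: TreeNode, node: TreeNode) -> TreeNode:
    """Re-orient the tree so ``node`` becomes the apex of the remainder.

    Every edge on the path from the old root down to ``node`` is
    reversed; branch lengths travel with their edges, so path lengths
    are preserved.  A unary apex (possible when the chosen edge hung off
    the old root of an already-rooted tree) is left in place — it is
    harmless in newick and keeps lengths additive.
    """
    if node is root:
        return node
    parent_of = {}

    def index(n: TreeNode):
        for c, b in n.children:
            parent_of[id(c)] = (n, b)
            index(c)

    index(root)
    path = []
    cur = node
    while id(cur) in parent_of:
        p, b = parent_of[id(cur)]
        path.append((p, cur, b))
        cur = p
    for p, c, b in path:
        p.children = [(x, xb) for x, xb in p.children if x is not c]
        c.children.append((p, b))
    return node


def bootstrap_support(
    m: Supermatrix, B: int, seed: int, method: str = "k2p"
) -> Tree:
    """NJ tree on the full matrix with bootstrap supports on internal edges.

    Columns are resampled with replacement ``B`` times; each replicate is
    rebuilt with the same distance method and NJ, and an internal edge's
    support is the percentage of replicates whose tree contains that
    bipartition.  Supports are invariant to taxon input order for a
    fixed seed because taxa are sorted before any computation.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    full = nj_tree(distance_matrix(m, method))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = m.n_columns
    for _ in range(B):
        idx = rng.integers(0, ncol, size=ncol)
        rep = m.column_subset(list(idx))
        try:
            rep_tree = nj_tree(distance_matrix(rep, method))
        except ValueError:
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1

    all_taxa = frozenset(m.taxa)
    ref = min(all_taxa)

    def annotate(node: TreeNode):
        for child, _ in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                canon = side if ref not in side else all_taxa - side
                if canon in counts:
                    child.support = 100.0 * counts[canon] / B
            annotate(child)

    annotate(full.root)
    return full
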
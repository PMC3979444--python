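"""Alignment statistics, neighbor-joining phylogeny, and group delineation.

Distances are amino-acid p-distances under pairwise deletion: for each pair
of rows, columns where either row carries a gap (or X) are excluded and the
distance is the fraction of mismatches among the remaining columns.  Trees
are built with the Saitou–Nei neighbor-joining agglomeration and supported by
nonparametric bootstrap over alignment columns.  Group delineation follows a
support-threshold policy on clades that are pure for one taxonomic order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .seqcore import ProteinRecord, SeqcoreError

GAP = "-"
MISSING = {GAP, "X", "?"}


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Msa
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """A multiple sequence alignment: id -> gapped row, all equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise PhyloError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def n_col(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def ungapped_to_column(self, rid: str) -> list[int]:
        """1-based column of each ungapped residue of row ``rid``, in order."""
        return [i + 1 for i, ch in enumerate(self.rows[rid]) if ch != GAP]

    def subset(self, ids: Sequence[str]) -> "Msa":
        return Msa({i: self.rows[i] for i in ids})

    def columns(self, idx: Sequence[int]) -> "Msa":
        """New alignment keeping 0-based columns ``idx`` in the given order."""
        return Msa({k: "".join(v[i] for i in idx) for k, v in self.rows.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "fasta")
        return cls({r.id.split("|")[0]: str(r.seq).upper() for r in aln})

    @classmethod
    def from_clustal(cls, path: str | Path) -> "Msa":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "clustal")
        return cls({r.id: str(r.seq).upper() for r in aln})

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in self.rows.items():
                fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # (n, n) p-distances
    v: np.ndarray | None = None  # valid-site counts per pair

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def pdistance(msa: Msa) -> DistanceMatrix:
    """Amino-acid p-distance with pairwise deletion of gaps and X.

    For each pair, columns where either row has a gap/X are excluded; the
    distance is mismatches / valid columns.  A pair with zero valid columns
    is an error (it carries no signal at all).
    """
    ids = msa.ids
    if len(ids) < 2:
        raise PhyloError("need at least 2 rows")
    arr = np.array([list(msa.rows[i]) for i in ids])
    ok = ~np.isin(arr, sorted(MISSING))
    n = len(ids)
    d = np.zeros((n, n))
    v = np.zeros((n, n), dtype=int)
    np.fill_diagonal(v, msa.n_col)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            nv = int(both.sum())
            if nv == 0:
                raise PhyloError(
                    f"pair ({ids[i]}, {ids[j]}) has no shared ungapped columns"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / nv
            v[i, j] = v[j, i] = nv
    return DistanceMatrix(ids, d, v)


def count_informative(msa: Msa) -> tuple[int, int]:
    """Total columns and parsimony-informative columns.

    A column is informative iff at least two distinct non-missing states each
    occur at least twice.
    """
    n_col = msa.n_col
    n_inf = 0
    rows = list(msa.rows.values())
    for c in range(n_col):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[c]
            if ch not in MISSING:
                counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for k in counts.values() if k >= 2) >= 2:
            n_inf += 1
    return n_col, n_inf


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

class Node:
    """Tree node; ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("name", "children", "parent", "length", "support", "length_clamped")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support: float | None = None
        self.length_clamped = False

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for ch in self.children:
            yield from ch.postorder()
        yield self

    def preorder(self):
        yield self
        for ch in self.children:
            yield from ch.preorder()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.postorder() if n.is_leaf)


class Tree:
    """Phylogeny with branch lengths and per-bipartition bootstrap supports.

    Neighbor-joining trees are unrooted and stored with a trifurcating root.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- basic access -----------------------------------------------------
    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def postorder(self):
        return self.root.postorder()

    def preorder(self):
        return self.root.preorder()

    def find_clade(self, names: Iterable[str]) -> Node | None:
        want = frozenset(names)
        for node in self.root.postorder():
            if node.leaf_names() == want:
                return node
        return None

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each canonicalized as the side *not*
        containing the lexicographically smallest leaf name."""
        all_leaves = self.leaf_names
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def bipartition_nodes(self) -> dict[frozenset[str], Node]:
        all_leaves = self.leaf_names
        ref = min(all_leaves)
        out: dict[frozenset[str], Node] = {}
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            key = all_leaves - side if ref in side else side
            if 2 <= len(key) <= len(all_leaves) - 2:
                out[key] = node
        return out

    # -- newick ------------------------------------------------------------
    def to_newick(self, support_labels: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if support_labels and node.support is not None:
                    s += f"{node.support:g}"
                elif node.name:
                    s += node.name
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            node = Node(
                name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
                length=dnode.edge.length,
            )
            label = dnode.label
            if label is not None and not dnode.is_leaf():
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            for ch in dnode.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))

    def copy(self) -> "Tree":
        return Tree.from_newick(self.to_newick())


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with a deterministic tie-break.

    The pair minimizing the rate-corrected criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` is joined; ties are broken on the
    lexicographically smallest (label_i, label_j) pair, where a cluster's
    label is the smallest leaf name it contains.  Negative branch-length
    estimates are clamped to zero and flagged.  The result is unrooted,
    returned with a trifurcating root.
    """
    n0 = len(dist.ids)
    if n0 < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    D = dist.d.astype(float).copy()
    nodes = [Node(name=i) for i in dist.ids]
    labels = list(dist.ids)
    active = list(range(n0))

    def set_length(node: Node, length: float) -> None:
        if length < 0:
            node.length = 0.0
            node.length_clamped = True
        else:
            node.length = float(length)

    while len(active) > 3:
        m = len(active)
        # sum addends in value order so r (hence Q) is bit-identical under
        # any permutation of the input rows
        r = {
            i: float(np.sum(np.sort([D[i, k] for k in active if k != i])))
            for i in active
        }
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                # r[i] + r[j] grouped: addition commutes in IEEE floats, so
                # q is bit-identical under input-row permutation
                q = (m - 2) * D[i, j] - (r[i] + r[j])
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        if labels[j] < labels[i]:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = Node()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances to the new cluster
        new = min(i, j)
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[new] = parent
        labels[new] = min(labels[i], labels[j])
        active.remove(max(i, j))

    a, b, c = sorted(active, key=lambda k: labels[k])
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        set_length(nodes[k], lk)
        root.add(nodes[k])
    return Tree(root)


def bootstrap_support(
    msa: Msa, n_reps: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree from ``msa`` with column-bootstrap supports (percent).

    Columns are resampled with replacement per replicate and the NJ tree is
    rebuilt; the support of each bipartition of the point-estimate tree is
    the percentage of replicates containing it.  A replicate leaving some
    pair with no shared ungapped columns is redrawn (up to 100 attempts).
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    tree = nj_tree(pdistance(msa))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    n_col = msa.n_col
    for _ in range(n_reps):
        for attempt in range(100):
            cols = rng.integers(0, n_col, size=n_col)
            try:
                rep_dist = pdistance(msa.columns(list(cols)))
                break
            except PhyloError:
                warnings.warn("bootstrap replicate had an all-gap pair; redrawn")
        else:
            raise PhyloError("100 consecutive bootstrap replicates failed")
        rep_bips = nj_tree(rep_dist).bipartitions()
        for bp in counts:
            if bp in rep_bips:
                counts[bp] += 1
    for bp, node in tree.bipartition_nodes().items():
        node.support = 100.0 * counts[bp] / n_reps
    return tree


# ---------------------------------------------------------------------------
# Group delineation
# ---------------------------------------------------------------------------

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV"]


@dataclass
class GroupAssignment:
    """Delineated phylogenetic groups plus leaves left as separate LPs."""

    groups: dict[str, list[str]]
    supports: dict[str, dict[str, float]]
    types: dict[str, list[str]] = field(default_factory=dict)
    orders: dict[str, str] = field(default_factory=dict)
    separate: list[str] = field(default_factory=list)


def delineate_groups(
    tree: Tree,
    type_calls: Mapping[str, str],
    orders: Mapping[str, str],
    strong: float = 90.0,
    member: float = 80.0,
    extra_supports: Mapping[str, Mapping[frozenset, float]] | None = None,
    exclude: Iterable[str] = (),
) -> GroupAssignment:
    """Delineate maximal well-supported, order-pure clades as groups.

    A clade qualifies when, over all available methods (the tree's own
    bootstrap plus any external per-bipartition support tables, e.g. from ML
    or MP analyses), either every support exceeds ``strong``, or every
    support exceeds ``member`` and at least one exceeds ``strong`` — and all
    its leaves share one taxonomic order.  Maximal qualifying clades are
    groups, named by the sorted set of LP types they contain, with Roman
    numerals appended when several groups share a type set.  Leaves in no
    qualifying clade are reported as separate LPs.  ``exclude`` removes
    outgroup ids from consideration.
    """
    extra_supports = extra_supports or {}
    excluded = set(exclude)
    all_leaves = tree.leaf_names - excluded
    ref = min(tree.leaf_names)

    def clade_supports(node: Node) -> list[float] | None:
        side = node.leaf_names()
        key = side if ref not in side else tree.leaf_names - side
        sups = []
        if node.support is not None:
            sups.append(node.support)
        for table in extra_supports.values():
            if key in table:
                sups.append(table[key])
        return sups or None

    def qualifies(node: Node) -> bool:
        leaves = node.leaf_names()
        if len(leaves) < 2 or leaves & excluded:
            return False
        ords = {orders.get(l, "") for l in leaves}
        if len(ords) != 1:
            return False
        sups = clade_supports(node)
        if not sups:
            return False
        if all(s > strong for s in sups):
            return True
        return all(s > member for s in sups) and any(s > strong for s in sups)

    picked: list[Node] = []

    def descend(node: Node) -> None:
        if node is not tree.root and not node.is_leaf and qualifies(node):
            picked.append(node)
            return
        for ch in node.children:
            descend(ch)

    descend(tree.root)

    # name groups in preorder (display) order
    order_index = {id(n): k for k, n in enumerate(tree.preorder())}
    picked.sort(key=lambda n: order_index[id(n)])
    typesets = []
    for node in picked:
        ts = sorted({type_calls.get(l, "?") for l in node.leaf_names()})
        typesets.append(" and ".join(ts))
    counts: dict[str, int] = {}
    for ts in typesets:
        counts[ts] = counts.get(ts, 0) + 1
    seen: dict[str, int] = {}
    groups: dict[str, list[str]] = {}
    supports: dict[str, dict[str, float]] = {}
    types: dict[str, list[str]] = {}
    group_orders: dict[str, str] = {}
    grouped: set[str] = set()
    for node, ts in zip(picked, typesets):
        if counts[ts] > 1:
            seen[ts] = seen.get(ts, 0) + 1
            name = f"{ts} {_ROMAN[seen[ts] - 1]}"
        else:
            name = ts
        members = sorted(node.leaf_names())
        groups[name] = members
        grouped |= set(members)
        sup: dict[str, float] = {}
        if node.support is not None:
            sup["NJ"] = node.support
        side = node.leaf_names()
        key = side if ref not in side else tree.leaf_names - side
        for method, table in extra_supports.items():
            if key in table:
                sup[method] = table[key]
        supports[name] = sup
        types[name] = sorted({type_calls.get(l, "?") for l in members})
        group_orders[name] = orders.get(members[0], "")
    separate = sorted(all_leaves - grouped)
    return GroupAssignment(groups, supports, types, group_orders, separate)


def species_monophyly_index(
    tree: Tree, species: Mapping[str, str], group: Iterable[str]
) -> float | None:
    """Fraction of multi-copy species in ``group`` whose copies are
    monophyletic within the group's clade.

    1.0 indicates concerted-evolution-like clustering (paralogs homogenized
    within each genome), 0.0 birth-and-death-like interleaving of species.
    Returns None when the group has no species with two or more copies.
    """
    members = frozenset(group)
    clade = tree.find_clade(members)
    if clade is None:
        raise PhyloError("group is not a clade of the tree")
    by_species: dict[str, set[str]] = {}
    for m in members:
        by_species.setdefault(species.get(m, m), set()).add(m)
    multi = {sp: ids for sp, ids in by_species.items() if len(ids) >= 2}
    if not multi:
        return None
    clade_sets = {node.leaf_names() for node in clade.postorder()}
    mono = sum(1 for ids in multi.values() if frozenset(ids) in clade_sets)
    return mono / len(multi)


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _load_matrix(name: str):
    from Bio.Align import substitution_matrices

    return substitution_matrices.load(name)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    denom = min(len(ka), len(kb))
    return 1.0 - len(ka & kb) / denom if denom else 1.0


def _profile_align(
    rows_a: list[str], rows_b: list[str], score: Callable[[str, str], float],
    gap_open: float, gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Gotoh affine-gap global alignment of two profiles.

    Column pairs are scored by the average substitution score over residue
    pairs (gap residues contribute 0).  Tie-break order: diagonal, then gap
    in B (up), then gap in A (left) — deterministic.
    """
    la, lb = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(la)]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(lb)]

    # column-pair scores as (residue-count profile) x S x (profile)^T,
    # averaged over all row pairs; gap residues contribute zero
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    a_idx = {ch: k for k, ch in enumerate(alphabet)}
    S = np.array([[score(x, y) for y in alphabet] for x in alphabet])

    def profile_counts(cols: list[str]) -> np.ndarray:
        out = np.zeros((len(cols), len(alphabet)))
        for i, col in enumerate(cols):
            for ch in col:
                if ch != GAP:
                    out[i, a_idx.get(ch, a_idx["X"])] += 1
        return out

    CA = profile_counts(cols_a)
    CB = profile_counts(cols_b)
    pair_scores = (CA @ S @ CB.T) / (len(rows_a) * len(rows_b))

    def colscore(i: int, j: int) -> float:
        return float(pair_scores[i - 1, j - 1])

    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = colscore(i, j)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i or j) else 0
        elif state == 1:
            out_a.append(cols_a[i - 1])
            out_b.append(GAP * len(rows_b))
            take_m = M[i - 1, j] - gap_open >= X[i - 1, j] - gap_extend
            i -= 1
            state = 0 if take_m else 1
        else:
            out_a.append(GAP * len(rows_a))
            out_b.append(cols_b[j - 1])
            take_m = M[i, j - 1] - gap_open >= Y[i, j - 1] - gap_extend
            j -= 1
            state = 0 if take_m else 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    out_a.reverse()
    out_b.reverse()
    n = len(out_a)
    new_a = ["".join(out_a[c][r] for c in range(n)) for r in range(len(rows_a))]
    new_b = ["".join(out_b[c][r] for c in range(n)) for r in range(len(rows_b))]
    return new_a, new_b


def align_progressive(
    records: Sequence[ProteinRecord],
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    matrix: str = "BLOSUM62",
) -> Msa:
    """Progressive multiple alignment with a k-mer NJ guide tree.

    The guide tree is a neighbor-joining tree on 3-mer set distances;
    profiles are merged bottom-up with affine-gap (Gotoh) global alignment.
    Deterministic; de-gapping any output row returns its input sequence.
    """
    if len(records) < 2:
        raise PhyloError("need at least 2 sequences")
    for rec in records:
        if not rec.residues:
            raise PhyloError(f"empty sequence: {rec.id!r}")
    mat = _load_matrix(matrix)

    def score(x: str, y: str) -> float:
        try:
            return float(mat[x, y])
        except (KeyError, IndexError):
            return 0.0

    seqs = {r.id: r.residues for r in records}
    ids = [r.id for r in records]
    if len(records) == 2:
        a, b = _profile_align([seqs[ids[0]]], [seqs[ids[1]]], score,
                              gap_open, gap_extend)
        return Msa({ids[0]: a[0], ids[1]: b[0]})

    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[ids[i]], seqs[ids[j]])
    guide = nj_tree(DistanceMatrix(ids, d))

    def merge(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [seqs[node.name]]
        child_profiles = [merge(ch) for ch in node.children]
        ids_acc, rows_acc = child_profiles[0]
        for ids_b, rows_b in child_profiles[1:]:
            rows_acc, rows_b = _profile_align(rows_acc, rows_b, score,
                                              gap_open, gap_extend)
            ids_acc = ids_acc + ids_b
            rows_acc = rows_acc + rows_b
        return ids_acc, rows_acc

    out_ids, out_rows = merge(guide.root)
    rows = dict(zip(out_ids, out_rows))
    return Msa({i: rows[i] for i in ids})
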
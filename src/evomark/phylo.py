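"""Per-site substitution rates and gene-level conservation from a time tree.

A :class:`TimeTree` is a rooted phylogeny whose branch lengths are divergence
times in million years (Myr).  For each alignment column the tree is pruned to
the taxa that carry a residue at that column; the evolutionary time span ``t``
of the column is the total branch length of the pruned tree (stem excluded),
the substitution count ``s`` comes from either the number of distinct residues
("distinct" mode) or minimum-change parsimony ("fitch" mode), and the absolute
substitution rate is ``r = 1000 * s / t`` in substitutions per billion years.
The gene-level rate ``R`` is the mean ``r`` over counted columns and its
reciprocal ``1/R`` is the evolutionary weight used downstream.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "AlignmentError",
    "Node",
    "TimeTree",
    "ProteinAlignment",
    "SiteRate",
    "GeneConservation",
    "parse_newick",
    "total_tree_length",
    "prune_to_taxa",
    "count_substitutions",
    "site_rates",
    "gene_rate",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
AMBIGUOUS = "X"


class TreeError(ValueError):
    """Structural problem with a tree or a tree operation."""


class AlignmentError(ValueError):
    """Structural problem with an alignment or a column operation."""


class Node:
    """A tree node with a parent link and a branch length to its parent.

    ``branch_length`` is ``None`` exactly at the root; everywhere else it is a
    non-negative duration in Myr.
    """

    __slots__ = ("name", "branch_length", "children", "parent")

    def __init__(self, name: str | None = None,
                 branch_length: float | None = None) -> None:
        self.name = name
        self.branch_length = branch_length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or '?'} {kind} bl={self.branch_length}>"


class TimeTree:
    """Rooted tree with branch lengths in million years."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if any(not n for n in names):
            raise TreeError("every leaf must carry a non-empty name")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf names: {sorted(dupes)}")
        no_length = [node.name or "<internal>" for node in self.preorder()
                     if node is not self.root and node.branch_length is None]
        if no_length:
            raise TreeError(
                f"missing branch length on node(s): {', '.join(repr(n) for n in no_length)}")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.branch_length < 0:
                raise TreeError(
                    f"negative branch length on node {node.name or '<internal>'}"
                )
            if not node.is_leaf and len(node.children) < 2:
                raise TreeError("internal node with a single child")

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_leaf)

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]

    def __len__(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (Myr); the root's stem contributes 0."""
        return sum(n.branch_length or 0.0 for n in self.preorder())

    def scale(self, factor: float) -> "TimeTree":
        """Return a copy with all branch lengths multiplied by ``factor``."""
        def _copy(node: Node) -> Node:
            new = Node(node.name,
                       None if node.branch_length is None
                       else node.branch_length * factor)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return TimeTree(_copy(self.root))

    def newick(self) -> str:
        def _fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(_fmt(c) for c in node.children) + ")"
            if node.branch_length is not None:
                body += f":{node.branch_length:g}"
            return body

        return _fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {len(self)} leaves, {self.total_length:g} Myr>"


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string with branch lengths into a :class:`TimeTree`.

    Raises
    ------
    TreeError
        On duplicate leaf names, missing branch lengths (other than the
        root's), or malformed input.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate taxon" in msg or "Multiple occurrences" in msg:
            raise TreeError(f"duplicate leaf names in Newick input: {msg}") from exc
        raise TreeError(f"malformed Newick input: {msg}") from exc

    def _convert(dnode: dendropy.Node) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(name=name, branch_length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    # collapse unary chains at the root so "(A:7);" parses as a lone leaf with
    # a 7-Myr stem (total length 7); the stem is kept on degenerate trees only
    while len(root.children) == 1:
        child = root.children[0]
        if root.branch_length is not None:
            child.branch_length = (child.branch_length or 0.0) + root.branch_length
        child.parent = None
        root = child
    if not root.children and root.name is None:
        raise TreeError("tree has no leaves")
    return TimeTree(root)


def total_tree_length(tree: TimeTree) -> float:
    """Total branch length of ``tree`` in Myr."""
    return tree.total_length


def prune_to_taxa(tree: TimeTree, taxa: Iterable[str]) -> TimeTree:
    """Induced subtree spanning exactly ``taxa``.

    Degree-2 pass-through nodes are collapsed with their branch lengths
    summed, and no stem edge is kept above the new root: time that does not
    separate the retained taxa cannot host observable substitutions.
    """
    wanted = set(taxa)
    if not wanted:
        raise TreeError("cannot prune to an empty taxon set")
    known = set(tree.leaf_names)
    unknown = wanted - known
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")

    def _prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in wanted:
                return Node(node.name, node.branch_length)
            return None
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # collapse the pass-through: child absorbs this node's stem
            child = kept[0]
            if node.branch_length is not None:
                child.branch_length = (child.branch_length or 0.0) + node.branch_length
            return child
        new = Node(node.name, node.branch_length)
        for c in kept:
            new.add_child(c)
        return new

    new_root = _prune(tree.root)
    assert new_root is not None
    new_root.branch_length = None  # drop any stem above the MRCA
    if len(wanted) == 1:
        # single-taxon prune: a lone leaf with no time span
        return TimeTree(new_root)
    return TimeTree(new_root)


# ---------------------------------------------------------------------------
# alignments


class ProteinAlignment:
    """Gap-aware aligned amino-acid matrix anchored on a reference taxon."""

    def __init__(self, names: Sequence[str], rows: Sequence[str],
                 reference_taxon: str) -> None:
        if len(names) != len(rows):
            raise AlignmentError("names and rows differ in count")
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate taxon names in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows of unequal length: {sorted(lengths)}")
        if reference_taxon not in names:
            raise AlignmentError(
                f"reference taxon {reference_taxon!r} not in alignment")
        allowed = AMINO_ACIDS | {GAP, AMBIGUOUS}
        cleaned = []
        for name, row in zip(names, rows):
            row = row.upper()
            bad = set(row) - allowed
            if bad:
                raise AlignmentError(
                    f"invalid residues {sorted(bad)} in sequence {name!r}")
            cleaned.append(row)
        self.names = list(names)
        self.rows = cleaned
        self.reference_taxon = reference_taxon
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> dict[str, str]:
        """Residues at column ``j`` keyed by taxon (gaps included)."""
        return {name: self.rows[i][j] for name, i in self._index.items()}

    def reference_row(self) -> str:
        return self.rows[self._index[self.reference_taxon]]

    @classmethod
    def from_fasta(cls, path_or_handle, reference_taxon: str) -> "ProteinAlignment":
        from Bio import SeqIO

        if isinstance(path_or_handle, str):
            records = list(SeqIO.parse(path_or_handle, "fasta"))
        else:
            records = list(SeqIO.parse(path_or_handle, "fasta"))
        if not records:
            raise AlignmentError("empty FASTA input")
        names = [r.id for r in records]
        rows = [str(r.seq) for r in records]
        return cls(names, rows, reference_taxon)

    def to_fasta(self) -> str:
        out = io.StringIO()
        for name, row in zip(self.names, self.rows):
            out.write(f">{name}\n{row}\n")
        return out.getvalue()


@dataclass(frozen=True)
class SiteRate:
    """Rate record for one alignment column (reference-taxon anchored)."""

    column_index: int
    s: float
    t: float
    r: float | None           # subst/Byr; None when the column is uncountable
    n_taxa_ungapped: int

    @property
    def missing(self) -> bool:
        return self.r is None


@dataclass(frozen=True)
class GeneConservation:
    """Gene-level evolutionary rate and its reciprocal weight."""

    gene_id: str
    R: float                  # mean r over counted columns, subst/Byr
    L: int                    # reference-sequence length (ungapped columns)
    L_effective: int          # columns entering the mean

    @property
    def WE(self) -> float:
        return 1.0 / self.R


# ---------------------------------------------------------------------------
# substitution counting


def _usable(column: Mapping[str, str]) -> dict[str, str]:
    """Drop gapped and ambiguous taxa; 'X' carries no substitution signal."""
    return {t: a for t, a in column.items() if a not in (GAP, AMBIGUOUS)}


def count_substitutions(column: Mapping[str, str], tree: TimeTree,
                        mode: str = "distinct") -> int:
    """Substitution count ``s`` for one column.

    ``distinct``
        Number of distinct amino-acid states observed (>= 1).
    ``fitch``
        Minimum number of state changes on the tree pruned to the column's
        taxa, by minimum-change parsimony (exact for multifurcations too).
    """
    residues = _usable(column)
    if not residues:
        raise AlignmentError("empty column: no ungapped, unambiguous residues")
    extra = set(residues) - set(tree.leaf_names)
    if extra:
        raise AlignmentError(f"column taxa absent from tree: {sorted(extra)}")

    if mode == "distinct":
        return len(set(residues.values()))
    if mode == "fitch":
        sub = prune_to_taxa(tree, residues.keys())
        return _min_changes(sub, residues)
    raise ValueError(f"unknown counting mode {mode!r}")


def _min_changes(tree: TimeTree, states: Mapping[str, str]) -> int:
    """Minimum-change parsimony count via Sankoff dynamic programming.

    Unit cost between any two different states; exact on arbitrary (including
    multifurcating) rooted trees, which pruning can produce.
    """
    alphabet = sorted(set(states.values()))
    k = len(alphabet)
    index = {a: i for i, a in enumerate(alphabet)}
    INF = float("inf")

    cost: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = [INF] * k
            vec[index[states[node.name]]] = 0.0
            cost[id(node)] = vec
        else:
            vec = []
            for s in range(k):
                total = 0.0
                for child in node.children:
                    cvec = cost[id(child)]
                    total += min(cvec[t] + (0.0 if t == s else 1.0)
                                 for t in range(k))
                vec.append(total)
            cost[id(node)] = vec
    return int(min(cost[id(tree.root)]))


def brute_force_min_changes(tree: TimeTree, states: Mapping[str, str]) -> int:
    """Exhaustive minimization over internal-state assignments (oracle).

    Exponential in internal node count; intended for trees with few leaves.
    """
    alphabet = sorted(set(states.values()))
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = None
    for assignment in itertools.product(alphabet, repeat=len(internals)):
        fixed = {id(n): a for n, a in zip(internals, assignment)}
        changes = 0
        for node in tree.preorder():
            if node is tree.root:
                continue
            mine = states[node.name] if node.is_leaf else fixed[id(node)]
            theirs = fixed[id(node.parent)]
            changes += mine != theirs
        if best is None or changes < best:
            best = changes
    if best is None:  # single-leaf tree: no internal nodes, no edges
        return 0
    return best


# ---------------------------------------------------------------------------
# per-site and per-gene rates


def site_rates(alignment: ProteinAlignment, tree: TimeTree,
               mode: str = "distinct",
               fitch_min_s: float = 0.5) -> list[SiteRate]:
    """Per-column substitution rates anchored on the reference taxon.

    One :class:`SiteRate` is produced per column where the reference taxon
    carries a residue.  Columns with fewer than two usable taxa (or a zero
    time span) are flagged missing and excluded from the gene mean.  In
    ``fitch`` mode a zero-change column receives the configurable pseudocount
    ``fitch_min_s`` so gene rates stay strictly positive.
    """
    missing_in_tree = set(alignment.names) - set(tree.leaf_names)
    if missing_in_tree:
        raise AlignmentError(
            f"alignment taxa absent from tree: {sorted(missing_in_tree)}")

    ref_row = alignment.reference_row()
    if all(a in (GAP, AMBIGUOUS) for a in ref_row):
        raise AlignmentError(
            f"reference taxon {alignment.reference_taxon!r} is fully gapped")

    span_cache: dict[frozenset, float] = {}
    out: list[SiteRate] = []
    for j in range(alignment.n_columns):
        if ref_row[j] in (GAP, AMBIGUOUS):
            continue
        residues = _usable(alignment.column(j))
        n = len(residues)
        if n < 2:
            out.append(SiteRate(j, s=0, t=0.0, r=None, n_taxa_ungapped=n))
            continue
        key = frozenset(residues)
        t = span_cache.get(key)
        if t is None:
            t = prune_to_taxa(tree, residues.keys()).total_length
            span_cache[key] = t
        if t <= 0.0:
            out.append(SiteRate(j, s=0, t=t, r=None, n_taxa_ungapped=n))
            continue
        if mode == "distinct":
            s: float = len(set(residues.values()))
        elif mode == "fitch":
            sub = prune_to_taxa(tree, residues.keys())
            s = max(float(_min_changes(sub, residues)), fitch_min_s)
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
        out.append(SiteRate(j, s=s, t=t, r=1000.0 * s / t, n_taxa_ungapped=n))
    return out


def gene_rate(rates: Sequence[SiteRate], gene_id: str = "gene") -> GeneConservation:
    """Average non-missing site rates into a :class:`GeneConservation`."""
    counted = [sr.r for sr in rates if sr.r is not None]
    if not counted:
        raise AlignmentError(
            f"gene {gene_id!r}: no countable columns, cannot estimate a rate")
    R = sum(counted) / len(counted)
    return GeneConservation(gene_id=gene_id, R=R, L=len(rates),
                            L_effective=len(counted))
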
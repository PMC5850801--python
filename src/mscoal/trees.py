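"""Rooted time-tree data model for multispecies-coalescent inference.

Both species trees and gene trees are strictly binary rooted trees whose node
heights are measured backwards in time: extant tips sit at height 0 and the
root is the highest node.  A branch is identified with the node below it, so
per-branch quantities (population size, relative substitution rate) are keyed
by the id of the branch's child node.  The species-tree root also owns a
branch: the ancestral lineage extending from the root height into the
infinite past, which matters for the coalescent process.

Node ids are stable: MCMC proposals move, delete and recreate connections but
an id always refers to the same lineage for bookkeeping purposes.

The central geometric computation is the *embedding* of a gene tree inside a
species tree: for every gene-tree branch, the ordered list of species-tree
branches it traverses and the time spent in each.  The embedding drives the
coalescent density, the species-tree relaxed clock, and the coordinated MCMC
operators.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Tree",
    "SpeciesTree",
    "GeneTree",
    "Embedding",
    "validate_mapping",
    "is_compatible",
    "embed_gene_tree",
    "descendant_individuals",
    "MappingError",
    "IncompatibleError",
]


class MappingError(ValueError):
    """Raised when a tip-to-species mapping is malformed."""


class IncompatibleError(ValueError):
    """Raised when a gene tree cannot be embedded in a species tree."""


class Node:
    __slots__ = ("id", "label", "height", "parent", "children")

    def __init__(self, nid: int, label: str | None = None, height: float = 0.0):
        self.id = nid
        self.label = label
        self.height = height
        self.parent: Node | None = None
        self.children: list[Node] = []

    def is_tip(self) -> bool:
        return not self.children

    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, {self.label!r}, h={self.height:.6g})"


class Tree:
    """Strictly binary rooted tree with stable node ids."""

    def __init__(self) -> None:
        self.nodes: dict[int, Node] = {}
        self.root: Node | None = None
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def new_node(self, label: str | None = None, height: float = 0.0) -> Node:
        node = Node(self._next_id, label, height)
        self._next_id += 1
        self.nodes[node.id] = node
        return node

    def attach(self, parent: Node, child: Node) -> None:
        parent.children.append(child)
        child.parent = parent

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse a newick string; branch lengths are interpreted as time.

        Polytomies are rejected: the models here assume binary trees.
        """
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            taxon_namespace=dendropy.TaxonNamespace(),
        )
        tree = cls()

        def build(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = tree.new_node(label=label)
            kids = dnode.child_nodes()
            if len(kids) not in (0, 2):
                raise ValueError(
                    f"tree is not strictly binary: node with {len(kids)} children"
                )
            for k in kids:
                tree.attach(node, build(k))
            return node

        tree.root = build(dtree.seed_node)
        # convert branch lengths to heights: tips at 0, increasing rootwards
        depth: dict[int, float] = {}

        def assign(node: Node, dnode, d: float) -> None:
            depth[node.id] = d
            for ch, dch in zip(node.children, dnode.child_nodes()):
                el = dch.edge.length if dch.edge.length is not None else 0.0
                assign(ch, dch, d + el)

        assign(tree.root, dtree.seed_node, 0.0)
        maxd = max(depth.values())
        for node in tree.nodes.values():
            node.height = maxd - depth[node.id]
        for tip in tree.tips():
            if abs(tip.height) > 1e-9 * max(maxd, 1.0):
                raise ValueError("tree is not ultrametric: tips not contemporaneous")
            tip.height = 0.0
        return tree

    # -- traversal --------------------------------------------------------

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip()]

    def internals(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip()]

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if node is None:
                return
            if seen:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node is None:
                return
            yield node
            stack.extend(reversed(node.children))

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def node_by_label(self, label: str) -> Node:
        for n in self.nodes.values():
            if n.label == label:
                return n
        raise KeyError(label)

    def leaf_set(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip():
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        if not want:
            raise ValueError("mrca of empty set")
        best = None
        for node in self.postorder():
            if want <= self.leaf_set(node):
                best = node
                break
        if best is None:
            raise KeyError(f"labels not in tree: {want}")
        return best

    def clades(self) -> set[frozenset[str]]:
        """All non-trivial rooted clades (internal nodes incl. root)."""
        return {self.leaf_set(n) for n in self.internals()}

    # -- editing ----------------------------------------------------------

    def validate(self) -> None:
        for node in self.postorder():
            if node.children:
                if len(node.children) != 2:
                    raise ValueError("non-binary node")
                for ch in node.children:
                    if ch.height >= node.height:
                        raise ValueError(
                            f"child height {ch.height} >= parent {node.height}"
                        )
                    if ch.parent is not node:
                        raise ValueError("broken parent link")
            else:
                if node.height != 0.0:
                    raise ValueError("tip not at height 0")

    def copy(self) -> "Tree":
        return self._copy_into(type(self)())

    def _copy_into(self, new: "Tree") -> "Tree":
        for nid, node in self.nodes.items():
            cn = Node(nid, node.label, node.height)
            new.nodes[nid] = cn
        for nid, node in self.nodes.items():
            cn = new.nodes[nid]
            cn.children = [new.nodes[c.id] for c in node.children]
            for c in cn.children:
                c.parent = cn
        new.root = new.nodes[self.root.id] if self.root else None
        new._next_id = self._next_id
        return new

    # -- serialization ----------------------------------------------------

    def to_newick(self, annotations: dict[int, dict[str, float]] | None = None,
                  precision: int = 12) -> str:
        """Newick with heights encoded as branch lengths.

        ``annotations`` maps node id -> {key: value} written as BEAST-style
        ``[&key=value,...]`` comments on the branch above the node.
        """

        def fmt(node: Node) -> str:
            if node.is_tip():
                core = node.label or str(node.id)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            ann = ""
            if annotations and node.id in annotations:
                inner = ",".join(
                    f"{k}={v:.{precision}g}" for k, v in annotations[node.id].items()
                )
                ann = f"[&{inner}]"
            if node.parent is None:
                return f"{core}{ann}"
            bl = node.parent.height - node.height
            return f"{core}{ann}:{bl:.{precision}g}"

        return fmt(self.root) + ";"


class SpeciesTree(Tree):
    """Species time-tree with per-branch population sizes and relative rates.

    ``pop_size[nid]`` is the haploid-equivalent size of the branch above node
    ``nid`` (the coalescence rate for j lineages in that branch is
    C(j,2)/pop_size); the root's entry covers the ancestral lineage above the
    root.  ``rate[nid]`` is the dimensionless relative substitution rate of
    the branch; the root branch rate is conventionally fixed at 1.
    """

    def __init__(self) -> None:
        super().__init__()
        self.pop_size: dict[int, float] = {}
        self.rate: dict[int, float] = {}

    def copy(self) -> "SpeciesTree":
        new = super()._copy_into(SpeciesTree())
        new.pop_size = dict(self.pop_size)
        new.rate = dict(self.rate)
        return new

    def branch_annotations(self) -> dict[int, dict[str, float]]:
        ann: dict[int, dict[str, float]] = {}
        for nid in self.nodes:
            d: dict[str, float] = {}
            if nid in self.pop_size:
                d["dmv"] = self.pop_size[nid]
            if nid in self.rate:
                d["rate"] = self.rate[nid]
            if d:
                ann[nid] = d
        return ann


class GeneTree(Tree):
    """Gene tree over sampled haplotypes, embeddable in a species tree.

    ``rate[nid]`` (substitutions/site/time), when set, is the clock rate of
    the branch above node ``nid``.
    """

    def __init__(self) -> None:
        super().__init__()
        self.rate: dict[int, float] = {}

    def copy(self) -> "GeneTree":
        new = super()._copy_into(GeneTree())
        new.rate = dict(self.rate)
        return new


# ---------------------------------------------------------------------------
# tip-to-species mapping
# ---------------------------------------------------------------------------

def validate_mapping(gene_tree: GeneTree, species_tree: SpeciesTree,
                     mapping: dict[str, str]) -> dict[str, str]:
    """Check a haplotype->species table against both trees.

    Every gene-tree tip must appear exactly once and map to an extant species
    (a species-tree tip label).
    """
    species = set(species_tree.tip_labels())
    seen: set[str] = set()
    for tip in gene_tree.tips():
        if tip.label not in mapping:
            raise MappingError(f"gene tip {tip.label!r} missing from mapping")
        if tip.label in seen:
            raise MappingError(f"duplicate gene tip {tip.label!r}")
        seen.add(tip.label)
        sp = mapping[tip.label]
        if sp not in species:
            raise MappingError(f"tip {tip.label!r} maps to unknown species {sp!r}")
    return {t: mapping[t] for t in sorted(seen)}


def read_mapping(path) -> dict[str, str]:
    """Two-column delimited text: haplotype<TAB>species (whitespace ok)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise MappingError(f"bad mapping line: {line!r}")
            hap, sp = parts
            if hap in mapping:
                raise MappingError(f"duplicate haplotype {hap!r}")
            mapping[hap] = sp
    return mapping


def write_mapping(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for hap in sorted(mapping):
            fh.write(f"{hap}\t{mapping[hap]}\n")


# ---------------------------------------------------------------------------
# compatibility and embedding
# ---------------------------------------------------------------------------

def gene_species_mrca(gene_tree: GeneTree, species_tree: SpeciesTree,
                      mapping: dict[str, str]) -> dict[int, Node]:
    """For each gene node, the species-tree MRCA of its tips' species.

    This node is the lowest species-tree position the gene node's lineage may
    occupy; compatibility requires every coalescence to sit at or above it.
    """
    # species node per label
    sp_tip = {t.label: t for t in species_tree.tips()}
    # ancestor chain index for MRCA computation: map node -> (depth, parent)
    depth: dict[int, int] = {}
    for node in species_tree.preorder():
        depth[node.id] = 0 if node.parent is None else depth[node.parent.id] + 1

    def mrca2(a: Node, b: Node) -> Node:
        while a is not b:
            if depth[a.id] >= depth[b.id]:
                a = a.parent
            else:
                b = b.parent
        return a

    out: dict[int, Node] = {}
    for node in gene_tree.postorder():
        if node.is_tip():
            out[node.id] = sp_tip[mapping[node.label]]
        else:
            m = out[node.children[0].id]
            for ch in node.children[1:]:
                m = mrca2(m, out[ch.id])
            out[node.id] = m
    return out


def is_compatible(gene_tree: GeneTree, species_tree: SpeciesTree,
                  mapping: dict[str, str]) -> bool:
    """True iff every gene coalescence is no older than allowed.

    A coalescence joining lineages whose tips span species X and Y must occur
    at or above the height of the species-tree MRCA of X and Y.
    """
    anchors = gene_species_mrca(gene_tree, species_tree, mapping)
    for node in gene_tree.internals():
        if node.height < anchors[node.id].height - 1e-13 * max(node.height, 1.0):
            return False
    return True


def residence(species_tree: SpeciesTree, anchor: Node, height: float) -> Node:
    """The species branch (child-node id) containing ``height`` on the
    ancestral path starting at ``anchor``."""
    node = anchor
    while node.parent is not None and node.parent.height <= height:
        node = node.parent
    return node


class Embedding:
    """Per gene-tree branch, the ordered species-branch segments it crosses.

    ``segments[nid]`` is a list of ``(species_branch_id, t_start, t_end)``
    tuples for the branch above gene node ``nid``, ordered from the node
    (younger) to its parent (older).  Segment lengths sum to the branch
    length.  The gene root has no branch and no entry.
    """

    def __init__(self, segments: dict[int, list[tuple[int, float, float]]]):
        self.segments = segments

    def lengths(self, nid: int) -> list[tuple[int, float]]:
        """(species branch id, L) pairs for the branch above gene node nid."""
        return [(sb, t1 - t0) for sb, t0, t1 in self.segments[nid]]


def embed_gene_tree(gene_tree: GeneTree, species_tree: SpeciesTree,
                    mapping: dict[str, str]) -> Embedding:
    """Compute the species-branch segments traversed by each gene branch."""
    anchors = gene_species_mrca(gene_tree, species_tree, mapping)
    segments: dict[int, list[tuple[int, float, float]]] = {}
    for node in gene_tree.postorder():
        if node.parent is None:
            continue
        t0, t1 = node.height, node.parent.height
        anchor = anchors[node.id]
        if t0 < anchor.height - 1e-13 * max(t0, 1.0):
            raise IncompatibleError(
                f"gene node at height {t0} below species MRCA at {anchor.height}"
            )
        sp = residence(species_tree, anchor, t0)
        segs: list[tuple[int, float, float]] = []
        t = t0
        while sp.parent is not None and sp.parent.height < t1:
            segs.append((sp.id, t, sp.parent.height))
            t = sp.parent.height
            sp = sp.parent
        segs.append((sp.id, t, t1))
        segments[node.id] = segs
    return Embedding(segments)


def descendant_individuals(node: Node, tree: Tree,
                           species_tree: SpeciesTree | None = None,
                           gene_trees: list[GeneTree] | None = None,
                           mapping: dict[str, str] | None = None) -> set[str]:
    """Haplotypes descending from a node.

    For a gene-tree node these are its descendant tips.  For a species-tree
    node they are all haplotypes (across the supplied gene trees) mapped to
    its descendant species.
    """
    if species_tree is not None and tree is species_tree:
        species = species_tree.leaf_set(node)
        out: set[str] = set()
        for gt in gene_trees or []:
            for tip in gt.tips():
                if mapping[tip.label] in species:
                    out.add(tip.label)
        return out
    return set(tree.leaf_set(node))
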
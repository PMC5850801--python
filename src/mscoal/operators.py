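"""Metropolis-Hastings proposal kernels.

Standard single-tree moves (scales, height slides, narrow exchange, subtree
prune-and-regraft, Wilson-Balding) plus the three coordinated operators that
move the species tree and all gene trees in one step:

* CoordinatedUniform — shifts a non-root species node and the "connected
  component" of gene nodes selected purely from topology and the tip
  mapping, uniformly within bounds that change no topology (symmetric).
* CoordinatedExponential — the adaptive root-height version; the new root
  offset x' is drawn from an exponential independent of the current value,
  so the log Hastings ratio is lambda*(x' - x).
* CoordinatedExchange — a species-tree NNI or height-preserving SPR with a
  coordinated rebuild of every gene coalescence inside the affected height
  window, re-paired uniformly among lineages co-resident in a species
  branch of the proposed tree; the Hastings ratio is the ratio of the
  forward and replayed-reverse choice probabilities.

Invalid proposals (incompatibility, empty choice sets) return
``Proposal(valid=False)`` and are rejected outright without touching
acceptance statistics of the target density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .state import McmcState
from .msc_model import BirthDeathParams
from .trees import Node, SpeciesTree, Tree

__all__ = [
    "Proposal",
    "Operator",
    "select_connected_component",
    "compute_shift_bounds",
    "adapt_exponential_rate",
    "CoordinatedUniform",
    "CoordinatedExponential",
    "CoordinatedExchange",
    "NarrowExchange",
    "SpeciesSPR",
    "WilsonBalding",
    "UniformNodeHeight",
    "RootHeightScale",
    "TreeScale",
    "CategoryResample",
    "CategorySwap",
    "PopSizeScale",
    "PopSizeMeanScale",
    "DiversificationScale",
    "ExtinctionWalk",
    "LocusRateExchange",
    "default_operators",
]


@dataclass
class Proposal:
    state: McmcState | None
    log_hastings: float = 0.0
    valid: bool = True
    touched: object = "all"          # loci whose likelihood must be refreshed

    @classmethod
    def invalid(cls) -> "Proposal":
        return cls(state=None, valid=False)


class Operator:
    name = "operator"

    def __init__(self, weight: float = 1.0):
        self.weight = weight
        self.n_proposed = 0
        self.n_accepted = 0

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        raise NotImplementedError

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _scale_factor(rng: np.random.Generator, lam: float = 0.75) -> float:
    """BEAST-style scale kernel: s uniform on [lam, 1/lam]."""
    return lam + rng.random() * (1.0 / lam - lam)


def _internal_nonroot(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n.children and n.parent is not None]


def _support_sets(tree: Tree, mapping: dict[str, str] | None) -> dict[int, frozenset]:
    """Per-node species support (tips translated through the mapping)."""
    out: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip():
            label = mapping[node.label] if mapping else node.label
            out[node.id] = frozenset((label,))
        else:
            s = frozenset()
            for ch in node.children:
                s |= out[ch.id]
            out[node.id] = s
    return out


class _SpeciesIndex:
    """Fast MRCA / residence queries against one species tree."""

    def __init__(self, st: SpeciesTree):
        self.st = st
        self.tip = {t.label: t for t in st.tips()}
        self.depth = {}
        for n in st.preorder():
            self.depth[n.id] = 0 if n.parent is None else self.depth[n.parent.id] + 1

    def mrca(self, species: frozenset) -> Node:
        it = iter(species)
        node = self.tip[next(it)]
        for lab in it:
            other = self.tip[lab]
            a, b = node, other
            while a is not b:
                if self.depth[a.id] >= self.depth[b.id]:
                    a = a.parent
                else:
                    b = b.parent
            node = a
        return node

    def residence(self, species: frozenset, height: float) -> int:
        node = self.mrca(species)
        while node.parent is not None and node.parent.height <= height:
            node = node.parent
        return node.id


# ---------------------------------------------------------------------------
# coordinated height operators
# ---------------------------------------------------------------------------

def select_connected_component(S: Node, state: McmcState) -> list[set[int]]:
    """Gene nodes to shift jointly with species node S, per locus.

    A gene node s is selected iff its descendant individuals overlap those
    of both children of S and are all contained in those of S.  The
    selection uses only topologies and the tip mapping — never heights —
    which is what makes the height shift symmetric.
    """
    left, right = S.children
    st = state.species_tree
    lset, rset = st.leaf_set(left), st.leaf_set(right)
    sset = lset | rset
    out: list[set[int]] = []
    for gt, mapping in zip(state.gene_trees, state.mappings):
        support = _support_sets(gt, mapping)
        chosen = {nid for nid, supp in support.items()
                  if gt.nodes[nid].children
                  and supp & lset and supp & rset and supp <= sset}
        out.append(chosen)
    return out


def compute_shift_bounds(S: Node, component: list[set[int]],
                         state: McmcState) -> tuple[float, float]:
    """(D, U): the height window for S within which shifting S and its
    connected component changes no topology in any tree.

    D is the tightest lower constraint (children of S; non-component
    children of shifted gene nodes, offset by each node's own height).
    U is the tightest upper constraint (parent of S; non-component parents
    of shifted gene nodes).  The species root has U = +inf.
    """
    h = S.height
    eta_lo = max(c.height for c in S.children) - h
    eta_hi = (S.parent.height - h) if S.parent is not None else math.inf
    for gt, comp in zip(state.gene_trees, component):
        for nid in comp:
            g = gt.nodes[nid]
            for ch in g.children:
                if ch.id not in comp:
                    eta_lo = max(eta_lo, ch.height - g.height)
            p = g.parent
            if p is not None and p.id not in comp:
                eta_hi = min(eta_hi, p.height - g.height)
    return h + eta_lo, h + eta_hi


def _apply_shift(state: McmcState, S_id: int, component: list[set[int]],
                 eta: float) -> McmcState:
    new = state.copy()
    new.species_tree.nodes[S_id].height += eta
    touched = set()
    for i, comp in enumerate(component):
        for nid in comp:
            new.gene_trees[i].nodes[nid].height += eta
        if comp:
            touched.add(i)
    # the species-node height change moves branch boundaries for every
    # locus, so coalescent statistics are stale everywhere; likelihoods
    # only for the loci whose gene nodes moved (or all under a
    # species-driven clock)
    if state.settings.clock_kind.startswith("st_") or state.settings.concatenation:
        new.invalidate("all")
    else:
        new.invalidate_species_heights(sorted(touched))
    return new


class CoordinatedUniform(Operator):
    """Shift a non-root species node and its connected component uniformly
    within the topology-preserving window; symmetric (log HR = 0)."""

    name = "coordinated_uniform"

    def propose(self, state, rng):
        nodes = _internal_nonroot(state.species_tree)
        if not nodes:
            return Proposal.invalid()
        S = nodes[rng.integers(len(nodes))]
        component = select_connected_component(S, state)
        D, U = compute_shift_bounds(S, component, state)
        if not U > D:
            return Proposal.invalid()
        eta = rng.uniform(D, U) - S.height
        new = _apply_shift(state, S.id, component, eta)
        return Proposal(new, 0.0)


def adapt_exponential_rate(mean_x: float) -> float:
    """Rate lambda with the exponential's median at the running posterior
    mean of the root offset x."""
    if mean_x <= 0:
        raise ValueError("mean of x must be positive")
    return math.log(2.0) / mean_x


class CoordinatedExponential(Operator):
    """Adaptive root-height move: new root offset x' ~ Exp(lambda),
    independent of x, so log HR = lambda * (x' - x).

    During burn-in, lambda is re-tuned every ``adapt_every`` proposals to
    the running mean of x (diminishing adaptation); ``freeze()`` stops it.
    """

    name = "coordinated_exponential"

    def __init__(self, weight: float = 1.0, rate: float = 1.0,
                 adapt_every: int = 100):
        super().__init__(weight)
        self.rate = rate
        self.adapt_every = adapt_every
        self.adapting = True
        self._x_sum = 0.0
        self._x_n = 0

    def freeze(self) -> None:
        self.adapting = False

    def propose(self, state, rng):
        S = state.species_tree.root
        component = select_connected_component(S, state)
        D, _ = compute_shift_bounds(S, component, state)
        x = S.height - D
        if x <= 0:
            return Proposal.invalid()
        if self.adapting:
            self._x_sum += x
            self._x_n += 1
            if self._x_n % self.adapt_every == 0:
                self.rate = adapt_exponential_rate(self._x_sum / self._x_n)
        x_new = rng.exponential(1.0 / self.rate)
        eta = x_new - x
        new = _apply_shift(state, S.id, component, eta)
        return Proposal(new, self.rate * eta)


# ---------------------------------------------------------------------------
# species topology moves
# ---------------------------------------------------------------------------

def _sibling(node: Node) -> Node:
    a, b = node.parent.children
    return b if a is node else a


def _prune_candidates(tree: Tree) -> list[Node]:
    """Nodes whose branch can be pruned for a height-preserving SPR: the
    node and its parent are both non-root."""
    return [n for n in tree.postorder()
            if n.parent is not None and n.parent.parent is not None]


def _prune(tree: Tree, C: Node) -> tuple[Node, Node, Node]:
    """Detach C's parent V from the tree (V keeps child C).  Returns
    (V, old sibling of C, grandparent)."""
    V = C.parent
    sib = _sibling(C)
    GP = V.parent
    GP.children = [sib if ch is V else ch for ch in GP.children]
    sib.parent = GP
    V.parent = None
    V.children = [C]
    return V, sib, GP


def _regraft(tree: Tree, V: Node, C: Node, target: Node) -> None:
    """Insert V (with child C) into the branch above ``target``."""
    TP = target.parent
    TP.children = [V if ch is target else ch for ch in TP.children]
    V.parent = TP
    V.children = [C, target]
    target.parent = V


def _crossing_edges(tree: Tree, height: float) -> list[Node]:
    return [n for n in tree.postorder()
            if n.parent is not None and n.height < height < n.parent.height]


def _pruned_mrca_window(sib: Node, target: Node) -> float:
    """Upper height of the region whose clade composition the SPR changes:
    the merge node of the old and new attachment paths in the pruned tree."""
    anc_of_sib = set()
    n = sib
    while n is not None:
        anc_of_sib.add(n.id)
        n = n.parent
    m = target
    while m.id not in anc_of_sib:
        m = m.parent
    if m is sib or m is target:
        return m.parent.height
    return m.height


class NarrowExchange(Operator):
    """Swap a node with its uncle (rooted NNI); heights unchanged.

    ``target`` is "species" or a locus index; species moves auto-reject when
    any gene tree becomes incompatible, gene moves when the gene tree leaves
    the species tree.  Selection is uniform over a topology-independent
    candidate count, so the move is symmetric.
    """

    def __init__(self, weight: float = 1.0, target="species"):
        super().__init__(weight)
        self.target = target
        self.name = f"narrow_exchange_{target}"

    def propose(self, state, rng):
        new = state.copy()
        tree = (new.species_tree if self.target == "species"
                else new.gene_trees[self.target])
        cands = _prune_candidates(tree)
        if not cands:
            return Proposal.invalid()
        C = cands[rng.integers(len(cands))]
        V = C.parent
        U = _sibling(V)
        if U.height >= V.height:
            return Proposal.invalid()
        GP = V.parent
        V.children = [U if ch is C else ch for ch in V.children]
        GP.children = [C if ch is U else ch for ch in GP.children]
        U.parent, C.parent = V, GP
        if self.target == "species":
            if not new.compatible():
                return Proposal.invalid()
            new.invalidate("all")
        else:
            from .trees import is_compatible
            if not is_compatible(tree, new.species_tree,
                                 new.mappings[self.target]):
                return Proposal.invalid()
            new.invalidate([self.target])
        return Proposal(new, 0.0)


class SpeciesSPR(Operator):
    """Naive height-preserving SPR on the species tree: prune a branch and
    re-attach its parent node at the same height on another branch crossing
    it; gene trees untouched, incompatibilities auto-reject."""

    name = "species_spr"

    def propose(self, state, rng):
        new = state.copy()
        tree = new.species_tree
        cands = _prune_candidates(tree)
        if not cands:
            return Proposal.invalid()
        cnt_fwd = len(cands)
        C = cands[rng.integers(len(cands))]
        h_v = C.parent.height
        V, sib, _ = _prune(tree, C)
        targets = _crossing_edges(tree, h_v)
        if not targets:
            return Proposal.invalid()
        target = targets[rng.integers(len(targets))]
        _regraft(tree, V, C, target)
        if not new.compatible():
            return Proposal.invalid()
        cnt_rev = len(_prune_candidates(tree))
        new.invalidate("all")
        return Proposal(new, math.log(cnt_fwd) - math.log(cnt_rev))


class WilsonBalding(Operator):
    """Wilson-Balding prune-and-regraft on one gene tree: the pruned
    branch's parent is re-inserted at a uniform height on another branch.
    log HR is the log ratio of the new and old insertion windows."""

    def __init__(self, weight: float = 1.0, locus: int = 0):
        super().__init__(weight)
        self.locus = locus
        self.name = f"wilson_balding_{locus}"

    def propose(self, state, rng):
        new = state.copy()
        gt = new.gene_trees[self.locus]
        cands = _prune_candidates(gt)
        if not cands:
            return Proposal.invalid()
        C = cands[rng.integers(len(cands))]
        all_nodes = [n for n in gt.postorder() if n.parent is not None]
        j = all_nodes[rng.integers(len(all_nodes))]
        V = C.parent
        # reject impossible targets: j inside C's clade (incl. C) or j = V
        if j is V:
            return Proposal.invalid()
        n = j
        while n is not None:
            if n is C:
                return Proposal.invalid()
            n = n.parent
        sib = _sibling(C)
        GP = V.parent
        range_old = GP.height - max(C.height, sib.height)
        _prune(gt, C)
        lo = max(C.height, j.height)
        hi = j.parent.height
        if hi <= lo:
            return Proposal.invalid()
        V.height = rng.uniform(lo, hi)
        _regraft(gt, V, C, j)
        from .trees import is_compatible
        if not is_compatible(gt, new.species_tree, new.mappings[self.locus]):
            return Proposal.invalid()
        new.invalidate([self.locus])
        return Proposal(new, math.log(hi - lo) - math.log(range_old))


# ---------------------------------------------------------------------------
# CoordinatedExchange
# ---------------------------------------------------------------------------

def _rebuild_window(gt, old_index: _SpeciesIndex, new_index: _SpeciesIndex,
                    mapping: dict[str, str], h_lo: float, h_hi: float,
                    rng: np.random.Generator):
    """Erase all gene coalescences with height in (h_lo, h_hi) and rebuild
    them at the same heights with uniformly chosen co-resident pairs in the
    proposed species tree.

    Returns (log q_forward, log q_reverse) for the gene part, or None when
    the rebuild cannot be completed (auto-reject).  ``gt`` is mutated.
    """
    window = sorted((n for n in gt.postorder()
                     if n.children and h_lo < n.height < h_hi),
                    key=lambda n: n.height)
    if not window:
        return 0.0, 0.0
    win_ids = {n.id for n in window}
    support = _support_sets(gt, mapping)
    orig_children = {n.id: [c.id for c in n.children] for n in window}

    # every lineage entering the window participates in the rebuild; every
    # link from the untouched structure at/above the window top down into it
    # (onto an erased node or straight through the window) is cut and becomes
    # a slot, keyed by the species branch the original occupant's lineage
    # occupies at the window top (identical in both species trees).
    entering = [n for n in gt.nodes.values()
                if n.height <= h_lo and n.parent is not None
                and n.parent.height > h_lo]
    slots = []  # (parent node, child index, branch)
    for n in gt.nodes.values():
        if n.parent is not None and n.height < h_hi \
                and n.parent.height >= h_hi:
            branch = old_index.residence(support[n.id], h_hi)
            slots.append((n.parent, n.parent.children.index(n), branch))
    root_in_window = gt.root.id in win_ids

    # ---- forward build -------------------------------------------------
    cur: dict[int, frozenset] = {n.id: support[n.id] for n in entering}
    log_q_fwd = 0.0
    for k, ev in enumerate(window):
        h = ev.height
        groups: dict[int, list[int]] = {}
        for nid, supp in cur.items():
            groups.setdefault(new_index.residence(supp, h), []).append(nid)
        pairs = [(a, b) for mem in groups.values()
                 for ai, a in enumerate(mem) for b in mem[ai + 1:]]
        if not pairs:
            return None
        a, b = pairs[rng.integers(len(pairs))]
        log_q_fwd -= math.log(len(pairs))
        na, nb = gt.nodes[a], gt.nodes[b]
        ev.children = [na, nb]
        na.parent = nb.parent = ev
        ev.parent = None
        cur[ev.id] = cur.pop(a) | cur.pop(b)

    # ---- reattach exits to slots ---------------------------------------
    exit_ids = list(cur.keys())
    if root_in_window:
        if len(exit_ids) != 1:
            return None
        gt.root = gt.nodes[exit_ids[0]]
        gt.root.parent = None
    else:
        by_branch_exit: dict[int, list[int]] = {}
        for nid in exit_ids:
            by_branch_exit.setdefault(
                new_index.residence(cur[nid], h_hi), []).append(nid)
        by_branch_slot: dict[int, list[tuple]] = {}
        for slot in slots:
            by_branch_slot.setdefault(slot[2], []).append(slot)
        if set(by_branch_exit) != set(by_branch_slot):
            return None
        for b in by_branch_exit:
            ex, sl = by_branch_exit[b], by_branch_slot[b]
            if len(ex) != len(sl):
                return None
            order = rng.permutation(len(ex))
            # matching probabilities are 1/m! in both directions and cancel
            for idx, (parent, child_idx, _) in zip(order, sl):
                child = gt.nodes[ex[int(idx)]]
                parent.children[child_idx] = child
                child.parent = parent

    # ---- reverse replay (probability of rebuilding the original) --------
    cur2 = {n.id: support[n.id] for n in entering}
    log_q_rev = 0.0
    for ev in window:
        h = ev.height
        groups = {}
        for nid, supp in cur2.items():
            groups.setdefault(old_index.residence(supp, h), []).append(nid)
        npairs = sum(len(m) * (len(m) - 1) // 2 for m in groups.values())
        log_q_rev -= math.log(npairs)
        c1, c2 = orig_children[ev.id]
        cur2[ev.id] = cur2.pop(c1) | cur2.pop(c2)
    return log_q_fwd, log_q_rev


class CoordinatedExchange(Operator):
    """Species NNI/SPR with coordinated gene-tree rebuilding.

    ``p_nni`` is the probability of the (less radical) NNI restriction; the
    remaining mass proposes a height-preserving SPR to a uniformly chosen
    non-uncle branch (the two outcome sets are disjoint, so kind
    probabilities cancel in the Hastings ratio).
    """

    name = "coordinated_exchange"

    def __init__(self, weight: float = 1.0, p_nni: float = 2.0 / 3.0):
        super().__init__(weight)
        self.p_nni = p_nni

    def propose(self, state, rng):
        new = state.copy()
        tree = new.species_tree
        cands = _prune_candidates(tree)
        if not cands:
            return Proposal.invalid()
        cnt_fwd = len(cands)
        C = cands[rng.integers(len(cands))]
        h_v = C.parent.height
        nni = rng.random() < self.p_nni
        uncle = _sibling(C.parent)
        V, sib, GP = _prune(tree, C)
        if nni:
            if uncle.height >= h_v:
                return Proposal.invalid()
            target = uncle
        else:
            targets = [t for t in _crossing_edges(tree, h_v) if t is not uncle]
            if not targets:
                return Proposal.invalid()
            target = targets[rng.integers(len(targets))]
        h_hi = _pruned_mrca_window(sib, target)
        old_index = _SpeciesIndex(state.species_tree)
        _regraft(tree, V, C, target)
        new_index = _SpeciesIndex(tree)

        log_hr = 0.0
        for i, gt in enumerate(new.gene_trees):
            res = _rebuild_window(gt, old_index, new_index, new.mappings[i],
                                  h_v, h_hi, rng)
            if res is None:
                return Proposal.invalid()
            fwd, rev = res
            log_hr += rev - fwd
        cnt_rev = len(_prune_candidates(tree))
        log_hr += math.log(cnt_fwd) - math.log(cnt_rev)
        new.invalidate("all")
        return Proposal(new, log_hr)


# ---------------------------------------------------------------------------
# height moves
# ---------------------------------------------------------------------------

class UniformNodeHeight(Operator):
    """Slide one internal non-root node height uniformly between its
    children and parent; symmetric, incompatibilities auto-reject."""

    def __init__(self, weight: float = 1.0, target="species"):
        super().__init__(weight)
        self.target = target
        self.name = f"uniform_height_{target}"

    def propose(self, state, rng):
        new = state.copy()
        tree = (new.species_tree if self.target == "species"
                else new.gene_trees[self.target])
        nodes = _internal_nonroot(tree)
        if not nodes:
            return Proposal.invalid()
        node = nodes[rng.integers(len(nodes))]
        lo = max(c.height for c in node.children)
        hi = node.parent.height
        node.height = rng.uniform(lo, hi)
        if self.target == "species":
            if not new.compatible():
                return Proposal.invalid()
            new.invalidate("all")
        else:
            from .trees import is_compatible
            if not is_compatible(tree, new.species_tree,
                                 new.mappings[self.target]):
                return Proposal.invalid()
            touched = ("all" if state.settings.clock_kind.startswith("st_")
                       else [self.target])
            new.invalidate(touched)
        return Proposal(new, 0.0)


class RootHeightScale(Operator):
    """Scale the root's offset above its older child (1-dim scale kernel,
    log HR = -log s)."""

    def __init__(self, weight: float = 1.0, target="species", lam: float = 0.75):
        super().__init__(weight)
        self.target = target
        self.lam = lam
        self.name = f"root_scale_{target}"

    def propose(self, state, rng):
        new = state.copy()
        tree = (new.species_tree if self.target == "species"
                else new.gene_trees[self.target])
        root = tree.root
        base = max(c.height for c in root.children)
        x = root.height - base
        if x <= 0:
            return Proposal.invalid()
        s = _scale_factor(rng, self.lam)
        root.height = base + x * s
        if self.target == "species":
            if not new.compatible():
                return Proposal.invalid()
            new.invalidate("all")
        else:
            from .trees import is_compatible
            if not is_compatible(tree, new.species_tree,
                                 new.mappings[self.target]):
                return Proposal.invalid()
            touched = ("all" if state.settings.clock_kind.startswith("st_")
                       else [self.target])
            new.invalidate(touched)
        return Proposal(new, -math.log(s))


class TreeScale(Operator):
    """Scale all internal heights of one tree, or of every tree jointly
    ("all", which preserves compatibility by construction);
    log HR = (dim - 2) log s."""

    def __init__(self, weight: float = 1.0, target="all", lam: float = 0.9):
        super().__init__(weight)
        self.target = target
        self.lam = lam
        self.name = f"tree_scale_{target}"

    def propose(self, state, rng):
        new = state.copy()
        s = _scale_factor(rng, self.lam)
        if self.target == "all":
            trees = [new.species_tree] + list(new.gene_trees)
        elif self.target == "species":
            trees = [new.species_tree]
        else:
            trees = [new.gene_trees[self.target]]
        dim = 0
        for tree in trees:
            for node in tree.postorder():
                if node.children:
                    node.height *= s
                    dim += 1
        if self.target == "all":
            new.invalidate("all")
        elif self.target == "species":
            if not new.compatible():
                return Proposal.invalid()
            new.invalidate("all")
        else:
            from .trees import is_compatible
            if not is_compatible(trees[0], new.species_tree,
                                 new.mappings[self.target]):
                return Proposal.invalid()
            touched = ("all" if state.settings.clock_kind.startswith("st_")
                       else [self.target])
            new.invalidate(touched)
        return Proposal(new, (dim - 2) * math.log(s))


# ---------------------------------------------------------------------------
# clock and hyperparameter moves
# ---------------------------------------------------------------------------

class CategoryResample(Operator):
    """Assign a uniformly random new rate category to one branch."""

    def __init__(self, weight: float = 1.0, target="species"):
        super().__init__(weight)
        self.target = target
        self.name = f"category_resample_{target}"

    def propose(self, state, rng):
        new = state.copy()
        if self.target == "species":
            cats = new.species_cats
            nbins = len(new._sp_bin_rates)
        else:
            cats = new.gene_cats[self.target]
            nbins = len(new._gt_bin_rates[self.target])
        keys = list(cats)
        cats[keys[rng.integers(len(keys))]] = int(rng.integers(nbins))
        if self.target == "species":
            new.sync_species_rates()
            new.invalidate("all", trees_changed=False)
        else:
            new.invalidate([self.target], trees_changed=False)
        return Proposal(new, 0.0)


class CategorySwap(Operator):
    """Swap the rate categories of two branches."""

    def __init__(self, weight: float = 1.0, target="species"):
        super().__init__(weight)
        self.target = target
        self.name = f"category_swap_{target}"

    def propose(self, state, rng):
        new = state.copy()
        cats = (new.species_cats if self.target == "species"
                else new.gene_cats[self.target])
        keys = list(cats)
        if len(keys) < 2:
            return Proposal.invalid()
        i, j = rng.choice(len(keys), size=2, replace=False)
        ki, kj = keys[int(i)], keys[int(j)]
        cats[ki], cats[kj] = cats[kj], cats[ki]
        if self.target == "species":
            new.sync_species_rates()
            new.invalidate("all", trees_changed=False)
        else:
            new.invalidate([self.target], trees_changed=False)
        return Proposal(new, 0.0)


class PopSizeScale(Operator):
    """Scale one explicitly sampled population size (mcmc mode)."""

    name = "popsize_scale"

    def __init__(self, weight: float = 1.0, lam: float = 0.5):
        super().__init__(weight)
        self.lam = lam

    def propose(self, state, rng):
        new = state.copy()
        keys = list(new.species_tree.pop_size)
        if not keys:
            return Proposal.invalid()
        k = keys[rng.integers(len(keys))]
        s = _scale_factor(rng, self.lam)
        new.species_tree.pop_size[k] *= s
        new.invalidate(loci=())
        return Proposal(new, -math.log(s))


class PopSizeMeanScale(Operator):
    """Scale the population-size mean hyperparameter."""

    name = "popsize_mean_scale"

    def __init__(self, weight: float = 1.0, lam: float = 0.5):
        super().__init__(weight)
        self.lam = lam

    def propose(self, state, rng):
        s = _scale_factor(rng, self.lam)
        new = state.with_popsize_mean(state.popsize_mean * s)
        return Proposal(new, -math.log(s), touched=())


class DiversificationScale(Operator):
    name = "diversification_scale"

    def __init__(self, weight: float = 1.0, lam: float = 0.5):
        super().__init__(weight)
        self.lam = lam

    def propose(self, state, rng):
        s = _scale_factor(rng, self.lam)
        bd = BirthDeathParams(state.bd.diversification * s,
                              state.bd.extinction_fraction)
        return Proposal(state.with_bd(bd), -math.log(s))


class ExtinctionWalk(Operator):
    """Reflected uniform random walk on the extinction fraction in [0, 1)."""

    name = "extinction_walk"

    def __init__(self, weight: float = 1.0, window: float = 0.1):
        super().__init__(weight)
        self.window = window

    def propose(self, state, rng):
        f = state.bd.extinction_fraction + rng.uniform(-self.window, self.window)
        if f < 0:
            f = -f
        if f >= 1:
            f = 2.0 - f
        if not 0 <= f < 1:
            return Proposal.invalid()
        bd = BirthDeathParams(state.bd.diversification, f)
        return Proposal(state.with_bd(bd), 0.0)


class LocusRateScale(Operator):
    """Scale one locus clock rate (unconstrained locus-rate mode)."""

    name = "locus_rate_scale"

    def __init__(self, weight: float = 1.0, lam: float = 0.75):
        super().__init__(weight)
        self.lam = lam

    def propose(self, state, rng):
        i = int(rng.integers(len(state.locus_rates)))
        s = _scale_factor(rng, self.lam)
        new = state.copy()
        new.locus_rates[i] *= s
        new.invalidate([i], trees_changed=False)
        return Proposal(new, -math.log(s))


class RateTreeCounterScale(Operator):
    """Scale all tree heights by s and all locus rates by 1/s, sliding the
    state along the rate-time confounding ridge (likelihood invariant);
    log HR = (n_up - n_down - 2) log s."""

    name = "rate_tree_counter_scale"

    def __init__(self, weight: float = 1.0, lam: float = 0.85):
        super().__init__(weight)
        self.lam = lam

    def propose(self, state, rng):
        s = _scale_factor(rng, self.lam)
        new = state.copy()
        n_up = 0
        for tree in [new.species_tree] + list(new.gene_trees):
            for node in tree.postorder():
                if node.children:
                    node.height *= s
                    n_up += 1
        new.locus_rates /= s
        n_down = len(new.locus_rates)
        new.invalidate("all")
        return Proposal(new, (n_up - n_down - 2) * math.log(s))


class LocusRateExchange(Operator):
    """Move rate mass between two loci, keeping the mean locus rate fixed
    (the identifiability constraint); symmetric."""

    name = "locus_rate_exchange"

    def __init__(self, weight: float = 1.0, window: float = 0.2):
        super().__init__(weight)
        self.window = window

    def propose(self, state, rng):
        if len(state.locus_rates) < 2:
            return Proposal.invalid()
        i, j = rng.choice(len(state.locus_rates), size=2, replace=False)
        i, j = int(i), int(j)
        d = rng.uniform(0.0, self.window)
        new = state.copy()
        new.locus_rates[i] += d
        new.locus_rates[j] -= d
        if new.locus_rates[j] <= 0:
            return Proposal.invalid()
        new.invalidate([i, j], trees_changed=False)
        return Proposal(new, 0.0)


# ---------------------------------------------------------------------------
# default operator suite
# ---------------------------------------------------------------------------

def default_operators(state: McmcState,
                      coordinated_topology: bool = False,
                      naive_topology: bool = True,
                      coordinated_heights: bool = True) -> list[Operator]:
    """The documented default mix.

    Mirrors the recommended configuration: coordinated height operators and
    analytical integration on, naive topology operators on, coordinated
    topology operators off (selectable).  Weights were tuned once on the
    synthetic fixtures.
    """
    s = state.settings
    ops: list[Operator] = []
    n_loci = len(state.gene_trees)
    ops.append(TreeScale(3.0, "all"))
    ops.append(TreeScale(1.0, "species"))
    ops.append(UniformNodeHeight(3.0, "species"))
    ops.append(RootHeightScale(1.0, "species"))
    if coordinated_heights:
        ops.append(CoordinatedUniform(5.0))
        ops.append(CoordinatedExponential(2.0))
    if not s.fixed_species_topology:
        if naive_topology:
            ops.append(NarrowExchange(3.0, "species"))
            ops.append(SpeciesSPR(1.0))
        if coordinated_topology:
            ops.append(CoordinatedExchange(3.0))
    for i in range(n_loci):
        ops.append(UniformNodeHeight(2.0, i))
        ops.append(RootHeightScale(0.5, i))
        ops.append(NarrowExchange(1.5, i))
        ops.append(WilsonBalding(1.5, i))
    if s.clock_kind.startswith("st_") or (s.concatenation
                                          and s.clock_kind != "strict"):
        ops.append(CategoryResample(3.0, "species"))
        ops.append(CategorySwap(1.0, "species"))
    if s.clock_kind.startswith("gt_"):
        for i in range(state.n_loci):
            ops.append(CategoryResample(1.0, i))
            ops.append(CategorySwap(0.5, i))
    if s.popsize_mode == "mcmc" and not s.concatenation:
        ops.append(PopSizeScale(3.0))
    if s.estimate_popsize_mean:
        ops.append(PopSizeMeanScale(1.0))
    if s.estimate_diversification:
        ops.append(DiversificationScale(1.0))
    if s.estimate_extinction:
        ops.append(ExtinctionWalk(1.0))
    if s.estimate_locus_rates:
        if s.locus_rate_constrain and state.n_loci > 1:
            ops.append(LocusRateExchange(2.0))
        else:
            ops.append(LocusRateScale(2.0))
            ops.append(RateTreeCounterScale(2.0))
    return ops
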
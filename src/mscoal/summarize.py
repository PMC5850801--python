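"""Posterior summaries: tree distances, credible sets, point estimates.

These are the statistics used to score inference accuracy and coverage:
rooted Robinson-Foulds distances to the truth, maximum clade credibility
topologies, 95% credible topology sets, highest-posterior-density intervals,
common-ancestor branch-length point estimates conditioned on a reference
topology, and the branch-length error/bias ratios.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from .trees import Tree

__all__ = [
    "rooted_rf_distance",
    "topology_key",
    "mcc_tree",
    "credible_set",
    "hpd_interval",
    "common_ancestor_heights",
    "common_ancestor_branch_lengths",
    "branch_length_error_and_bias",
    "rate_regression",
]


def rooted_rf_distance(tree1: Tree, tree2: Tree) -> int:
    """Number of rooted clades present in exactly one of the two trees."""
    if set(tree1.tip_labels()) != set(tree2.tip_labels()):
        raise ValueError("trees have different tip sets")
    return len(tree1.clades() ^ tree2.clades())


def topology_key(tree: Tree) -> frozenset[frozenset[str]]:
    """Hashable rooted-topology identifier (the set of clades)."""
    return frozenset(tree.clades())


def mcc_tree(samples: list[Tree]) -> Tree:
    """Maximum clade credibility topology.

    Among sampled topologies, the one maximizing the product of posterior
    clade frequencies; ties broken deterministically by the lexicographically
    smallest sorted clade-string representation.
    """
    if not samples:
        raise ValueError("no samples")
    clade_counts: Counter[frozenset[str]] = Counter()
    for t in samples:
        clade_counts.update(t.clades())
    n = len(samples)

    def score(t: Tree) -> float:
        return sum(math.log(clade_counts[c] / n) for c in t.clades())

    def tiebreak(t: Tree) -> str:
        return ";".join(sorted(",".join(sorted(c)) for c in t.clades()))

    best = None
    seen: set[frozenset[frozenset[str]]] = set()
    for t in samples:
        key = topology_key(t)
        if key in seen:
            continue
        seen.add(key)
        cand = (score(t), t)
        if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and tiebreak(t) < tiebreak(best[1])):
            best = cand
    return best[1]


def credible_set(topology_frequencies: dict, level: float = 0.95) -> set:
    """Smallest high-to-low prefix of topologies whose cumulative posterior
    probability reaches the level."""
    total = sum(topology_frequencies.values())
    out = set()
    cum = 0.0
    for topo, f in sorted(topology_frequencies.items(),
                          key=lambda kv: (-kv[1], str(kv[0]))):
        out.add(topo)
        cum += f / total
        if cum >= level - 1e-12:
            break
    return out


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing at least ``level`` of the samples.

    Sorted-window search; ties broken toward the lower left endpoint.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    k = int(math.ceil(level * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def common_ancestor_heights(samples: list[Tree],
                            reference: Tree) -> dict[int, float | None]:
    """Common-ancestor node-height point estimates on a reference topology.

    For each internal reference node, the mean over posterior samples of the
    height of the MRCA of that node's tip set.  A clade that is never
    monophyletic still has an MRCA, so the estimate always exists; estimates
    keyed by reference node id (tips report 0).
    """
    if not samples:
        raise ValueError("no samples")
    out: dict[int, float | None] = {}
    for node in reference.postorder():
        if node.is_tip():
            out[node.id] = 0.0
            continue
        tips = reference.leaf_set(node)
        heights = [t.mrca(tips).height for t in samples]
        out[node.id] = float(np.mean(heights))
    return out


def common_ancestor_branch_lengths(samples: list[Tree],
                                   reference: Tree) -> dict[int, float]:
    """Per-branch point estimates: differences of common-ancestor heights
    between each reference node and its parent (root branch excluded)."""
    heights = common_ancestor_heights(samples, reference)
    out: dict[int, float] = {}
    for node in reference.postorder():
        if node.parent is None:
            continue
        out[node.id] = heights[node.parent.id] - heights[node.id]
    return out


def branch_length_error_and_bias(estimates: dict, truth: dict,
                                 branch_ids=None) -> tuple[float, float]:
    """Relative branch-length error and total bias over a branch set.

    error = sum |est - true| / sum true; bias = (sum est - sum true)/sum true.
    """
    ids = list(branch_ids) if branch_ids is not None else list(truth)
    if not ids:
        raise ValueError("empty branch set")
    est = np.array([estimates[b] for b in ids], dtype=float)
    tru = np.array([truth[b] for b in ids], dtype=float)
    denom = tru.sum()
    if denom <= 0:
        raise ValueError("true branch lengths sum to zero")
    error = float(np.abs(est - tru).sum() / denom)
    bias = float((est.sum() - tru.sum()) / denom)
    return error, bias


def rate_regression(true_rates, estimated_rates) -> float:
    """OLS R^2 of estimated branch rates against true rates.

    Root branches (fixed at 1 during inference) are expected to be excluded
    by the caller.
    """
    x = np.asarray(true_rates, dtype=float)
    y = np.asarray(estimated_rates, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired rates")
    if np.var(x) == 0:
        raise ValueError("true rates have zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
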
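"""Molecular clock models: strict, gene-tree relaxed, species-tree relaxed.

Every model ultimately produces one substitution rate per gene-tree branch,
which is what the phylogenetic likelihood consumes.  Relaxed-clock rate
distributions (log-normal or exponential, mean 1 in real space) are
discretized into quantile-midpoint bins; each branch carries an integer
category index, the standard device that keeps the prior on rates uniform
over categories.

The species-tree relaxed clock assigns a relative rate R to every species
branch; a gene branch's rate is the length-weighted average of the species
rates it traverses, times the locus clock rate c:

    r = sum_segments(c * L * R) / l

where L is the time the gene branch spends in a species branch and
l = sum L is the gene branch length, so the expected substitutions r*l equal
sum c*L*R exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import expon, lognorm

from .trees import Embedding, GeneTree, SpeciesTree, embed_gene_tree

__all__ = [
    "discretize_rates",
    "RateCategoryAssignment",
    "SpeciesRates",
    "species_clock_gene_branch_rate",
    "species_clock_rates",
    "gene_tree_relaxed_rates",
    "strict_rates",
]


def discretize_rates(kind: str, sigma: float, n_bins: int) -> np.ndarray:
    """Quantile-midpoint discretization of a mean-1 rate distribution.

    Rates are the distribution quantiles at probabilities (i+0.5)/n_bins,
    renormalized so their arithmetic mean is exactly 1.  ``kind`` is
    "lognormal" (real-space mean 1, log-sd ``sigma``, i.e. log-mean
    -sigma^2/2) or "exponential" (mean 1; ``sigma`` ignored).
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    p = (np.arange(n_bins) + 0.5) / n_bins
    if kind == "lognormal":
        if sigma == 0.0:
            return np.ones(n_bins)
        rates = lognorm.ppf(p, s=sigma, scale=math.exp(-0.5 * sigma * sigma))
    elif kind == "exponential":
        rates = expon.ppf(p)
    else:
        raise ValueError(f"unknown rate distribution kind {kind!r}")
    return rates / rates.mean()


@dataclass
class RateCategoryAssignment:
    """Discretized relaxed-clock state: one category index per branch.

    ``categories`` is keyed by the id of the node below each branch.  The
    bin rates always have mean 1 before multiplication by the locus rate.
    """

    kind: str = "lognormal"
    sigma: float = 0.3
    n_bins: int = 1
    categories: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rates = discretize_rates(self.kind, self.sigma, self.n_bins)
        for cat in self.categories.values():
            if not 0 <= cat < self.n_bins:
                raise ValueError("category index out of range")

    @property
    def bin_rates(self) -> np.ndarray:
        return self._rates

    def rate_of(self, branch_id: int) -> float:
        return float(self._rates[self.categories[branch_id]])

    def copy(self) -> "RateCategoryAssignment":
        return RateCategoryAssignment(self.kind, self.sigma, self.n_bins,
                                      dict(self.categories))


@dataclass
class SpeciesRates:
    """Relative substitution rate per species branch plus the locus clock.

    ``rates`` is keyed by species branch (child-node id); the root branch is
    fixed at 1 during inference by convention.
    """

    rates: dict[int, float]
    locus_rate: float = 1.0


def species_clock_gene_branch_rate(segments: list[tuple[int, float]],
                                   species_rates: dict[int, float],
                                   locus_rate: float) -> float:
    """Rate of one gene branch from its (species branch, L) segments."""
    total_time = sum(L for _, L in segments)
    if total_time <= 0:
        raise ValueError("zero-length gene branch")
    expected_subs = sum(locus_rate * L * species_rates[b] for b, L in segments)
    return expected_subs / total_time


def species_clock_rates(gene_tree: GeneTree, species_tree: SpeciesTree,
                        mapping: dict[str, str], locus_rate: float,
                        embedding: Embedding | None = None) -> dict[int, float]:
    """Per-gene-branch rates under the species-tree relaxed clock."""
    if embedding is None:
        embedding = embed_gene_tree(gene_tree, species_tree, mapping)
    return {
        nid: species_clock_gene_branch_rate(
            embedding.lengths(nid), species_tree.rate, locus_rate)
        for nid in embedding.segments
    }


def gene_tree_relaxed_rates(assignment: RateCategoryAssignment,
                            locus_rate: float) -> dict[int, float]:
    """Per-branch rates for a gene-tree relaxed clock (UCLN/UCED)."""
    return {nid: locus_rate * assignment.rate_of(nid)
            for nid in assignment.categories}


def strict_rates(gene_tree: GeneTree, locus_rate: float) -> dict[int, float]:
    """Strict clock: every branch evolves at the locus rate."""
    return {n.id: locus_rate for n in gene_tree.postorder() if n.parent is not None}
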
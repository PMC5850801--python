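"""Prior and model densities for multispecies-coalescent inference.

Covers the MSC coalescent density of gene trees embedded in a species tree
with constant per-branch population sizes, its analytical marginalization
over population sizes under a conjugate inverse-gamma prior, the gamma prior
used when population sizes are sampled explicitly by MCMC, and the
birth-death / Yule species-tree prior.

Population sizes follow the haploid-equivalent convention: ``N_b`` is the
size entering the coalescence rate directly, so j lineages coalesce at rate
C(j,2)/N_b and a branch of duration tau spans tau/N_b coalescent units
(equal to tau/(2*Ne) with diploid Ne = N_b/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .trees import GeneTree, SpeciesTree, gene_species_mrca, residence

__all__ = [
    "InverseGammaPrior",
    "BirthDeathParams",
    "BranchCoalStats",
    "branch_coal_stats",
    "coalescent_log_density",
    "integrated_coalescent_log_density",
    "invgamma_mean_cv",
    "birth_death_log_density",
    "yule_log_density",
    "mcmc_popsize_log_prior",
    "log_one_over_x_prior",
]


@dataclass(frozen=True)
class InverseGammaPrior:
    """Conjugate inverse-gamma prior on per-branch population sizes.

    With the shape fixed at ``alpha = 3`` the mean is ``beta/2`` and the
    coefficient of variation is exactly 1, so only the mean needs estimating.
    """

    alpha: float = 3.0
    beta: float = 0.004

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("inverse-gamma parameters must be positive")

    @property
    def mean(self) -> float:
        if self.alpha <= 1:
            raise ValueError("mean undefined for alpha <= 1")
        return self.beta / (self.alpha - 1.0)

    @classmethod
    def from_mean(cls, mean: float, alpha: float = 3.0) -> "InverseGammaPrior":
        return cls(alpha=alpha, beta=mean * (alpha - 1.0))


def invgamma_mean_cv(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and coefficient of variation of an inverse-gamma distribution.

    Requires ``alpha > 2`` so both moments exist; with ``alpha = 3`` the
    coefficient of variation is 1 for every scale.
    """
    if alpha <= 2:
        raise ValueError("alpha must exceed 2 for the cv to exist")
    mean = beta / (alpha - 1.0)
    cv = 1.0 / math.sqrt(alpha - 2.0)
    return mean, cv


@dataclass(frozen=True)
class BirthDeathParams:
    """Net diversification rate d = lambda - mu and extinction fraction
    f = mu/lambda of the species-tree birth-death prior."""

    diversification: float
    extinction_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.diversification <= 0:
            raise ValueError("net diversification must be positive")
        if not 0.0 <= self.extinction_fraction < 1.0:
            raise ValueError("extinction fraction must be in [0, 1)")

    @property
    def birth(self) -> float:
        return self.diversification / (1.0 - self.extinction_fraction)

    @property
    def death(self) -> float:
        return self.birth * self.extinction_fraction

    @classmethod
    def from_rates(cls, birth: float, death: float) -> "BirthDeathParams":
        if birth <= death:
            raise ValueError("birth rate must exceed death rate")
        return cls(diversification=birth - death,
                   extinction_fraction=death / birth)


@dataclass
class BranchCoalStats:
    """Sufficient statistics of the coalescent process per species branch.

    ``n[b]`` counts coalescences inside branch b (keyed by child-node id,
    root branch included); ``gamma[b]`` is the integrated coalescent
    intensity sum_intervals C(j,2)*dt.  Pooled over loci, these are all the
    coalescent density needs, which is what makes the inverse-gamma
    integration analytic.
    """

    n: dict[int, int] = field(default_factory=dict)
    gamma: dict[int, float] = field(default_factory=dict)

    def add(self, other: "BranchCoalStats") -> None:
        for b, k in other.n.items():
            self.n[b] = self.n.get(b, 0) + k
        for b, g in other.gamma.items():
            self.gamma[b] = self.gamma.get(b, 0.0) + g


def _single_locus_stats(gene_tree: GeneTree, species_tree: SpeciesTree,
                        mapping: dict[str, str],
                        ploidy: float = 1.0) -> BranchCoalStats:
    """Sweep one gene tree through the species tree.

    ``ploidy`` rescales the effective size of this locus relative to the
    shared per-branch size (coalescence rate C(j,2)/(ploidy*N_b)); the gamma
    statistic absorbs the factor so pooling across loci stays valid.
    """
    anchors = gene_species_mrca(gene_tree, species_tree, mapping)
    # per species branch: list of (time, delta_lineages); coalescence count
    events: dict[int, list[tuple[float, int]]] = {b: [] for b in species_tree.nodes}
    ncoal: dict[int, int] = {b: 0 for b in species_tree.nodes}
    for node in gene_tree.postorder():
        if node.parent is None:
            continue
        t0, t1 = node.height, node.parent.height
        sp = residence(species_tree, anchors[node.id], t0)
        t = t0
        while sp.parent is not None and sp.parent.height < t1:
            events[sp.id].append((t, +1))
            events[sp.id].append((sp.parent.height, -1))
            t = sp.parent.height
            sp = sp.parent
        events[sp.id].append((t, +1))
        events[sp.id].append((t1, -1))
    for node in gene_tree.internals():
        sp = residence(species_tree, anchors[node.id], node.height)
        ncoal[sp.id] += 1
    stats = BranchCoalStats()
    inv_ploidy = 1.0 / ploidy
    for b, evs in events.items():
        gamma = 0.0
        if evs:
            evs.sort()
            j = 0
            tprev = evs[0][0]
            for t, d in evs:
                if t > tprev and j >= 2:
                    gamma += 0.5 * j * (j - 1) * (t - tprev)
                tprev = t
                j += d
        stats.gamma[b] = gamma * inv_ploidy
        stats.n[b] = ncoal[b]
    return stats


def branch_coal_stats(gene_trees: list[GeneTree], species_tree: SpeciesTree,
                      mappings: list[dict[str, str]],
                      ploidies: list[float] | None = None) -> BranchCoalStats:
    """Coalescence counts and integrated intensities pooled across loci."""
    stats = BranchCoalStats()
    stats.n = {b: 0 for b in species_tree.nodes}
    stats.gamma = {b: 0.0 for b in species_tree.nodes}
    for i, (gt, mp) in enumerate(zip(gene_trees, mappings)):
        p = ploidies[i] if ploidies else 1.0
        stats.add(_single_locus_stats(gt, species_tree, mp, ploidy=p))
    return stats


def coalescent_log_density(gene_tree: GeneTree, species_tree: SpeciesTree,
                           mapping: dict[str, str],
                           pop_sizes: dict[int, float] | None = None,
                           ploidy: float = 1.0) -> float:
    """Log MSC density of one gene tree given explicit population sizes.

    ``prod_b N_b^{-n_b} exp(-gamma_b / N_b)`` over species branches, with
    sizes taken from the species tree when not supplied.
    """
    if pop_sizes is None:
        pop_sizes = species_tree.pop_size
    stats = _single_locus_stats(gene_tree, species_tree, mapping, ploidy=ploidy)
    out = 0.0
    for b in stats.n:
        nb, gb = stats.n[b], stats.gamma[b]
        if nb == 0 and gb == 0.0:
            continue
        if pop_sizes[b] <= 0:
            raise ValueError("population sizes must be positive")
        # effective size for this locus is ploidy*N_b; gamma already carries
        # the 1/ploidy factor from the sweep
        out += -nb * (math.log(pop_sizes[b]) + math.log(ploidy)) \
            - gb / pop_sizes[b]
    return out


def integrated_coalescent_log_density(stats: BranchCoalStats,
                                      prior: InverseGammaPrior) -> float:
    """Log marginal coalescent density with population sizes integrated out.

    Per branch, ``int_0^inf N^{-n} e^{-gamma/N} invgamma(N; a, b) dN`` has
    the closed conjugate form ``b^a Gamma(a+n) / (Gamma(a) (b+gamma)^{a+n})``
    (the inverse-gamma posterior update a -> a+n, b -> b+gamma).
    """
    a, b = prior.alpha, prior.beta
    out = 0.0
    base = a * math.log(b) - gammaln(a)
    for br, nb in stats.n.items():
        gb = stats.gamma[br]
        if nb == 0 and gb == 0.0:
            continue
        out += base + gammaln(a + nb) - (a + nb) * math.log(b + gb)
    return out


# ---------------------------------------------------------------------------
# species tree priors
# ---------------------------------------------------------------------------

def _log_p1(t: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """log p1(t): probability a lineage of age t leaves exactly one
    extant descendant (complete sampling)."""
    r = lam - mu
    return 2.0 * math.log(r) - r * t - 2.0 * np.log(lam - mu * np.exp(-r * t))


def birth_death_log_density(species_tree: SpeciesTree,
                            params: BirthDeathParams) -> float:
    """Log prior density of a species time-tree under the reconstructed
    birth-death process conditioned on its number of extant tips.

    The process starts from a single lineage whose origin time carries an
    improper uniform prior (equivalently: the tree is observed at a
    stationary time while n species are extant).  The resulting joint
    density over the labeled topology and the ordered internal-node heights
    x_1 > ... > x_{n-1} is

        2^{n-1}/(n-1)! * lambda * Q(x_1) * prod_i lambda * p1(x_i)

    with p1(t) = r^2 e^{-rt} / (lambda - mu e^{-rt})^2 and
    Q(x) = int_x^inf p1 = r e^{-rx} / (lambda (lambda - mu e^{-rx})).
    For mu = 0 this reduces to the Yule form lambda^{n-1} e^{-lambda L}
    (L = total branch length) up to the same topology constant.
    """
    lam, mu = params.birth, params.death
    r = lam - mu
    heights = np.array([n.height for n in species_tree.internals()], dtype=float)
    if heights.size == 0:
        raise ValueError("species tree has no internal nodes")
    n = heights.size + 1
    x1 = float(heights.max())
    log_q = math.log(r) - r * x1 - math.log(lam) - math.log(lam - mu * math.exp(-r * x1))
    out = (n - 1) * math.log(2.0) - gammaln(n) + math.log(lam)
    out += log_q
    out += float(np.sum(math.log(lam) + _log_p1(heights, lam, mu)))
    return out


def yule_log_density(species_tree: SpeciesTree, birth: float) -> float:
    """Pure-birth species-tree prior: birth_death with extinction 0."""
    return birth_death_log_density(
        species_tree, BirthDeathParams(diversification=birth))


def mcmc_popsize_log_prior(pop_sizes: dict[int, float] | list[float],
                           mean: float, shape: float = 2.0) -> float:
    """Gamma prior on explicitly sampled population sizes.

    Shape fixed (default 2) with the scale set so the prior mean equals the
    ``mean`` hyperparameter; i.i.d. across branches.
    """
    if mean <= 0:
        raise ValueError("mean population size must be positive")
    vals = list(pop_sizes.values()) if isinstance(pop_sizes, dict) else list(pop_sizes)
    scale = mean / shape
    out = 0.0
    for N in vals:
        if N <= 0:
            raise ValueError("population sizes must be positive")
        out += (shape - 1.0) * math.log(N) - N / scale \
            - shape * math.log(scale) - gammaln(shape)
    return out


def log_one_over_x_prior(x: float, lo: float, hi: float) -> float:
    """Truncated 1/x prior (proper on [lo, hi]); used as the hyperprior on
    the population-size mean."""
    if not (lo > 0 and hi > lo):
        raise ValueError("need 0 < lo < hi")
    if not (lo <= x <= hi):
        return -math.inf
    return -math.log(x) - math.log(math.log(hi / lo))
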
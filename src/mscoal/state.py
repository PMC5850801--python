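"""The joint MCMC state: species tree, gene trees, clocks, hyperparameters.

The state owns cached per-locus branch rates and log-likelihoods; proposal
kernels copy the state, mutate the copy, and invalidate exactly the loci
they touched.  Prior terms are cheap and recomputed lazily as a block.
Cache coherence (cached totals equal a fresh recomputation) is a tested
invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .clocks import discretize_rates, species_clock_rates
from .msc_model import (BirthDeathParams, BranchCoalStats, InverseGammaPrior,
                        _single_locus_stats, birth_death_log_density,
                        integrated_coalescent_log_density,
                        log_one_over_x_prior, mcmc_popsize_log_prior)
from .phylo_likelihood import (Alignment, SiteRateModel, SubstModel,
                               locus_log_likelihood)
from .trees import GeneTree, SpeciesTree, is_compatible

__all__ = ["ModelSettings", "McmcState"]


@dataclass(frozen=True)
class ModelSettings:
    """Immutable run configuration shared by all states of a chain."""

    tree_prior: str = "birth_death"          # "yule" | "birth_death"
    estimate_diversification: bool = False
    estimate_extinction: bool = False
    diversification_range: tuple[float, float] = (1e-3, 1e6)

    popsize_mode: str = "integrated"         # "integrated" | "mcmc"
    popsize_alpha: float = 3.0               # inverse-gamma shape (integrated)
    popsize_gamma_shape: float = 2.0         # gamma shape (mcmc mode)
    estimate_popsize_mean: bool = False
    popsize_mean_range: tuple[float, float] = (1e-8, 10.0)

    clock_kind: str = "strict"   # strict | st_ucln | st_uced | gt_ucln | gt_uced
    clock_sigma: float = 0.3
    clock_bins: int | None = None            # None => number of branches

    estimate_locus_rates: bool = False
    locus_rate_sigma: float = 0.6
    # True: sample on the mean-rate-1 manifold (identifiability device for
    # many-locus runs); False: rates free with their i.i.d. lognormal prior
    locus_rate_constrain: bool = True

    ploidies: tuple[float, ...] | None = None
    concatenation: bool = False
    fixed_species_topology: bool = False

    def rate_distribution(self) -> str:
        return "exponential" if self.clock_kind.endswith("uced") else "lognormal"


class McmcState:
    """One point of the posterior: trees plus scalar parameters.

    In ``concatenation`` mode there are no gene trees: every locus is scored
    directly on the species tree (the shared-tree model that concatenated
    analyses assume) and the coalescent term is dropped.
    """

    def __init__(self, settings: ModelSettings, species_tree: SpeciesTree,
                 gene_trees: list[GeneTree], mappings: list[dict[str, str]],
                 locus_rates: np.ndarray,
                 bd: BirthDeathParams,
                 popsize_mean: float,
                 species_cats: dict[int, int] | None = None,
                 gene_cats: list[dict[int, int]] | None = None,
                 alignments: list[Alignment] | None = None,
                 subst_models: list[SubstModel] | None = None,
                 site_models: list[SiteRateModel | None] | None = None):
        self.settings = settings
        self.species_tree = species_tree
        self.gene_trees = gene_trees
        self.mappings = mappings
        self.locus_rates = np.asarray(locus_rates, dtype=float)
        self.bd = bd
        self.popsize_mean = float(popsize_mean)
        self.species_cats = species_cats
        self.gene_cats = gene_cats
        self.alignments = alignments
        self.subst_models = subst_models
        self.site_models = site_models

        kind = settings.clock_kind
        n_sp_branches = sum(1 for n in species_tree.postorder()
                            if n.parent is not None)
        bins = settings.clock_bins
        if kind.startswith("st_") or settings.concatenation and kind != "strict":
            self._sp_bin_rates = discretize_rates(
                settings.rate_distribution(), settings.clock_sigma,
                bins if bins is not None else n_sp_branches)
        else:
            self._sp_bin_rates = None
        if kind.startswith("gt_"):
            self._gt_bin_rates = [discretize_rates(
                settings.rate_distribution(), settings.clock_sigma,
                bins if bins is not None else len(gc)) for gc in gene_cats]
        else:
            self._gt_bin_rates = None
        self.sync_species_rates()

        n_loci = len(alignments) if alignments else len(gene_trees)
        self.n_loci = n_loci
        self._lik: list[float | None] = [None] * n_loci
        self._branch_rates: list[dict[int, float] | None] = [None] * n_loci
        self._coal_stats: list[BranchCoalStats | None] = \
            [None] * len(gene_trees)
        self._prior: float | None = None
        self._prior_parts: dict[str, float] | None = None

    # -- bookkeeping ------------------------------------------------------

    def sync_species_rates(self) -> None:
        """Refresh the species-tree per-branch rates from the categories."""
        if self._sp_bin_rates is None:
            return
        rates = {nid: float(self._sp_bin_rates[cat])
                 for nid, cat in self.species_cats.items()}
        rates[self.species_tree.root.id] = 1.0  # root branch fixed at 1
        self.species_tree.rate = rates

    def copy(self) -> "McmcState":
        new = object.__new__(McmcState)
        new.settings = self.settings
        new.species_tree = self.species_tree.copy()
        new.gene_trees = [g.copy() for g in self.gene_trees]
        new.mappings = self.mappings
        new.locus_rates = self.locus_rates.copy()
        new.bd = self.bd
        new.popsize_mean = self.popsize_mean
        new.species_cats = dict(self.species_cats) if self.species_cats else None
        new.gene_cats = ([dict(g) for g in self.gene_cats]
                         if self.gene_cats else None)
        new.alignments = self.alignments
        new.subst_models = self.subst_models
        new.site_models = self.site_models
        new._sp_bin_rates = self._sp_bin_rates
        new._gt_bin_rates = self._gt_bin_rates
        new.n_loci = self.n_loci
        new._lik = list(self._lik)
        new._branch_rates = list(self._branch_rates)
        new._coal_stats = list(self._coal_stats)
        new._prior = self._prior
        new._prior_parts = self._prior_parts
        return new

    def invalidate(self, loci="all", trees_changed: bool = True) -> None:
        """Drop caches: prior always, per-locus likelihood for touched loci.

        ``trees_changed=False`` keeps the per-locus coalescent sufficient
        statistics (correct for moves that only alter rates, categories or
        hyperparameters, never tree shapes or heights).
        """
        self._prior = None
        self._prior_parts = None
        if loci == "all":
            self._lik = [None] * self.n_loci
            self._branch_rates = [None] * self.n_loci
            if trees_changed:
                self._coal_stats = [None] * len(self.gene_trees)
        else:
            for i in loci:
                self._lik[i] = None
                self._branch_rates[i] = None
                if trees_changed and i < len(self._coal_stats):
                    self._coal_stats[i] = None

    def invalidate_species_heights(self, touched_loci) -> None:
        """Species node heights moved (topologies intact): every locus's
        coalescent statistics are stale, but likelihoods only for the loci
        whose gene nodes moved."""
        self._prior = None
        self._prior_parts = None
        self._coal_stats = [None] * len(self.gene_trees)
        for i in touched_loci:
            self._lik[i] = None
            self._branch_rates[i] = None

    def coal_stats(self, i: int) -> BranchCoalStats:
        if self._coal_stats[i] is None:
            s = self.settings
            p = s.ploidies[i] if s.ploidies else 1.0
            self._coal_stats[i] = _single_locus_stats(
                self.gene_trees[i], self.species_tree, self.mappings[i],
                ploidy=p)
        return self._coal_stats[i]

    def compatible(self) -> bool:
        return all(is_compatible(g, self.species_tree, m)
                   for g, m in zip(self.gene_trees, self.mappings))

    # -- clock ------------------------------------------------------------

    def branch_rates(self, i: int) -> dict[int, float]:
        if self._branch_rates[i] is None:
            kind = self.settings.clock_kind
            c = float(self.locus_rates[i])
            if self.settings.concatenation:
                tree = self.species_tree
                if kind == "strict":
                    rates = {n.id: c for n in tree.postorder()
                             if n.parent is not None}
                else:
                    rates = {nid: c * float(self._sp_bin_rates[cat])
                             for nid, cat in self.species_cats.items()}
            elif kind == "strict":
                rates = {n.id: c for n in self.gene_trees[i].postorder()
                         if n.parent is not None}
            elif kind.startswith("st_"):
                rates = species_clock_rates(
                    self.gene_trees[i], self.species_tree, self.mappings[i], c)
            else:  # gt_ucln / gt_uced
                bins = self._gt_bin_rates[i]
                rates = {nid: c * float(bins[cat])
                         for nid, cat in self.gene_cats[i].items()}
            self._branch_rates[i] = rates
        return self._branch_rates[i]

    # -- densities ---------------------------------------------------------

    def locus_log_likelihood(self, i: int) -> float:
        if self._lik[i] is None:
            if not self.alignments:
                self._lik[i] = 0.0
            else:
                tree = (self.species_tree if self.settings.concatenation
                        else self.gene_trees[i])
                self._lik[i] = locus_log_likelihood(
                    self.alignments[i], tree, self.branch_rates(i),
                    self.subst_models[i],
                    self.site_models[i] if self.site_models else None)
        return self._lik[i]

    def log_likelihood(self) -> float:
        return sum(self.locus_log_likelihood(i) for i in range(self.n_loci))

    def log_prior_parts(self) -> dict[str, float]:
        if self._prior_parts is not None:
            return self._prior_parts
        s = self.settings
        parts: dict[str, float] = {}
        parts["tree_prior"] = birth_death_log_density(self.species_tree, self.bd)

        coal = 0.0
        popsize_prior = 0.0
        if not s.concatenation and self.gene_trees:
            pooled = BranchCoalStats()
            pooled.n = {b: 0 for b in self.species_tree.nodes}
            pooled.gamma = {b: 0.0 for b in self.species_tree.nodes}
            for i in range(len(self.gene_trees)):
                pooled.add(self.coal_stats(i))
            if s.popsize_mode == "integrated":
                prior = InverseGammaPrior.from_mean(self.popsize_mean,
                                                    alpha=s.popsize_alpha)
                coal = integrated_coalescent_log_density(pooled, prior)
            else:
                # explicit sizes: density from the pooled statistics; the
                # per-locus ploidy factors are already inside gamma, and the
                # n*log(ploidy) terms are state-independent constants
                for b, nb in pooled.n.items():
                    gb = pooled.gamma[b]
                    if nb == 0 and gb == 0.0:
                        continue
                    N = self.species_tree.pop_size[b]
                    coal += -nb * math.log(N) - gb / N
                popsize_prior = mcmc_popsize_log_prior(
                    self.species_tree.pop_size, self.popsize_mean,
                    shape=s.popsize_gamma_shape)
        parts["coalescent"] = coal
        parts["popsize_prior"] = popsize_prior

        hyper = 0.0
        if s.estimate_popsize_mean:
            hyper += log_one_over_x_prior(self.popsize_mean,
                                          *s.popsize_mean_range)
        if s.estimate_diversification:
            hyper += log_one_over_x_prior(self.bd.diversification,
                                          *s.diversification_range)
        # extinction fraction: uniform on [0,1), contributes 0
        parts["hyperprior"] = hyper

        clock = 0.0
        if s.estimate_locus_rates:
            sig = s.locus_rate_sigma
            mu = -0.5 * sig * sig
            for c in self.locus_rates:
                if c <= 0:
                    clock = -math.inf
                    break
                z = (math.log(c) - mu) / sig
                clock += -math.log(c * sig) - 0.5 * z * z \
                    - 0.5 * math.log(2.0 * math.pi)
        parts["clock_prior"] = clock
        self._prior_parts = parts
        return parts

    def log_prior(self) -> float:
        if self._prior is None:
            self._prior = sum(self.log_prior_parts().values())
        return self._prior

    def log_posterior(self) -> float:
        lp = self.log_prior()
        if not math.isfinite(lp):
            return lp
        return lp + self.log_likelihood()

    # -- recorded statistics -----------------------------------------------

    def trace_row(self, step: int) -> dict[str, float]:
        parts = self.log_prior_parts()
        lik = self.log_likelihood()
        prior = self.log_prior()
        return {
            "state": step,
            "posterior": prior + lik,
            "likelihood": lik,
            "prior": prior,
            "coalescent": parts["coalescent"],
            "tree_prior": parts["tree_prior"],
            "net_diversification": self.bd.diversification,
            "extinction_fraction": self.bd.extinction_fraction,
            "popsize_mean": self.popsize_mean,
            "species_tree_height": self.species_tree.root.height,
        }

    # -- parameter update helpers (used by operators) ------------------------

    def with_bd(self, bd: BirthDeathParams) -> "McmcState":
        new = self.copy()
        new.bd = bd
        new.invalidate(loci=())
        return new

    def with_popsize_mean(self, mean: float) -> "McmcState":
        new = self.copy()
        new.popsize_mean = mean
        new.invalidate(loci=())
        return new
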
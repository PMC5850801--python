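"""Generative models: birth-death species trees, MSC gene trees, clock rates
and sequence alignments, plus the preset study designs used for validation.

The species-tree simulator draws from exactly the same conditioned
birth-death law as the MCMC prior density (`msc_model.birth_death_log_density`):
the process starts from one lineage whose origin time is uniform-improper,
conditioned on n extant tips.  In CDF space the oldest speciation time is
Beta(n-1, 2) distributed and the remaining times are i.i.d. uniform below
it, so sampling is by exact inversion; the ranked labeled topology is
uniform and is built by merging uniformly chosen lineage pairs backwards in
time.  Agreement between this simulator and MCMC prior sampling is the
correctness protocol for the whole inference engine.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .clocks import discretize_rates, species_clock_rates
from .phylo_likelihood import (PAIR_TO_IUPAC, Alignment, SiteRateModel,
                               SubstModel)
from .trees import GeneTree, Node, SpeciesTree, write_mapping

__all__ = [
    "SimRecipe",
    "simulate_birth_death_tree",
    "simulate_msc_gene_tree",
    "simulate_pop_sizes",
    "simulate_species_rates",
    "simulate_alignment",
    "make_fixture",
    "coalescent_unit_summary",
    "ambiguity_collapse",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def _bd_cdf_inverse(q: np.ndarray, birth: float, death: float) -> np.ndarray:
    """Inverse of the per-node speciation-time CDF
    F(t) = birth*(1-e^{-rt})/(birth - death*e^{-rt})."""
    r = birth - death
    u = birth * (1.0 - q) / (birth - q * death)
    return -np.log(u) / r


def _build_ranked_topology(tree: SpeciesTree | GeneTree, labels: list[str],
                           heights: np.ndarray, rng: np.random.Generator,
                           join_order: list[tuple[int, int]] | None = None):
    """Coalesce tip lineages at the given ascending heights.

    Pairs are chosen uniformly (yielding the uniform ranked labeled
    topology) unless an explicit ``join_order`` of lineage-list indices is
    given, which pins the topology (used for the fixed SPILS caterpillar).
    """
    lineages = [tree.new_node(label=lab, height=0.0) for lab in labels]
    for k, h in enumerate(np.sort(heights)):
        if join_order is not None:
            i, j = join_order[k]
        else:
            i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = min(i, j), max(i, j)
        parent = tree.new_node(height=float(h))
        tree.attach(parent, lineages[i])
        tree.attach(parent, lineages[j])
        lineages[i] = parent
        del lineages[j]
    tree.root = lineages[0]
    return tree


def simulate_birth_death_tree(n_tips: int, birth: float, death: float,
                              rng: np.random.Generator,
                              labels: list[str] | None = None) -> SpeciesTree:
    """Ultrametric species tree conditioned on ``n_tips`` extant species."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    if labels is None:
        labels = [f"S{i+1}" for i in range(n_tips)]
    if n_tips == 2:
        # single split: u_1 ~ Beta(1, 2)
        u = np.array([rng.beta(1.0, 2.0)])
    else:
        u1 = rng.beta(n_tips - 1.0, 2.0)
        rest = rng.uniform(0.0, u1, size=n_tips - 2)
        u = np.concatenate([[u1], rest])
    heights = _bd_cdf_inverse(u, birth, death)
    tree = SpeciesTree()
    _build_ranked_topology(tree, labels, heights, rng)
    return tree


def simulate_caterpillar_tree(labels: list[str], birth: float, death: float,
                              rng: np.random.Generator) -> SpeciesTree:
    """Birth-death heights on the fixed pectinate topology
    ((((labels[0],labels[1]),...).  Heights are exchangeable with topology
    under the conditioned process, so conditioning on the ladder shape does
    not change their law."""
    n = len(labels)
    u1 = rng.beta(n - 1.0, 2.0)
    rest = rng.uniform(0.0, u1, size=n - 2)
    heights = _bd_cdf_inverse(np.concatenate([[u1], rest]), birth, death)
    # join (0,1) first, then attach each next label to the growing clade
    join_order = [(0, 1)] * (n - 1)
    tree = SpeciesTree()
    _build_ranked_topology(tree, labels, heights, rng, join_order=join_order)
    return tree


def simulate_pop_sizes(species_tree: SpeciesTree, distribution: str,
                       shape: float, scale: float,
                       rng: np.random.Generator) -> None:
    """Draw a haploid-equivalent population size for every branch
    (root branch included) in place."""
    for nid in species_tree.nodes:
        if distribution == "gamma":
            N = rng.gamma(shape, scale)
        elif distribution == "inverse_gamma":
            N = scale / rng.gamma(shape, 1.0)
        else:
            raise ValueError(f"unknown population-size distribution {distribution!r}")
        species_tree.pop_size[nid] = float(N)


def simulate_species_rates(species_tree: SpeciesTree, sigma: float,
                           renormalize: bool, rng: np.random.Generator,
                           kind: str = "lognormal",
                           n_bins: int | None = None) -> dict[int, float]:
    """Draw a relative rate for every non-root species branch in place.

    Continuous draws come from the mean-1 real-space distribution; when
    ``n_bins`` is given the draw is from the discretized version (uniform
    category), matching how the MCMC samples rates.  ``renormalize`` rescales
    the non-root rates to arithmetic mean exactly 1.  The root branch rate is
    fixed at 1.
    """
    nonroot = [n.id for n in species_tree.postorder() if n.parent is not None]
    if n_bins is not None:
        bins = discretize_rates(kind, sigma, n_bins)
        rates = bins[rng.integers(0, n_bins, size=len(nonroot))]
    elif kind == "lognormal":
        if sigma == 0.0:
            rates = np.ones(len(nonroot))
        else:
            rates = rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(nonroot))
    elif kind == "exponential":
        rates = rng.exponential(1.0, size=len(nonroot))
    else:
        raise ValueError(f"unknown rate distribution {kind!r}")
    if renormalize and len(nonroot) > 0:
        rates = rates / rates.mean()
    species_tree.rate = {nid: float(r) for nid, r in zip(nonroot, rates)}
    species_tree.rate[species_tree.root.id] = 1.0
    return species_tree.rate


# ---------------------------------------------------------------------------
# gene trees under the MSC
# ---------------------------------------------------------------------------

def simulate_msc_gene_tree(species_tree: SpeciesTree,
                           samples_per_species: int | dict[str, int],
                           rng: np.random.Generator,
                           pop_sizes: dict[int, float] | None = None,
                           ploidy: float = 1.0,
                           ) -> tuple[GeneTree, dict[str, str]]:
    """Simulate one gene tree inside the species tree.

    Within the branch above species node b, j lineages coalesce at rate
    C(j,2)/(ploidy*N_b); survivors are handed to the parent branch, and the
    ancestral (root) branch runs until one lineage remains.  Returns the
    gene tree and its haplotype->species mapping.
    """
    if pop_sizes is None:
        pop_sizes = species_tree.pop_size
    if not pop_sizes:
        raise ValueError("species tree has no population sizes")
    gt = GeneTree()
    mapping: dict[str, str] = {}
    active: dict[int, list[Node]] = {}
    order = sorted(species_tree.nodes.values(), key=lambda n: (n.height, n.id))
    for sp in order:
        if sp.is_tip():
            if isinstance(samples_per_species, int):
                haps = [f"{sp.label}_{i}" for i in range(samples_per_species)]
            else:
                spec = samples_per_species.get(sp.label, 0)
                haps = (list(spec) if not isinstance(spec, int)
                        else [f"{sp.label}_{i}" for i in range(spec)])
            lineages = []
            for hap in haps:
                lineages.append(gt.new_node(label=hap, height=0.0))
                mapping[hap] = sp.label
        else:
            lineages = []
            for ch in sp.children:
                lineages.extend(active.pop(ch.id))
        t = sp.height
        top = sp.parent.height if sp.parent is not None else math.inf
        N = pop_sizes[sp.id] * ploidy
        while len(lineages) > 1:
            j = len(lineages)
            t_next = t + rng.exponential(N / (0.5 * j * (j - 1)))
            if t_next >= top:
                break
            t = t_next
            i1, i2 = rng.choice(j, size=2, replace=False)
            i1, i2 = min(i1, i2), max(i1, i2)
            parent = gt.new_node(height=t)
            gt.attach(parent, lineages[i1])
            gt.attach(parent, lineages[i2])
            lineages[i1] = parent
            del lineages[i2]
        active[sp.id] = lineages
    final = active[species_tree.root.id]
    if len(final) != 1:
        raise ValueError("no haplotypes sampled: check the tip-to-species "
                         "mapping against the species tree labels")
    gt.root = final[0]
    return gt, mapping


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def simulate_alignment(gene_tree: GeneTree, branch_rates: dict[int, float],
                       model: SubstModel, site_rates: SiteRateModel | None,
                       length: int, rng: np.random.Generator) -> Alignment:
    """Evolve sequences down the gene tree.

    The root sequence is drawn from the stationary frequencies; each site is
    assigned one discrete-gamma category for its whole history; branches use
    transition matrices at distance rate x duration x category rate.
    """
    if length <= 0:
        raise ValueError("alignment length must be positive")
    cat_rates = site_rates.rates() if site_rates is not None else np.ones(1)
    ncat = len(cat_rates)
    site_cat = rng.integers(0, ncat, size=length)
    states: dict[int, np.ndarray] = {}
    root_state = rng.choice(4, size=length, p=model.freqs)
    states[gene_tree.root.id] = root_state
    for node in gene_tree.preorder():
        if node.parent is None:
            continue
        dt = node.parent.height - node.height
        P = model.transition(branch_rates[node.id] * dt * cat_rates)  # (ncat,4,4)
        parent_state = states[node.parent.id]
        probs = P[site_cat, parent_state]  # (length, 4)
        u = rng.random(length)
        states[node.id] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    bases = np.array(list("ACGT"))
    taxa, seqs = [], []
    for tip in gene_tree.tips():
        taxa.append(tip.label)
        seqs.append("".join(bases[states[tip.id]]))
    return Alignment(taxa, seqs)


def ambiguity_collapse(alignment: Alignment,
                       mapping: dict[str, str]) -> Alignment:
    """Collapse two phased haplotypes per species into one unphased sequence.

    Sites where the haplotypes agree pass through; heterozygous sites become
    the IUPAC code of the base pair.  Requires exactly two haplotypes per
    species.
    """
    by_species: dict[str, list[str]] = {}
    for taxon in alignment.taxa:
        by_species.setdefault(mapping[taxon], []).append(taxon)
    taxa, seqs = [], []
    for sp in sorted(by_species):
        haps = by_species[sp]
        if len(haps) != 2:
            raise ValueError(f"species {sp!r} has {len(haps)} haplotypes, need 2")
        s1, s2 = (alignment.sequence(h) for h in haps)
        out = []
        for a, b in zip(s1, s2):
            if a == b:
                out.append(a)
            else:
                out.append(PAIR_TO_IUPAC.get(frozenset((a, b)), "N"))
        taxa.append(sp)
        seqs.append("".join(out))
    return Alignment(taxa, seqs)


# ---------------------------------------------------------------------------
# summaries and presets
# ---------------------------------------------------------------------------

def coalescent_unit_summary(species_trees: list[SpeciesTree]) -> float:
    """Mean branch length in coalescent units tau/(2*Ne) over all non-root
    branches of the supplied trees (haploid sizes: tau/(2Ne) = tau/N)."""
    vals = []
    for st in species_trees:
        if not st.pop_size:
            raise ValueError("species tree lacks population sizes")
        for node in st.postorder():
            if node.parent is None:
                continue
            tau = node.parent.height - node.height
            vals.append(tau / st.pop_size[node.id])
    return float(np.mean(vals))


@dataclass(frozen=True)
class SimRecipe:
    """One replicate's generative settings."""

    n_species: int = 5
    samples_per_species: int = 1
    birth: float = 200.0
    death: float = 100.0
    popsize_distribution: str = "inverse_gamma"   # or "gamma"
    popsize_shape: float = 3.0
    popsize_scale: float = 0.004
    species_rate_sigma: float = 0.3
    species_rate_renormalize: bool = False
    species_rate_bins: int | None = None
    locus_rate_sigma: float = 0.0                 # 0 => fixed locus rates
    locus_rates: tuple[float, ...] | None = None  # explicit per-locus rates
    subst_model: str = "JC"
    kappa: float = 1.0
    gamma_shape: float | None = None
    gamma_categories: int = 4
    n_loci: int = 2
    length: int = 0                               # 0 => no sequences
    fixed_topology: tuple[str, ...] | None = None # caterpillar label order

    def species_labels(self) -> list[str]:
        if self.fixed_topology is not None:
            return list(self.fixed_topology)
        if self.n_species <= 26:
            return [chr(ord("A") + i) for i in range(self.n_species)]
        return [f"S{i+1}" for i in range(self.n_species)]


# The three validation designs.  prior_test: sampling-from-the-prior
# equivalence; simstudy: the 21-species parameter-recovery design; spils:
# the asymmetric-tree strict-clock design that elicits substitutions
# produced by incomplete lineage sorting.
PRESETS: dict[str, SimRecipe] = {
    "prior_test": SimRecipe(
        n_species=5, samples_per_species=1, birth=200.0, death=100.0,
        popsize_distribution="inverse_gamma", popsize_shape=3.0,
        popsize_scale=0.004, species_rate_sigma=0.3, species_rate_bins=100,
        locus_rates=(0.5, 2.0), n_loci=2, length=0),
    "simstudy": SimRecipe(
        n_species=21, samples_per_species=2, birth=100.0, death=30.0,
        popsize_distribution="gamma", popsize_shape=2.0, popsize_scale=0.002,
        species_rate_sigma=0.3, species_rate_renormalize=True,
        locus_rate_sigma=0.6, subst_model="HKY", kappa=3.0, gamma_shape=0.2,
        gamma_categories=4, n_loci=26, length=600),
    "spils": SimRecipe(
        n_species=5, samples_per_species=1, birth=10.0, death=0.0,
        popsize_distribution="inverse_gamma", popsize_shape=3.0,
        popsize_scale=0.2, species_rate_sigma=0.0, subst_model="JC",
        gamma_shape=None, n_loci=100, length=1000,
        fixed_topology=("A", "B", "C", "D", "E")),
}


def simulate_replicate(recipe: SimRecipe, rng: np.random.Generator):
    """Draw one full replicate: species tree (+sizes, +rates), gene trees,
    per-locus clock rates, per-gene-branch rates, and optional alignments."""
    labels = recipe.species_labels()
    if recipe.fixed_topology is not None:
        st = simulate_caterpillar_tree(labels, recipe.birth, recipe.death, rng)
    else:
        st = simulate_birth_death_tree(len(labels), recipe.birth,
                                       recipe.death, rng, labels=labels)
    simulate_pop_sizes(st, recipe.popsize_distribution, recipe.popsize_shape,
                       recipe.popsize_scale, rng)
    simulate_species_rates(st, recipe.species_rate_sigma,
                           recipe.species_rate_renormalize, rng,
                           n_bins=recipe.species_rate_bins)
    if recipe.locus_rates is not None:
        locus_rates = list(recipe.locus_rates)
    elif recipe.locus_rate_sigma > 0:
        s = recipe.locus_rate_sigma
        locus_rates = list(rng.lognormal(-0.5 * s * s, s, size=recipe.n_loci))
    else:
        locus_rates = [1.0] * recipe.n_loci
    model = SubstModel(recipe.subst_model, kappa=recipe.kappa)
    site_rates = (SiteRateModel(recipe.gamma_categories, recipe.gamma_shape)
                  if recipe.gamma_shape else None)
    gene_trees, mappings, alignments = [], [], []
    for c in locus_rates:
        gt, mapping = simulate_msc_gene_tree(
            st, recipe.samples_per_species, rng)
        gt.rate = species_clock_rates(gt, st, mapping, c)
        gene_trees.append(gt)
        mappings.append(mapping)
        if recipe.length > 0:
            alignments.append(simulate_alignment(
                gt, gt.rate, model, site_rates, recipe.length, rng))
    return {
        "species_tree": st,
        "gene_trees": gene_trees,
        "mappings": mappings,
        "locus_rates": locus_rates,
        "alignments": alignments,
        "recipe": recipe,
    }


def make_fixture(preset: str, scale: float, seed: int, out_dir,
                 n_replicates: int = 1) -> list[str]:
    """Write full replicate datasets to disk.

    ``scale`` in (0, 1] shrinks the number of loci (never the recipe's
    distributions).  Layout per replicate: ``loci/locus_###.fasta``,
    ``truth/species.nwk``, ``truth/gene_###.nwk``, ``truth/rates.tsv``,
    ``mapping.tsv``.  Returns the replicate directories.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    base = PRESETS[preset]
    n_loci = max(1, round(base.n_loci * scale))
    recipe = SimRecipe(**{**base.__dict__, "n_loci": n_loci,
                          "locus_rates": (base.locus_rates[:n_loci]
                                          if base.locus_rates else None)})
    rng = np.random.default_rng(seed)
    dirs = []
    for rep in range(n_replicates):
        rep_dir = os.path.join(str(out_dir), f"rep{rep:03d}")
        os.makedirs(os.path.join(rep_dir, "loci"), exist_ok=True)
        os.makedirs(os.path.join(rep_dir, "truth"), exist_ok=True)
        data = simulate_replicate(recipe, rng)
        st: SpeciesTree = data["species_tree"]
        with open(os.path.join(rep_dir, "truth", "species.nwk"), "w") as fh:
            fh.write(st.to_newick(annotations=st.branch_annotations()) + "\n")
        with open(os.path.join(rep_dir, "truth", "rates.tsv"), "w") as fh:
            fh.write("locus\tclock_rate\n")
            for i, c in enumerate(data["locus_rates"]):
                fh.write(f"{i}\t{c:.12g}\n")
        for i, gt in enumerate(data["gene_trees"]):
            ann = {nid: {"rate": r} for nid, r in gt.rate.items()}
            with open(os.path.join(rep_dir, "truth", f"gene_{i:03d}.nwk"), "w") as fh:
                fh.write(gt.to_newick(annotations=ann) + "\n")
        write_mapping(data["mappings"][0], os.path.join(rep_dir, "mapping.tsv"))
        for i, aln in enumerate(data["alignments"]):
            aln.write_fasta(os.path.join(rep_dir, "loci", f"locus_{i:03d}.fasta"))
        dirs.append(rep_dir)
    return dirs
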
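"""Metropolis-Hastings kernel, operator scheduling, traces and convergence.

The chain is a plain MH sampler over `McmcState`: one weighted-random
operator per step, acceptance probability min(1, exp(dlog posterior +
log HR)), invalid proposals rejected outright.  Runs are bit-reproducible
for a fixed seed.  Convergence bookkeeping follows the chain-doubling
protocol: discard 12.5% burn-in, estimate effective sample sizes for the
recorded statistics, and double the chain (halving the sampling rate so the
number of stored samples stays constant) until every monitored statistic
clears the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msc_model import BirthDeathParams
from .operators import Operator, Proposal, default_operators
from .phylo_likelihood import Alignment, SiteRateModel, SubstModel
from .simulate import simulate_msc_gene_tree
from .state import McmcState, ModelSettings
from .trees import GeneTree, SpeciesTree, read_mapping

__all__ = [
    "McmcState",
    "ModelSettings",
    "mh_step",
    "Mcmc",
    "build_state",
    "run_chain",
    "effective_sample_size",
    "burn_in_filter",
    "convergence_protocol",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "state", "posterior", "likelihood", "prior", "coalescent", "tree_prior",
    "net_diversification", "extinction_fraction", "popsize_mean",
    "species_tree_height",
]


def mh_step(state: McmcState, operator: Operator,
            rng: np.random.Generator) -> tuple[McmcState, bool]:
    """One Metropolis-Hastings update; returns (state, accepted)."""
    cur_lp = state.log_posterior()
    if not math.isfinite(cur_lp):
        raise ValueError("current state has non-finite posterior")
    operator.n_proposed += 1
    prop = operator.propose(state, rng)
    if prop is None or not prop.valid:
        return state, False
    new_lp = prop.state.log_posterior()
    if new_lp == -math.inf:
        return state, False
    delta = new_lp - cur_lp + prop.log_hastings
    if delta >= 0 or rng.random() < math.exp(delta):
        operator.n_accepted += 1
        return prop.state, True
    return state, False


class Mcmc:
    """A single deterministic-seed chain with sample storage.

    ``collectors`` are callables state -> dict merged into every trace row
    (used by the validation protocols to record tree statistics).
    ``log_trees`` stores newick strings of the species tree (and gene trees
    when requested) at every sample.
    """

    def __init__(self, state: McmcState, operators: list[Operator],
                 seed: int | np.random.Generator,
                 sample_interval: int = 10,
                 collectors: list | None = None,
                 log_trees: bool = True, log_gene_trees: bool = False,
                 coherence_every: int = 0, debug: bool = False):
        self.state = state
        self.operators = operators
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        w = np.array([op.weight for op in operators], dtype=float)
        self._probs = w / w.sum()
        self.sample_interval = sample_interval
        self.collectors = collectors or []
        self.log_trees = log_trees
        self.log_gene_trees = log_gene_trees
        self.coherence_every = coherence_every
        self.debug = debug
        self.rows: list[dict] = []
        self.species_tree_log: list[str] = []
        self.gene_tree_log: list[list[str]] = []
        self.step_count = 0
        self._record()

    # -- sampling ---------------------------------------------------------

    def _record(self) -> None:
        row = self.state.trace_row(self.step_count)
        for fn in self.collectors:
            row.update(fn(self.state))
        self.rows.append(row)
        if self.log_trees:
            st = self.state.species_tree
            self.species_tree_log.append(
                st.to_newick(annotations=st.branch_annotations()))
        if self.log_gene_trees:
            self.gene_tree_log.append(
                [g.to_newick() for g in self.state.gene_trees])
        if self.coherence_every and len(self.rows) % self.coherence_every == 0:
            self.check_coherence()

    def check_coherence(self) -> None:
        """Assert cached log posterior equals a fresh recomputation."""
        fresh = self.state.copy()
        fresh.invalidate("all")
        diff = abs(fresh.log_posterior() - self.state.log_posterior())
        if not diff < 1e-8:
            raise AssertionError(f"cache incoherence: {diff}")

    def run(self, n_steps: int) -> None:
        for _ in range(n_steps):
            i = self.rng.choice(len(self.operators), p=self._probs)
            self.state, accepted = mh_step(self.state, self.operators[i],
                                           self.rng)
            if self.debug and accepted and not self.state.compatible():
                raise AssertionError(
                    f"operator {self.operators[i].name} broke compatibility")
            self.step_count += 1
            if self.step_count % self.sample_interval == 0:
                self._record()

    def freeze_adaptation(self) -> None:
        for op in self.operators:
            if hasattr(op, "freeze"):
                op.freeze()

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    # -- chain doubling ----------------------------------------------------

    def thin_by_two(self) -> None:
        """Keep every second stored sample and double the sampling interval
        (used when the chain length doubles)."""
        self.rows = self.rows[::2]
        self.species_tree_log = self.species_tree_log[::2]
        self.gene_tree_log = self.gene_tree_log[::2]
        self.sample_interval *= 2


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(series) -> float:
    """ESS by Geyer's initial-positive-sequence estimator.

    Sums autocovariance pairs Gamma_k = gamma_{2k} + gamma_{2k+1} while they
    remain positive; ESS = n * gamma_0 / (-gamma_0 + 2 * sum Gamma_k).
    A constant series has no information and reports 0 (with a warning).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.all(x == x[0]):
        warnings.warn("constant series: ESS undefined, reporting 0")
        return 0.0
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    g0 = acov[0]
    tau = -g0
    k = 0
    while 2 * k + 1 < n:
        pair = acov[2 * k] + acov[2 * k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 1
    if tau <= 0:
        return float(n)
    return float(n * g0 / tau)


def burn_in_filter(trace: pd.DataFrame, fraction: float = 0.125) -> pd.DataFrame:
    """Drop the first ceil(fraction * rows) rows as burn-in."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("burn-in fraction must be in [0, 1)")
    drop = math.ceil(fraction * len(trace))
    return trace.iloc[drop:].reset_index(drop=True)


def _monitored_columns(chain: Mcmc) -> list[str]:
    """Trace statistics that actually vary under the run configuration."""
    s = chain.state.settings
    cols = ["posterior", "prior", "tree_prior", "species_tree_height"]
    if chain.state.alignments:
        cols.append("likelihood")
    if not s.concatenation and chain.state.gene_trees:
        cols.append("coalescent")
    if s.estimate_diversification:
        cols.append("net_diversification")
    if s.estimate_extinction:
        cols.append("extinction_fraction")
    if s.estimate_popsize_mean:
        cols.append("popsize_mean")
    return cols


def convergence_protocol(chain: Mcmc, ess_threshold: float = 200.0,
                         max_doublings: int = 8,
                         stats: list[str] | None = None,
                         burn_in: float = 0.125) -> dict:
    """Double the chain until the minimum ESS clears the threshold.

    Each doubling reruns as many steps as already taken and halves the
    sampling rate so the stored sample count stays constant.  Hitting
    ``max_doublings`` is reported, not raised.
    """
    if stats is None:
        stats = _monitored_columns(chain)
    doublings = 0
    while True:
        trace = burn_in_filter(chain.trace(), burn_in)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = {c: effective_sample_size(trace[c].to_numpy())
                   for c in stats}
        if min(ess.values()) >= ess_threshold:
            return {"converged": True, "doublings": doublings, "ess": ess}
        if doublings >= max_doublings:
            return {"converged": False, "doublings": doublings, "ess": ess}
        steps_so_far = chain.step_count
        chain.thin_by_two()
        chain.run(steps_so_far)
        doublings += 1


# ---------------------------------------------------------------------------
# state construction and config-driven runs
# ---------------------------------------------------------------------------

def build_state(settings: ModelSettings, rng: np.random.Generator, *,
                species_tree: SpeciesTree | None = None,
                n_species: int = 5,
                species_labels: list[str] | None = None,
                alignments: list[Alignment] | None = None,
                mapping: dict[str, str] | None = None,
                n_loci: int | None = None,
                samples_per_species: int = 1,
                locus_rates=None,
                diversification: float = 100.0,
                extinction_fraction: float = 0.0,
                popsize_mean: float = 0.002,
                subst_models: list[SubstModel] | None = None,
                site_models: list[SiteRateModel | None] | None = None,
                ) -> McmcState:
    """Assemble a valid initial state.

    When no species tree is given one is drawn from the birth-death prior;
    gene trees are always drawn from the MSC inside the species tree (with
    the prior-mean population size on every branch), which guarantees a
    compatible, finite-posterior starting point.
    """
    from .simulate import simulate_birth_death_tree

    bd = BirthDeathParams(diversification, extinction_fraction)
    if species_tree is None:
        if species_labels is None and mapping is not None:
            species_labels = sorted(set(mapping.values()))
        if species_labels is not None:
            n_species = len(species_labels)
        species_tree = simulate_birth_death_tree(
            n_species, bd.birth, bd.death, rng, labels=species_labels)
    st = species_tree
    if settings.popsize_mode == "mcmc" and not st.pop_size:
        for nid in st.nodes:
            st.pop_size[nid] = popsize_mean
    init_sizes = st.pop_size or {nid: popsize_mean for nid in st.nodes}

    if alignments:
        n_loci = len(alignments)
    elif n_loci is None:
        n_loci = 0 if settings.concatenation else 2

    gene_trees: list[GeneTree] = []
    mappings: list[dict[str, str]] = []
    if not settings.concatenation:
        for i in range(n_loci):
            if alignments is not None and mapping is not None:
                tips_by_sp: dict[str, list[str]] = {}
                for taxon in alignments[i].taxa:
                    tips_by_sp.setdefault(mapping[taxon], []).append(taxon)
                spec = tips_by_sp
            else:
                spec = samples_per_species
            gt, mp = simulate_msc_gene_tree(st, spec, rng,
                                            pop_sizes=init_sizes)
            gene_trees.append(gt)
            mappings.append(mp)

    if locus_rates is None:
        locus_rates = np.ones(max(n_loci, len(alignments or []), 1))
    locus_rates = np.asarray(locus_rates, dtype=float)

    species_cats = None
    gene_cats = None
    kind = settings.clock_kind
    if kind.startswith("st_") or (settings.concatenation and kind != "strict"):
        nonroot = [n.id for n in st.postorder() if n.parent is not None]
        bins = settings.clock_bins if settings.clock_bins else len(nonroot)
        species_cats = {nid: bins // 2 for nid in nonroot}
    if kind.startswith("gt_"):
        gene_cats = []
        for gt in gene_trees:
            nonroot = [n.id for n in gt.postorder() if n.parent is not None]
            bins = settings.clock_bins if settings.clock_bins else len(nonroot)
            gene_cats.append({nid: bins // 2 for nid in nonroot})

    return McmcState(settings, st, gene_trees, mappings, locus_rates, bd,
                     popsize_mean, species_cats, gene_cats,
                     alignments=alignments, subst_models=subst_models,
                     site_models=site_models)


@dataclass
class ChainResult:
    trace: pd.DataFrame
    chain: Mcmc
    convergence: dict | None = None


def run_chain(config: dict, seed: int) -> ChainResult:
    """Run one chain from a configuration mapping.

    See ``docs/methods.md`` for the configuration schema; fixed seeds give
    bit-identical traces.
    """
    rng = np.random.default_rng(seed)
    model = dict(config.get("model", {}))
    inits = dict(config.get("init", {}))
    settings_fields = {f for f in ModelSettings.__dataclass_fields__}
    settings = ModelSettings(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in model.items()
                                if k in settings_fields})

    alignments = None
    mapping = None
    subst_models = None
    site_models = None
    data = config.get("data")
    if data:
        schema = data.get("schema", "fasta")
        alignments = [Alignment.read(p, schema) for p in data["loci"]]
        if data.get("mapping"):
            mapping = read_mapping(data["mapping"])
        else:
            mapping = {t: t for aln in alignments for t in aln.taxa}
        sub = config.get("subst", {})
        model_obj = SubstModel(sub.get("kind", "JC"),
                               kappa=sub.get("kappa", 1.0))
        site = (SiteRateModel(sub.get("gamma_categories", 4),
                              sub.get("gamma_shape"))
                if sub.get("gamma_shape") else None)
        subst_models = [model_obj] * len(alignments)
        site_models = [site] * len(alignments)

    species_tree = None
    if inits.get("species_tree"):
        species_tree = SpeciesTree.from_newick(inits["species_tree"])

    state = build_state(
        settings, rng,
        species_tree=species_tree,
        n_species=config.get("n_species", 5),
        alignments=alignments, mapping=mapping,
        n_loci=config.get("n_loci"),
        samples_per_species=config.get("samples_per_species", 1),
        locus_rates=inits.get("locus_rates"),
        diversification=inits.get("diversification", 100.0),
        extinction_fraction=inits.get("extinction_fraction", 0.0),
        popsize_mean=inits.get("popsize_mean", 0.002),
        subst_models=subst_models, site_models=site_models)

    opcfg = config.get("operators", {})
    operators = default_operators(
        state,
        coordinated_topology=opcfg.get("coordinated_topology", False),
        naive_topology=opcfg.get("naive_topology", True),
        coordinated_heights=opcfg.get("coordinated_heights", True))

    chain_length = int(config.get("chain_length", 10000))
    interval = int(config.get("sample_interval", 10))
    chain = Mcmc(state, operators, rng, sample_interval=interval,
                 log_gene_trees=config.get("log_gene_trees", False),
                 coherence_every=config.get("coherence_every", 0),
                 debug=config.get("debug", False))
    burn = int(0.125 * chain_length)
    chain.run(burn)
    chain.freeze_adaptation()
    chain.run(chain_length - burn)

    convergence = None
    if config.get("converge"):
        convergence = convergence_protocol(
            chain, ess_threshold=config.get("ess_threshold", 200.0),
            max_doublings=config.get("max_doublings", 4))

    prefix = config.get("out_prefix")
    if prefix:
        trace = chain.trace()
        trace.to_csv(f"{prefix}.trace.tsv", sep="\t", index=False)
        with open(f"{prefix}.species.trees", "w") as fh:
            for nwk in chain.species_tree_log:
                fh.write(nwk + "\n")
    return ChainResult(chain.trace(), chain, convergence)
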
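"""MH kernel, scheduling, ESS, burn-in, convergence, calibration."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as ss

from mscoal import simulate as sim
from mscoal.mcmc import (Mcmc, build_state, burn_in_filter,
                         convergence_protocol, effective_sample_size,
                         mh_step, run_chain)
from mscoal.operators import Operator, Proposal, default_operators
from mscoal.phylo_likelihood import Alignment, SubstModel
from mscoal.state import ModelSettings
from mscoal.summarize import hpd_interval


class _ToyState:
    """Scalar Gaussian target, duck-typing the state protocol."""

    def __init__(self, x):
        self.x = x

    def log_posterior(self):
        return -0.5 * self.x * self.x

    def compatible(self):
        return True


class _ToyWalk(Operator):
    name = "toy_walk"

    def __init__(self, width):
        super().__init__()
        self.width = width

    def propose(self, state, rng):
        return Proposal(_ToyState(state.x + rng.uniform(-self.width,
                                                        self.width)))


class TestMhStep:
    def test_always_accept_when_flat(self, rng):
        class Flat(_ToyState):
            def log_posterior(self):
                return 0.0

        class Move(Operator):
            def propose(self, state, rng):
                return Proposal(Flat(0.0), 0.0)

        op = Move()
        s = Flat(0.0)
        for _ in range(50):
            s, acc = mh_step(s, op, rng)
            assert acc

    def test_zero_probability_proposal_rejected(self, rng):
        class Bad(Operator):
            def propose(self, state, rng):
                out = _ToyState(state.x)
                out.log_posterior = lambda: -math.inf
                return Proposal(out)

        s = _ToyState(0.0)
        s2, acc = mh_step(s, Bad(), rng)
        assert not acc and s2 is s

    def test_gaussian_toy_acceptance_rate(self, rng):
        """Empirical acceptance on N(0,1) with a uniform random-walk kernel
        matches the closed-form double integral E[min(1, pi(x')/pi(x))]."""
        w = 2.0
        op = _ToyWalk(w)
        s = _ToyState(0.0)
        n = 40000
        for _ in range(n):
            s, _ = mh_step(s, op, rng)
        emp = op.n_accepted / op.n_proposed

        def inner(x):
            val, _ = integrate.quad(
                lambda e: min(1.0, math.exp(-0.5 * (x + e) ** 2
                                            + 0.5 * x * x)) / (2 * w),
                -w, w)
            return val * math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)

        analytic, _ = integrate.quad(inner, -8, 8, limit=100)
        assert emp == pytest.approx(analytic, abs=0.02)


class TestChainMechanics:
    def _config(self, **kw):
        cfg = {"model": {"popsize_mode": "integrated",
                         "clock_kind": "strict"},
               "n_species": 4, "n_loci": 1, "samples_per_species": 1,
               "init": {"diversification": 100.0,
                        "extinction_fraction": 0.5,
                        "popsize_mean": 0.002},
               "chain_length": 2000, "sample_interval": 10}
        cfg.update(kw)
        return cfg

    def test_same_seed_identical_traces(self):
        t1 = run_chain(self._config(), 42).trace
        t2 = run_chain(self._config(), 42).trace
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        t1 = run_chain(self._config(), 42).trace
        t2 = run_chain(self._config(), 43).trace
        assert not t1.equals(t2)

    def test_row_count_matches_interval(self):
        res = run_chain(self._config(chain_length=1000, sample_interval=20), 1)
        assert len(res.trace) == 1000 // 20 + 1
        for col in ("posterior", "likelihood", "prior", "coalescent",
                    "tree_prior", "net_diversification",
                    "extinction_fraction", "popsize_mean",
                    "species_tree_height"):
            assert col in res.trace.columns

    def test_operator_draw_frequencies(self, rng):
        class Null(Operator):
            def __init__(self, name, weight):
                super().__init__(weight)
                self.name = name

            def propose(self, state, rng):
                return Proposal.invalid()

        a, b = Null("a", 3.0), Null("b", 1.0)
        state = build_state(ModelSettings(clock_kind="strict"), rng,
                            n_species=3, n_loci=1, samples_per_species=1,
                            diversification=100.0, popsize_mean=0.002)
        chain = Mcmc(state, [a, b], rng, sample_interval=10 ** 9,
                     log_trees=False)
        n = 100000
        chain.run(n)
        p_hat = a.n_proposed / n
        assert abs(p_hat - 0.75) < 4 * math.sqrt(0.75 * 0.25 / n)

    def test_cache_coherence_under_data(self, rng):
        """Cached posterior equals fresh recomputation throughout a run with
        sequence data and a species-tree relaxed clock."""
        recipe = sim.SimRecipe(n_species=4, samples_per_species=1,
                               birth=100.0, death=30.0,
                               popsize_distribution="gamma",
                               popsize_shape=2.0, popsize_scale=0.01,
                               n_loci=2, length=100)
        data = sim.simulate_replicate(recipe, rng)
        settings = ModelSettings(popsize_mode="integrated",
                                 clock_kind="st_ucln")
        st = data["species_tree"].copy()
        st.pop_size = {}
        st.rate = {}
        state = build_state(settings, rng, species_tree=st,
                            alignments=data["alignments"],
                            mapping=data["mappings"][0],
                            diversification=70.0, popsize_mean=0.01,
                            subst_models=[SubstModel("JC")] * 2,
                            site_models=[None] * 2)
        ops = default_operators(state, coordinated_topology=True)
        chain = Mcmc(state, ops, rng, sample_interval=25,
                     coherence_every=10, log_trees=False)
        chain.run(3000)  # raises on any incoherence


class TestEss:
    def test_iid_near_n(self, rng):
        x = rng.normal(size=10000)
        assert 8000 <= effective_sample_size(x) <= 12000

    def test_ar1_autocorrelation_time(self, rng):
        rho = 0.9
        n = 40000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_series_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert effective_sample_size([1.0] * 100) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size([1.0, 2.0])


class TestBurnIn:
    def test_eighth_of_800(self):
        import pandas as pd

        trace = pd.DataFrame({"x": np.arange(800)})
        assert len(burn_in_filter(trace, 0.125)) == 700

    def test_zero_fraction_identity(self):
        import pandas as pd

        trace = pd.DataFrame({"x": np.arange(9)})
        assert burn_in_filter(trace, 0.0).equals(trace)

    def test_ceil_rounding_on_9_rows(self):
        import pandas as pd

        trace = pd.DataFrame({"x": np.arange(9)})
        assert len(burn_in_filter(trace, 0.125)) == 7

    def test_bad_fraction_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            burn_in_filter(pd.DataFrame({"x": [1]}), 1.0)


class TestConvergenceProtocol:
    def _chain(self, rng, steps=4000):
        state = build_state(ModelSettings(clock_kind="strict"), rng,
                            n_species=3, n_loci=1, samples_per_species=1,
                            diversification=100.0, extinction_fraction=0.5,
                            popsize_mean=0.002)
        ops = default_operators(state)
        chain = Mcmc(state, ops, rng, sample_interval=5, log_trees=False)
        chain.run(steps)
        return chain

    def test_converged_chain_no_doubling(self, rng):
        chain = self._chain(rng, steps=8000)
        report = convergence_protocol(chain, ess_threshold=30.0,
                                      max_doublings=3)
        assert report["converged"] and report["doublings"] == 0

    def test_doubling_halves_sample_rate(self, rng):
        chain = self._chain(rng, steps=2000)
        n_rows = len(chain.rows)
        report = convergence_protocol(chain, ess_threshold=120.0,
                                      max_doublings=2)
        assert chain.sample_interval >= 10  # halved rate = doubled interval
        assert abs(len(chain.rows) - n_rows) <= n_rows // 2 + 1
        assert report["doublings"] >= 1

    def test_pathological_constant_chain_hits_cap(self, rng):
        chain = self._chain(rng, steps=500)

        class Stuck(Operator):
            name = "stuck"

            def propose(self, state, rng):
                return Proposal.invalid()

        chain.operators = [Stuck()]
        chain._probs = np.array([1.0])
        chain.rows = chain.rows[-1:]  # constant from here on
        chain.species_tree_log = []
        chain.run(500)
        report = convergence_protocol(chain, ess_threshold=50.0,
                                      max_doublings=1)
        assert not report["converged"]
        assert report["doublings"] == 1


class TestFlatData:
    def test_all_ambiguous_data_sampling_equals_prior(self, rng):
        """A likelihood that is constant in the parameters (all-N
        sequences) must reproduce the prior distribution."""
        ref = []
        rng_ref = np.random.default_rng(71)
        for _ in range(4000):
            st = sim.simulate_birth_death_tree(3, 200.0, 100.0, rng_ref)
            sim.simulate_pop_sizes(st, "inverse_gamma", 3.0, 0.004, rng_ref)
            sim.simulate_msc_gene_tree(st, 1, rng_ref)
            ref.append(st.root.height)
        settings = ModelSettings(popsize_mode="integrated",
                                 clock_kind="strict")
        rng_mc = np.random.default_rng(72)
        aln = Alignment(["A_0", "B_0", "C_0"], ["N" * 50] * 3)
        state = build_state(settings, rng_mc, n_species=3,
                            species_labels=["A", "B", "C"],
                            alignments=[aln],
                            mapping={"A_0": "A", "B_0": "B", "C_0": "C"},
                            diversification=100.0, extinction_fraction=0.5,
                            popsize_mean=0.002,
                            subst_models=[SubstModel("JC")],
                            site_models=[None])
        chain = Mcmc(state, default_operators(state), rng_mc,
                     sample_interval=25, log_trees=False)
        chain.run(100000)
        x = chain.trace().iloc[100:].species_tree_height.to_numpy()[::4]
        assert ss.ks_2samp(x, ref).pvalue > 0.01


class TestParameterRecovery:
    def test_hpd_coverage_smoke(self, rng):
        """Calibration: 95% HPDs for the species-tree height and the locus
        clock rates cover the simulated truth in at least 90% of 20
        repetitions (3 species, 3 loci, short alignments)."""
        height_cov = 0
        rate_cov = 0
        rate_total = 0
        gen = np.random.default_rng(2017)
        for rep in range(20):
            st = sim.simulate_birth_death_tree(3, 100.0, 30.0, gen)
            # every generative law matches the corresponding inference
            # prior exactly, so this is a genuine calibration check:
            # inverse-gamma(3) population sizes and i.i.d. mean-1 lognormal
            # locus rates (inference runs with unconstrained rates)
            sim.simulate_pop_sizes(st, "inverse_gamma", 3.0, 0.004, gen)
            locus_rates = gen.lognormal(-0.18, 0.6, size=3)
            model = SubstModel("JC")
            alns, gts, mps = [], [], []
            for c in locus_rates:
                gt, mp = sim.simulate_msc_gene_tree(st, 2, gen)
                rates = {n.id: c for n in gt.postorder()
                         if n.parent is not None}
                alns.append(sim.simulate_alignment(gt, rates, model, None,
                                                   400, gen))
                gts.append(gt)
                mps.append(mp)
            settings = ModelSettings(popsize_mode="integrated",
                                     clock_kind="strict",
                                     estimate_locus_rates=True,
                                     locus_rate_sigma=0.6,
                                     locus_rate_constrain=False)
            init = st.copy()
            init.pop_size = {}
            init.rate = {}
            state = build_state(settings, gen, species_tree=init,
                                alignments=alns, mapping=mps[0],
                                diversification=70.0,
                                extinction_fraction=0.3,
                                popsize_mean=0.002,
                                subst_models=[model] * 3,
                                site_models=[None] * 3)
            chain = Mcmc(state, default_operators(state), gen,
                         sample_interval=20, log_trees=False,
                         collectors=[lambda s: {
                             f"c{i}": s.locus_rates[i] for i in range(3)}])
            chain.run(14000)
            tr = chain.trace().iloc[int(len(chain.rows) * 0.125):]
            lo, hi = hpd_interval(tr.species_tree_height.to_numpy(), 0.95)
            if lo <= st.root.height <= hi:
                height_cov += 1
            for i in range(3):
                lo, hi = hpd_interval(tr[f"c{i}"].to_numpy(), 0.95)
                rate_total += 1
                if lo <= locus_rates[i] <= hi:
                    rate_cov += 1
        assert height_cov >= 18
        assert rate_cov >= 0.9 * rate_total
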
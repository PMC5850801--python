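"""Proposal kernels: component selection, shift bounds, Hastings ratios,
round-trips, and single-operator sampling correctness."""

import math

import numpy as np
import pytest
from scipy import stats as ss

from conftest import assert_tree_sound, chi2_two_sample
from mscoal import simulate as sim
from mscoal.mcmc import Mcmc, build_state, mh_step
from mscoal.operators import (CategoryResample, CoordinatedExchange,
                              CoordinatedExponential, CoordinatedUniform,
                              NarrowExchange, RootHeightScale, SpeciesSPR,
                              TreeScale, UniformNodeHeight, WilsonBalding,
                              adapt_exponential_rate, compute_shift_bounds,
                              select_connected_component)
from mscoal.state import ModelSettings
from mscoal.summarize import topology_key
from mscoal.trees import GeneTree, SpeciesTree, is_compatible


def prior_state(rng, n_species=4, n_loci=1, samples=1, d=100.0, f=0.5):
    settings = ModelSettings(popsize_mode="integrated", clock_kind="strict")
    return build_state(settings, rng, n_species=n_species, n_loci=n_loci,
                       samples_per_species=samples, diversification=d,
                       extinction_fraction=f, popsize_mean=0.002)


class TestConnectedComponent:
    def test_two_species_selects_coalescence(self, two_species_state, rng):
        st, gt, mapping = two_species_state
        settings = ModelSettings(clock_kind="strict")
        from mscoal.msc_model import BirthDeathParams
        from mscoal.state import McmcState

        state = McmcState(settings, st, [gt], [mapping], np.ones(1),
                          BirthDeathParams(100.0), 0.002)
        comp = select_connected_component(st.root, state)
        assert comp == [{gt.root.id}]

    def test_single_sided_node_excluded(self):
        st = SpeciesTree.from_newick("((A:1,B:1):1,C:2);")
        gt = GeneTree.from_newick("((a1:0.5,a2:0.5):2.5,(b:1.5,c:1.5):1.5);")
        mapping = {"a1": "A", "a2": "A", "b": "B", "c": "C"}
        from mscoal.msc_model import BirthDeathParams
        from mscoal.state import McmcState

        state = McmcState(ModelSettings(clock_kind="strict"), st, [gt],
                          [mapping], np.ones(1), BirthDeathParams(1.0), 0.01)
        S = st.mrca({"A", "B"})
        comp = select_connected_component(S, state)
        # the a1-a2 coalescence is inside A only: criterion 2 fails
        a_node = gt.mrca({"a1", "a2"})
        assert a_node.id not in comp[0]

    def test_matches_set_algebra_oracle(self, rng):
        """Brute-force evaluation of the three descendant-individual
        criteria on random multi-locus states."""
        from mscoal.trees import descendant_individuals

        for _ in range(15):
            state = prior_state(rng, n_species=5, n_loci=3, samples=2)
            st = state.species_tree
            for S in st.internals():
                comp = select_connected_component(S, state)
                left, right = S.children
                for i, gt in enumerate(state.gene_trees):
                    mapping = state.mappings[i]
                    dl = descendant_individuals(left, st, species_tree=st,
                                                gene_trees=[gt],
                                                mapping=mapping)
                    dr = descendant_individuals(right, st, species_tree=st,
                                                gene_trees=[gt],
                                                mapping=mapping)
                    ds = dl | dr
                    want = set()
                    for node in gt.nodes.values():
                        if node.is_tip():
                            continue
                        d = descendant_individuals(node, gt)
                        if d & dl and d & dr and d <= ds:
                            want.add(node.id)
                    assert comp[i] == want


class TestShiftBounds:
    def test_bounds_by_grid_scan(self, rng):
        """Authoritative oracle: scan a fine eta grid; every state inside
        (D, U) must be valid with identical topologies and the same
        component; immediately outside must not."""
        checked = 0
        for _ in range(12):
            state = prior_state(rng, n_species=4, n_loci=2, samples=2)
            st = state.species_tree
            internals = [n for n in st.internals() if n.parent is not None]
            for S in internals:
                comp = select_connected_component(S, state)
                D, U = compute_shift_bounds(S, comp, state)
                assert D <= S.height <= U
                span = U - D
                if span <= 0:
                    continue
                checked += 1
                for frac in (0.02, 0.5, 0.98):
                    t_new = D + frac * span
                    shifted = _shift(state, S.id, comp, t_new - S.height)
                    assert shifted.compatible()
                    _assert_same_topologies(state, shifted)
                    S2 = shifted.species_tree.nodes[S.id]
                    assert select_connected_component(S2, shifted) == comp
                eps = 1e-4 * span
                for t_bad in (D - eps, U + eps):
                    shifted = _shift(state, S.id, comp, t_bad - S.height)
                    assert not _state_valid(shifted)
        assert checked >= 10

    def test_component_parent_inside_component_unconstrained(self):
        """When a shifted gene node's parent is also shifted, the parent
        imposes no upper bound (only the species parent does)."""
        st = SpeciesTree.from_newick("((A:1,B:1):2,C:3);")
        # both gene coalescences have support {A, B}: both are selected, so
        # the lower one's parent (the gene root of the A/B haplotypes) does
        # not cap the shift — only the species root at 3 does
        gt = GeneTree.from_newick("((a1:1.2,b:1.2):0.5,a2:1.7);")
        mapping = {"a1": "A", "a2": "A", "b": "B"}
        from mscoal.msc_model import BirthDeathParams
        from mscoal.state import McmcState

        state = McmcState(ModelSettings(clock_kind="strict"), st, [gt],
                          [mapping], np.ones(1), BirthDeathParams(1.0), 0.01)
        S = st.mrca({"A", "B"})
        comp = select_connected_component(S, state)
        assert comp == [{gt.mrca({"a1", "b"}).id, gt.root.id}]
        D, U = compute_shift_bounds(S, comp, state)
        assert U == pytest.approx(3.0)
        assert D == pytest.approx(0.0)


def _shift(state, S_id, comp, eta):
    new = state.copy()
    new.species_tree.nodes[S_id].height += eta
    for i, c in enumerate(comp):
        for nid in c:
            new.gene_trees[i].nodes[nid].height += eta
    new.invalidate("all")
    return new


def _state_valid(state):
    try:
        state.species_tree.validate()
        for gt in state.gene_trees:
            gt.validate()
    except ValueError:
        return False
    return state.compatible()


def _assert_same_topologies(a, b):
    assert topology_key(a.species_tree) == topology_key(b.species_tree)
    for g1, g2 in zip(a.gene_trees, b.gene_trees):
        assert g1.clades() == g2.clades()


class TestCoordinatedUniform:
    def test_proposals_remain_compatible(self, rng):
        state = prior_state(rng, n_species=5, n_loci=2, samples=2)
        op = CoordinatedUniform()
        for _ in range(300):
            prop = op.propose(state, rng)
            if prop.valid:
                assert prop.state.compatible()
                assert prop.log_hastings == 0.0
                _assert_same_topologies(state, prop.state)

    def test_round_trip_restores_state(self, rng):
        """Applying the opposite shift restores every height exactly."""
        state = prior_state(rng, n_species=4, n_loci=2, samples=2)
        st = state.species_tree
        S = next(n for n in st.internals() if n.parent is not None)
        comp = select_connected_component(S, state)
        eta = 0.3 * (compute_shift_bounds(S, comp, state)[1] - S.height)
        fwd = _shift(state, S.id, comp, eta)
        back = _shift(fwd, S.id, comp, -eta)
        for nid, node in state.species_tree.nodes.items():
            assert back.species_tree.nodes[nid].height == \
                pytest.approx(node.height, abs=1e-15)

    def test_detailed_balance_height_distribution(self, rng):
        """Only this operator (plus direct gene resampling is absent):
        on a fixed 3-species topology the internal height distribution
        matches direct simulation."""
        ref = []
        rng_ref = np.random.default_rng(101)
        for _ in range(5000):
            st = sim.simulate_birth_death_tree(3, 200.0, 100.0, rng_ref)
            sim.simulate_pop_sizes(st, "inverse_gamma", 3.0, 0.004, rng_ref)
            gt, mp = sim.simulate_msc_gene_tree(st, 1, rng_ref)
            inner = next(n for n in st.internals() if n.parent is not None)
            ref.append(inner.height)

        settings = ModelSettings(popsize_mode="integrated",
                                 clock_kind="strict",
                                 fixed_species_topology=True)
        rng_mc = np.random.default_rng(102)
        state = build_state(settings, rng_mc, n_species=3, n_loci=1,
                            samples_per_species=1, diversification=100.0,
                            extinction_fraction=0.5, popsize_mean=0.002)
        inner_id = next(n.id for n in state.species_tree.internals()
                        if n.parent is not None)
        ops = [CoordinatedUniform(5.0), CoordinatedExponential(2.0),
               TreeScale(2.0, "all"), UniformNodeHeight(1.0, 0),
               RootHeightScale(1.0, 0), NarrowExchange(1.0, 0)]
        chain = Mcmc(state, ops, rng_mc, sample_interval=40, log_trees=False,
                     collectors=[lambda s:
                                 {"inner": s.species_tree.nodes[inner_id].height}])
        chain.run(120000)
        x = chain.trace().iloc[100:].inner.to_numpy()[::3]
        assert ss.ks_2samp(x, ref).pvalue > 0.01


class TestCoordinatedExponential:
    def test_log_hastings_is_rate_times_eta(self, rng):
        state = prior_state(rng, n_species=4, n_loci=1)
        op = CoordinatedExponential(rate=2.0)
        op.freeze()
        for _ in range(50):
            prop = op.propose(state, rng)
            if not prop.valid:
                continue
            eta = prop.state.species_tree.root.height - \
                state.species_tree.root.height
            assert prop.log_hastings == pytest.approx(2.0 * eta, rel=1e-9)

    def test_direct_substitution(self):
        # lambda = 2, eta = 0.3 -> log HR = 0.6
        assert 2.0 * 0.3 == pytest.approx(0.6)
        assert adapt_exponential_rate(math.log(2.0)) == pytest.approx(1.0)
        assert adapt_exponential_rate(0.6931) == pytest.approx(1.0, abs=1e-4)

    def test_root_prior_recovered(self, rng):
        """Chain whose root height moves only via this operator recovers
        the direct-simulation root-height distribution."""
        rng_ref = np.random.default_rng(33)
        ref = []
        for _ in range(5000):
            st = sim.simulate_birth_death_tree(3, 150.0, 50.0, rng_ref)
            sim.simulate_pop_sizes(st, "inverse_gamma", 3.0, 0.004, rng_ref)
            sim.simulate_msc_gene_tree(st, 1, rng_ref)
            ref.append(st.root.height)
        settings = ModelSettings(popsize_mode="integrated",
                                 clock_kind="strict",
                                 fixed_species_topology=True)
        rng_mc = np.random.default_rng(34)
        state = build_state(settings, rng_mc, n_species=3, n_loci=1,
                            samples_per_species=1, diversification=100.0,
                            extinction_fraction=1.0 / 3.0, popsize_mean=0.002)
        ops = [CoordinatedExponential(4.0), CoordinatedUniform(2.0),
               UniformNodeHeight(1.0, "species"), UniformNodeHeight(1.0, 0),
               RootHeightScale(1.0, 0), NarrowExchange(1.0, 0)]
        chain = Mcmc(state, ops, rng_mc, sample_interval=40, log_trees=False)
        chain.run(20000)
        chain.freeze_adaptation()
        chain.run(100000)
        x = chain.trace().iloc[len(chain.rows) // 3:]
        x = x.species_tree_height.to_numpy()[::3]
        assert ss.ks_2samp(x, ref).pvalue > 0.01


class TestCoordinatedExchange:
    def test_structural_soundness_and_compatibility(self, rng):
        state = prior_state(rng, n_species=5, n_loci=2, samples=2)
        op = CoordinatedExchange()
        for _ in range(3000):
            state, acc = mh_step(state, op, rng)
            if acc:
                for tree in [state.species_tree] + state.gene_trees:
                    assert_tree_sound(tree)
                assert state.compatible()
        assert op.acceptance_rate > 0.05

    def test_pure_species_move_when_no_window_events(self):
        """If no gene coalescence falls in the affected window the move is a
        plain species rearrangement with only the selection-count ratio."""
        st = SpeciesTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        # gene tree coalescing far above the root: nothing in any window
        gt = GeneTree.from_newick("(((a:10,b:10):1,c:11):1,d:12);")
        mapping = {x: x.upper() for x in "abcd"}
        from mscoal.msc_model import BirthDeathParams
        from mscoal.state import McmcState

        state = McmcState(ModelSettings(clock_kind="strict"), st, [gt],
                          [mapping], np.ones(1), BirthDeathParams(1.0), 0.01)
        op = CoordinatedExchange()
        rng = np.random.default_rng(0)
        for _ in range(100):
            prop = op.propose(state, rng)
            if prop.valid:
                assert prop.state.compatible()
                for g1, g2 in zip(state.gene_trees, prop.state.gene_trees):
                    assert g1.clades() == g2.clades()

    def test_prior_equivalence_topology_frequencies(self, rng):
        """The sampling-correctness gate: a chain whose topology moves come
        only from CoordinatedExchange reproduces the direct-simulation
        species topology frequencies on 4 species."""
        rng_ref = np.random.default_rng(55)
        ref_topo = {}
        for _ in range(8000):
            st = sim.simulate_birth_death_tree(4, 200.0, 100.0, rng_ref)
            sim.simulate_pop_sizes(st, "inverse_gamma", 3.0, 0.004, rng_ref)
            sim.simulate_msc_gene_tree(st, 1, rng_ref)
            k = topology_key(st)
            ref_topo[k] = ref_topo.get(k, 0) + 1

        settings = ModelSettings(popsize_mode="integrated",
                                 clock_kind="strict")
        rng_mc = np.random.default_rng(56)
        state = build_state(settings, rng_mc, n_species=4, n_loci=1,
                            samples_per_species=1, diversification=100.0,
                            extinction_fraction=0.5, popsize_mean=0.002)
        ops = [TreeScale(3.0, "all"), UniformNodeHeight(3.0, "species"),
               RootHeightScale(1.0, "species"), CoordinatedUniform(5.0),
               CoordinatedExponential(2.0), CoordinatedExchange(6.0),
               UniformNodeHeight(2.0, 0), RootHeightScale(0.5, 0)]
        chain = Mcmc(state, ops, rng_mc, sample_interval=100, log_trees=False,
                     collectors=[lambda s:
                                 {"topo": topology_key(s.species_tree)}])
        chain.run(250000)
        tr = chain.trace().iloc[150:]
        mc = tr.topo.value_counts().to_dict()
        assert chi2_two_sample(ref_topo, mc) > 0.01


class TestStandardOperators:
    def test_scale_identity_when_s_one(self, rng):
        """The scale kernel near s=1 leaves heights nearly unchanged and the
        Hastings ratio follows (dim-2)ln s."""
        state = prior_state(rng, n_species=4, n_loci=1)
        op = TreeScale(1.0, "species", lam=0.999)
        prop = op.propose(state, rng)
        s = prop.state.species_tree.root.height / \
            state.species_tree.root.height
        dim = len(state.species_tree.internals())
        assert prop.log_hastings == pytest.approx((dim - 2) * math.log(s),
                                                  rel=1e-6)

    def test_narrow_exchange_double_application_restores(self, rng):
        """Re-applying the same swap is the identity on the topology."""
        state = prior_state(rng, n_species=5, n_loci=1)
        op = NarrowExchange(1.0, "species")
        for _ in range(200):
            prop = op.propose(state, rng)
            if prop is None or not prop.valid:
                continue
            before = topology_key(state.species_tree)
            after = topology_key(prop.state.species_tree)
            if before == after:
                continue
            # find and re-apply the inverse by brute force
            restored = False
            for _ in range(500):
                prop2 = op.propose(prop.state, rng)
                if prop2 is not None and prop2.valid and \
                        topology_key(prop2.state.species_tree) == before:
                    restored = True
                    break
            assert restored
            break

    def test_naive_species_moves_autoreject_incompatible(self, rng):
        """Accepted naive topology moves always leave a compatible state."""
        state = prior_state(rng, n_species=5, n_loci=2, samples=2)
        for op in (NarrowExchange(1.0, "species"), SpeciesSPR(1.0)):
            s = state
            for _ in range(500):
                s, acc = mh_step(s, op, rng)
                if acc:
                    assert s.compatible()

    def test_wilson_balding_soundness(self, rng):
        state = prior_state(rng, n_species=4, n_loci=1, samples=3)
        op = WilsonBalding(1.0, 0)
        s = state
        accepted = 0
        for _ in range(2000):
            s, acc = mh_step(s, op, rng)
            if acc:
                accepted += 1
                assert_tree_sound(s.gene_trees[0])
                assert s.compatible()
        assert accepted > 10

    def test_category_resample_changes_only_rates(self, rng):
        settings = ModelSettings(popsize_mode="integrated",
                                 clock_kind="st_ucln", clock_sigma=0.3)
        state = build_state(settings, rng, n_species=4, n_loci=1,
                            samples_per_species=1, diversification=100.0,
                            extinction_fraction=0.5, popsize_mean=0.002)
        op = CategoryResample(1.0, "species")
        prop = op.propose(state, rng)
        assert prop.valid
        _assert_same_topologies(state, prop.state)
        rates = prop.state.species_tree.rate
        bins = prop.state._sp_bin_rates
        assert all(r in set(bins) or r == 1.0 for r in rates.values())
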
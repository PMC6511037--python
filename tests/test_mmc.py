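"""Metropolis engine: proposals, acceptance, termination, synapse dynamics."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from netclone import (
    DYNAMIC_SPARSE,
    CostParams,
    DynamicsParams,
    MCParams,
    SynapseSet,
    generate_er,
    init_state,
    metropolis_accept,
    metropolis_step,
    network_to_pairs,
    predicted_attempts,
    propose_move,
    prune_and_read_out,
    recover_mapping,
    relocate_empty_synapses,
    run,
)

from conftest import make_oboc_state, make_random_state


class TestInitState:
    def test_every_pair_placed_with_counts(self, small_ensemble):
        syn = SynapseSet.full(12)
        st = init_state(small_ensemble, syn, rng=3)
        assert st.n_pairs == len(small_ensemble)
        assert all(0 <= s < len(syn) for s in st.pair_syn)
        assert sum(map(sum, st.counts)) == 2 * st.n_pairs

    def test_same_seed_identical(self, small_ensemble):
        syn = SynapseSet.full(12)
        a = init_state(small_ensemble, syn, rng=9)
        b = init_state(small_ensemble, syn, rng=9)
        assert a.pair_syn == b.pair_syn and a.pair_orient == b.pair_orient

    def test_occupancy_uniform_over_seeds(self):
        net = generate_er(8, 0.5, seed=0)
        ens = network_to_pairs(net)
        syn = SynapseSet.full(8)
        tally = np.zeros(len(syn))
        for seed in range(200):
            st = init_state(ens, syn, rng=seed)
            for s in st.pair_syn:
                tally[s] += 1
        p = stats.chisquare(tally).pvalue
        assert 1e-4 < p

    def test_empty_synapse_set_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            init_state(small_ensemble, SynapseSet(12, []), rng=0)


class TestProposeMove:
    def test_kind_frequencies_match_probabilities(self):
        st = make_random_state(n_cells=20, density=0.2, seed=1)
        probs = MCParams().resolved_probs(0.2, 20)
        rng = random.Random(4)
        n = 100_000
        tally = {"jump": 0, "swap": 0, "flip": 0}
        for _ in range(n):
            mv = propose_move(st, probs, rng)
            tally[mv.kind] += 1
        # swap fallback re-draws as jump, so compare jump+swap jointly and flip
        for kind, p in zip(("flip",), (probs[2],)):
            sd = math.sqrt(n * p * (1 - p))
            assert abs(tally[kind] - n * p) < 3 * sd
        p_swap = probs[1]
        sd = math.sqrt(n * p_swap * (1 - p_swap))
        assert tally["swap"] <= n * p_swap + 3 * sd  # fallback only reduces swaps

    def test_jump_destination_shares_a_cell(self):
        st = make_random_state(n_cells=10, density=0.3, seed=2)
        rng = random.Random(7)
        for _ in range(2000):
            mv = propose_move(st, (1.0, 0.0, 0.0), rng)
            src_cells = {st.syn_pre[st.pair_syn[mv.pair]], st.syn_post[st.pair_syn[mv.pair]]}
            dst_cells = {st.syn_pre[mv.dest_syn], st.syn_post[mv.dest_syn]}
            assert src_cells & dst_cells
            assert mv.dest_syn != st.pair_syn[mv.pair]

    def test_single_pair_swap_redrawn_as_jump(self):
        from netclone import CloneState, PairEnsemble

        ens = PairEnsemble([(0, 1)], 4)
        syn = SynapseSet.full(4)
        st = CloneState(ens, syn, [0], [0])
        rng = random.Random(0)
        for _ in range(500):
            mv = propose_move(st, (0.0, 1.0, 0.0), rng)
            assert mv is None or mv.kind == "jump"

    def test_probability_resolution_clamps_and_normalizes(self):
        pj, ps, pf = MCParams().resolved_probs(0.05, 10)  # f < 1/N
        assert ps == 0.0 and abs(pj + ps + pf - 1.0) < 1e-12
        pj, ps, pf = MCParams().resolved_probs(0.2, 10)
        assert (pj, ps, pf) == (0.8, 0.2 - 0.1, 0.1)
        with pytest.raises(ValueError):
            MCParams(p_jump=-0.1).resolved_probs(0.2, 10)


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        rng = random.Random(0)
        assert all(metropolis_accept(-3, 1e-4, rng) for _ in range(100))
        assert all(metropolis_accept(0, 1e-4, rng) for _ in range(100))

    def test_uphill_frozen_at_low_temperature(self):
        rng = random.Random(1)
        assert not any(metropolis_accept(1, 1e-4, rng) for _ in range(1_000_000))

    def test_uphill_rate_at_unit_temperature(self):
        rng = random.Random(2)
        n = 100_000
        hits = sum(metropolis_accept(1, 1.0, rng) for _ in range(n))
        p = math.exp(-1)
        assert abs(hits - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_step_applies_atomically(self, random_state):
        rng = random.Random(3)
        mv = propose_move(random_state, (1.0, 0.0, 0.0), rng)
        h0 = random_state.H
        accepted, dh = metropolis_step(random_state, mv, rng=rng)
        assert random_state.H == h0 + (dh if accepted else 0)


class TestRunStatic:
    def test_python_engine_matches_public_move_path(self):
        """The optimized loop consumes randomness exactly like
        propose_move + metropolis_step, so whole runs are replayable."""
        for seed in (1, 2):
            net = generate_er(12, 0.3, seed=seed)
            ens = network_to_pairs(net)
            syn = SynapseSet.full(12)
            res = run(ens, syn, seed=seed, engine="python")

            rng = random.Random(seed)
            st = init_state(ens, syn, rng=rng)
            probs = MCParams().resolved_probs(st.n_pairs / (12 * 11), 12)
            attempts = acc = 0
            while attempts < res.max_attempts:
                attempts += 1
                mv = propose_move(st, probs, rng)
                if mv is None:
                    continue
                a, _ = metropolis_step(st, mv, rng=rng)
                acc += a
                if st.is_oboc():
                    break
            assert (attempts, acc, st.H) == (
                res.n_steps_total,
                sum(res.accepted.values()),
                res.h_final,
            )

    def test_small_network_clones_exactly(self):
        net = generate_er(6, 0.3, seed=4)
        ens = network_to_pairs(net)
        res = run(ens, SynapseSet.full(6), seed=11)
        assert res.converged and res.oboc
        _, verified = recover_mapping(res.state, net.matrix())
        assert verified

    def test_already_oboc_initial_state_converges_untouched(self, small_net):
        st = make_oboc_state(small_net, perm=list(range(small_net.n_cells)))
        res = run(
            network_to_pairs(small_net),
            SynapseSet.full(small_net.n_cells),
            initial_state=st,
            seed=0,
        )
        assert res.converged
        assert res.n_steps_total == 0
        assert sum(res.accepted.values()) == 0

    def test_empty_ensemble_trivially_converged(self):
        from netclone import PairEnsemble

        res = run(PairEnsemble([], 5), SynapseSet.full(5), seed=0)
        assert res.converged and res.n_steps_total == 0

    @pytest.mark.parametrize("n,seed", [(10, 0), (20, 1), (30, 2), (30, 3)])
    def test_static_runs_converge_and_verify(self, n, seed):
        """No non-OBOC minima for eps >= 1: every static full run reaches
        OBOC and clones the target exactly."""
        net = generate_er(n, 0.3, seed=seed)
        res = run(network_to_pairs(net), SynapseSet.full(n), seed=seed + 100)
        assert res.converged
        _, verified = recover_mapping(res.state, net.matrix())
        assert verified

    def test_no_uphill_moves_at_low_temperature(self):
        net = generate_er(16, 0.3, seed=5)
        res = run(network_to_pairs(net), SynapseSet.full(16), seed=6)
        assert res.h_final <= res.h_init
        assert res.n_strict_decreasing <= res.h_init - res.h_final

    def test_attempts_per_pair_identity(self):
        net = generate_er(14, 0.3, seed=6)
        res = run(network_to_pairs(net), SynapseSet.full(14), seed=7)
        assert res.n_steps_per_pair == res.n_steps_total / res.n_pairs

    def test_engines_agree_statistically(self):
        """Kernel and Python engines implement the same dynamics: all runs
        converge to verified copies and mean convergence times agree."""
        net = generate_er(16, 0.3, seed=8)
        ens = network_to_pairs(net)
        syn = SynapseSet.full(16)
        steps = {}
        for engine in ("python", "kernel"):
            vals = []
            for seed in range(10):
                res = run(ens, syn, seed=seed, engine=engine)
                assert res.converged
                _, verified = recover_mapping(res.state, net.matrix())
                assert verified
                vals.append(res.n_steps_total)
            steps[engine] = np.mean(vals)
        ratio = steps["kernel"] / steps["python"]
        assert 0.5 < ratio < 2.0

    def test_kernel_engine_requires_static_exact_case(self):
        net = generate_er(8, 0.3, seed=0)
        with pytest.raises(ValueError):
            run(
                network_to_pairs(net),
                SynapseSet.full(8),
                CostParams(gamma=3, epsilon=10),
                seed=0,
                engine="kernel",
            )


class TestDynamicSynapses:
    def test_relocation_conserves_synapse_count_and_avoids_occupied(self):
        net = generate_er(12, 0.2, seed=3)
        ens = network_to_pairs(net)
        syn = SynapseSet.random_sparse(12, 0.5, seed=4)
        st = init_state(ens, syn, rng=5)
        before = len(st.syn_pre)
        occupied = {
            (st.syn_pre[s], st.syn_post[s])
            for s, pl in enumerate(st.syn_pairs)
            if pl
        }
        rng = random.Random(6)
        relocated, shortfall = relocate_empty_synapses(st, rng)
        assert len(st.syn_pre) == before
        assert shortfall == 0
        # occupied synapses untouched; all synapses still distinct ordered pairs
        now = {(st.syn_pre[s], st.syn_post[s]) for s, pl in enumerate(st.syn_pairs) if pl}
        assert now == occupied
        all_syn = list(zip(st.syn_pre, st.syn_post))
        assert len(set(all_syn)) == len(all_syn)
        assert all(a != b for a, b in all_syn)

    def test_full_network_relocation_is_noop(self):
        st = make_random_state(n_cells=6, density=0.9, seed=1)
        pairs_before = list(zip(st.syn_pre, st.syn_post))
        n_empty = sum(1 for pl in st.syn_pairs if not pl)
        relocated, shortfall = relocate_empty_synapses(st, random.Random(0))
        # full tabula rasa: no vacant cell pair exists to relocate into
        assert relocated == 0 and shortfall == n_empty
        assert list(zip(st.syn_pre, st.syn_post)) == pairs_before

    @pytest.mark.parametrize("n,f,seed", [(20, 0.2, 0), (30, 0.2, 1), (40, 0.15, 2)])
    def test_dynamic_sparse_runs_converge_and_verify(self, n, f, seed):
        net = generate_er(n, f, seed=seed)
        ens = network_to_pairs(net)
        f_real = len(ens) / (n * (n - 1))
        f_tr = DynamicsParams.tabula_rasa_density(f_real)
        syn = SynapseSet.random_sparse(n, f_tr, seed=seed + 50)
        res = run(
            ens,
            syn,
            dyn=DynamicsParams(mode=DYNAMIC_SPARSE),
            seed=seed + 500,
        )
        assert res.converged
        assert res.n_relocation_sweeps > 0
        _, verified = recover_mapping(res.state, net.matrix())
        assert verified

    def test_tabula_rasa_density_formula(self):
        assert DynamicsParams.tabula_rasa_density(0.0) == pytest.approx(0.3)
        assert DynamicsParams.tabula_rasa_density(1.0) == pytest.approx(1.0)
        assert DynamicsParams.tabula_rasa_density(0.4) == pytest.approx(0.58)


class TestPruneAndReadOut:
    def test_oboc_readout_counts_edges(self):
        net = generate_er(6, 0.4, seed=9)
        st = make_oboc_state(net, perm=[3, 1, 4, 0, 5, 2])
        w, mapping, oboc = prune_and_read_out(st)
        assert oboc
        assert int(w.sum()) == st.n_pairs

    def test_non_oboc_readout_flags_and_falls_back(self, random_state):
        w, mapping, oboc = prune_and_read_out(random_state)
        assert not oboc
        assert sorted(mapping.values()) == list(range(random_state.n_types))

    def test_predicted_attempts_monotone(self):
        assert predicted_attempts(0.2, 20) < predicted_attempts(0.2, 40)
        assert predicted_attempts(0.1, 30) < predicted_attempts(0.4, 30)
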
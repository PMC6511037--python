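"""Cost function, counts bookkeeping, and incremental cost changes."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from netclone import (
    CloneState,
    CostParams,
    InvalidMoveError,
    MoveProposal,
    PairEnsemble,
    SynapseSet,
    apply_move,
    compute_counts,
    cost,
    cost_from_counts,
    cost_terms,
    delta_cost_move,
    propose_move,
    relocation_delta,
)
from netclone.state import load_state, save_state

from conftest import make_random_state

EPS10 = CostParams(gamma=2, epsilon=10)


def state_fingerprint(st_):
    return (
        tuple(st_.pair_syn),
        tuple(st_.pair_orient),
        tuple(tuple(r) for r in st_.counts),
        st_.H,
        st_.n_impure_cells,
        st_.n_spread_types,
    )


def random_move(state, rng):
    return propose_move(state, (0.6, 0.3, 0.1), rng)


class TestCostWorkedExamples:
    """The two-copies-in-one-cell vs split worked cases, gamma = 2."""

    @pytest.mark.parametrize("eps", [1, 10])
    def test_first_term_same_type_concentrated_vs_split(self, eps):
        params = CostParams(gamma=2, epsilon=eps)
        together = [[2, 0], [0, 0]]
        split = [[1, 0], [1, 0]]
        assert cost_terms(together, params)[0] == -4 * (1 + eps)
        assert cost_terms(split, params)[0] == -2 * (1 + eps)

    @pytest.mark.parametrize("eps", [1, 10])
    def test_second_term_two_types_concentrated_vs_split(self, eps):
        params = CostParams(gamma=2, epsilon=eps)
        together = [[2, 2], [0, 0]]
        split = [[2, 0], [0, 2]]
        assert cost_terms(together, params)[1] == 16 * eps
        assert cost_terms(split, params)[1] == 8 * eps

    def test_empty_state_costs_zero(self):
        assert cost_from_counts([[0, 0], [0, 0]], EPS10) == 0

    def test_integer_exactness(self):
        st_ = make_random_state(n_cells=6, density=0.5, seed=2)
        assert isinstance(st_.H, int)
        assert st_.H == cost(st_)


class TestComputeCounts:
    def test_single_forward_pair(self):
        ens = PairEnsemble([(0, 1)], 4)
        syn = SynapseSet.full(4)
        sid = {ab: i for i, ab in enumerate(syn.synapses)}
        st_ = CloneState(ens, syn, [sid[(1, 2)]], [0], EPS10)
        expect = [[0] * 4 for _ in range(4)]
        expect[1][0] = 1  # pre-type 0 faces cell 1
        expect[2][1] = 1  # post-type 1 faces cell 2
        assert st_.counts == expect

    def test_reversed_orientation_swaps_facings(self):
        ens = PairEnsemble([(0, 1)], 4)
        syn = SynapseSet.full(4)
        sid = {ab: i for i, ab in enumerate(syn.synapses)}
        st_ = CloneState(ens, syn, [sid[(1, 2)]], [1], EPS10)
        assert st_.counts[2][0] == 1 and st_.counts[1][1] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_endpoint_conservation(self, seed):
        st_ = make_random_state(n_cells=8, density=0.4, seed=seed)
        assert sum(map(sum, st_.counts)) == 2 * st_.n_pairs


counts_strategy = st.lists(
    st.lists(st.integers(min_value=0, max_value=5), min_size=6, max_size=6),
    min_size=6,
    max_size=6,
)


class TestRelocationFormula:
    """The single-endpoint relocation cost change (quadratic case)."""

    def test_null_relocation_is_zero(self):
        counts = [[3, 0], [0, 1]]
        assert relocation_delta(counts, 0, 0, 0, EPS10) == 0

    def test_empty_source_rejected(self):
        with pytest.raises(InvalidMoveError):
            relocation_delta([[0, 1], [2, 0]], 0, 0, 1, EPS10)

    def test_gamma_must_be_two(self):
        with pytest.raises(ValueError):
            relocation_delta([[1]], 0, 0, 0, CostParams(gamma=3, epsilon=1))

    @settings(max_examples=200, derandomize=True)
    @given(counts=counts_strategy, eps=st.sampled_from([1, 10]),
           beta=st.integers(0, 5), m=st.integers(0, 5), n=st.integers(0, 5))
    def test_shared_type_round_trip_sums_to_minus_two(self, counts, eps, beta, m, n):
        """For two cells both hosting a type, the forward and reverse
        relocation changes always sum to -2 — so one direction is downhill."""
        if m == n:
            return
        counts[m][beta] = max(1, counts[m][beta])
        counts[n][beta] = max(1, counts[n][beta])
        params = CostParams(gamma=2, epsilon=eps)
        fwd = relocation_delta(counts, beta, m, n, params)
        rev = relocation_delta(counts, beta, n, m, params)
        assert fwd + rev == -2

    @settings(max_examples=200, derandomize=True)
    @given(counts=counts_strategy, eps=st.sampled_from([1, 10]),
           beta=st.integers(0, 5), m=st.integers(0, 5), n=st.integers(0, 5))
    def test_formula_is_half_the_exact_cost_change(self, counts, eps, beta, m, n):
        if m == n or counts[m][beta] == 0:
            return
        params = CostParams(gamma=2, epsilon=eps)
        before = cost_from_counts(counts, params)
        moved = [list(r) for r in counts]
        moved[m][beta] -= 1
        moved[n][beta] += 1
        after = cost_from_counts(moved, params)
        assert after - before == 2 * relocation_delta(counts, beta, m, n, params)

    @pytest.mark.parametrize("eps", [1, 10])
    def test_case1_move_to_empty_cell_is_downhill(self, eps):
        """Each type confined to one cell, one multi-type cell, one empty
        cell: relocating the least-abundant type to the empty cell costs
        at most -1."""
        params = CostParams(gamma=2, epsilon=eps)
        counts = [
            [3, 2, 0, 0],  # cell 0 hosts types 0 and 1
            [0, 0, 4, 0],
            [0, 0, 0, 1],
            [0, 0, 0, 0],  # empty cell
        ]
        least = 1  # type 1 has the minimal abundance in cell 0
        assert relocation_delta(counts, least, 0, 3, params) <= -1


class TestDeltaCostMove:
    @pytest.mark.parametrize("seed", range(4))
    def test_incremental_matches_full_recompute(self, seed):
        """Random flips/jumps/swaps: incremental dH equals the recomputed
        cost difference exactly, every time."""
        st_ = make_random_state(n_cells=8, density=0.35, seed=seed)
        rng = random.Random(seed)
        checked = 0
        while checked < 250:
            mv = random_move(st_, rng)
            if mv is None:
                continue
            before = cost(st_)
            dh = delta_cost_move(st_, mv)
            apply_move(st_, mv, dh)
            assert cost(st_) - before == dh
            checked += 1

    def test_general_gamma_falls_back_to_recompute(self):
        params = CostParams(gamma=3.0, epsilon=2.5)
        st_ = make_random_state(n_cells=6, density=0.4, seed=1, params=params)
        rng = random.Random(0)
        for _ in range(50):
            mv = random_move(st_, rng)
            if mv is None:
                continue
            before = cost(st_, params)
            dh = delta_cost_move(st_, mv, params)
            apply_move(st_, mv, dh)
            assert cost(st_, params) - before == pytest.approx(dh, abs=1e-9)

    def test_jump_matches_relocation_formula_times_two(self):
        """A jump that relocates exactly one endpoint agrees with the
        analytic single-endpoint formula (on the doubled scale)."""
        ens = PairEnsemble([(0, 1)], 4)
        syn = SynapseSet.full(4)
        sid = {ab: i for i, ab in enumerate(syn.synapses)}
        st_ = CloneState(ens, syn, [sid[(1, 2)]], [0], EPS10)
        # move pair to synapse (1,3) forward: endpoint of type 1 goes 2 -> 3
        mv = MoveProposal("jump", 0, sid[(1, 3)], 0)
        eq4 = relocation_delta(st_.counts, 1, 2, 3, EPS10)
        assert delta_cost_move(st_, mv) == 2 * eq4

    def test_invalid_move_rejected_and_state_unchanged(self, random_state):
        fp = state_fingerprint(random_state)
        with pytest.raises(InvalidMoveError):
            apply_move(random_state, MoveProposal("jump", 10**6, 0, 0))
        assert state_fingerprint(random_state) == fp


class TestApplyMove:
    def test_inverse_move_restores_state(self):
        st_ = make_random_state(n_cells=6, density=0.5, seed=3)
        rng = random.Random(3)
        for _ in range(100):
            mv = random_move(st_, rng)
            if mv is None:
                continue
            fp = state_fingerprint(st_)
            if mv.kind == "swap":
                inv = MoveProposal(
                    "swap",
                    mv.pair, mv.dest_syn2, st_.pair_orient[mv.pair],
                    mv.pair2, mv.dest_syn, st_.pair_orient[mv.pair2],
                )
            else:
                inv = MoveProposal(
                    mv.kind, mv.pair, st_.pair_syn[mv.pair], st_.pair_orient[mv.pair]
                )
            apply_move(st_, mv)
            apply_move(st_, inv)
            assert state_fingerprint(st_) == fp

    def test_no_cached_cost_drift_over_many_moves(self):
        st_ = make_random_state(n_cells=8, density=0.3, seed=5)
        rng = random.Random(5)
        applied = 0
        while applied < 10_000:
            mv = random_move(st_, rng)
            if mv is None:
                continue
            apply_move(st_, mv)
            applied += 1
        rebuilt = CloneState(
            st_.ensemble(), st_.synapse_set(), st_.pair_syn, st_.pair_orient, st_.params
        )
        assert st_.H == rebuilt.H
        assert st_.counts == rebuilt.counts
        assert st_.n_impure_cells == rebuilt.n_impure_cells
        assert st_.n_spread_types == rebuilt.n_spread_types
        assert sum(map(sum, st_.counts)) == 2 * st_.n_pairs

    def test_pair_count_conserved(self, random_state):
        rng = random.Random(1)
        n0 = random_state.n_pairs
        for _ in range(200):
            mv = random_move(random_state, rng)
            if mv is not None:
                apply_move(random_state, mv)
        assert random_state.n_pairs == n0
        assert sum(len(l) for l in random_state.syn_pairs) == n0


class TestSnapshot:
    def test_round_trip(self, tmp_path, random_state):
        table = tmp_path / "state.tsv"
        sidecar = tmp_path / "state.json"
        save_state(random_state, table, sidecar)
        back = load_state(table, sidecar)
        assert state_fingerprint(back) == state_fingerprint(random_state)
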
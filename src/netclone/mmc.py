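"""Metropolis Monte Carlo dynamics of barcode pairs.

Pairs move through the recipient network by three local moves — jumps
(relocation to another synapse of the same cell), swaps (two pairs on two
synapses of one cell trade places) and flips (reinsertion in the same
synapse with the other orientation) — attempted with probabilities
``1 - f``, ``f - 1/N`` and ``1/N``, where ``f`` is the realized pair
density.  Moves are accepted by the Metropolis rule at low temperature
(default ``T = 1e-4``), so the dynamics is effectively greedy with free
lateral (dH = 0) exploration.  A simulation terminates when the
one-barcode-one-cell (OBOC) state is reached; empty synapses are then
pruned and the recovered connectivity read out.

In the dynamic-synapse variant the tabula rasa is sparse (density
``f_TR = f + 0.3 * (1 - f)``) and, every ``Na`` attempts, synapses holding
no pairs are torn down and rebuilt between currently unconnected cell
pairs — a crude model of synaptic turnover during development.

``N_steps`` counts *attempts* (every proposal, including null proposals
where no destination exists), matching the convention used for the
convergence power law; accepted moves are tracked separately.
"""

from __future__ import annotations

import functools
import math
import random
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .netgen import PairEnsemble
from .state import (
    CloneState,
    CostParams,
    MoveProposal,
    SynapseSet,
    apply_move,
    delta_cost_move,
)

__all__ = [
    "MCParams",
    "DynamicsParams",
    "RunResult",
    "init_state",
    "propose_move",
    "metropolis_accept",
    "metropolis_step",
    "run",
    "relocate_empty_synapses",
    "prune_and_read_out",
]

STATIC_FULL = "static_full"
DYNAMIC_SPARSE = "dynamic_sparse"


@dataclass
class MCParams:
    """Monte Carlo control parameters.

    Move probabilities left as None default to (1 - f, f - 1/N, 1/N) with
    negative values clamped to zero and the triple renormalized to sum to 1
    (a residual redraw).  ``max_attempts`` defaults to 100 times the
    predicted mean convergence time ``f^1.5 N^3.5``.
    """

    temperature: float = 1e-4
    p_jump: float | None = None
    p_swap: float | None = None
    p_flip: float | None = None
    max_attempts: int | None = None
    oboc_check_interval: int | None = None
    enable_swaps_flips: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def resolved_probs(self, f: float, n_cells: int) -> tuple[float, float, float]:
        if not self.enable_swaps_flips:
            return (1.0, 0.0, 0.0)
        pj = (1.0 - f) if self.p_jump is None else self.p_jump
        ps = max(0.0, f - 1.0 / n_cells) if self.p_swap is None else self.p_swap
        pf = (1.0 / n_cells) if self.p_flip is None else self.p_flip
        if min(pj, ps, pf) < 0:
            raise ValueError("move probabilities must be nonnegative")
        total = pj + ps + pf
        if total <= 0:
            raise ValueError("at least one move kind must have positive probability")
        if total > 1.0:
            pj, ps, pf = pj / total, ps / total, pf / total
        return (pj, ps, pf)


@dataclass
class DynamicsParams:
    """Synapse-dynamics settings.

    ``static_full`` runs on the all-to-all tabula rasa.  ``dynamic_sparse``
    runs on a sparse tabula rasa of density ``f_tr = f + 0.3 * (1 - f)``
    with empty-synapse relocation every ``relocation_interval`` attempts
    (default: predicted run length / ``target_relocations``, reproducing
    roughly ``target_relocations`` turnover sweeps per run).
    """

    mode: str = STATIC_FULL
    f_tr: float | None = None
    relocation_interval: int | None = None
    target_relocations: int = 100

    def __post_init__(self) -> None:
        if self.mode not in (STATIC_FULL, DYNAMIC_SPARSE):
            raise ValueError(f"unknown mode {self.mode!r}")

    @staticmethod
    def tabula_rasa_density(f: float) -> float:
        return f + 0.3 * (1.0 - f)


@dataclass
class RunResult:
    converged: bool
    n_steps_total: int
    n_pairs: int
    attempted: dict[str, int]
    accepted: dict[str, int]
    n_strict_decreasing: int
    h_init: int | float
    h_final: int | float
    h_trajectory: list[tuple[int, int | float]]
    max_attempts: int
    n_relocation_sweeps: int
    oboc: bool
    w_recovered: np.ndarray
    mapping: dict[int, int]
    state: CloneState = field(repr=False)
    seed: int | None = None

    @property
    def n_steps_per_pair(self) -> float:
        """Attempts per barcode pair, n_steps = N_steps / P."""
        return self.n_steps_total / self.n_pairs if self.n_pairs else 0.0


def predicted_attempts(f: float, n_cells: int) -> float:
    """The empirical convergence power law ``f^1.5 * N^3.5``, used to size
    attempt caps and relocation intervals."""
    return max(1.0, f**1.5 * n_cells**3.5)


def init_state(
    ensemble: PairEnsemble,
    synapses: SynapseSet,
    params: CostParams | None = None,
    rng: random.Random | int | None = None,
) -> CloneState:
    """Place every pair on a uniformly random synapse with a uniformly
    random orientation, independently."""
    if len(synapses) == 0:
        raise ValueError("cannot initialize on an empty synapse set")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    nsyn = len(synapses)
    n = len(ensemble)
    placement = [rng.randrange(nsyn) for _ in range(n)]
    orientations = [rng.randrange(2) for _ in range(n)]
    return CloneState(ensemble, synapses, placement, orientations, params)


def _draw_jump(state: CloneState, rng: random.Random) -> MoveProposal | None:
    # uniform draws as int(random() * k): one C-level call per draw
    rnd = rng.random
    p = int(rnd() * len(state.pair_pre))
    s = state.pair_syn[p]
    fa, fb = state.facing_cells(p)
    c = fa if int(rnd() * 2) == 0 else fb
    syns = state.cell_syns[c]
    if len(syns) < 2:
        return None
    while True:
        d = syns[int(rnd() * len(syns))]
        if d != s:
            break
    return MoveProposal("jump", p, d, int(rnd() * 2))


def propose_move(
    state: CloneState,
    probs: tuple[float, float, float],
    rng: random.Random,
) -> MoveProposal | None:
    """Draw one move with the configured kind probabilities.

    Returns None for a null attempt (no legal destination).  A swap whose
    chosen cell lacks two occupied synapses is re-drawn as a jump, counted
    as the same single attempt.
    """
    if not state.pair_pre:
        return None
    pj, ps, pf = probs
    c2 = pj + ps
    c3 = c2 + pf
    while True:
        u = rng.random()
        if u < pj:
            return _draw_jump(state, rng)
        if u < c2:
            rnd = rng.random
            c = int(rnd() * state.n_cells)
            occ = state.cell_occ[c]
            nocc = len(occ)
            if nocc < 2:
                return _draw_jump(state, rng)
            i = int(rnd() * nocc)
            j = int(rnd() * (nocc - 1))
            if j >= i:
                j += 1
            s1, s2 = occ[i], occ[j]
            l1, l2 = state.syn_pairs[s1], state.syn_pairs[s2]
            p1 = l1[int(rnd() * len(l1))]
            p2 = l2[int(rnd() * len(l2))]
            return MoveProposal(
                "swap", p1, s2, int(rnd() * 2), p2, s1, int(rnd() * 2)
            )
        if u < c3:
            p = int(rng.random() * len(state.pair_pre))
            return MoveProposal("flip", p, state.pair_syn[p], 1 - state.pair_orient[p])
        # residual probability mass: redraw


def metropolis_accept(dh: int | float, temperature: float, rng: random.Random) -> bool:
    """Accept downhill and lateral (dh <= 0) moves always; uphill moves with
    probability exp(-dh / T)."""
    if dh <= 0:
        return True
    x = dh / temperature
    p = math.exp(-x) if x < 745.0 else 0.0
    return rng.random() < p


def metropolis_step(
    state: CloneState,
    move: MoveProposal,
    cost_params: CostParams | None = None,
    mc: MCParams | None = None,
    rng: random.Random | None = None,
):
    """Evaluate and (on acceptance) atomically apply one move.

    Returns ``(accepted, dh)``.
    """
    mc = mc or MCParams()
    rng = rng if isinstance(rng, random.Random) else random.Random(rng)
    dh = delta_cost_move(state, move, cost_params)
    accepted = metropolis_accept(dh, mc.temperature, rng)
    if accepted:
        apply_move(state, move, dh)
    return accepted, dh


def relocate_empty_synapses(state: CloneState, rng: random.Random) -> tuple[int, int]:
    """Tear down every synapse holding zero pairs and rebuild it between a
    uniformly chosen, currently unconnected ordered cell pair.

    Occupied synapses are untouched and the synapse count is conserved.
    Returns ``(n_relocated, shortfall)``; a shortfall occurs only when no
    vacant ordered pair remains.
    """
    n = state.n_cells
    syn_index = state.syn_index
    empties = [s for s, plist in enumerate(state.syn_pairs) if not plist]
    relocated = 0
    for s in empties:
        vacancy = n * (n - 1) - len(syn_index)
        if vacancy <= 0:
            break
        found = None
        # rejection sampling; fall back to enumeration when vacancies are rare
        for _ in range(64):
            a = rng.randrange(n)
            b = rng.randrange(n - 1)
            if b >= a:
                b += 1
            if (a, b) not in syn_index:
                found = (a, b)
                break
        if found is None:
            vacant = [
                (a, b)
                for a in range(n)
                for b in range(n)
                if a != b and (a, b) not in syn_index
            ]
            found = vacant[rng.randrange(len(vacant))]
        a0, b0 = state.syn_pre[s], state.syn_post[s]
        del syn_index[(a0, b0)]
        for c in (a0, b0):
            pos = state.cell_syn_pos[c].pop(s)
            lst = state.cell_syns[c]
            last = lst[-1]
            lst[pos] = last
            if last != s:
                state.cell_syn_pos[c][last] = pos
            lst.pop()
        a, b = found
        state.syn_pre[s], state.syn_post[s] = a, b
        syn_index[(a, b)] = s
        for c in (a, b):
            state.cell_syn_pos[c][s] = len(state.cell_syns[c])
            state.cell_syns[c].append(s)
        relocated += 1
    return relocated, len(empties) - relocated


def prune_and_read_out(state: CloneState):
    """Delete barcode-free synapses and read out the recovered connectivity.

    Returns ``(w_recovered, mapping, oboc)``.  Each retained synapse
    functions in the direction written by its resident pair: a pair whose
    pre-type endpoint faces cell ``a`` and post-type endpoint faces cell
    ``b`` contributes the edge ``a -> b`` (``w_recovered[b, a] = 1``).  The
    orientation bit and the synapse slot together encode which directed
    synapse a pair occupies, so this is the slot-independent readout of the
    placement.  ``mapping`` assigns each cell its unique facing barcode
    type; on a non-OBOC state it falls back to the greedy dominant-barcode
    assignment and ``oboc`` is False.
    """
    from .verify import dominant_mapping  # local import: verify builds on state

    n = state.n_cells
    w = np.zeros((n, n), dtype=np.int64)
    for p in range(state.n_pairs):
        fa, fb = state.facing_cells(p)
        w[fb, fa] = 1
    oboc = state.is_oboc()
    if oboc:
        mapping: dict[int, int] = {}
        used_types = set()
        for cell, row in enumerate(state.counts):
            for beta, v in enumerate(row):
                if v:
                    mapping[cell] = beta
                    used_types.add(beta)
                    break
        leftover_cells = [c for c in range(n) if c not in mapping]
        leftover_types = [b for b in range(state.n_types) if b not in used_types]
        for c, b in zip(leftover_cells, leftover_types):
            mapping[c] = b
    else:
        mapping = dominant_mapping(state)
    return w, mapping, oboc


@functools.lru_cache(maxsize=8)
def _full_order(n: int) -> tuple[tuple[int, int], ...]:
    return tuple((a, b) for a in range(n) for b in range(n) if a != b)


def _try_kernel(
    ensemble, synapses, cost_params, mc, dyn, seed, rng, initial_state, progress, force
):
    """Dispatch to the compiled engine when the run qualifies; None means
    'use the Python loop'."""
    from . import _kernel

    n = synapses.n_cells
    n_pairs = len(ensemble)
    supported = (
        _kernel.HAVE_NUMBA
        and initial_state is None
        and progress is None
        and dyn.mode == STATIC_FULL
        and cost_params.gamma == 2
        and cost_params.exact
        and n_pairs > 0
        and len(synapses) == n * (n - 1)
        and tuple(synapses.synapses) == _full_order(n)
    )
    if not supported:
        if force:
            raise ValueError(
                "kernel engine requires a static full synapse set, gamma=2, "
                "integer epsilon, no initial state and no progress callback"
            )
        return None
    f_real = n_pairs / (n * (n - 1))
    predicted = predicted_attempts(f_real, n)
    max_attempts = mc.max_attempts if mc.max_attempts is not None else math.ceil(100 * predicted)
    pj, ps, pf = mc.resolved_probs(f_real, n)
    kseed = rng.randrange(2**31)  # deterministic substream for the kernel RNG
    pre = np.fromiter((mu for mu, _ in ensemble.pairs), np.int64, n_pairs)
    post = np.fromiter((nu for _, nu in ensemble.pairs), np.int64, n_pairs)
    (
        status, attempts, converged, h_init, h_final, n_strict,
        att_j, att_s, att_f, acc_j, acc_s, acc_f, pair_syn, pair_orient,
    ) = _kernel.run_static_kernel(
        n, pre, post, pj, ps, pf, int(cost_params.epsilon),
        mc.temperature, max_attempts, kseed,
    )
    if status != _kernel.STATUS_OK:
        return None  # pathological occupancy: redo with the list-based loop
    state = CloneState(
        ensemble, synapses, pair_syn.tolist(), pair_orient.tolist(), cost_params
    )
    if state.H != h_final:
        raise RuntimeError(
            f"kernel/python cost disagreement: {h_final} vs {state.H}"
        )
    w, mapping, oboc = prune_and_read_out(state)
    return RunResult(
        converged=bool(converged),
        n_steps_total=int(attempts),
        n_pairs=n_pairs,
        attempted={"jump": int(att_j), "swap": int(att_s), "flip": int(att_f), "null": 0},
        accepted={"jump": int(acc_j), "swap": int(acc_s), "flip": int(acc_f)},
        n_strict_decreasing=int(n_strict),
        h_init=int(h_init),
        h_final=int(h_final),
        h_trajectory=[(0, int(h_init)), (int(attempts), int(h_final))],
        max_attempts=max_attempts,
        n_relocation_sweeps=0,
        oboc=oboc,
        w_recovered=w,
        mapping=mapping,
        state=state,
        seed=seed,
    )


def run(
    ensemble: PairEnsemble,
    synapses: SynapseSet,
    cost_params: CostParams | None = None,
    mc: MCParams | None = None,
    dyn: DynamicsParams | None = None,
    seed: int | None = None,
    initial_state: CloneState | None = None,
    progress: Callable[[int, int | float, float], None] | None = None,
    engine: str = "auto",
) -> RunResult:
    """Run the Metropolis dynamics until OBOC or the attempt cap.

    ``engine="auto"`` dispatches static fully connected, gamma = 2,
    integer-epsilon runs to the compiled kernel and everything else to the
    pure-Python loop; ``"python"`` / ``"kernel"`` force one of the two.
    Both engines implement identical dynamics but draw from distinct seeded
    random streams, so their individual trajectories differ while all exact
    invariants (integer H bookkeeping, OBOC at termination) coincide.

    The Python loop draws random numbers in exactly the same order as
    :func:`propose_move` followed by :func:`metropolis_step`, so a run is
    reproducible move-for-move from its seed through either path.
    """
    if engine not in ("auto", "python", "kernel"):
        raise ValueError(f"unknown engine {engine!r}")
    cost_params = cost_params or CostParams()
    mc = mc or MCParams()
    dyn = dyn or DynamicsParams()
    if seed is None:
        seed = mc.seed
    rng = random.Random(seed)

    dynamic = dyn.mode == DYNAMIC_SPARSE
    if engine != "python":
        result = _try_kernel(
            ensemble, synapses, cost_params, mc, dyn, seed, rng,
            initial_state, progress, force=engine == "kernel",
        )
        if result is not None:
            return result

    state = initial_state or init_state(ensemble, synapses, cost_params, rng)
    n = state.n_cells
    n_pairs = state.n_pairs
    f_real = n_pairs / (n * (n - 1))
    predicted = predicted_attempts(f_real, n)
    max_attempts = mc.max_attempts if mc.max_attempts is not None else math.ceil(100 * predicted)
    log_interval = mc.oboc_check_interval or max(n_pairs, 1000)
    na = 0
    if dynamic:
        na = dyn.relocation_interval or max(1, math.ceil(predicted / dyn.target_relocations))

    attempted = {"jump": 0, "swap": 0, "flip": 0, "null": 0}
    accepted = {"jump": 0, "swap": 0, "flip": 0}
    n_strict = 0
    n_sweeps = 0
    h_init = state.H
    traj: list[tuple[int, int | float]] = [(0, h_init)]
    attempts = 0
    converged = n_pairs == 0 or state.is_oboc()

    if not converged:
        exact = cost_params.exact and cost_params.gamma == 2
        eps = int(cost_params.epsilon) if exact else cost_params.epsilon
        e1x2 = 2 * (1 + eps)
        temperature = mc.temperature
        pj, ps, pf = mc.resolved_probs(f_real, n)
        c2 = pj + ps
        c3 = c2 + pf
        counts = state.counts
        totals = state.totals
        pair_pre = state.pair_pre
        pair_post = state.pair_post
        pair_syn = state.pair_syn
        pair_orient = state.pair_orient
        syn_pre = state.syn_pre
        syn_post = state.syn_post
        syn_pairs = state.syn_pairs
        cell_syns = state.cell_syns
        cell_occ = state.cell_occ
        rnd = rng.random

        e1 = 1 + eps
        dh_cap = 745.0 * temperature  # exp(-dh/T) underflows beyond this
        att_jump = att_swap = att_flip = att_null = 0
        acc_jump = acc_swap = acc_flip = 0
        ae = state.apply_endpoint

        while attempts < max_attempts:
            attempts += 1
            # --- propose (kind probabilities; residual mass redrawn) ---
            kind = 0  # 0 jump, 1 swap, 2 flip
            while True:
                u = rnd()
                if u < pj:
                    break
                if u < c2:
                    kind = 1
                    break
                if u < c3:
                    kind = 2
                    break

            if kind == 1:
                c = int(rnd() * n)
                occ = cell_occ[c]
                nocc = len(occ)
                if nocc >= 2:
                    i = int(rnd() * nocc)
                    j = int(rnd() * (nocc - 1))
                    if j >= i:
                        j += 1
                    s1, s2 = occ[i], occ[j]
                    l1, l2 = syn_pairs[s1], syn_pairs[s2]
                    p1 = l1[int(rnd() * len(l1))]
                    p2 = l2[int(rnd() * len(l2))]
                    o1 = int(rnd() * 2)
                    o2 = int(rnd() * 2)
                    att_swap += 1
                    if exact:
                        # endpoint changes for p1: s1 -> s2 and p2: s2 -> s1
                        aa, bb = syn_pre[s1], syn_post[s1]
                        fa1, fb1 = (bb, aa) if pair_orient[p1] else (aa, bb)
                        cc, dd = syn_pre[s2], syn_post[s2]
                        a21, b21 = (dd, cc) if o1 else (cc, dd)
                        fa2, fb2 = (dd, cc) if pair_orient[p2] else (cc, dd)
                        a22, b22 = (bb, aa) if o2 else (aa, bb)
                        mu1, nu1 = pair_pre[p1], pair_post[p1]
                        mu2, nu2 = pair_pre[p2], pair_post[p2]
                        m1 = fa1 != a21
                        m2 = fb1 != b21
                        m3 = fa2 != a22
                        m4 = fb2 != b22
                        if mu1 != mu2 and mu1 != nu2 and nu1 != mu2 and nu1 != nu2:
                            # the two pairs share no type: count keys distinct
                            ops = None
                            dh = 0
                            if m1:
                                dh -= e1x2 * (counts[a21][mu1] - counts[fa1][mu1] + 1)
                            if m2:
                                dh -= e1x2 * (counts[b21][nu1] - counts[fb1][nu1] + 1)
                            if m3:
                                dh -= e1x2 * (counts[a22][mu2] - counts[fa2][mu2] + 1)
                            if m4:
                                dh -= e1x2 * (counts[b22][nu2] - counts[fb2][nu2] + 1)
                            if m1 or m2 or m3 or m4:
                                dtot: dict = {}
                                if m1:
                                    dtot[fa1] = dtot.get(fa1, 0) - 1
                                    dtot[a21] = dtot.get(a21, 0) + 1
                                if m2:
                                    dtot[fb1] = dtot.get(fb1, 0) - 1
                                    dtot[b21] = dtot.get(b21, 0) + 1
                                if m3:
                                    dtot[fa2] = dtot.get(fa2, 0) - 1
                                    dtot[a22] = dtot.get(a22, 0) + 1
                                if m4:
                                    dtot[fb2] = dtot.get(fb2, 0) - 1
                                    dtot[b22] = dtot.get(b22, 0) + 1
                                for cellx, ddx in dtot.items():
                                    if ddx:
                                        tv = totals[cellx]
                                        dh += eps * (2 * tv * ddx + ddx * ddx)
                        else:
                            ops = []
                            if m1:
                                ops.append((fa1, mu1, -1))
                                ops.append((a21, mu1, 1))
                            if m2:
                                ops.append((fb1, nu1, -1))
                                ops.append((b21, nu1, 1))
                            if m3:
                                ops.append((fa2, mu2, -1))
                                ops.append((a22, mu2, 1))
                            if m4:
                                ops.append((fb2, nu2, -1))
                                ops.append((b22, nu2, 1))
                            dh = 0
                            if ops:
                                dcount: dict = {}
                                dtot2: dict = {}
                                for cellx, betax, ddx in ops:
                                    key = (cellx, betax)
                                    dcount[key] = dcount.get(key, 0) + ddx
                                    dtot2[cellx] = dtot2.get(cellx, 0) + ddx
                                for (cellx, betax), ddx in dcount.items():
                                    if ddx:
                                        cv = counts[cellx][betax]
                                        dh -= e1 * (2 * cv * ddx + ddx * ddx)
                                for cellx, ddx in dtot2.items():
                                    if ddx:
                                        tv = totals[cellx]
                                        dh += eps * (2 * tv * ddx + ddx * ddx)
                        if dh <= 0 or (
                            rnd() < (math.exp(-dh / temperature) if dh < dh_cap else 0.0)
                        ):
                            if ops is None:
                                if m1:
                                    ae(fa1, mu1, -1)
                                    ae(a21, mu1, 1)
                                if m2:
                                    ae(fb1, nu1, -1)
                                    ae(b21, nu1, 1)
                                if m3:
                                    ae(fa2, mu2, -1)
                                    ae(a22, mu2, 1)
                                if m4:
                                    ae(fb2, nu2, -1)
                                    ae(b22, nu2, 1)
                            else:
                                for cellx, betax, ddx in ops:
                                    ae(cellx, betax, ddx)
                            state.move_synapse(p1, s2, o1)
                            state.move_synapse(p2, s1, o2)
                            state.H += dh
                            acc_swap += 1
                            if dh < 0:
                                n_strict += 1
                            if state.n_impure_cells == 0 and state.n_spread_types == 0:
                                converged = True
                    else:
                        move = MoveProposal("swap", p1, s2, o1, p2, s1, o2)
                        dh = delta_cost_move(state, move, cost_params)
                        if dh <= 0 or (
                            rnd() < (math.exp(-dh / temperature) if dh < dh_cap else 0.0)
                        ):
                            apply_move(state, move, dh)
                            acc_swap += 1
                            if dh < 0:
                                n_strict += 1
                            if state.n_impure_cells == 0 and state.n_spread_types == 0:
                                converged = True
                    if converged:
                        break
                    if dynamic and attempts % na == 0:
                        n_sweeps += 1
                        relocate_empty_synapses(state, rng)
                    if attempts % log_interval == 0:
                        traj.append((attempts, state.H))
                        if progress is not None:
                            progress(
                                attempts,
                                state.H,
                                (acc_jump + acc_swap + acc_flip) / attempts,
                            )
                    continue
                kind = 0  # swap impossible at this cell: re-draw as jump

            if kind == 2:
                # flip: toggle orientation in place
                p = int(rnd() * n_pairs)
                att_flip += 1
                d = pair_syn[p]
                a, b = syn_pre[d], syn_post[d]
                if pair_orient[p] == 0:
                    fa, fb, new_o = a, b, 1
                else:
                    fa, fb, new_o = b, a, 0
                a2, b2 = fb, fa
                mu, nu = pair_pre[p], pair_post[p]
            else:
                # jump: relocate a pair to another synapse of one of its cells
                p = int(rnd() * n_pairs)
                s = pair_syn[p]
                a, b = syn_pre[s], syn_post[s]
                if pair_orient[p] == 0:
                    fa, fb = a, b
                else:
                    fa, fb = b, a
                c = fa if int(rnd() * 2) == 0 else fb
                syns = cell_syns[c]
                nsyn_c = len(syns)
                if nsyn_c < 2:
                    att_null += 1
                    if dynamic and attempts % na == 0:
                        n_sweeps += 1
                        relocate_empty_synapses(state, rng)
                    if attempts % log_interval == 0:
                        traj.append((attempts, state.H))
                    continue
                while True:
                    d = syns[int(rnd() * nsyn_c)]
                    if d != s:
                        break
                new_o = int(rnd() * 2)
                att_jump += 1
                a2, b2 = syn_pre[d], syn_post[d]
                if new_o:
                    a2, b2 = b2, a2
                mu, nu = pair_pre[p], pair_post[p]

            # --- single-pair delta (gamma = 2 fast path) ---
            moved_a = fa != a2
            moved_b = fb != b2
            if exact:
                dh = 0
                if moved_a:
                    dh -= e1x2 * (counts[a2][mu] - counts[fa][mu] + 1)
                if moved_b:
                    dh -= e1x2 * (counts[b2][nu] - counts[fb][nu] + 1)
                if moved_a or moved_b:
                    dt: dict[int, int] = {}
                    if moved_a:
                        dt[fa] = dt.get(fa, 0) - 1
                        dt[a2] = dt.get(a2, 0) + 1
                    if moved_b:
                        dt[fb] = dt.get(fb, 0) - 1
                        dt[b2] = dt.get(b2, 0) + 1
                    for tc, td in dt.items():
                        if td:
                            dh += eps * (2 * totals[tc] * td + td * td)
            else:
                mv = MoveProposal("flip" if kind == 2 else "jump", p, d, new_o)
                dh = delta_cost_move(state, mv, cost_params)

            if dh <= 0 or (rnd() < (math.exp(-dh / temperature) if dh < dh_cap else 0.0)):
                if moved_a:
                    ae(fa, mu, -1)
                    ae(a2, mu, 1)
                if moved_b:
                    ae(fb, nu, -1)
                    ae(b2, nu, 1)
                state.move_synapse(p, d, new_o)
                state.H += dh
                if kind == 2:
                    acc_flip += 1
                else:
                    acc_jump += 1
                if dh < 0:
                    n_strict += 1
                if state.n_impure_cells == 0 and state.n_spread_types == 0:
                    converged = True
                    break
            if dynamic and attempts % na == 0:
                n_sweeps += 1
                relocate_empty_synapses(state, rng)
            if attempts % log_interval == 0:
                traj.append((attempts, state.H))
                if progress is not None:
                    progress(
                        attempts, state.H, (acc_jump + acc_swap + acc_flip) / attempts
                    )

        attempted.update(jump=att_jump, swap=att_swap, flip=att_flip, null=att_null)
        accepted.update(jump=acc_jump, swap=acc_swap, flip=acc_flip)

    traj.append((attempts, state.H))
    w, mapping, oboc = prune_and_read_out(state)
    return RunResult(
        converged=converged,
        n_steps_total=attempts,
        n_pairs=n_pairs,
        attempted=attempted,
        accepted=accepted,
        n_strict_decreasing=n_strict,
        h_init=h_init,
        h_final=state.H,
        h_trajectory=traj,
        max_attempts=max_attempts,
        n_relocation_sweeps=n_sweeps,
        oboc=oboc,
        w_recovered=w,
        mapping=mapping,
        state=state,
        seed=seed,
    )
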
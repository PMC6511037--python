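"""Barcode-placement state and the cost function driving its dynamics.

Every barcode pair ``(mu, nu)`` sits on exactly one synapse ``(a, b)`` of
the recipient (tabula rasa) network, with an orientation bit: forward means
``mu`` faces cell ``a`` and ``nu`` faces cell ``b``; reversed swaps the two.
The counts matrix ``c[n][beta]`` records how many barcode copies (endpoints,
not pairs) of type ``beta`` face cell ``n``.

The cost function, for exponent ``gamma`` and weight ``epsilon``::

    H = -(1 + eps) * sum_n sum_b c[n][b]**gamma + eps * sum_n (sum_b c[n][b])**gamma

With ``gamma = 2`` the first term rewards same-type barcodes congregating in
one cell, the second term penalizes different types sharing a cell; its
minima are exactly the one-barcode-one-cell (OBOC) arrangements.  With
``gamma = 2`` and integer ``epsilon`` all costs here are exact integers, so
Metropolis comparisons carry no floating-point ambiguity.

Cost changes for moves are always computed from the per-cell contributions
``H_n = -(1+eps) * sum_b c[n][b]^2 + eps * t_n^2`` of the (at most four)
affected cells.  The classical single-endpoint relocation formula

    dH(m -> n) = c[m][b] - c[n][b] - 1 + eps * sum_{a != b} (c[n][a] - c[m][a])

(:func:`relocation_delta`) is exposed separately: it equals exactly half the
true change of H and is used as an analytic oracle and in optimality
certificates, where only its sign matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .netgen import PairEnsemble

__all__ = [
    "CostParams",
    "SynapseSet",
    "MoveProposal",
    "CloneState",
    "InvalidMoveError",
    "compute_counts",
    "cost_from_counts",
    "cost_terms",
    "cost",
    "relocation_delta",
    "delta_cost_move",
    "apply_move",
    "save_state",
    "load_state",
]


class InvalidMoveError(ValueError):
    """A proposed move does not apply to the current state."""


@dataclass(frozen=True)
class CostParams:
    """Cost-function parameters.  gamma > 1 is required for the OBOC rule to
    be favoured; epsilon >= 1 is required by the optimality guarantees."""

    gamma: float = 2.0
    epsilon: float = 10.0

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")

    @property
    def exact(self) -> bool:
        """True when H is guaranteed to be an exact integer."""
        return self.gamma == 2 and float(self.epsilon).is_integer()


@dataclass
class SynapseSet:
    """Indexed set of directed synapses (ordered cell pairs, no self-loops)."""

    n_cells: int
    synapses: list[tuple[int, int]]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.synapses:
            if a == b:
                raise ValueError(f"self-synapse {a}->{b} not allowed")
            if not (0 <= a < self.n_cells and 0 <= b < self.n_cells):
                raise ValueError(f"synapse {a}->{b} out of range")
            if (a, b) in seen:
                raise ValueError(f"duplicate synapse {a}->{b}")
            seen.add((a, b))

    def __len__(self) -> int:
        return len(self.synapses)

    @classmethod
    def full(cls, n_cells: int) -> "SynapseSet":
        """Fully connected tabula rasa: all N(N-1) ordered pairs, both
        directions between every two cells."""
        syn = [(a, b) for a in range(n_cells) for b in range(n_cells) if a != b]
        return cls(n_cells=n_cells, synapses=syn)

    @classmethod
    def random_sparse(cls, n_cells: int, density: float, seed=None) -> "SynapseSet":
        """Sparse Erdős–Rényi tabula rasa with connection probability
        ``density`` per ordered pair (the dynamic-synapse variant)."""
        import numpy as np

        rng = np.random.default_rng(seed)
        mask = rng.random((n_cells, n_cells)) < density
        np.fill_diagonal(mask, False)
        src, tgt = np.nonzero(mask)
        return cls(n_cells=n_cells, synapses=list(zip(src.tolist(), tgt.tolist())))


@dataclass(frozen=True)
class MoveProposal:
    """One of the three local moves.

    ``flip``  — reinsert ``pair`` in its current synapse with the other
    orientation; ``jump`` — relocate ``pair`` to ``dest_syn`` (a synapse
    sharing a cell with its current one) with a fresh orientation; ``swap``
    — ``pair`` moves to ``dest_syn`` and ``pair2`` (currently on
    ``dest_syn``... strictly: on the synapse given by ``dest_syn2``'s
    counterpart) moves to ``dest_syn2``, both with fresh orientations.
    """

    kind: str
    pair: int
    dest_syn: int
    new_orient: int
    pair2: int | None = None
    dest_syn2: int | None = None
    new_orient2: int | None = None


class CloneState:
    """Mutable placement of a pair ensemble on a synapse set, with cached
    counts, per-cell totals, purity counters and cost H.

    The attributes below are plain lists/dicts on purpose: the Monte Carlo
    inner loop reads and writes them directly.
    """

    __slots__ = (
        "n_cells",
        "n_types",
        "params",
        "pair_pre",
        "pair_post",
        "pair_syn",
        "pair_orient",
        "pair_pos",
        "syn_pre",
        "syn_post",
        "syn_index",
        "syn_pairs",
        "cell_syns",
        "cell_syn_pos",
        "cell_occ",
        "cell_occ_pos",
        "counts",
        "totals",
        "H",
        "cell_ntypes",
        "type_ncells",
        "n_impure_cells",
        "n_spread_types",
    )

    def __init__(
        self,
        ensemble: PairEnsemble,
        synapses: SynapseSet,
        placement: Sequence[int],
        orientations: Sequence[int],
        params: CostParams | None = None,
    ) -> None:
        if len(synapses) == 0 and len(ensemble) > 0:
            raise ValueError("cannot place pairs on an empty synapse set")
        if len(placement) != len(ensemble) or len(orientations) != len(ensemble):
            raise ValueError("placement/orientations must match the ensemble size")
        self.params = params or CostParams()
        self.n_cells = synapses.n_cells
        self.n_types = ensemble.n_types
        self.pair_pre = [mu for mu, _ in ensemble.pairs]
        self.pair_post = [nu for _, nu in ensemble.pairs]
        self.pair_syn = list(placement)
        self.pair_orient = list(orientations)
        self.syn_pre = [a for a, _ in synapses.synapses]
        self.syn_post = [b for _, b in synapses.synapses]
        self.syn_index = {ab: i for i, ab in enumerate(synapses.synapses)}
        self.syn_pairs = [[] for _ in range(len(synapses))]
        self.pair_pos = [0] * len(ensemble)
        for p, s in enumerate(self.pair_syn):
            if not 0 <= s < len(self.syn_pre):
                raise ValueError(f"pair {p} placed on nonexistent synapse {s}")
            lst = self.syn_pairs[s]
            self.pair_pos[p] = len(lst)
            lst.append(p)
        n = self.n_cells
        self.cell_syns = [[] for _ in range(n)]
        self.cell_syn_pos = [dict() for _ in range(n)]
        for s, (a, b) in enumerate(zip(self.syn_pre, self.syn_post)):
            for c in (a, b):
                self.cell_syn_pos[c][s] = len(self.cell_syns[c])
                self.cell_syns[c].append(s)
        self.cell_occ = [[] for _ in range(n)]
        self.cell_occ_pos = [dict() for _ in range(n)]
        for s, plist in enumerate(self.syn_pairs):
            if plist:
                for c in (self.syn_pre[s], self.syn_post[s]):
                    self.cell_occ_pos[c][s] = len(self.cell_occ[c])
                    self.cell_occ[c].append(s)
        self._rebuild_counts()

    # ---------------------------------------------------------------- counts

    def facing_cells(self, pair: int) -> tuple[int, int]:
        """Cells faced by the pair's (pre_type, post_type) endpoints."""
        s = self.pair_syn[pair]
        a, b = self.syn_pre[s], self.syn_post[s]
        return (a, b) if self.pair_orient[pair] == 0 else (b, a)

    def _rebuild_counts(self) -> None:
        self.counts = compute_counts(self)
        self.totals = [sum(row) for row in self.counts]
        self.cell_ntypes = [sum(1 for v in row if v) for row in self.counts]
        tnc = [0] * self.n_types
        for row in self.counts:
            for beta, v in enumerate(row):
                if v:
                    tnc[beta] += 1
        self.type_ncells = tnc
        self.n_impure_cells = sum(1 for k in self.cell_ntypes if k > 1)
        self.n_spread_types = sum(1 for k in tnc if k > 1)
        self.H = cost_from_counts(self.counts, self.params)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_pre)

    def is_oboc(self) -> bool:
        """One-barcode-one-cell: every cell's facing endpoints are of a single
        type, and no type faces more than one cell."""
        return self.n_impure_cells == 0 and self.n_spread_types == 0

    def synapse_set(self) -> SynapseSet:
        return SynapseSet(self.n_cells, list(zip(self.syn_pre, self.syn_post)))

    def ensemble(self) -> PairEnsemble:
        return PairEnsemble(list(zip(self.pair_pre, self.pair_post)), self.n_types)

    # ------------------------------------------------------------- mutation

    def _endpoint_ops(self, move: MoveProposal) -> list[tuple[int, int, int]]:
        """(cell, type, +1/-1) endpoint changes implied by a move."""
        ops: list[tuple[int, int, int]] = []
        items = [(move.pair, move.dest_syn, move.new_orient)]
        if move.pair2 is not None:
            items.append((move.pair2, move.dest_syn2, move.new_orient2))
        for p, dest, orient in items:
            mu, nu = self.pair_pre[p], self.pair_post[p]
            fa, fb = self.facing_cells(p)
            a2, b2 = self.syn_pre[dest], self.syn_post[dest]
            if orient:
                a2, b2 = b2, a2
            if fa != a2:
                ops.append((fa, mu, -1))
                ops.append((a2, mu, 1))
            if fb != b2:
                ops.append((fb, nu, -1))
                ops.append((b2, nu, 1))
        return ops

    def _validate(self, move: MoveProposal) -> None:
        npairs, nsyn = len(self.pair_pre), len(self.syn_pre)
        if not 0 <= move.pair < npairs:
            raise InvalidMoveError(f"no such pair {move.pair}")
        if not 0 <= move.dest_syn < nsyn:
            raise InvalidMoveError(f"no such synapse {move.dest_syn}")
        if move.pair2 is not None and not (
            0 <= move.pair2 < npairs and 0 <= (move.dest_syn2 or 0) < nsyn
        ):
            raise InvalidMoveError("swap references absent pair or synapse")

    def move_synapse(self, pair: int, dest: int, orient: int) -> None:
        """Low-level relocation bookkeeping (no cost update)."""
        src = self.pair_syn[pair]
        if src != dest:
            lst = self.syn_pairs[src]
            pos = self.pair_pos[pair]
            last = lst[-1]
            lst[pos] = last
            self.pair_pos[last] = pos
            lst.pop()
            if not lst:  # synapse became empty
                for c in (self.syn_pre[src], self.syn_post[src]):
                    self._occ_remove(c, src)
            dlst = self.syn_pairs[dest]
            if not dlst:  # synapse becomes occupied
                for c in (self.syn_pre[dest], self.syn_post[dest]):
                    self._occ_add(c, dest)
            self.pair_pos[pair] = len(dlst)
            dlst.append(pair)
            self.pair_syn[pair] = dest
        self.pair_orient[pair] = orient

    def _occ_add(self, cell: int, syn: int) -> None:
        self.cell_occ_pos[cell][syn] = len(self.cell_occ[cell])
        self.cell_occ[cell].append(syn)

    def _occ_remove(self, cell: int, syn: int) -> None:
        pos = self.cell_occ_pos[cell].pop(syn)
        lst = self.cell_occ[cell]
        last = lst[-1]
        lst[pos] = last
        if last != syn:
            self.cell_occ_pos[cell][last] = pos
        lst.pop()

    def apply_endpoint(self, cell: int, beta: int, delta: int) -> None:
        """Update counts, totals and purity counters for one endpoint change."""
        row = self.counts[cell]
        old = row[beta]
        new = old + delta
        row[beta] = new
        self.totals[cell] += delta
        if old == 0 and new > 0:
            self.cell_ntypes[cell] += 1
            if self.cell_ntypes[cell] == 2:
                self.n_impure_cells += 1
            self.type_ncells[beta] += 1
            if self.type_ncells[beta] == 2:
                self.n_spread_types += 1
        elif old > 0 and new == 0:
            self.cell_ntypes[cell] -= 1
            if self.cell_ntypes[cell] == 1:
                self.n_impure_cells -= 1
            self.type_ncells[beta] -= 1
            if self.type_ncells[beta] == 1:
                self.n_spread_types -= 1


def compute_counts(state: CloneState) -> list[list[int]]:
    """Fresh counts matrix c[n][beta] from the placement alone: the number of
    pair endpoints of type beta facing cell n (pre- and postsynaptic facings
    both counted)."""
    counts = [[0] * state.n_types for _ in range(state.n_cells)]
    for p in range(len(state.pair_pre)):
        fa, fb = state.facing_cells(p)
        counts[fa][state.pair_pre[p]] += 1
        counts[fb][state.pair_post[p]] += 1
    return counts


def cost_terms(counts: Sequence[Sequence[int]], params: CostParams) -> tuple:
    """The two sums of the cost function, returned separately:
    ``term1 = -(1+eps) * sum c^gamma`` and ``term2 = eps * sum t^gamma``."""
    g = params.gamma
    eps = params.epsilon
    if params.exact:
        eps = int(eps)
        s1 = sum(v * v for row in counts for v in row)
        s2 = sum(sum(row) ** 2 for row in counts)
        return (-(1 + eps) * s1, eps * s2)
    s1 = sum(v**g for row in counts for v in row if v)
    s2 = sum(sum(row) ** g for row in counts if any(row))
    return (-(1 + eps) * s1, eps * s2)


def cost_from_counts(counts: Sequence[Sequence[int]], params: CostParams) -> int | float:
    t1, t2 = cost_terms(counts, params)
    return t1 + t2


def cost(state: CloneState, params: CostParams | None = None) -> int | float:
    """Full recomputation of H from the placement (the slow, oracle path)."""
    return cost_from_counts(compute_counts(state), params or state.params)


def relocation_delta(
    counts: Sequence[Sequence[int]],
    beta: int,
    from_cell: int,
    to_cell: int,
    params: CostParams,
) -> int | float:
    """Cost change for relocating one endpoint of type ``beta`` from cell
    ``m`` to cell ``n``, on the conventional half-H scale::

        dH = c[m][b] - c[n][b] - 1 + eps * sum_{a != b} (c[n][a] - c[m][a])

    Only valid for gamma = 2.  The true change of H equals exactly twice this
    value; the sign (all that optimality arguments use) is identical.  A null
    relocation (m == n) returns 0.
    """
    if params.gamma != 2:
        raise ValueError("the relocation formula is specific to gamma = 2")
    if counts[from_cell][beta] < 1:
        raise InvalidMoveError(f"cell {from_cell} holds no endpoint of type {beta}")
    if from_cell == to_cell:
        return 0
    eps = int(params.epsilon) if params.exact else params.epsilon
    cm, cn = counts[from_cell], counts[to_cell]
    tm, tn = sum(cm), sum(cn)
    return cm[beta] - cn[beta] - 1 + eps * ((tn - cn[beta]) - (tm - cm[beta]))


def delta_cost_move(state: CloneState, move: MoveProposal, params: CostParams | None = None):
    """Exact H change for a move, from the contributions of the affected
    cells only.  Integer for gamma = 2 with integer epsilon."""
    params = params or state.params
    state._validate(move)
    ops = state._endpoint_ops(move)
    if not ops:
        return 0 if params.exact else 0.0
    if params.gamma == 2:
        eps = int(params.epsilon) if params.exact else params.epsilon
        dcount: dict[tuple[int, int], int] = {}
        dtot: dict[int, int] = {}
        for cell, beta, d in ops:
            key = (cell, beta)
            dcount[key] = dcount.get(key, 0) + d
            dtot[cell] = dtot.get(cell, 0) + d
        dh = 0
        counts = state.counts
        for (cell, beta), d in dcount.items():
            if d:
                c = counts[cell][beta]
                dh -= (1 + eps) * (2 * c * d + d * d)
        totals = state.totals
        for cell, d in dtot.items():
            if d:
                t = totals[cell]
                dh += eps * (2 * t * d + d * d)
        return dh
    # general gamma: recompute the affected cells' contributions
    g = params.gamma
    eps = params.epsilon
    cells = sorted({cell for cell, _, _ in ops})
    before = after = 0.0
    newrows = {cell: list(state.counts[cell]) for cell in cells}
    for cell, beta, d in ops:
        newrows[cell][beta] += d
    for cell in cells:
        row, nrow = state.counts[cell], newrows[cell]
        before += -(1 + eps) * sum(v**g for v in row if v) + eps * sum(row) ** g
        after += -(1 + eps) * sum(v**g for v in nrow if v) + eps * sum(nrow) ** g
    return after - before


def apply_move(state: CloneState, move: MoveProposal, dh=None) -> None:
    """Apply a validated move atomically: placement, counts, totals, purity
    counters and cached H all stay consistent.  Raises
    :class:`InvalidMoveError` (state untouched) on a bad move."""
    state._validate(move)
    if dh is None:
        dh = delta_cost_move(state, move)
    for cell, beta, d in state._endpoint_ops(move):
        state.apply_endpoint(cell, beta, d)
    state.move_synapse(move.pair, move.dest_syn, move.new_orient)
    if move.pair2 is not None:
        state.move_synapse(move.pair2, move.dest_syn2, move.new_orient2)
    state.H += dh


# ------------------------------------------------------------- persistence


def save_state(state: CloneState, table_path: str | Path, sidecar_path: str | Path) -> None:
    """Snapshot: TSV placement table plus a JSON sidecar (H, parameters,
    synapse list) sufficient to restart."""
    with open(table_path, "w") as fh:
        fh.write("pair_id\tpre_type\tpost_type\tpre_cell\tpost_cell\torientation\n")
        for p in range(state.n_pairs):
            s = state.pair_syn[p]
            fh.write(
                f"{p}\t{state.pair_pre[p]}\t{state.pair_post[p]}\t"
                f"{state.syn_pre[s]}\t{state.syn_post[s]}\t{state.pair_orient[p]}\n"
            )
    sidecar = {
        "H": state.H,
        "gamma": state.params.gamma,
        "epsilon": state.params.epsilon,
        "n_cells": state.n_cells,
        "n_types": state.n_types,
        "synapses": [[a, b] for a, b in zip(state.syn_pre, state.syn_post)],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar))


def load_state(table_path: str | Path, sidecar_path: str | Path) -> CloneState:
    meta = json.loads(Path(sidecar_path).read_text())
    synapses = SynapseSet(meta["n_cells"], [tuple(ab) for ab in meta["synapses"]])
    syn_index = {ab: i for i, ab in enumerate(synapses.synapses)}
    pairs, placement, orientations = [], [], []
    lines = Path(table_path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        _, mu, nu, a, b, o = (int(x) for x in line.split("\t"))
        pairs.append((mu, nu))
        placement.append(syn_index[(a, b)])
        orientations.append(o)
    ensemble = PairEnsemble(pairs, meta["n_types"])
    params = CostParams(gamma=meta["gamma"], epsilon=meta["epsilon"])
    st = CloneState(ensemble, synapses, placement, orientations, params)
    if st.H != meta["H"] and abs(st.H - meta["H"]) > 1e-9:
        raise ValueError("snapshot inconsistent: recomputed H differs from stored H")
    return st
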
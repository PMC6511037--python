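"""Readout verification: OBOC detection, permutation recovery, overlap.

A converged state assigns every cell a unique barcode type; reading the
retained synapses through that assignment must reproduce the target
connectivity exactly, up to the permutation — ``W_B = M W_N M^T`` with M
the cell-to-type permutation matrix.  This module recovers and verifies
that mapping, provides the greedy dominant-barcode assignment used to
compare intermediate states against the target, and implements the
exhaustive search certifying that every non-OBOC state admits a
cost-decreasing single-endpoint relocation (the no-bad-local-minima
property that makes greedy/low-temperature dynamics sufficient).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .state import CloneState, CostParams, relocation_delta

__all__ = [
    "PermutationMapping",
    "Certificate",
    "is_oboc",
    "is_oboc_counts",
    "recover_mapping",
    "dominant_mapping",
    "mapped_matrix",
    "overlap_fraction",
    "downhill_relocation_certificate",
]


@dataclass(frozen=True)
class PermutationMapping:
    """Bijection cell index -> barcode-type index."""

    mapping: tuple[int, ...]  # mapping[cell] = type

    def __post_init__(self) -> None:
        if sorted(self.mapping) != list(range(len(self.mapping))):
            raise ValueError("mapping is not a permutation")

    def __getitem__(self, cell: int) -> int:
        return self.mapping[cell]

    def to_matrix(self) -> np.ndarray:
        """Permutation matrix M with M[type, cell] = 1 when the cell carries
        the type; satisfies M @ M.T = I."""
        n = len(self.mapping)
        m = np.zeros((n, n), dtype=np.int64)
        for cell, beta in enumerate(self.mapping):
            m[beta, cell] = 1
        return m


@dataclass(frozen=True)
class Certificate:
    """A strictly cost-decreasing single-endpoint relocation."""

    barcode_type: int
    from_cell: int
    to_cell: int
    delta: int | float  # on the half-H (relocation formula) scale


def is_oboc_counts(counts: Sequence[Sequence[int]]) -> bool:
    """OBOC at the counts level: every cell with facing endpoints hosts a
    single type, and no type faces more than one cell."""
    seen_types: set[int] = set()
    for row in counts:
        present = [beta for beta, v in enumerate(row) if v]
        if len(present) > 1:
            return False
        if present:
            beta = present[0]
            if beta in seen_types:
                return False
            seen_types.add(beta)
    return True


def is_oboc(state: CloneState) -> bool:
    return is_oboc_counts(state.counts)


def _complete_mapping(partial: dict[int, int], n_cells: int, n_types: int) -> tuple[int, ...]:
    """Extend a partial cell->type assignment to a bijection, matching
    leftover cells and types in index order."""
    used = set(partial.values())
    leftover_types = [b for b in range(n_types) if b not in used]
    out = []
    k = 0
    for cell in range(n_cells):
        if cell in partial:
            out.append(partial[cell])
        else:
            out.append(leftover_types[k])
            k += 1
    return tuple(out)


def recover_mapping(
    state: CloneState,
    target: np.ndarray | None = None,
) -> tuple[PermutationMapping, bool]:
    """Recover the cell->type permutation of an OBOC state and verify that
    the pruned recovered network reproduces the target exactly.

    ``target`` is the barcode connectivity W_B (``W[post, pre]``); when
    omitted it is reconstructed from the state's own pair ensemble.  Raises
    on a non-OBOC state — use :func:`dominant_mapping` there instead.
    """
    if not is_oboc(state):
        raise ValueError("state is not OBOC; use dominant_mapping for partial readout")
    from .mmc import prune_and_read_out

    w_n, mapping_dict, _ = prune_and_read_out(state)
    mapping = PermutationMapping(tuple(mapping_dict[c] for c in range(state.n_cells)))
    if target is None:
        target = state.ensemble().to_matrix()
    if target.shape != w_n.shape:
        raise ValueError("target and recovered matrices differ in size")
    verified = bool(np.array_equal(target, mapped_matrix(w_n, mapping)))
    return mapping, verified


def mapped_matrix(w_n: np.ndarray, mapping: PermutationMapping) -> np.ndarray:
    """Apply the cell->type permutation: (M W_N M^T)[type_b, type_a] =
    W_N[cell_b, cell_a]."""
    m = mapping.to_matrix()
    return m @ w_n @ m.T


def dominant_mapping(state: CloneState) -> dict[int, int]:
    """Greedy dominant-barcode assignment.

    All (cell, type) count entries are sorted by count descending (ties:
    lower cell index, then lower type index) and assigned greedily, skipping
    cells and types already taken; leftover cells and types are matched in
    index order.  On an OBOC state this reduces to the exact permutation.
    """
    entries = [
        (row[beta], cell, beta)
        for cell, row in enumerate(state.counts)
        for beta in range(state.n_types)
        if row[beta]
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    partial: dict[int, int] = {}
    used_types: set[int] = set()
    for _, cell, beta in entries:
        if cell in partial or beta in used_types:
            continue
        partial[cell] = beta
        used_types.add(beta)
    full = _complete_mapping(partial, state.n_cells, state.n_types)
    return {cell: beta for cell, beta in enumerate(full)}


def overlap_fraction(
    w_target: np.ndarray,
    w_recovered: np.ndarray,
    mapping: PermutationMapping | dict[int, int] | Sequence[int],
) -> float:
    """Fraction of target edges present in the mapped recovered network;
    1.0 iff the copy is perfect under the mapping."""
    if w_target.shape != w_recovered.shape:
        raise ValueError("matrices differ in size")
    if isinstance(mapping, dict):
        mapping = PermutationMapping(tuple(mapping[c] for c in range(len(mapping))))
    elif not isinstance(mapping, PermutationMapping):
        mapping = PermutationMapping(tuple(mapping))
    n_target = int(w_target.sum())
    if n_target == 0:
        return 1.0
    mapped = mapped_matrix(w_recovered, mapping)
    both = int(((w_target > 0) & (mapped > 0)).sum())
    return both / n_target


def downhill_relocation_certificate(
    state_or_counts: CloneState | Sequence[Sequence[int]],
    cost_params: CostParams | None = None,
) -> Certificate | None:
    """Exhaustively search single-endpoint relocations for one with a
    strictly negative cost change (gamma = 2, epsilon >= 1).

    Returns the first such relocation in (type, source cell, destination
    cell) order, or None — in which case the state must be OBOC.
    """
    params = cost_params or CostParams()
    if params.gamma != 2:
        raise ValueError("certificates are defined for gamma = 2")
    counts = (
        state_or_counts.counts
        if isinstance(state_or_counts, CloneState)
        else [list(r) for r in state_or_counts]
    )
    n_cells = len(counts)
    n_types = len(counts[0]) if counts else 0
    for beta in range(n_types):
        for m in range(n_cells):
            if counts[m][beta] < 1:
                continue
            for n in range(n_cells):
                if n == m:
                    continue
                dh = relocation_delta(counts, beta, m, n, params)
                if dh < 0:
                    return Certificate(beta, m, n, dh)
    return None
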
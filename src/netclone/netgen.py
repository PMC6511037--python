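"""Target networks, barcode libraries, and the barcode-pair representation.

A directed network over N neurons can be written down as a multiset of
barcode pairs: each neuron carries a unique nucleotide barcode, and every
directed synapse ``source -> target`` is represented by one record
``pre-barcode ++ spacer ++ post-barcode``.  This module generates target
networks (Erdős–Rényi or Barabási–Albert), builds barcode libraries, and
converts between the network, the pair ensemble, and FASTA pair reads.

Matrix convention used throughout the package: ``W[target][source] = 1``
for a connection ``source -> target``; indices are 0-based; self-loops are
excluded everywhere, so a network over N cells has N(N-1) possible edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TargetNetwork",
    "BarcodeLibrary",
    "PairEnsemble",
    "DecodeError",
    "generate_er",
    "generate_ba",
    "make_barcode_library",
    "network_to_pairs",
    "pairs_to_matrix",
    "encode_pairs",
    "decode_pairs",
    "write_fasta",
    "read_fasta",
    "write_edge_list",
    "read_edge_list",
    "write_barcode_library",
    "read_barcode_library",
]

_ALPHABET = "ACGT"
DEFAULT_BARCODE_LENGTH = 20
DEFAULT_SPACER = "AACCGGTT"


class DecodeError(ValueError):
    """A barcode-pair record could not be decoded against the library."""


@dataclass(frozen=True)
class TargetNetwork:
    """Directed binary connectivity over ``n_cells`` neurons, no self-loops."""

    n_cells: int
    edges: frozenset[tuple[int, int]]  # (source, target)
    density: float

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("a network needs at least 2 cells")
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-loop {s}->{t} not allowed")
            if not (0 <= s < self.n_cells and 0 <= t < self.n_cells):
                raise ValueError(f"edge {s}->{t} out of range")

    @classmethod
    def from_edges(cls, n_cells: int, edges: Iterable[tuple[int, int]]) -> "TargetNetwork":
        es = frozenset((int(s), int(t)) for s, t in edges)
        dens = len(es) / (n_cells * (n_cells - 1))
        return cls(n_cells=n_cells, edges=es, density=dens)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def matrix(self) -> np.ndarray:
        """Adjacency matrix W with W[target, source] = 1."""
        w = np.zeros((self.n_cells, self.n_cells), dtype=np.int64)
        for s, t in self.edges:
            w[t, s] = 1
        return w


@dataclass(frozen=True)
class BarcodeLibrary:
    """Bijection between barcode-type indices and unique nucleotide strings."""

    sequences: tuple[str, ...]
    spacer: str

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("barcode sequences must be distinct")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all barcodes must have the same length")

    @property
    def n_types(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def index_of(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sequences)}


@dataclass
class PairEnsemble:
    """Multiset of (pre_type, post_type) barcode pairs, one per directed edge."""

    pairs: list[tuple[int, int]]
    n_types: int
    decode_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mu, nu in self.pairs:
            if mu == nu:
                raise ValueError(f"degenerate pair ({mu},{nu}): targets have no self-loops")
            if not (0 <= mu < self.n_types and 0 <= nu < self.n_types):
                raise ValueError(f"pair ({mu},{nu}) outside type range")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_matrix(self) -> np.ndarray:
        """Summing pairs as a matrix: W[post, pre] += 1 per pair."""
        return pairs_to_matrix(self.pairs, self.n_types)


def pairs_to_matrix(pairs: Sequence[tuple[int, int]], n_types: int) -> np.ndarray:
    w = np.zeros((n_types, n_types), dtype=np.int64)
    for mu, nu in pairs:
        w[nu, mu] += 1
    return w


def generate_er(n_cells: int, density: float, seed: int | None = None) -> TargetNetwork:
    """Directed Erdős–Rényi G(N, f): each ordered pair (i, j), i != j, is an
    edge independently with probability ``density``."""
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_cells, n_cells)) < density
    np.fill_diagonal(mask, False)
    src, tgt = np.nonzero(mask)
    return TargetNetwork.from_edges(n_cells, zip(src.tolist(), tgt.tolist()))


def generate_ba(n_cells: int, attach_m: int, seed: int | None = None) -> TargetNetwork:
    """Barabási–Albert preferential attachment, then a fair coin flip per
    undirected edge to pick its direction."""
    if not 1 <= attach_m < n_cells:
        raise ValueError("attach_m must satisfy 1 <= attach_m < n_cells")
    ss = np.random.SeedSequence(seed)
    nx_seed, flip_seed = (int(s) for s in ss.generate_state(2) >> 1)
    g = nx.barabasi_albert_graph(n_cells, attach_m, seed=nx_seed)
    flips = np.random.default_rng(flip_seed).integers(0, 2, size=g.number_of_edges())
    edges = []
    for (u, v), flip in zip(sorted(g.edges()), flips):
        edges.append((u, v) if flip == 0 else (v, u))
    return TargetNetwork.from_edges(n_cells, edges)


def _spacer_safe(barcode: str, spacer: str) -> bool:
    # Spacer must appear exactly once in any pre+spacer / spacer+post context,
    # so splitting a read at the spacer is unambiguous without alignment.
    return (barcode + spacer).find(spacer) == len(barcode) and (spacer + barcode).find(spacer, 1) == -1


def make_barcode_library(
    n_types: int,
    length: int = DEFAULT_BARCODE_LENGTH,
    spacer: str = DEFAULT_SPACER,
    seed: int | None = None,
) -> BarcodeLibrary:
    """Draw ``n_types`` distinct uniform-random barcodes of ``length`` nt.

    Barcodes are rejected if the spacer could occur anywhere except at the
    designed position of an encoded read (inside a barcode or straddling a
    barcode–spacer junction).
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if length < 1 or 4**length < n_types:
        raise ValueError(f"4^{length} sequences cannot hold {n_types} distinct barcodes")
    if set(spacer) - set(_ALPHABET):
        raise ValueError("spacer must be a nucleotide string over ACGT")
    if (spacer + spacer).find(spacer, 1) != len(spacer):
        raise ValueError("spacer overlaps itself; splitting would be ambiguous")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    seqs: list[str] = []
    attempts = 0
    cap = 1000 * n_types + 1000
    while len(seqs) < n_types:
        attempts += 1
        if attempts > cap:
            raise ValueError("could not draw enough spacer-safe distinct barcodes; increase length")
        bc = "".join(_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if bc in seen or not _spacer_safe(bc, spacer):
            continue
        seen.add(bc)
        seqs.append(bc)
    return BarcodeLibrary(sequences=tuple(seqs), spacer=spacer)


def network_to_pairs(net: TargetNetwork) -> PairEnsemble:
    """One (pre_type, post_type) pair per directed edge; barcode-type index
    equals the cell index of the original network."""
    pairs = sorted(net.edges)
    return PairEnsemble(pairs=list(pairs), n_types=net.n_cells)


def encode_pairs(ensemble: PairEnsemble, lib: BarcodeLibrary) -> list[SeqRecord]:
    """FASTA records ``pre-barcode ++ spacer ++ post-barcode``, one per pair.

    Record ids carry only a serial number — the readout side never sees cell
    identities.
    """
    for mu, nu in ensemble.pairs:
        if mu >= lib.n_types or nu >= lib.n_types:
            raise ValueError(f"pair ({mu},{nu}) exceeds library size {lib.n_types}")
    records = []
    for k, (mu, nu) in enumerate(ensemble.pairs):
        seq = lib.sequences[mu] + lib.spacer + lib.sequences[nu]
        records.append(SeqRecord(Seq(seq), id=f"pair{k:06d}", description=""))
    return records


def decode_pairs(
    records: Iterable[SeqRecord],
    lib: BarcodeLibrary,
    strict: bool = True,
) -> PairEnsemble:
    """Split each read at the spacer and match both flanks exactly.

    In strict mode any malformed record raises :class:`DecodeError` naming the
    record; in lenient mode bad records are skipped and reported in
    ``PairEnsemble.decode_errors``.
    """
    index = lib.index_of()
    L, S = lib.length, len(lib.spacer)
    pairs: list[tuple[int, int]] = []
    errors: list[str] = []
    for rec in records:
        seq = str(rec.seq)
        problem = None
        if len(seq) != 2 * L + S:
            problem = f"length {len(seq)} != {2 * L + S}"
        elif seq[L : L + S] != lib.spacer:
            problem = "spacer not found at expected position"
        else:
            pre, post = seq[:L], seq[L + S :]
            if pre not in index:
                problem = f"unknown pre-barcode {pre!r}"
            elif post not in index:
                problem = f"unknown post-barcode {post!r}"
            else:
                pairs.append((index[pre], index[post]))
        if problem is not None:
            msg = f"record {rec.id}: {problem}"
            if strict:
                raise DecodeError(msg)
            errors.append(msg)
    return PairEnsemble(pairs=pairs, n_types=lib.n_types, decode_errors=errors)


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    # unwrapped sequences, one line per record
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_edge_list(net: TargetNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for s, t in sorted(net.edges):
            fh.write(f"{s}\t{t}\n")


def read_edge_list(path: str | Path, n_cells: int | None = None) -> TargetNetwork:
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        s, t = line.split("\t")
        edges.append((int(s), int(t)))
    if n_cells is None:
        n_cells = max((max(s, t) for s, t in edges), default=1) + 1
    return TargetNetwork.from_edges(n_cells, edges)


def write_barcode_library(lib: BarcodeLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spacer\t{lib.spacer}\n")
        fh.write("# type_id\tsequence\n")
        for i, s in enumerate(lib.sequences):
            fh.write(f"{i}\t{s}\n")


def read_barcode_library(path: str | Path) -> BarcodeLibrary:
    spacer = None
    seqs: list[tuple[int, str]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# spacer\t"):
            spacer = line.split("\t")[1].strip()
        elif line.startswith("#") or not line.strip():
            continue
        else:
            i, s = line.split("\t")
            seqs.append((int(i), s.strip()))
    if spacer is None:
        raise ValueError("library file lacks a '# spacer' header line")
    seqs.sort()
    return BarcodeLibrary(sequences=tuple(s for _, s in seqs), spacer=spacer)
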
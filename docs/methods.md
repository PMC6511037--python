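# Methods

## Model

A target network is a directed binary graph over N cells with no
self-connections: `W_B[target, source] ∈ {0,1}`, density
`f = |edges| / (N(N−1))`.  Its barcode representation assigns each cell a
unique barcode type and lists one `(pre_type, post_type)` pair per edge;
summing the pairs as a matrix reproduces `W_B` exactly, and the number of
pairs P equals the number of nonzero entries.

The recipient (tabula rasa) network has the same N cells and either all
N(N−1) directed synapses (static variant) or a sparse random subset
(dynamic variant).  A *placement* puts every pair on one synapse with an
orientation bit; the pair's pre-type endpoint *faces* one cell of the
synapse and its post-type endpoint the other.  The counts matrix
`c[n][β]` is the number of endpoints of type β facing cell n
(`Σ c = 2P` always).  The cost is

```
H = -(1+ε) Σ_n Σ_β c_nβ^γ + ε Σ_n t_n^γ,     t_n = Σ_β c_nβ
```

with defaults γ = 2, ε = 10.  γ must exceed 1 for concentration of
same-type copies to be favoured; ε ≥ 1 is required by the optimality
guarantees below.  With γ = 2 and integer ε, H and every ΔH are exact
integers; all bookkeeping and Metropolis comparisons are done in integer
arithmetic, so there are no floating-point ties.

A state is **OBOC** (one-barcode-one-cell) when (a) all endpoints facing
any one cell are of a single type and (b) no type faces more than one
cell.  Requirement (b) is part of the terminator because purely local
purity admits "split-type" states (one type pure in two cells); those are
never cost minima — a downhill relocation always exists — but a
terminator without (b) could stop on one and break the permutation
readout.  With N barcode types on N cells, (a) + (b) make the cell→type
map a bijection.

## Moves and dynamics

Three local moves, attempted with probabilities `(1−f, f−1/N, 1/N)`
(realized pair density f):

- **jump** — pick a uniform random pair, one of its two facing cells,
  and a uniform random other synapse of that cell; reinsert with a fresh
  random orientation;
- **swap** — pick a uniform random cell, two of its occupied synapses,
  one random pair from each; exchange synapses, fresh orientations.  If
  the chosen cell lacks two occupied synapses the attempt is re-drawn as
  a jump (still one attempt);
- **flip** — toggle a random pair's orientation bit in place.  (An
  orientation toggle on slot (a,b) and a relocation to the antiparallel
  slot (b,a) are the same state in facing terms; the in-place toggle is
  used because it remains well-defined on sparse recipient networks where
  the antiparallel slot may not exist.)

When f < 1/N the swap probability clamps to zero and the triple is
renormalized.  Acceptance follows Metropolis at T = 1e-4: ΔH ≤ 0 always
accepted (including ΔH = 0, enabling free lateral diffusion), uphill with
probability `exp(−ΔH/T)` — at this temperature effectively never, so the
dynamics is greedy-with-plateaus.  ΔH is computed incrementally from the
per-cell contributions `H_n = −(1+ε)Σ_β c_nβ² + ε t_n²` of the at most
four affected cells (O(1) per attempt); for γ ≠ 2 the affected cells'
contributions are recomputed with real exponents instead (no optimized
path — general γ is supported for exploration only).

`N_steps` counts *attempts*: every proposal, including re-drawn swaps and
the rare null proposals (no legal destination, possible only on sparse
recipients).  OBOC is detected in O(1) after every accepted move via
incrementally maintained counters (number of impure cells, number of
spread types), so termination is exact, not interval-sampled.  Runs are
capped at `100 × f^1.5 N^3.5` attempts and flagged (not raised) if
unconverged; in practice all study-condition runs converge at
~5–30× `f^1.5 N^3.5` (the proportionality constant depends on
move-accounting conventions; only the exponents are meaningful).

### Single-endpoint relocation formula

For γ = 2, relocating one endpoint of type β from cell m to cell n
changes the cost by

```
ΔH(m→n) = c_mβ − c_nβ − 1 + ε Σ_{α≠β} (c_nα − c_mα)
```

on the conventional half-scale: the exact change of H is **twice** this
value (verified algebraically and, in the tests, against full
recomputation).  The sign — all that optimality arguments use — is
unaffected.  Two identities follow and are tested exhaustively: when two
cells share a type, the forward and reverse relocations sum to exactly
−2, so one is downhill; and when every type is confined to one cell, one
cell is crowded and one is empty, moving the least-abundant type to the
empty cell costs ≤ −1.  Together they imply no non-OBOC minima for ε ≥ 1
(`downhill_relocation_certificate` finds a strictly downhill relocation for every
non-OBOC state, checked by exhaustive enumeration of all reachable count
matrices of 4-cell/5-pair systems).

### Readout

At termination, synapses holding no pairs are pruned.  The recovered edge
for a resident pair runs from the cell its pre-type endpoint faces to the
cell its post-type endpoint faces — equivalently, the orientation bit and
the synapse slot jointly encode *which directed synapse* the pair
occupies, and the readout is slot-independent.  At OBOC each cell has a
unique facing type; the resulting permutation M is applied and
`W_B = M W_N Mᵀ` is checked entrywise (isolated cells and unused types,
possible in sparse targets, are matched in index order and carry empty
rows/columns).  For non-OBOC states a greedy dominant-barcode assignment
is used instead: (count, cell, type) entries sorted by count descending
(ties broken by lower cell, then type index — the tie-break is a
reproducibility choice), assigned greedily, leftovers matched in index
order; it coincides with the exact permutation at OBOC.

## Dynamic synapses

The developmental variant starts from a sparse Erdős–Rényi tabula rasa of
density `f_TR = f + 0.3(1−f)` — a 30% excess of synapses over the clone's
needs — and, every `Na` attempts, tears down all barcode-free synapses
and rebuilds each between a uniformly chosen currently-unconnected
ordered cell pair (synapse count conserved; occupied synapses untouched;
if no vacancy exists, as on a full network, the sweep is a no-op).
`Na = ⌈f^1.5 N^3.5 / 100⌉` so a typical run experiences ~100 turnover
sweeps without a calibration pre-run.  Move-kind probabilities use the
pair density f, not `f_TR`, since they are motivated by pair occupancy.

## Engines

Two implementations of the same dynamics:

- a pure-Python reference loop, bit-reproducible against the public
  `propose_move` / `metropolis_step` API (the test suite replays whole
  runs through both paths and requires identical attempt counts,
  acceptance counts and final H);
- a numba-compiled kernel (`engine="auto"` selects it for static full
  recipients with γ = 2, integer ε), ~15× faster, used for the scaling
  grids.  It draws from its own seeded Mersenne-Twister stream, so
  individual trajectories differ from the Python engine while all exact
  invariants coincide; every kernel run is integrity-checked by
  rebuilding the final placement in Python and recomputing H, and the
  engines' mean convergence times are compared in the tests.

Seeding: one master seed; each grid run derives an independent substream
seed as `crc32(topology|N|f|replicate) XOR master` (< 2³¹), so grids are
reproducible row-by-row and insensitive to execution order.

## Synthetic data

All inputs are generated: directed ER targets (each ordered pair an edge
with probability f) and BA targets (undirected preferential attachment,
each edge then oriented by a fair coin flip — preserving the edge count
the growth rule implies).  Barcode libraries draw distinct uniform random
20-nt sequences; the fixed 8-nt spacer (`AACCGGTT`) is validated at build
time to occur exactly once in every possible read (not inside any barcode
nor straddling a junction), so decoding is exact string splitting with no
alignment.  There is deliberately no sequencing-error, PCR or chimera
model: decoding failures exercised in the tests are structural
(truncation, unknown barcode), and passing tests say nothing about
error-tolerant decoding of real sequencing reads.  Likewise the ER/BA
targets probe topology only; real connectomes' degree correlations,
weights and multi-synapses are out of scope (binary edges, one pair per
synapse).

## Study conditions and problem sizes

Defaults throughout are the study conditions: γ = 2, ε = 10, T = 1e-4,
move probabilities `(1−f, f−1/N, 1/N)`, ~100 turnover sweeps in dynamic
mode.  The scaling analysis uses desk-scale grids chosen as an
exponential-spacing miniature of the full design: N ∈ {10, 16, 25, 40,
63, 100} at f = 0.2 and f ∈ {0.05, 0.1, 0.2, 0.4, 0.8} at N = 60, five
seeds per cell; exponents come from OLS on log N_steps (joint regression
when both predictors vary, ≥ 3 levels per fitted predictor, converged
runs only, standard errors reported).  On these grids the fitted
exponents land within ~0.1 of 3.5 and 1.5.  Small grids bias the size
exponent slightly upward (finite-size transients at N ≈ 10 and the mild
f-dependence of the proportionality constant); extending either axis
tightens the fit.

## Known limitations

- The cost constant in `N_steps ≈ c·f^1.5 N^3.5` is implementation- and
  convention-dependent (here c ≈ 5–30); compare exponents, not constants.
- B = N is assumed (as many barcode types as cells); unequal counts are
  not modelled.
- No annealing schedule and no parallel pair updates: the per-pair
  attempt count `n_steps = N_steps / P` quantifies the parallelism
  argument but the simulation itself is sequential.
- General γ ≠ 2 runs lack the incremental-ΔH fast path, the optimality
  guarantees, and the compiled engine.
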
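"""Convergence-scaling experiments and power-law fits.

The number of move attempts to reach OBOC grows as ``N_steps ~ f^1.5 *
N^3.5`` with network size N and connection density f; per barcode pair
(pairs can in principle move in parallel) this is ``n_steps = N_steps / P
~ f^0.5 * N^1.5``.  This module runs seeded grids of cloning simulations
over ER or BA targets and fits the exponents by ordinary least squares in
log-log space, attaching standard errors.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mmc import (
    DYNAMIC_SPARSE,
    DynamicsParams,
    MCParams,
    RunResult,
    run,
)
from .netgen import TargetNetwork, generate_ba, generate_er, network_to_pairs
from .state import CostParams, SynapseSet
from .verify import dominant_mapping, overlap_fraction, recover_mapping

__all__ = [
    "CloneOutcome",
    "PowerLawFit",
    "clone_network",
    "derive_seed",
    "run_scaling_experiment",
    "fit_power_law",
    "write_scaling_table",
    "read_scaling_table",
]

SCALING_COLUMNS = ["topology", "N", "f", "seed", "n_steps", "converged"]


@dataclass
class CloneOutcome:
    """A full clone of one target: run record, readout and verification."""

    result: RunResult
    mapping: dict[int, int]
    verified: bool  # exact entrywise W_B = M W_N M^T under the mapping
    overlap: float  # fraction of target edges reproduced under the mapping


def derive_seed(master: int, *parts) -> int:
    """Stable per-run substream seed: CRC32 of the run descriptor folded
    with the master seed (always < 2^31)."""
    tag = "|".join(str(p) for p in parts).encode()
    return (zlib.crc32(tag) ^ (master & 0xFFFFFFFF)) & 0x7FFFFFFF


def clone_network(
    net: TargetNetwork,
    cost_params: CostParams | None = None,
    mc: MCParams | None = None,
    dyn: DynamicsParams | None = None,
    seed: int | None = None,
) -> CloneOutcome:
    """Encode a target as barcode pairs, run the Monte Carlo dynamics on a
    tabula rasa network, prune, and verify the recovered connectivity."""
    dyn = dyn or DynamicsParams()
    ensemble = network_to_pairs(net)
    n = net.n_cells
    if dyn.mode == DYNAMIC_SPARSE:
        f_real = len(ensemble) / (n * (n - 1))
        f_tr = dyn.f_tr if dyn.f_tr is not None else DynamicsParams.tabula_rasa_density(f_real)
        tr_seed = derive_seed(seed or 0, "tabula_rasa")
        synapses = SynapseSet.random_sparse(n, f_tr, tr_seed)
        if len(synapses) == 0:
            synapses = SynapseSet.full(n)
    else:
        synapses = SynapseSet.full(n)
    result = run(ensemble, synapses, cost_params, mc, dyn, seed=seed)
    target = net.matrix()
    if result.oboc:
        mapping_obj, verified = recover_mapping(result.state, target)
        mapping = {c: mapping_obj[c] for c in range(n)}
    else:
        mapping = dominant_mapping(result.state)
        verified = False
    overlap = overlap_fraction(target, result.w_recovered, mapping)
    return CloneOutcome(result=result, mapping=mapping, verified=verified, overlap=overlap)


def run_scaling_experiment(
    topology: str,
    sizes: Sequence[int],
    densities: Sequence[float],
    replicates: int = 5,
    cost_params: CostParams | None = None,
    mc: MCParams | None = None,
    dyn: DynamicsParams | None = None,
    master_seed: int = 0,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run one cloning simulation per (size, density, replicate) grid cell.

    ``topology`` is "er" (densities are edge probabilities f) or "ba"
    (densities are integer attachment counts m; the realized density is
    recorded).  Every run gets an independent seed derived from
    ``master_seed`` and its grid coordinates.  Returns a table with one row
    per run; unconverged runs are flagged, not raised.
    """
    if topology not in ("er", "ba"):
        raise ValueError("topology must be 'er' or 'ba'")
    if not sizes or not densities or replicates < 1:
        raise ValueError("grid must be non-empty")
    rows = []
    for n in sizes:
        for dens in densities:
            for rep in range(replicates):
                seed = derive_seed(master_seed, topology, n, dens, rep)
                if topology == "er":
                    net = generate_er(n, float(dens), derive_seed(seed, "net"))
                else:
                    net = generate_ba(n, int(dens), derive_seed(seed, "net"))
                outcome = clone_network(net, cost_params, mc, dyn, seed=seed)
                res = outcome.result
                rows.append(
                    {
                        "topology": topology,
                        "N": n,
                        "f": net.density,
                        "seed": seed,
                        "n_steps": res.n_steps_total,
                        "converged": res.converged,
                        "n_pairs": res.n_pairs,
                        "n_strict_decreasing": res.n_strict_decreasing,
                        "h_init": res.h_init,
                        "h_final": res.h_final,
                        "max_attempts": res.max_attempts,
                        "verified": outcome.verified,
                        "overlap": outcome.overlap,
                    }
                )
                if progress is not None:
                    progress(
                        f"{topology} N={n} f={net.density:.4f} rep={rep} "
                        f"seed={seed} n_steps={res.n_steps_total} "
                        f"converged={res.converged}"
                    )
    return pd.DataFrame(rows)


@dataclass
class PowerLawFit:
    """OLS fit of log n_steps on log N and/or log f."""

    p_n: float
    se_n: float
    p_f: float
    se_f: float
    n_rows: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "p_N": self.p_n,
                "se_N": self.se_n,
                "p_f": self.p_f,
                "se_f": self.se_f,
                "n_rows": self.n_rows,
            }
        )


def fit_power_law(table: pd.DataFrame, min_levels: int = 3) -> PowerLawFit:
    """Fit convergence exponents by linear regression in log-log space.

    Only converged rows with positive n_steps and f enter the fit.  A
    predictor (N or f) is fitted only where it takes at least
    ``min_levels`` distinct values; when both vary, a joint regression is
    used.  Raises on a fully degenerate design.
    """
    df = table[(table["converged"]) & (table["n_steps"] > 0) & (table["f"] > 0)]
    if df.empty:
        raise ValueError("no converged rows to fit")
    log_steps = np.log(df["n_steps"].to_numpy(dtype=float))
    log_n = np.log(df["N"].to_numpy(dtype=float))
    log_f = np.log(df["f"].to_numpy(dtype=float))
    fit_n = len(np.unique(log_n)) >= min_levels
    fit_f = len(np.unique(log_f)) >= min_levels
    if not fit_n and not fit_f:
        raise ValueError(
            f"need at least {min_levels} distinct levels of N or f to fit exponents"
        )
    cols = []
    if fit_n:
        cols.append(log_n)
    if fit_f:
        cols.append(log_f)
    x = sm.add_constant(np.column_stack(cols))
    ols = sm.OLS(log_steps, x).fit()
    params = list(ols.params[1:])
    errors = list(ols.bse[1:])
    p_n = se_n = p_f = se_f = math.nan
    if fit_n:
        p_n, se_n = params.pop(0), errors.pop(0)
    if fit_f:
        p_f, se_f = params.pop(0), errors.pop(0)
    return PowerLawFit(p_n=p_n, se_n=se_n, p_f=p_f, se_f=se_f, n_rows=len(df))


def write_scaling_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SCALING_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scaling_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
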
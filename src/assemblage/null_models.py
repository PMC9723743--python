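"""Randomisation procedures that nullify host selection (swap) or all
selection (lottery).

Lottery
-------
Each culture's observed OTUs are replaced by a weighted draw without
replacement from the station's candidate pool (OTUs present in the local
source community AND seen in at least one culture anywhere), with selection
probability proportional to source abundance.  The culture's observed
abundance multiset is reassigned to the drawn OTUs in draw order, so
per-sample richness, total reads and Shannon diversity are preserved
exactly.

Swap (quasiswap)
----------------
Within each station block of the culture matrix: (1) draw an independent
random count matrix with the observed row and column totals (Patefield
algorithm); (2) apply unit transfers along the diagonals of random 2x2
submatrices, accepting only moves that keep all entries non-negative and do
not move the number of zero cells away from the observed fill, until the
fill matches; (3) mix further with fill-preserving transfers for
``n_sweeps * (non-zero entries)`` trials.  Row totals, column totals and
matrix fill are therefore preserved exactly, while the zero/non-zero
pattern is randomised rather than locally perturbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core_data import CountTable, SampleFrame

__all__ = [
    "RandomisedDataset",
    "LotteryError",
    "lottery_randomise",
    "quasiswap_randomise",
    "make_ensemble",
    "replicate_seed",
    "station_pools",
]

LOTTERY = "lottery"
SWAP = "swap"


class LotteryError(ValueError):
    """Raised when a culture cannot be lottery-randomised (pool too small
    or culture empty); no silent fallback."""


@dataclass(frozen=True)
class RandomisedDataset:
    table: CountTable
    procedure: str
    seed: int
    replicate_index: int = 0


# ----------------------------------------------------------------------------
# Lottery procedure
# ----------------------------------------------------------------------------

def station_pools(
    cultures: CountTable, sources: CountTable, frame: SampleFrame
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-station candidate pool: indices (into ``cultures.otu_ids``) of
    OTUs present in the station's source sample and observed in at least one
    culture anywhere, with their source abundances as weights."""
    culture_ids = [s for s in cultures.sample_ids]
    ever_in_culture = cultures.counts.sum(axis=0) > 0
    src_pos = {o: j for j, o in enumerate(sources.otu_ids)}
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for culture in culture_ids:
        station = frame.station_of(culture)
        if station in pools:
            continue
        source_id = frame.source_of(culture)
        src_row = sources.row(source_id)
        weights = np.zeros(cultures.n_otus, dtype=float)
        for j, otu in enumerate(cultures.otu_ids):
            sj = src_pos.get(otu)
            if sj is not None:
                weights[j] = src_row[sj]
        mask = (weights > 0) & ever_in_culture
        pools[station] = (np.flatnonzero(mask), weights[mask])
    return pools


def _weighted_draw_order(idx: np.ndarray, weights: np.ndarray, k: int,
                         rng: np.random.Generator) -> np.ndarray:
    # Exponential race: arrival time ~ Exp(rate w_i); the k earliest arrivals
    # in order are exactly a sequential weighted draw without replacement.
    times = rng.exponential(scale=1.0, size=len(weights)) / weights
    order = np.argsort(times, kind="stable")
    return idx[order[:k]]


def lottery_randomise(
    cultures: CountTable,
    sources: CountTable,
    frame: SampleFrame,
    seed: int,
    replicate_index: int = 0,
    _pools: dict | None = None,
) -> RandomisedDataset:
    """Reassemble every culture from its station's source community by
    abundance-proportional sampling without replacement."""
    rng = np.random.default_rng(seed)
    pools = _pools if _pools is not None else station_pools(cultures, sources, frame)
    out = np.zeros_like(cultures.counts)
    for i, culture in enumerate(cultures.sample_ids):
        row = cultures.counts[i]
        abundances = np.sort(row[row > 0])[::-1]
        k = len(abundances)
        if k == 0:
            raise LotteryError(f"culture {culture!r} has zero reads")
        idx, weights = pools[frame.station_of(culture)]
        if len(idx) < k:
            raise LotteryError(
                f"culture {culture!r}: pool of {len(idx)} OTUs smaller than "
                f"observed richness {k}"
            )
        chosen = _weighted_draw_order(idx, weights, k, rng)
        out[i, chosen] = abundances  # largest count to first-drawn OTU
    table = CountTable(cultures.sample_ids, cultures.otu_ids, out)
    return RandomisedDataset(table, LOTTERY, seed, replicate_index)


# ----------------------------------------------------------------------------
# Quasiswap procedure
# ----------------------------------------------------------------------------

def _swap_kernel_py(block, ri, rj, ci, cj, direction, target_zeros, zeros):
    """Unit-transfer trials on 2x2 submatrices.

    While ``zeros != target_zeros`` moves that bring the zero count toward
    the target (or leave it unchanged) are accepted; once the target is
    reached only zero-count-preserving moves are accepted, so margins AND
    fill are exact from then on.  Returns the final zero count.
    """
    for t in range(len(ri)):
        a = block[ri[t], ci[t]]
        b = block[ri[t], cj[t]]
        c = block[rj[t], ci[t]]
        d = block[rj[t], cj[t]]
        if direction[t]:
            na, nb, nc, nd = a - 1, b + 1, c + 1, d - 1
        else:
            na, nb, nc, nd = a + 1, b - 1, c - 1, d + 1
        if na < 0 or nb < 0 or nc < 0 or nd < 0:
            continue
        dz = ((na == 0) + (nb == 0) + (nc == 0) + (nd == 0)) - \
             ((a == 0) + (b == 0) + (c == 0) + (d == 0))
        if zeros == target_zeros:
            if dz != 0:
                continue
        elif zeros < target_zeros:
            if dz < 0:
                continue
        else:
            if dz > 0:
                continue
        block[ri[t], ci[t]] = na
        block[ri[t], cj[t]] = nb
        block[rj[t], ci[t]] = nc
        block[rj[t], cj[t]] = nd
        zeros += dz
    return zeros


def _steer_kernel_py(block, ri, rj, ci, cj, direction, target_zeros, zeros):
    """Fill-steering trials: transfer the whole smaller diagonal entry (an
    emptying move), accepted when it brings the zero count toward the
    observed value.  Used only to reach the observed fill from an
    independent margins-fixed draw."""
    for t in range(len(ri)):
        if zeros == target_zeros:
            break
        a = block[ri[t], ci[t]]
        b = block[ri[t], cj[t]]
        c = block[rj[t], ci[t]]
        d = block[rj[t], cj[t]]
        if direction[t]:
            step = a if a < d else d
            na, nb, nc, nd = a - step, b + step, c + step, d - step
        else:
            step = b if b < c else c
            na, nb, nc, nd = a + step, b - step, c - step, d + step
        if step == 0:
            continue
        dz = ((na == 0) + (nb == 0) + (nc == 0) + (nd == 0)) - \
             ((a == 0) + (b == 0) + (c == 0) + (d == 0))
        if zeros < target_zeros:
            if dz < 0 or zeros + dz > target_zeros:
                continue
        else:
            if dz > 0 or zeros + dz < target_zeros:
                continue
        block[ri[t], ci[t]] = na
        block[ri[t], cj[t]] = nb
        block[rj[t], ci[t]] = nc
        block[rj[t], cj[t]] = nd
        zeros += dz
    return zeros


_swap_kernel = _swap_kernel_py
_steer_kernel = _steer_kernel_py
try:  # numba speeds the inner loops up ~100x; pure python fallback is exact
    import numba

    _swap_kernel = numba.njit(cache=False)(_swap_kernel_py)
    _steer_kernel = numba.njit(cache=False)(_steer_kernel_py)
except Exception:  # pragma: no cover - numba is normally available
    pass


def _random_margin_table(block: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.stats import random_table

    rows = block.sum(axis=1)
    cols = block.sum(axis=0)
    live_r = np.flatnonzero(rows)
    live_c = np.flatnonzero(cols)
    out = np.zeros_like(block)
    if len(live_r) and len(live_c):
        draw = random_table(rows[live_r], cols[live_c]).rvs(random_state=rng)
        out[np.ix_(live_r, live_c)] = np.asarray(draw, dtype=np.int64)
    return out


def _run_trials(block, zeros, target_zeros, trials, rng, kernel=None):
    n, p = block.shape
    ri = rng.integers(0, n, size=trials)
    rj = rng.integers(0, n - 1, size=trials)
    rj = np.where(rj >= ri, rj + 1, rj)  # distinct rows
    ci = rng.integers(0, p, size=trials)
    cj = rng.integers(0, p - 1, size=trials)
    cj = np.where(cj >= ci, cj + 1, cj)  # distinct columns
    direction = rng.integers(0, 2, size=trials).astype(np.bool_)
    kernel = _swap_kernel if kernel is None else kernel
    return int(kernel(block, ri, rj, ci, cj, direction, target_zeros, zeros))


def _quasiswap_block(block: np.ndarray, n_sweeps: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Randomise one station block preserving row/column totals and fill."""
    n, p = block.shape
    if n < 2 or p < 2:
        return block.copy()
    target_zeros = int((block == 0).sum())
    nnz = block.size - target_zeros
    out = _random_margin_table(block, rng)
    zeros = int((out == 0).sum())
    # steer the independent draw to the observed fill; emptying moves raise
    # the zero count efficiently, unit moves lower it (and unstick corners)
    for _ in range(500):
        if zeros == target_zeros:
            break
        zeros = _run_trials(out, zeros, target_zeros, 10 * max(nnz, 1), rng,
                            kernel=_steer_kernel)
        if zeros != target_zeros:
            zeros = _run_trials(out, zeros, target_zeros, 10 * max(nnz, 1),
                                rng, kernel=_swap_kernel)
    else:  # pragma: no cover - pathological margins
        raise RuntimeError("quasiswap could not reach the observed fill")
    # extra fill-preserving mixing
    zeros = _run_trials(out, zeros, target_zeros, n_sweeps * max(nnz, 1), rng)
    assert zeros == target_zeros
    return out


def quasiswap_randomise(
    cultures: CountTable,
    frame: SampleFrame,
    seed: int,
    n_sweeps: int = 100,
    replicate_index: int = 0,
) -> RandomisedDataset:
    """Station-constrained quasiswap: each station block is randomised
    independently, preserving its row totals, column totals and fill."""
    rng = np.random.default_rng(seed)
    out = cultures.counts.copy()
    pos = {s: i for i, s in enumerate(cultures.sample_ids)}
    for station, members in sorted(frame.cultures_by_station().items()):
        members = [m for m in members if m in pos]
        idx = [pos[m] for m in members]
        if len(idx) < 2:
            warnings.warn(
                f"station {station!r} has a single culture; block returned "
                "unchanged (no valid moves)",
                stacklevel=2,
            )
            continue
        block = out[idx]
        out[idx] = _quasiswap_block(block, n_sweeps, rng)
    table = CountTable(cultures.sample_ids, cultures.otu_ids, out)
    return RandomisedDataset(table, SWAP, seed, replicate_index)


# ----------------------------------------------------------------------------
# Ensembles
# ----------------------------------------------------------------------------

def replicate_seed(base_seed: int, replicate: int) -> int:
    """Stable per-replicate seed; replicate r computed alone equals
    replicate r of the stream."""
    ss = np.random.SeedSequence([int(base_seed), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))


def make_ensemble(
    procedure: str,
    cultures: CountTable,
    frame: SampleFrame,
    n_replicates: int,
    base_seed: int,
    sources: CountTable | None = None,
    n_sweeps: int = 100,
) -> Iterator[RandomisedDataset]:
    """Stream ``n_replicates`` randomised datasets; never materialises the
    whole ensemble."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if procedure == LOTTERY:
        if sources is None:
            raise ValueError("lottery procedure requires a source table")
        pools = station_pools(cultures, sources, frame)
        for r in range(n_replicates):
            yield lottery_randomise(
                cultures, sources, frame, replicate_seed(base_seed, r),
                replicate_index=r, _pools=pools,
            )
    elif procedure == SWAP:
        for r in range(n_replicates):
            yield quasiswap_randomise(
                cultures, frame, replicate_seed(base_seed, r),
                n_sweeps=n_sweeps, replicate_index=r,
            )
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
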
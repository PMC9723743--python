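"""Alpha/beta, phylogenetic and co-occurrence indices used to compare
observed and randomised datasets.

Index conventions
-----------------
* Shannon uses natural log (nats).
* MPD within/between communities is unweighted (incidence only), in
  branch-length units; between-community MPD averages over ALL cross pairs,
  so shared OTUs contribute zero-distance pairs.
* Incidence Bray-Curtis is the Sorensen dissimilarity
  ``1 - 2|A & B| / (|A| + |B|)``, the value Bray-Curtis takes on 0/1 data.
* The C-score averages checkerboard units ``(R_i - S)(R_j - S)`` over
  unordered OTU pairs; the normalised variant divides each unit by
  ``R_i * R_j`` and lies in [0, 1].

Undefined values (e.g. MPD of a one-OTU community) are returned as NaN and
excluded, with a count, from dataset means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .core_data import CountTable, FunctionMap, PhyloDistances
from .preprocess import FunctionTable, annotate_functions, to_incidence

__all__ = [
    "shannon",
    "shannon_rows",
    "function_indices",
    "mpd_within",
    "mpd_between",
    "bray_curtis_incidence",
    "c_score",
    "DatasetSummary",
    "dataset_summary",
    "FIG5_INDICES",
]

FIG5_INDICES = (
    "shannon_otu",
    "shannon_function",
    "mpd_within",
    "bray_curtis_otu",
    "bray_curtis_function",
    "mpd_between",
)


def shannon(counts, base: float | None = None) -> float:
    """Shannon index H = -sum p ln p over positive entries (nats unless a
    log base is given).  NaN for an all-zero vector."""
    v = np.asarray(counts, dtype=float)
    total = v.sum()
    if total <= 0:
        return float("nan")
    # canonical (sorted) summation order: H is then exactly invariant under
    # permutation of the counts, which null-model invariants rely on
    p = np.sort(v[v > 0])[::-1] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def shannon_rows(matrix: np.ndarray, base: float | None = None) -> np.ndarray:
    m = np.sort(np.asarray(matrix, dtype=float), axis=1)[:, ::-1]  # canonical
    totals = m.sum(axis=1)
    out = np.full(m.shape[0], np.nan)
    ok = totals > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = m[ok] / totals[ok, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
    out[ok] = -terms.sum(axis=1)
    if base is not None:
        out = out / math.log(base)
    return out


def function_indices(ftable: FunctionTable, base: float | None = None):
    """Per-sample Shannon over function abundances and function richness.

    Returns ``(shannon: ndarray, richness: ndarray)`` aligned with
    ``ftable.sample_ids``; samples with no annotated OTU get richness 0 and
    NaN Shannon.
    """
    h = shannon_rows(ftable.abundances, base=base)
    richness = (ftable.abundances > 0).sum(axis=1)
    return h, richness


def _present_indices(incidence) -> np.ndarray:
    v = np.asarray(incidence)
    return np.flatnonzero(v > 0)


def mpd_within(incidence, dist: PhyloDistances | np.ndarray) -> float:
    """Mean patristic distance over all unordered pairs of present OTUs.
    NaN when fewer than two OTUs are present."""
    d = dist.dist if isinstance(dist, PhyloDistances) else np.asarray(dist, float)
    idx = _present_indices(incidence)
    k = len(idx)
    if k < 2:
        return float("nan")
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mpd_between(incidence_a, incidence_b, dist: PhyloDistances | np.ndarray) -> float:
    """Mean patristic distance over all cross pairs (i in A, j in B);
    shared OTUs contribute d = 0 pairs.  NaN when either side is empty."""
    d = dist.dist if isinstance(dist, PhyloDistances) else np.asarray(dist, float)
    ia, ib = _present_indices(incidence_a), _present_indices(incidence_b)
    if len(ia) == 0 or len(ib) == 0:
        return float("nan")
    return float(d[np.ix_(ia, ib)].mean())


def bray_curtis_incidence(a, b) -> float:
    """Sorensen dissimilarity 1 - 2|A&B|/(|A|+|B|) on presence/absence."""
    va = np.asarray(a) > 0
    vb = np.asarray(b) > 0
    na, nb = int(va.sum()), int(vb.sum())
    if na + nb == 0:
        return float("nan")
    shared = int((va & vb).sum())
    return 1.0 - 2.0 * shared / (na + nb)


def c_score(incidence: np.ndarray, normalise: bool = True) -> float:
    """Checkerboard score over unordered OTU pairs.

    For OTUs i, j with occupancies R_i, R_j and S shared samples the
    checkerboard unit is (R_i - S)(R_j - S); the normalised variant divides
    by R_i * R_j.  OTUs occurring in no sample are excluded.  NaN when fewer
    than two occupied OTUs remain.
    """
    inc = (np.asarray(incidence) > 0).astype(np.int64)
    occ = inc.sum(axis=0)
    cols = np.flatnonzero(occ > 0)
    if len(cols) < 2:
        return float("nan")
    b = inc[:, cols]
    r = occ[cols].astype(float)
    s = (b.T @ b).astype(float)  # shared-sample counts
    cu = (r[:, None] - s) * (r[None, :] - s)
    if normalise:
        cu = cu / (r[:, None] * r[None, :])
    iu = np.triu_indices(len(cols), k=1)
    return float(cu[iu].mean())


def _pairwise_mean(values: np.ndarray) -> tuple[float, int]:
    finite = values[np.isfinite(values)]
    return (float(finite.mean()) if len(finite) else float("nan"),
            int(len(values) - len(finite)))


@dataclass(frozen=True)
class DatasetSummary:
    """Per-dataset mean of each index, with counts of NaN-flagged values
    excluded from the means."""

    means: Mapping[str, float]
    n_excluded: Mapping[str, int]

    def __getitem__(self, key: str) -> float:
        return self.means[key]


def dataset_summary(
    table: CountTable,
    tree: PhyloDistances | None = None,
    fmap: FunctionMap | None = None,
    which: Iterable[str] | None = None,
    log_base: float | None = None,
) -> DatasetSummary:
    """Mean value of each requested index across a dataset.

    Per-sample indices are averaged over samples; pairwise indices over all
    unordered sample pairs; the C-score is already a per-dataset quantity
    (both variants are reported).  NaN-flagged values are excluded from the
    means and counted in ``n_excluded``.
    """
    wanted = set(which) if which is not None else set(FIG5_INDICES) | {
        "function_richness", "c_score", "c_score_unnormalised"}
    means: dict[str, float] = {}
    nex: dict[str, int] = {}
    n = table.n_samples
    inc = to_incidence(table)

    def record(name: str, values: np.ndarray) -> None:
        means[name], nex[name] = _pairwise_mean(np.asarray(values, dtype=float))

    if "shannon_otu" in wanted:
        record("shannon_otu", shannon_rows(table.counts, base=log_base))

    ftable = None
    if fmap is not None and wanted & {"shannon_function", "function_richness",
                                      "bray_curtis_function"}:
        ftable = annotate_functions(table, fmap)
    if ftable is not None and "shannon_function" in wanted:
        h, richness = function_indices(ftable, base=log_base)
        record("shannon_function", h)
        if "function_richness" in wanted:
            record("function_richness", richness.astype(float))
    elif ftable is not None and "function_richness" in wanted:
        _, richness = function_indices(ftable, base=log_base)
        record("function_richness", richness.astype(float))

    dist = None
    if tree is not None and wanted & {"mpd_within", "mpd_between"}:
        dist = tree.submatrix(table.otu_ids)
    if dist is not None and "mpd_within" in wanted:
        record("mpd_within", np.array([mpd_within(inc[i], dist) for i in range(n)]))

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if "bray_curtis_otu" in wanted:
        if pairs:
            record("bray_curtis_otu",
                   np.array([bray_curtis_incidence(inc[i], inc[j]) for i, j in pairs]))
        else:
            means["bray_curtis_otu"], nex["bray_curtis_otu"] = float("nan"), 0
    if dist is not None and "mpd_between" in wanted:
        if pairs:
            record("mpd_between",
                   np.array([mpd_between(inc[i], inc[j], dist) for i, j in pairs]))
        else:
            means["mpd_between"], nex["mpd_between"] = float("nan"), 0
    if ftable is not None and "bray_curtis_function" in wanted:
        finc = to_incidence(ftable)
        if pairs:
            record("bray_curtis_function",
                   np.array([bray_curtis_incidence(finc[i], finc[j]) for i, j in pairs]))
        else:
            means["bray_curtis_function"], nex["bray_curtis_function"] = float("nan"), 0

    if "c_score" in wanted:
        means["c_score"] = c_score(inc, normalise=True)
        nex["c_score"] = 0
    if "c_score_unnormalised" in wanted:
        means["c_score_unnormalised"] = c_score(inc, normalise=False)
        nex["c_score_unnormalised"] = 0
    return DatasetSummary(means, nex)
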
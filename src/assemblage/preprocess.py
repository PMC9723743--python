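"""Filtering, rarefaction and function-annotation steps that turn raw OTU
tables into analysis-ready culture and source datasets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import CountTable, FunctionMap, ValidationError

__all__ = [
    "FunctionTable",
    "FilterResult",
    "DropResult",
    "RarefyResult",
    "noise_floor_filter",
    "drop_flagged_otus",
    "rarefy",
    "curate_functions",
    "annotate_functions",
    "to_incidence",
]


@dataclass(frozen=True)
class FunctionTable:
    """Sample x function abundance matrix (summed reads of carrier OTUs).

    Functions that are absent from every sample are dropped on construction.
    """

    sample_ids: tuple[str, ...]
    function_labels: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=np.int64)
        if ab.shape != (len(self.sample_ids), len(self.function_labels)):
            raise ValidationError("abundance matrix shape mismatch")
        if (ab < 0).any():
            raise ValidationError("negative function abundance")
        keep = ab.sum(axis=0) > 0
        labels = tuple(f for f, k in zip(self.function_labels, keep) if k)
        ab = ab[:, keep]
        ab.setflags(write=False)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "function_labels", labels)
        object.__setattr__(self, "abundances", ab)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances.copy(),
            index=list(self.sample_ids),
            columns=list(self.function_labels),
        )


@dataclass(frozen=True)
class FilterResult:
    table: CountTable
    flagged_otus: tuple[str, ...]  # OTUs that became all-zero


@dataclass(frozen=True)
class DropResult:
    table: CountTable
    removed_fraction: Mapping[str, float]  # label -> fraction of reads removed


@dataclass(frozen=True)
class RarefyResult:
    table: CountTable
    dropped_samples: tuple[str, ...]  # below min_reads


def noise_floor_filter(table: CountTable, threshold: int) -> FilterResult:
    """Zero every count strictly below ``threshold``; counts >= threshold
    are untouched.  OTUs that become all-zero are retained but flagged."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    counts = table.counts.copy()
    counts[counts < threshold] = 0
    filtered = table.with_counts(counts)
    was_occupied = table.otu_totals() > 0
    now_empty = filtered.otu_totals() == 0
    flagged = tuple(
        o for o, w, e in zip(table.otu_ids, was_occupied, now_empty) if w and e
    )
    return FilterResult(filtered, flagged)


def drop_flagged_otus(table: CountTable, flags: Mapping[str, set]) -> DropResult:
    """Remove OTUs flagged with any label (e.g. chloroplast, mitochondria);
    report the read fraction removed per label and overall."""
    total = int(table.counts.sum())
    per_label: dict[str, float] = {}
    flagged_ids = [o for o in table.otu_ids if flags.get(o)]
    labels = sorted({lab for fs in flags.values() for lab in fs})
    otu_reads = dict(zip(table.otu_ids, table.otu_totals()))
    for lab in labels:
        reads = sum(int(otu_reads[o]) for o in flagged_ids if lab in flags[o])
        per_label[lab] = reads / total if total else 0.0
    removed_reads = sum(int(otu_reads[o]) for o in flagged_ids)
    per_label["total"] = removed_reads / total if total else 0.0
    keep = [o for o in table.otu_ids if o not in set(flagged_ids)]
    return DropResult(table.select_otus(keep), per_label)


def rarefy(table: CountTable, depth: int, min_reads: int | None = None,
           seed: int = 0) -> RarefyResult:
    """Subsample every sample WITHOUT replacement to exactly ``depth`` reads
    (one multivariate hypergeometric draw per sample), dropping samples with
    fewer than ``min_reads`` total first."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if min_reads is None:
        min_reads = depth
    if min_reads < depth:
        raise ValueError(f"min_reads ({min_reads}) must be >= depth ({depth})")
    totals = table.sample_totals()
    keep_mask = totals >= min_reads
    dropped = tuple(s for s, k in zip(table.sample_ids, keep_mask) if not k)
    kept_ids = [s for s, k in zip(table.sample_ids, keep_mask) if k]
    rng = np.random.default_rng(seed)
    rows = []
    for s in kept_ids:
        row = table.row(s)
        if row.sum() == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, table.n_otus), dtype=np.int64)
    return RarefyResult(CountTable(tuple(kept_ids), table.otu_ids, counts), dropped)


def curate_functions(fmap: FunctionMap) -> FunctionMap:
    """Remove nested-function overlaps: whenever an OTU carries a function
    and also (transitively) one of its broader containers, drop the broad
    label from that OTU so functional diversity is not double-counted."""
    curated: dict[str, frozenset[str]] = {}
    for otu, funcs in fmap.assignments.items():
        redundant: set[str] = set()
        for f in funcs:
            redundant |= fmap.broad_ancestors(f)
        curated[otu] = frozenset(funcs - redundant)
    return FunctionMap(curated, fmap.nesting)


def annotate_functions(table: CountTable, fmap: FunctionMap) -> FunctionTable:
    """Sum reads per function per sample over carrier OTUs.  OTUs without
    an assignment contribute to no function."""
    labels = sorted({f for o in table.otu_ids for f in fmap.functions_of(o)})
    pos = {f: j for j, f in enumerate(labels)}
    # otu x function indicator
    ind = np.zeros((table.n_otus, len(labels)), dtype=np.int64)
    for i, o in enumerate(table.otu_ids):
        for f in fmap.functions_of(o):
            ind[i, pos[f]] = 1
    ab = table.counts @ ind
    return FunctionTable(table.sample_ids, tuple(labels), ab)


def to_incidence(table) -> np.ndarray:
    """Presence/absence (0/1 int) matrix of a count or function table, or of
    a bare array."""
    if isinstance(table, CountTable):
        m = table.counts
    elif isinstance(table, FunctionTable):
        m = table.abundances
    else:
        m = np.asarray(table)
    return (m > 0).astype(np.int64)
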
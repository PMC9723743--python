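"""Domain types and tab-delimited I/O for count tables, metadata, trees and
function maps.

All tables are UTF-8, tab-delimited; lines starting with ``#`` are comments.
Samples-as-rows is the canonical in-memory orientation for count tables.
Identifiers are opaque strings and all joins between objects are by
identifier, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleFrame",
    "PhyloDistances",
    "FunctionMap",
    "HostFrame",
    "ValidationReport",
    "CountTableParseError",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_function_map",
    "write_function_map",
    "read_host_frame",
    "tree_to_distances",
    "validate_bundle",
]

SOURCE = "source"
CULTURE = "culture"


class CountTableParseError(ValueError):
    """Raised when a TSV cell cannot be interpreted as a count."""


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class CountTable:
    """Sample x OTU matrix of non-negative integer read counts."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_otus), integer dtype

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if (counts < 0).any():
            raise ValidationError("negative counts are not allowed")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        wanted = list(sample_ids)
        idx = [self.sample_index(s) for s in wanted]
        return CountTable(tuple(wanted), self.otu_ids, self.counts[idx])

    def select_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        wanted = list(otu_ids)
        idx = [pos[o] for o in wanted]
        return CountTable(self.sample_ids, tuple(wanted), self.counts[:, idx])

    def drop_empty_otus(self) -> "CountTable":
        keep = self.counts.sum(axis=0) > 0
        return CountTable(
            self.sample_ids,
            tuple(o for o, k in zip(self.otu_ids, keep) if k),
            self.counts[:, keep],
        )

    def with_counts(self, counts: np.ndarray) -> "CountTable":
        return CountTable(self.sample_ids, self.otu_ids, counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.sample_ids), columns=list(self.otu_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata: kind, station, habitat and named covariates.

    Backed by a DataFrame indexed by sample id with the reserved columns
    ``kind``, ``station``, ``habitat`` and ``source_sample_id``; every other
    column is treated as an environmental covariate.  Missing covariates are
    permitted (NaN) and surfaced by :meth:`require_covariates`.
    """

    data: pd.DataFrame

    RESERVED = ("kind", "station", "habitat", "source_sample_id")

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in metadata")
        for col in ("kind", "station"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad_kind = set(df["kind"]) - {SOURCE, CULTURE}
        if bad_kind:
            raise ValidationError(f"unknown sample kind(s): {sorted(bad_kind)}")
        if (df["station"].astype(str).str.len() == 0).any():
            raise ValidationError("station must be non-empty for every sample")
        if "source_sample_id" not in df.columns:
            df["source_sample_id"] = pd.NA
        if "habitat" not in df.columns:
            df["habitat"] = pd.NA
        object.__setattr__(self, "data", df)

    def dangling_sources(self) -> list[str]:
        """Culture ids whose source_sample_id does not resolve to a source."""
        df = self.data
        sources = set(df.index[df["kind"] == SOURCE])
        cultures = df[df["kind"] == CULTURE]
        return [
            s for s, src in cultures["source_sample_id"].items()
            if pd.isna(src) or str(src) not in sources
        ]

    def validate(self) -> None:
        dangling = self.dangling_sources()
        if dangling:
            raise ValidationError(
                f"cultures with unresolved source_sample_id: {dangling}"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def kinds(self) -> pd.Series:
        return self.data["kind"]

    def stations(self) -> pd.Series:
        return self.data["station"]

    def station_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "station"])

    def source_of(self, culture_id: str) -> str:
        row = self.data.loc[culture_id]
        if row["kind"] != CULTURE:
            raise KeyError(f"{culture_id!r} is not a culture sample")
        return str(row["source_sample_id"])

    def samples_of_kind(self, kind: str) -> list[str]:
        return list(self.data.index[self.data["kind"] == kind])

    def cultures_by_station(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples_of_kind(CULTURE):
            out.setdefault(self.station_of(s), []).append(s)
        return out

    def covariates(self) -> pd.DataFrame:
        extra = [c for c in self.data.columns if c not in self.RESERVED]
        return self.data[extra]

    def require_covariates(self, names: Sequence[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"missing covariate column(s): {missing}")
        sub = self.data[list(names)]
        nan_cols = [n for n in names if sub[n].isna().any()]
        if nan_cols:
            raise ValidationError(f"covariate(s) with missing values: {nan_cols}")
        return sub

    def subset(self, sample_ids: Iterable[str]) -> "SampleFrame":
        wanted = [str(s) for s in sample_ids]
        df = self.data.loc[wanted].copy()
        # keep referenced sources so culture -> source links stay resolvable
        needed = set(df.loc[df["kind"] == CULTURE, "source_sample_id"].dropna().astype(str))
        extra = sorted(needed - set(df.index))
        if extra:
            df = pd.concat([df, self.data.loc[extra]])
        return SampleFrame(df)


@dataclass(frozen=True)
class PhyloDistances:
    """Symmetric patristic distance matrix over OTU tips."""

    otu_ids: tuple[str, ...]
    dist: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        _check_unique(self.otu_ids, "OTU")
        d = np.asarray(self.dist, dtype=float)
        n = len(self.otu_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if (d < 0).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d.setflags(write=False)
        object.__setattr__(self, "dist", d)

    def submatrix(self, otu_ids: Iterable[str]) -> "PhyloDistances":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        wanted = list(otu_ids)
        missing = [o for o in wanted if o not in pos]
        if missing:
            raise KeyError(f"OTUs absent from tree: {missing}")
        idx = [pos[o] for o in wanted]
        return PhyloDistances(tuple(wanted), self.dist[np.ix_(idx, idx)])

    def distance(self, a: str, b: str) -> float:
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        return float(self.dist[pos[a], pos[b]])


@dataclass(frozen=True)
class FunctionMap:
    """OTU -> set of ecological function labels plus a nesting relation.

    ``nesting`` is a set of ``(narrow, broad)`` pairs meaning that the narrow
    function is contained within the broad one.
    """

    assignments: Mapping[str, frozenset[str]]
    nesting: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        clean = {str(o): frozenset(str(f) for f in fs) for o, fs in self.assignments.items()}
        object.__setattr__(self, "assignments", clean)
        nesting = tuple((str(a), str(b)) for a, b in self.nesting)
        object.__setattr__(self, "nesting", nesting)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: dict[str, set[str]] = {}
        for narrow, broad in self.nesting:
            children.setdefault(narrow, set()).add(broad)
        WHITE, GREY, BLACK = 0, 1, 2
        colour: dict[str, int] = {}

        def visit(node: str) -> None:
            colour[node] = GREY
            for nxt in children.get(node, ()):
                state = colour.get(nxt, WHITE)
                if state == GREY:
                    raise ValidationError(f"cycle in function nesting at {nxt!r}")
                if state == WHITE:
                    visit(nxt)
            colour[node] = BLACK

        for node in list(children):
            if colour.get(node, WHITE) == WHITE:
                visit(node)

    def labels(self) -> set[str]:
        out: set[str] = set()
        for fs in self.assignments.values():
            out |= fs
        for narrow, broad in self.nesting:
            out |= {narrow, broad}
        return out

    def functions_of(self, otu_id: str) -> frozenset[str]:
        return self.assignments.get(otu_id, frozenset())

    def broad_ancestors(self, label: str) -> set[str]:
        """All labels reachable by following narrow -> broad links."""
        out: set[str] = set()
        frontier = [label]
        up: dict[str, set[str]] = {}
        for narrow, broad in self.nesting:
            up.setdefault(narrow, set()).add(broad)
        while frontier:
            node = frontier.pop()
            for parent in up.get(node, ()):
                if parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out


@dataclass(frozen=True)
class HostFrame:
    """Host culture genetic p-distances and trait covariates."""

    culture_ids: tuple[str, ...]
    genetic_dist: np.ndarray  # culture x culture, p-distances in [0, 1]
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        object.__setattr__(self, "culture_ids", tuple(str(c) for c in self.culture_ids))
        _check_unique(self.culture_ids, "culture")
        d = np.asarray(self.genetic_dist, dtype=float)
        n = len(self.culture_ids)
        if d.shape != (n, n):
            raise ValidationError(f"genetic distance shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("genetic distances must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("genetic distance diagonal must be zero")
        if (d < 0).any() or (d > 1).any():
            raise ValidationError("p-distances must lie in [0, 1]")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d.setflags(write=False)
        object.__setattr__(self, "genetic_dist", d)
        traits = self.traits if self.traits is not None else pd.DataFrame()
        if len(traits) and list(traits.index.astype(str)) != list(self.culture_ids):
            traits = traits.loc[list(self.culture_ids)]
        object.__setattr__(self, "traits", traits)


# ----------------------------------------------------------------------------
# TSV I/O
# ----------------------------------------------------------------------------

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_count_table(path, orientation: str = "samples_as_rows") -> CountTable:
    """Read a count table TSV, normalising to samples-as-rows.

    The first column holds row identifiers; the header row holds column
    identifiers.  Every body cell must parse as a non-negative integer; the
    error for a bad cell names its row and column.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    body = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (row, raw) in enumerate(df[col].items()):
            try:
                value = int(str(raw))
            except (TypeError, ValueError):
                raise CountTableParseError(
                    f"non-integer count {raw!r} at row {row!r}, column {col!r}"
                ) from None
            body[i, j] = value
    if orientation == "otus_as_rows":
        sample_ids, otu_ids = tuple(df.columns), tuple(df.index)
        body = body.T
    else:
        sample_ids, otu_ids = tuple(df.index), tuple(df.columns)
    return CountTable(sample_ids, otu_ids, body)


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_sample_frame(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path) -> None:
    frame.data.to_csv(path, sep="\t", index_label="sample_id")


def read_function_map(assignments_path, nesting_path=None) -> FunctionMap:
    """Read an OTU->functions map (``otu<TAB>f1;f2``) and optional nesting
    map (``narrow<TAB>broad``)."""
    assignments: dict[str, frozenset[str]] = {}
    with open(assignments_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            otu = parts[0]
            funcs = parts[1] if len(parts) > 1 else ""
            labels = frozenset(f for f in funcs.split(";") if f)
            assignments[otu] = labels
    nesting: list[tuple[str, str]] = []
    if nesting_path is not None:
        with open(nesting_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                narrow, broad = line.split("\t")[:2]
                nesting.append((narrow, broad))
    return FunctionMap(assignments, tuple(nesting))


def write_function_map(fmap: FunctionMap, assignments_path, nesting_path=None) -> None:
    with open(assignments_path, "w", encoding="utf-8") as fh:
        for otu in sorted(fmap.assignments):
            fh.write(f"{otu}\t{';'.join(sorted(fmap.assignments[otu]))}\n")
    if nesting_path is not None:
        with open(nesting_path, "w", encoding="utf-8") as fh:
            for narrow, broad in sorted(fmap.nesting):
                fh.write(f"{narrow}\t{broad}\n")


def read_host_frame(dist_path, traits_path=None) -> HostFrame:
    dist = pd.read_csv(dist_path, sep="\t", comment="#", index_col=0)
    dist.index = dist.index.astype(str)
    dist.columns = dist.columns.astype(str)
    if list(dist.index) != list(dist.columns):
        raise ValidationError("genetic distance matrix rows and columns disagree")
    traits = pd.DataFrame(index=dist.index)
    if traits_path is not None:
        traits = pd.read_csv(traits_path, sep="\t", comment="#", index_col=0)
        traits.index = traits.index.astype(str)
    return HostFrame(tuple(dist.index), dist.to_numpy(dtype=float), traits)


# ----------------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------------

def tree_to_distances(path_or_newick) -> PhyloDistances:
    """Patristic (sum of branch lengths along the path) distances between
    all tips of a Newick tree.

    Accepts a file path or a raw Newick string.  Every non-root edge must
    carry a branch length and tip labels must be unique.
    """
    text = str(path_or_newick)
    try:
        if text.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     preserve_underscores=True)
        else:
            with open(path_or_newick, encoding="utf-8") as fh:
                tree = dendropy.Tree.get(file=fh, schema="newick",
                                         preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip label in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    _check_unique(labels, "tip")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError("tree has an edge without a branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            dist[i, j] = dist[j, i] = d
    return PhyloDistances(tuple(labels), dist)


# ----------------------------------------------------------------------------
# Bundle validation
# ----------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only consistency check across a data bundle."""

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    @property
    def empty(self) -> bool:
        return not self.fatal and not self.warnings


def validate_bundle(
    table: CountTable,
    frame: SampleFrame,
    tree: PhyloDistances | None = None,
    fmap: FunctionMap | None = None,
) -> ValidationReport:
    """Cross-check a count table against metadata, tree tips and the
    function map.  OTUs without a function assignment are a warning only;
    OTUs missing from the tree are fatal for phylogenetic indices."""
    report = ValidationReport()
    for c in frame.dangling_sources():
        report.fatal.append(f"culture {c!r} has unresolved source_sample_id")
    meta_ids = set(frame.sample_ids)
    for s in table.sample_ids:
        if s not in meta_ids:
            report.fatal.append(f"sample {s!r} has no metadata row")
    occupied = [o for o, t in zip(table.otu_ids, table.otu_totals()) if t > 0]
    if tree is not None:
        tips = set(tree.otu_ids)
        culture_rows = [s for s in table.sample_ids if s in meta_ids
                        and frame.data.loc[s, "kind"] == CULTURE]
        if culture_rows:
            sub = table.select_samples(culture_rows)
            culture_occupied = {
                o for o, t in zip(sub.otu_ids, sub.otu_totals()) if t > 0
            }
        else:
            culture_occupied = set(occupied)
        for o in sorted(culture_occupied - tips):
            report.fatal.append(
                f"OTU {o!r} missing from tree (fatal for phylogenetic indices only)"
            )
    if fmap is not None:
        declared = fmap.labels()
        for narrow, broad in fmap.nesting:
            if narrow not in declared or broad not in declared:
                report.fatal.append(f"nesting pair ({narrow!r}, {broad!r}) undeclared")
        unannotated = [o for o in occupied if not fmap.functions_of(o)]
        if unannotated:
            report.warnings.append(
                f"{len(unannotated)} occupied OTU(s) without function assignment"
            )
    return report
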
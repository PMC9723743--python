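"""Synthetic scenario generator: source communities, bacterial phylogeny,
host genotypes and host microbiomes with known ground truth.

Assembly model for each culture: OTUs are recruited sequentially without
replacement from the local source community with weight

    w(i) = p_source(i) * exp(selection_strength * affinity(host, i))
           * (1 - exp(-d_min(i, already_chosen) / competition_strength))

where the competition factor is skipped for the first draw and equals 1 when
``competition_strength`` is 0.  Setting ``selection_strength = 0`` and
``competition_strength = 0`` therefore reduces the generator to the exact
abundance-proportional lottery, which downstream null models assume.

All randomness flows from ``cfg.seed`` through named substreams (one per
culture), so adding cultures never perturbs earlier draws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core_data import (
    CountTable,
    FunctionMap,
    HostFrame,
    PhyloDistances,
    SampleFrame,
    tree_to_distances,
    write_count_table,
    write_function_map,
    write_sample_frame,
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Bundle",
    "gen_tree",
    "gen_sources",
    "gen_hosts",
    "gen_cultures",
    "gen_functions",
    "generate_scenario",
    "write_bundle",
    "competition_factor",
]

# substream tags (mixed with the scenario seed to form SeedSequences)
_TREE, _SOURCES, _HOSTS, _FUNCTIONS, _CULTURE, _ENV = 1, 2, 3, 4, 5, 6


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


@dataclass(frozen=True)
class ScenarioConfig:
    n_stations: int = 4
    n_otus_pool: int = 300
    otu_abundance_mu: float = 2.0   # lognormal log-mean of source abundances
    otu_abundance_sigma: float = 1.5
    station_occupancy: float = 0.6  # fraction of the pool present per station
    station_turnover: float = 0.3   # fraction of membership replaced between stations
    n_cultures_per_station: int = 10
    richness_lambda: float = 8.0    # Poisson mean, truncated to [1, 19]
    richness_max: int = 19
    selection_strength: float = 0.0
    phylo_signal: float = 0.0
    competition_strength: float = 0.0
    # scale (in units of the mean host p-distance) over which host-affinity
    # correlation decays between hosts; small values make selection more
    # host-idiosyncratic while staying structured by close relatedness
    host_corr_scale: float = 1.0
    # number of distinct host haplotypes shared among the hosts (isolates of
    # the same haplotype have identical genotypes and hence identical
    # selective preferences); 0 means every host is genetically distinct
    n_host_haplotypes: int = 0
    n_functions: int = 20
    source_depth: int = 50_000
    culture_depth: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.n_otus_pool < 2:
            raise ValueError("n_stations >= 1 and n_otus_pool >= 2 required")
        if not (0.0 <= self.station_turnover <= 1.0):
            raise ValueError("station_turnover must be in [0, 1]")
        if not (0.0 < self.station_occupancy <= 1.0):
            raise ValueError("station_occupancy must be in (0, 1]")
        for name in ("selection_strength", "phylo_signal", "competition_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """Per-culture recruitment channels and the host-affinity matrix."""

    channels: dict[str, list[tuple[str, str]]]  # culture -> [(otu, channel)]
    host_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    affinity: np.ndarray  # host x OTU
    # mean realised richness; under pure lottery the Sloan product N*m is
    # approximately this value (m = mean_richness / N at fit depth N)
    mean_richness: float
    true_m_at_depth: float | None  # mean_richness / culture_depth when neutral

    def to_json(self) -> dict:
        return {
            "channels": self.channels,
            "host_ids": list(self.host_ids),
            "otu_ids": list(self.otu_ids),
            "affinity": self.affinity.tolist(),
            "mean_richness": self.mean_richness,
            "true_m_at_depth": self.true_m_at_depth,
        }


# ----------------------------------------------------------------------------
# Tree
# ----------------------------------------------------------------------------

def _yule_newick(n_tips: int, rng: np.random.Generator, prefix: str,
                 branch_scale: float = 0.1) -> str:
    """Random pure-birth topology with exponential branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    # children[node] = (left, right) or None for tips
    children: dict[int, tuple[int, int] | None] = {0: None, 1: None}
    root_children = [0, 1]
    tips = [0, 1]
    next_id = 2
    while len(tips) < n_tips:
        pick = int(rng.integers(len(tips)))
        node = tips.pop(pick)
        left, right = next_id, next_id + 1
        next_id += 2
        children[node] = (left, right)
        children[left] = children[right] = None
        tips.extend([left, right])
    lengths = {node: float(rng.exponential(branch_scale)) + 1e-4
               for node in children}
    label: dict[int, str] = {}
    counter = [0]

    def render(node: int) -> str:
        kids = children[node]
        if kids is None:
            counter[0] += 1
            name = f"{prefix}{counter[0]:04d}"
            label[node] = name
            return f"{name}:{lengths[node]:.6f}"
        left, right = kids
        return f"({render(left)},{render(right)}):{lengths[node]:.6f}"

    inner = ",".join(render(c) for c in root_children)
    return f"({inner});"


def gen_tree(n_otus: int, seed: int, prefix: str = "OTU_") -> str:
    """Deterministic random Yule tree as a Newick string, tips labelled
    ``OTU_0001`` onward."""
    if n_otus < 2:
        raise ValueError("n_otus must be >= 2")
    return _yule_newick(n_otus, _rng(seed, _TREE), prefix)


# ----------------------------------------------------------------------------
# Sources
# ----------------------------------------------------------------------------

def _station_ids(cfg: ScenarioConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(cfg.n_stations)]


def gen_sources(cfg: ScenarioConfig) -> tuple[CountTable, pd.DataFrame]:
    """One source sample per station.  Station membership drifts along the
    station sequence: a ``station_turnover`` fraction of the previous
    station's members is replaced by currently-absent pool OTUs.

    Returns the source count table and its metadata rows.
    """
    rng = rng_s = _rng(cfg.seed, _SOURCES)
    env_rng = _rng(cfg.seed, _ENV)
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(cfg.n_otus_pool)]
    stations = _station_ids(cfg)
    n_member = max(2, int(round(cfg.station_occupancy * cfg.n_otus_pool)))
    membership: list[np.ndarray] = []
    for s in range(cfg.n_stations):
        if s == 0:
            members = rng.choice(cfg.n_otus_pool, size=n_member, replace=False)
        else:
            prev = membership[-1]
            n_replace = int(round(cfg.station_turnover * len(prev)))
            keep = rng_s.choice(prev, size=len(prev) - n_replace, replace=False)
            absent = np.setdiff1d(np.arange(cfg.n_otus_pool), prev)
            n_new = min(n_replace, len(absent))
            if n_new < n_replace:
                warnings.warn("pool too small for requested turnover", stacklevel=2)
            new = rng_s.choice(absent, size=n_new, replace=False)
            members = np.concatenate([keep, new])
        membership.append(np.sort(members))
    counts = np.zeros((cfg.n_stations, cfg.n_otus_pool), dtype=np.int64)
    for s, members in enumerate(membership):
        raw = rng.lognormal(cfg.otu_abundance_mu, cfg.otu_abundance_sigma,
                            size=len(members))
        scaled = np.maximum(1, np.round(raw / raw.sum() * cfg.source_depth))
        counts[s, members] = scaled.astype(np.int64)
    sample_ids = [f"SRC_{st}" for st in stations]
    table = CountTable(tuple(sample_ids), tuple(otu_ids), counts)
    coords = env_rng.uniform(0, 100, size=(cfg.n_stations, 2))
    meta = pd.DataFrame(
        {
            "kind": "source",
            "station": stations,
            "habitat": [("sediment", "water")[s % 2] for s in range(cfg.n_stations)],
            "source_sample_id": pd.NA,
            "salinity": np.round(env_rng.normal(30, 3, cfg.n_stations), 2),
            "nitrite": np.round(env_rng.lognormal(3, 1, cfg.n_stations), 2),
            "phosphate": np.round(env_rng.lognormal(5, 1, cfg.n_stations), 2),
            "coord_x": np.round(coords[:, 0], 3),
            "coord_y": np.round(coords[:, 1], 3),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return table, meta


# ----------------------------------------------------------------------------
# Hosts
# ----------------------------------------------------------------------------

def _p_distances_from_tree(n: int, rng: np.random.Generator,
                           seq_len: int = 400, rate: float = 0.5) -> np.ndarray:
    """Pairwise p-distances of binary sequences evolved along a random Yule
    topology (gives the genetic distances phylogenetic structure)."""
    children: dict[int, tuple[int, int] | None] = {0: None, 1: None}
    tips = [0, 1]
    next_id = 2
    parent = {0: -1, 1: -1}
    edge_len = {0: rng.exponential(0.1), 1: rng.exponential(0.1)}
    while len(tips) < n:
        pick = int(rng.integers(len(tips)))
        node = tips.pop(pick)
        left, right = next_id, next_id + 1
        next_id += 2
        children[node] = (left, right)
        children[left] = children[right] = None
        parent[left] = parent[right] = node
        edge_len[left] = rng.exponential(0.1)
        edge_len[right] = rng.exponential(0.1)
        tips.extend([left, right])
    root_seq = rng.integers(0, 2, size=seq_len)
    seqs: dict[int, np.ndarray] = {}

    def evolve(node: int, seq: np.ndarray) -> None:
        p_flip = min(0.45, rate * edge_len[node])
        flips = rng.random(seq_len) < p_flip
        new = np.where(flips, 1 - seq, seq)
        kids = children.get(node)
        if kids is None:
            seqs[node] = new
        else:
            for kid in kids:
                evolve(kid, new)

    for top in (0, 1):
        evolve(top, root_seq)
    tip_ids = sorted(seqs)
    mat = np.array([seqs[t] for t in tip_ids])
    diff = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    np.fill_diagonal(diff, 0.0)
    return diff


def gen_hosts(
    cfg: ScenarioConfig, tree: PhyloDistances, sources: CountTable
) -> tuple[HostFrame, np.ndarray]:
    """Host genotypes plus the host x OTU affinity matrix.

    Affinities have standard-normal marginals; rows are correlated in
    proportion to host genetic relatedness, and columns follow the bacterial
    phylogeny with strength ``phylo_signal`` (``phylo_signal = 0`` gives
    i.i.d. affinities across OTUs).  Hosts with identical genotypes get
    identical affinity rows.
    """
    rng = _rng(cfg.seed, _HOSTS)
    n_hosts = cfg.n_stations * cfg.n_cultures_per_station
    host_ids = tuple(f"H{i + 1:03d}" for i in range(n_hosts))
    if cfg.n_host_haplotypes and 2 <= cfg.n_host_haplotypes < n_hosts:
        # isolates share a limited haplotype pool: same haplotype -> p-dist 0
        hap_d = _p_distances_from_tree(cfg.n_host_haplotypes, rng)
        hap_of = rng.integers(0, cfg.n_host_haplotypes, size=n_hosts)
        gdist = hap_d[np.ix_(hap_of, hap_of)]
    elif n_hosts >= 2:
        gdist = _p_distances_from_tree(n_hosts, rng)
    else:
        gdist = np.zeros((1, 1))
    traits = pd.DataFrame(
        {"cell_perimeter": np.round(rng.normal(60, 8, n_hosts), 2)},
        index=pd.Index(host_ids, name="culture_id"),
    )
    hosts = HostFrame(host_ids, gdist, traits)

    # group hosts with identical genotypes so their affinity rows coincide
    reps: list[int] = []
    rep_of = np.full(n_hosts, -1, dtype=int)
    for i in range(n_hosts):
        for r in reps:
            if gdist[i, r] == 0.0:
                rep_of[i] = r
                break
        if rep_of[i] == -1:
            reps.append(i)
            rep_of[i] = i
    rep_index = {r: k for k, r in enumerate(reps)}

    gscale = max(float(gdist[np.triu_indices(n_hosts, 1)].mean()), 1e-6) \
        if n_hosts > 1 else 1.0
    gscale *= cfg.host_corr_scale
    sig_h = np.exp(-gdist[np.ix_(reps, reps)] / gscale)
    d = tree.dist
    if cfg.phylo_signal > 0:
        dbar = max(float(d[np.triu_indices(len(d), 1)].mean()), 1e-12)
        sig_b = np.exp(-d / (cfg.phylo_signal * dbar))
    else:
        sig_b = np.eye(len(d))
    lh = np.linalg.cholesky(sig_h + 1e-10 * np.eye(len(reps)))
    lb = np.linalg.cholesky(sig_b + 1e-10 * np.eye(len(d)))
    g = rng.standard_normal((len(reps), len(d)))
    a_rep = lh @ g @ lb.T
    affinity = a_rep[[rep_index[rep_of[i]] for i in range(n_hosts)]]
    return hosts, affinity


# ----------------------------------------------------------------------------
# Cultures
# ----------------------------------------------------------------------------

def competition_factor(d_min: np.ndarray, rho: float) -> np.ndarray:
    """Limiting-similarity weight 1 - exp(-d_min / rho); 1 when rho = 0."""
    if rho <= 0:
        return np.ones_like(np.asarray(d_min, dtype=float))
    return -np.expm1(-np.asarray(d_min, dtype=float) / rho)


def _truncated_poisson(lam: float, low: int, high: int,
                       rng: np.random.Generator) -> int:
    for _ in range(1000):
        k = int(rng.poisson(lam))
        if low <= k <= high:
            return k
    return int(np.clip(round(lam), low, high))


def gen_cultures(
    cfg: ScenarioConfig,
    sources: CountTable,
    source_meta: pd.DataFrame,
    tree: PhyloDistances,
    hosts: HostFrame,
    affinity: np.ndarray,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Assemble one culture microbiome per host by sequential weighted
    recruitment from the local source community (see module docstring)."""
    otu_ids = sources.otu_ids
    tree_sub = tree.submatrix(otu_ids)
    d = tree_sub.dist
    stations = _station_ids(cfg)
    p_rel = sources.counts / sources.counts.sum(axis=1, keepdims=True)
    culture_rows = []
    culture_ids = []
    meta_rows = []
    channels: dict[str, list[tuple[str, str]]] = {}
    richness_seen = []
    host_idx = 0
    for s, station in enumerate(stations):
        src_id = f"SRC_{station}"
        present = np.flatnonzero(sources.counts[s] > 0)
        for c in range(cfg.n_cultures_per_station):
            rng = _rng(cfg.seed, _CULTURE, s, c)
            host = hosts.culture_ids[host_idx]
            culture_id = f"CUL_{station}_{c + 1:02d}"
            k = _truncated_poisson(cfg.richness_lambda, 1, cfg.richness_max, rng)
            if k > len(present):
                warnings.warn(
                    f"{culture_id}: richness {k} capped to source richness "
                    f"{len(present)}", stacklevel=2)
                k = len(present)
            base_w = p_rel[s, present] * np.exp(
                cfg.selection_strength * affinity[host_idx, present])
            chosen: list[int] = []
            avail = present.copy()
            w_avail = base_w.copy()
            for _ in range(k):
                w = w_avail.copy()
                if chosen and cfg.competition_strength > 0:
                    dmin = d[np.ix_(avail, chosen)].min(axis=1)
                    w = w * competition_factor(dmin, cfg.competition_strength)
                total = w.sum()
                if total <= 0:  # degenerate weights; fall back to lottery
                    w = p_rel[s, avail]
                    total = w.sum()
                pick = rng.choice(len(avail), p=w / total)
                chosen.append(int(avail[pick]))
                avail = np.delete(avail, pick)
                w_avail = np.delete(w_avail, pick)
            # abundances: ranked lognormal deviates follow the draw order
            raw = np.sort(rng.lognormal(cfg.otu_abundance_mu,
                                        cfg.otu_abundance_sigma, size=k))[::-1]
            reads = np.maximum(1, np.round(raw / raw.sum() * cfg.culture_depth))
            row = np.zeros(len(otu_ids), dtype=np.int64)
            row[chosen] = reads.astype(np.int64)
            culture_rows.append(row)
            culture_ids.append(culture_id)
            richness_seen.append(k)
            ch = []
            for j in chosen:
                selected = (cfg.selection_strength > 0
                            and affinity[host_idx, j] > 0)
                ch.append((otu_ids[j], "selection" if selected else "lottery"))
            channels[culture_id] = ch
            src_row = source_meta.loc[src_id]
            meta_rows.append({
                "sample_id": culture_id,
                "kind": "culture",
                "station": station,
                "habitat": src_row["habitat"],
                "source_sample_id": src_id,
                "salinity": src_row["salinity"],
                "nitrite": src_row["nitrite"],
                "phosphate": src_row["phosphate"],
                "coord_x": src_row["coord_x"],
                "coord_y": src_row["coord_y"],
                "host_id": host,
            })
            host_idx += 1
    table = CountTable(tuple(culture_ids), otu_ids,
                       np.array(culture_rows, dtype=np.int64))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    mean_rich = float(np.mean(richness_seen))
    neutral = cfg.selection_strength == 0 and cfg.competition_strength == 0
    truth = GroundTruth(
        channels=channels,
        host_ids=hosts.culture_ids,
        otu_ids=otu_ids,
        affinity=affinity,
        mean_richness=mean_rich,
        true_m_at_depth=(mean_rich / cfg.culture_depth) if neutral else None,
    )
    return table, meta, truth


# ----------------------------------------------------------------------------
# Functions
# ----------------------------------------------------------------------------

def gen_functions(tree_newick: str, n_functions: int, seed: int) -> FunctionMap:
    """Clade-structured annotation: each function is carried by all tips
    under one randomly chosen internal node.  Nesting pairs are emitted for
    every strict clade containment between two functions."""
    rng = _rng(seed, _FUNCTIONS)
    tree = dendropy.Tree.get(data=tree_newick, schema="newick",
                             preserve_underscores=True)
    internals = [n for n in tree.preorder_node_iter()
                 if not n.is_leaf() and n is not tree.seed_node]
    if not internals:
        return FunctionMap({}, ())
    n_functions = min(n_functions, len(internals))
    picked = rng.choice(len(internals), size=n_functions, replace=False)
    clades: dict[str, frozenset[str]] = {}
    for rank, node_i in enumerate(sorted(picked)):
        tips = frozenset(l.taxon.label for l in internals[node_i].leaf_iter())
        clades[f"func_{rank + 1:02d}"] = tips
    assignments: dict[str, set[str]] = {}
    for fn, tips in clades.items():
        for tip in tips:
            assignments.setdefault(tip, set()).add(fn)
    nesting = []
    names = sorted(clades)
    for a in names:
        for b in names:
            if a != b and clades[a] < clades[b]:
                nesting.append((a, b))  # a is the narrower function
    return FunctionMap({k: frozenset(v) for k, v in assignments.items()},
                       tuple(nesting))


# ----------------------------------------------------------------------------
# Scenario bundle
# ----------------------------------------------------------------------------

@dataclass
class Bundle:
    cfg: ScenarioConfig
    tree_newick: str
    tree: PhyloDistances
    sources: CountTable
    cultures: CountTable
    frame: SampleFrame
    hosts: HostFrame
    fmap: FunctionMap
    truth: GroundTruth


def generate_scenario(cfg: ScenarioConfig) -> Bundle:
    """Run the full generator: tree, sources, hosts, cultures, functions."""
    newick = gen_tree(cfg.n_otus_pool, cfg.seed)
    tree = tree_to_distances(newick)
    sources, source_meta = gen_sources(cfg)
    hosts, affinity = gen_hosts(cfg, tree, sources)
    cultures, culture_meta, truth = gen_cultures(
        cfg, sources, source_meta, tree, hosts, affinity)
    frame = SampleFrame(pd.concat([source_meta, culture_meta]))
    fmap = gen_functions(newick, cfg.n_functions, cfg.seed)
    return Bundle(cfg, newick, tree, sources, cultures, frame, hosts, fmap, truth)


def write_bundle(bundle: Bundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(bundle.sources, out / "sources.tsv")
    write_count_table(bundle.cultures, out / "cultures.tsv")
    write_sample_frame(bundle.frame, out / "samples.tsv")
    (out / "tree.nwk").write_text(bundle.tree_newick + "\n", encoding="utf-8")
    write_function_map(bundle.fmap, out / "functions.tsv", out / "nesting.tsv")
    gd = pd.DataFrame(bundle.hosts.genetic_dist,
                      index=list(bundle.hosts.culture_ids),
                      columns=list(bundle.hosts.culture_ids))
    gd.to_csv(out / "host_distances.tsv", sep="\t", index_label="culture_id")
    bundle.hosts.traits.to_csv(out / "host_traits.tsv", sep="\t",
                               index_label="culture_id")
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.truth.to_json(), fh, indent=1)
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(bundle.cfg), fh, indent=1)
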
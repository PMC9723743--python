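"""Observed-vs-ensemble comparison machinery: per-replicate dataset means,
one-sided empirical exceedance counts, star coding, and per-replicate
variation partitioning.

Star coding (per procedure, for the distribution of replicate means around
the observed value): ``***`` when every replicate lies strictly to one side
of the observed value; ``**`` when between 1 and 10 replicates are equal to
the observed value or on its opposite side; ``ns`` otherwise.  The side is
the one opposite the bulk of the distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_data import CountTable, FunctionMap, PhyloDistances, SampleFrame
from .diversity import FIG5_INDICES, dataset_summary
from .null_models import LOTTERY, SWAP, RandomisedDataset, make_ensemble
from .ordination import varpart2
from .preprocess import rarefy

__all__ = [
    "EnsembleResult",
    "empirical_counts",
    "significance_code",
    "run_fig5",
    "run_fig6",
    "run_all",
    "EnsembleInvariantError",
]

COMPARE_INDICES = FIG5_INDICES + ("c_score", "c_score_unnormalised",
                                  "function_richness")


class EnsembleInvariantError(RuntimeError):
    """A replicate violated a null-model invariant (corrupt ensemble)."""


@dataclass(frozen=True)
class EnsembleResult:
    index_name: str
    observed: float
    randomised_means: tuple[float, ...]
    n_below: int
    n_equal: int
    n_above: int
    side: str  # 'lower' | 'upper': where the opposite-side count is taken
    significance_code: str  # '***' | '**' | 'ns'

    @property
    def n_more_extreme(self) -> int:
        """Replicates equal to or on the opposite side of the observed."""
        opposite = self.n_below if self.side == "upper" else self.n_above
        return opposite + self.n_equal


def empirical_counts(observed: float, randomised) -> tuple[int, int, int]:
    """Exact (n_below, n_equal, n_above) of the randomised values relative
    to the observed value; ties go to n_equal."""
    values = np.asarray(list(randomised), dtype=float)
    if values.size < 1:
        raise ValueError("need at least one randomised value")
    below = int((values < observed).sum())
    above = int((values > observed).sum())
    equal = int(values.size) - below - above
    return below, equal, above


def significance_code(n_below: int, n_equal: int, n_above: int) -> tuple[str, str]:
    """(side, code) from the empirical counts — a pure function.

    The side is chosen so the bulk of replicate values sits on it; the
    opposite-side-or-equal count then yields *** (0), ** (1..10) or ns.
    """
    side = "upper" if n_above >= n_below else "lower"
    opposite = n_below if side == "upper" else n_above
    n_extreme = opposite + n_equal
    if n_extreme == 0:
        code = "***"
    elif 1 <= n_extreme <= 10:
        code = "**"
    else:
        code = "ns"
    return side, code


def _make_result(name: str, observed: float, means: list[float]) -> EnsembleResult:
    below, equal, above = empirical_counts(observed, means)
    side, code = significance_code(below, equal, above)
    return EnsembleResult(name, observed, tuple(means), below, equal, above,
                          side, code)


def _check_replicate(obs: CountTable, rep: RandomisedDataset) -> None:
    t = rep.table
    if t.sample_ids != obs.sample_ids:
        raise EnsembleInvariantError(
            f"replicate {rep.replicate_index}: sample ids differ from observed")
    if not np.array_equal(t.sample_totals(), obs.sample_totals()):
        raise EnsembleInvariantError(
            f"replicate {rep.replicate_index}: per-sample totals changed")
    if rep.procedure == LOTTERY:
        if not np.array_equal((t.counts > 0).sum(axis=1),
                              (obs.counts > 0).sum(axis=1)):
            raise EnsembleInvariantError(
                f"replicate {rep.replicate_index}: per-sample richness changed")
    elif rep.procedure == SWAP:
        if not np.array_equal(t.otu_totals(), obs.otu_totals()):
            raise EnsembleInvariantError(
                f"replicate {rep.replicate_index}: OTU totals changed")
        if int((t.counts > 0).sum()) != int((obs.counts > 0).sum()):
            raise EnsembleInvariantError(
                f"replicate {rep.replicate_index}: matrix fill changed")


def run_fig5(
    observed: CountTable,
    ensembles: Mapping[str, Iterable[RandomisedDataset]],
    tree: PhyloDistances | None = None,
    fmap: FunctionMap | None = None,
    which: Iterable[str] | None = None,
) -> dict[str, dict[str, EnsembleResult]]:
    """Observed-vs-ensemble comparison of dataset-mean indices.

    ``ensembles`` maps a procedure label to a stream of replicates; the
    streams are consumed once and only per-replicate means are retained
    (constant memory in the replicate count).  Returns
    ``{procedure: {index_name: EnsembleResult}}``.
    """
    wanted = tuple(which) if which is not None else COMPARE_INDICES
    obs_summary = dataset_summary(observed, tree=tree, fmap=fmap, which=wanted)
    out: dict[str, dict[str, EnsembleResult]] = {}
    for procedure, stream in ensembles.items():
        means: dict[str, list[float]] = {k: [] for k in wanted}
        n_reps = 0
        for rep in stream:
            _check_replicate(observed, rep)
            summary = dataset_summary(rep.table, tree=tree, fmap=fmap, which=wanted)
            for k in wanted:
                means[k].append(summary.means.get(k, float("nan")))
            n_reps += 1
        if n_reps == 0:
            raise ValueError(f"ensemble {procedure!r} is empty")
        out[procedure] = {
            k: _make_result(k, obs_summary.means.get(k, float("nan")), means[k])
            for k in wanted
        }
    return out


def run_fig6(
    observed: CountTable,
    ensembles: Mapping[str, Iterable[RandomisedDataset]],
    X_host: pd.DataFrame,
    X_env: pd.DataFrame,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Variation partitioning of the observed dataset and of every replicate
    with identical variable sets and seeds; per-procedure mean +/- SD of the
    adjusted unique fractions and empirical counts vs the observed."""
    obs_vp = varpart2(observed, X_host, X_env, n_perm=n_perm, seed=seed)
    report: dict = {
        "observed": {
            "fractions": obs_vp.fractions,
            "adjusted": obs_vp.adjusted,
            "p_host": obs_vp.p_host,
            "p_env": obs_vp.p_env,
        },
        "procedures": {},
    }
    for procedure, stream in ensembles.items():
        host_fracs, env_fracs = [], []
        for rep in stream:
            _check_replicate(observed, rep)
            vp = varpart2(rep.table, X_host, X_env, n_perm=n_perm, seed=seed)
            host_fracs.append(vp.adjusted["host_unique"])
            env_fracs.append(vp.adjusted["env_unique"])
        h = np.asarray(host_fracs)
        e = np.asarray(env_fracs)
        hb, he, ha = empirical_counts(obs_vp.adjusted["host_unique"], h)
        eb, ee, ea = empirical_counts(obs_vp.adjusted["env_unique"], e)
        report["procedures"][procedure] = {
            "host_unique_mean": float(h.mean()),
            "host_unique_sd": float(h.std(ddof=1)) if len(h) > 1 else 0.0,
            "env_unique_mean": float(e.mean()),
            "env_unique_sd": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
            "host_counts": {"below": hb, "equal": he, "above": ha},
            "env_counts": {"below": eb, "equal": ee, "above": ea},
            "host_code": significance_code(hb, he, ha)[1],
            "env_code": significance_code(eb, ee, ea)[1],
            "n_replicates": len(host_fracs),
        }
    return report


# ----------------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------------

_REQUIRED_CONFIG = ("seed", "n_replicates")


def run_all(config: Mapping, outdir=None) -> dict:
    """Run simulate -> preprocess -> randomise -> indices -> neutral fit ->
    varpart -> compare on a synthetic scenario, fully determined by the
    config (which must name every seed)."""
    from .neutral_fit import fit_neutral, occurrence_frequencies
    from .synthetic_data import ScenarioConfig, generate_scenario

    for key in _REQUIRED_CONFIG:
        if key not in config:
            raise ValueError(f"config missing required key {key!r} "
                             "(no silent nondeterminism)")
    scenario_kwargs = dict(config.get("scenario", {}))
    scenario_kwargs["seed"] = int(config["seed"])
    cfg = ScenarioConfig(**scenario_kwargs)
    n_reps = int(config["n_replicates"])
    n_perm = int(config.get("n_perm", 199))
    depth = int(config.get("rarefaction_depth", 0))
    sweeps = int(config.get("n_sweeps", 100))

    bundle = generate_scenario(cfg)
    cultures = bundle.cultures
    if depth:
        cultures = rarefy(cultures, depth, seed=int(config["seed"]) + 1).table

    def ensembles():
        return {
            LOTTERY: make_ensemble(LOTTERY, cultures, bundle.frame, n_reps,
                                   int(config["seed"]), sources=bundle.sources),
            SWAP: make_ensemble(SWAP, cultures, bundle.frame, n_reps,
                                int(config["seed"]), n_sweeps=sweeps),
        }

    fig5 = run_fig5(cultures, ensembles(), tree=bundle.tree, fmap=bundle.fmap)

    stations = sorted({bundle.frame.station_of(s) for s in cultures.sample_ids})
    per_otu, _ = occurrence_frequencies(cultures, bundle.sources, bundle.frame,
                                        stations=set(stations))
    fit_depth = depth or cfg.culture_depth
    neutral = fit_neutral(per_otu, N=fit_depth)

    hosts = bundle.hosts
    culture_ids = list(cultures.sample_ids)
    host_of = {c: bundle.frame.data.loc[c, "host_id"] for c in culture_ids}
    hpos = {h: i for i, h in enumerate(hosts.culture_ids)}
    gsub = hosts.genetic_dist[np.ix_([hpos[host_of[c]] for c in culture_ids],
                                     [hpos[host_of[c]] for c in culture_ids])]
    from .ordination import pcnm
    host_vecs = pcnm(gsub).as_frame(index=culture_ids, prefix="phyloPCNM")
    n_host_vars = min(3, host_vecs.shape[1])
    X_host = host_vecs.iloc[:, :n_host_vars]
    env = bundle.frame.data.loc[culture_ids]
    from .ordination import drop_collinear
    X_env = drop_collinear(pd.DataFrame({
        "habitat_sediment": (env["habitat"] == "sediment").astype(float),
        "salinity": env["salinity"].astype(float),
        "log_nitrite": np.log1p(env["nitrite"].astype(float)),
    }, index=culture_ids))
    X_host = drop_collinear(X_host)
    fig6 = run_fig6(cultures, ensembles(), X_host, X_env,
                    n_perm=n_perm, seed=int(config["seed"]))

    report = {
        "config": {k: config[k] for k in sorted(config)},
        "fig5": {
            proc: {
                name: {
                    "observed": res.observed,
                    "mean_randomised": float(np.nanmean(res.randomised_means)),
                    "sd_randomised": float(np.nanstd(res.randomised_means)),
                    "n_below": res.n_below,
                    "n_equal": res.n_equal,
                    "n_above": res.n_above,
                    "side": res.side,
                    "code": res.significance_code,
                }
                for name, res in results.items()
            }
            for proc, results in fig5.items()
        },
        "neutral_fit": {
            "m": neutral.m,
            "N": neutral.N,
            "pseudo_r2": neutral.pseudo_r2,
            "n_otus_fit": neutral.n_otus_fit,
        },
        "fig6": fig6,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, allow_nan=True)
    return report
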
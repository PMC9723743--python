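"""Neutral community model fit: OTU occurrence frequencies across cultures
vs mean relative abundance in the source communities.

The predicted detection frequency of OTU i under migration parameter m and
local community size N reads, with detection limit d reads, is

    fhat_i = 1 - BetaCDF(d / N; N m p_i, N m (1 - p_i))

m is estimated by least squares over OTUs (coarse log-grid search followed
by bounded local refinement) and goodness of fit is Efron's pseudo R^2,
which may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import CountTable, SampleFrame

__all__ = [
    "NeutralFit",
    "occurrence_frequencies",
    "predict_frequencies",
    "fit_neutral",
    "pseudo_r2_efron",
]

M_BOUNDS = (1e-6, 1e3)


@dataclass(frozen=True)
class NeutralFit:
    m: float
    N: int
    detection_limit: int
    pseudo_r2: float
    per_otu: pd.DataFrame  # index otu_id, columns p, f, fhat
    n_otus_fit: int
    station_set: tuple[str, ...]
    unfittable_otus: tuple[str, ...]  # f > 0 but p = 0


def occurrence_frequencies(
    cultures: CountTable,
    sources: CountTable,
    frame: SampleFrame,
    stations: set[str] | None = None,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Per-OTU (p_i, f_i) over the included stations.

    f_i is the fraction of included cultures containing OTU i; p_i the mean
    relative source abundance across the included stations.  Returns the
    table restricted to OTUs with p > 0 or f > 0, plus the ids of OTUs that
    occur in cultures but are absent from every included source (cannot be
    fit).
    """
    culture_ids = [s for s in cultures.sample_ids
                   if stations is None or frame.station_of(s) in stations]
    if stations is not None:
        counts = {}
        for c in culture_ids:
            counts[frame.station_of(c)] = counts.get(frame.station_of(c), 0) + 1
        thin = [st for st, n in counts.items() if n < 2]
        if thin:
            raise ValueError(f"station(s) with < 2 cultures: {sorted(thin)}")
        for st in stations:
            if st not in counts:
                raise ValueError(f"station {st!r} has no cultures")
    source_ids = sorted({frame.source_of(c) for c in culture_ids})
    missing = [s for s in source_ids if s not in sources.sample_ids]
    if missing:
        raise ValueError(f"station source sample(s) missing: {missing}")
    sub_c = cultures.select_samples(culture_ids)
    sub_s = sources.select_samples(source_ids)
    f_by_otu = dict(zip(sub_c.otu_ids,
                        (sub_c.counts > 0).mean(axis=0)))
    rel = sub_s.counts / sub_s.counts.sum(axis=1, keepdims=True)
    p_by_otu = dict(zip(sub_s.otu_ids, rel.mean(axis=0)))
    otus = sorted(set(f_by_otu) | set(p_by_otu))
    rows = []
    for o in otus:
        p = float(p_by_otu.get(o, 0.0))
        f = float(f_by_otu.get(o, 0.0))
        if p > 0 or f > 0:
            rows.append((o, p, f))
    df = pd.DataFrame(rows, columns=["otu_id", "p", "f"]).set_index("otu_id")
    unfittable = tuple(df.index[(df["p"] == 0) & (df["f"] > 0)])
    return df, unfittable


def predict_frequencies(p: np.ndarray, m: float, N: int,
                        detection_limit: int = 1) -> np.ndarray:
    """Detection probability 1 - BetaCDF(d/N; Nmp, Nm(1-p))."""
    p = np.asarray(p, dtype=float)
    nm = N * m
    a = np.clip(nm * p, 1e-12, None)  # clamp against underflow
    b = np.clip(nm * (1.0 - p), 1e-12, None)
    return stats.beta.sf(detection_limit / N, a, b)


def pseudo_r2_efron(f, fhat) -> float:
    """Efron's pseudo R^2 = 1 - SSE/SST; negative when the model does worse
    than the mean, NaN when f has zero variance."""
    f = np.asarray(f, dtype=float)
    fhat = np.asarray(fhat, dtype=float)
    if f.shape != fhat.shape or f.size < 2:
        raise ValueError("f and fhat must be equal-length vectors (>= 2)")
    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    sse = float(((f - fhat) ** 2).sum())
    return 1.0 - sse / sst


def fit_neutral(
    per_otu: pd.DataFrame,
    N: int = 538,
    detection_limit: int = 1,
    stations: tuple[str, ...] = (),
) -> NeutralFit:
    """Least-squares fit of m on the OTUs with p > 0."""
    fit_df = per_otu[per_otu["p"] > 0]
    unfittable = tuple(per_otu.index[(per_otu["p"] == 0) & (per_otu["f"] > 0)])
    if len(fit_df) < 5:
        raise ValueError(f"need >= 5 OTUs with p > 0, have {len(fit_df)}")
    p = fit_df["p"].to_numpy()
    f = fit_df["f"].to_numpy()

    def sse(log10_m: float) -> float:
        fhat = predict_frequencies(p, 10.0 ** log10_m, N, detection_limit)
        return float(((f - fhat) ** 2).sum())

    lo, hi = np.log10(M_BOUNDS[0]), np.log10(M_BOUNDS[1])
    grid = np.linspace(lo, hi, 91)
    losses = [sse(g) for g in grid]
    best = int(np.argmin(losses))
    g_lo = grid[max(best - 1, 0)]
    g_hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(g_lo, g_hi), method="bounded")
    if not res.success:
        raise RuntimeError(f"m optimisation did not converge: {res}")
    m = float(10.0 ** res.x)
    fhat = predict_frequencies(p, m, N, detection_limit)
    table = fit_df.assign(fhat=fhat)
    return NeutralFit(
        m=m,
        N=N,
        detection_limit=detection_limit,
        pseudo_r2=pseudo_r2_efron(f, fhat),
        per_otu=table,
        n_otus_fit=len(fit_df),
        station_set=tuple(stations),
        unfittable_otus=unfittable,
    )
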
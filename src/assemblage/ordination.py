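"""Constrained correspondence analysis (CCA), PCNM spatial/phylogenetic
eigenvector construction, forward selection, VIF filtering and two-set
variation partitioning with permutation tests.

CCA follows the classical weighted-regression formulation: the community
table is chi-square standardised, conditioning variables are partialled out
by row-weighted regression, and the constrained inertia is the sum of
squares of the fitted values of the weighted regression of the transform on
the constraints.  Inertia decomposes exactly:

    total = conditioned + constrained + residual

Permutation p-values use (1 + #{F_perm >= F_obs}) / (1 + n_perm); with a
condition matrix, residuals of the reduced model are permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .core_data import CountTable, SampleFrame

__all__ = [
    "CcaResult",
    "VarpartResult",
    "PcnmResult",
    "cca",
    "permutation_test",
    "pcnm",
    "vif_filter",
    "forward_select",
    "varpart2",
    "sample_type_cca",
    "station_dummies",
]

_RANK_TOL = 1e-9
_REL_TOL = 1e-8


class CollinearityError(ValueError):
    """Raised for rank-deficient constraint matrices, naming the columns."""


@dataclass(frozen=True)
class CcaResult:
    total_inertia: float
    constrained_inertia: float
    conditioned_inertia: float
    residual_inertia: float
    r2: float  # constrained / (total - conditioned)
    eigenvalues: tuple[float, ...]
    rank: int  # rank of the constraint space
    n_samples: int
    condition_rank: int = 0
    permutation_p: float | None = None


@dataclass(frozen=True)
class VarpartResult:
    fractions: dict[str, float]  # raw R2: host_unique, env_unique, shared, residual
    adjusted: dict[str, float]   # permutation-adjusted R2 (may be negative)
    p_host: float
    p_env: float


@dataclass(frozen=True)
class PcnmResult:
    vectors: np.ndarray  # n x k orthonormal eigenvectors, eigenvalue-ordered
    eigenvalues: np.ndarray
    threshold: float

    def as_frame(self, index=None, prefix: str = "PCNM") -> pd.DataFrame:
        cols = [f"{prefix}{i + 1}" for i in range(self.vectors.shape[1])]
        return pd.DataFrame(self.vectors, index=index, columns=cols)


# ----------------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------------

def _as_matrix(X, n: int):
    if X is None:
        return None, []
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        M = X.to_numpy(dtype=float)
    elif isinstance(X, pd.Series):
        names = [str(X.name or "x")]
        M = X.to_numpy(dtype=float)[:, None]
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{j}" for j in range(M.shape[1])]
    if M.shape[0] != n:
        raise ValueError(f"constraint matrix has {M.shape[0]} rows, expected {n}")
    if np.isnan(M).any():
        raise ValueError("constraint matrix contains missing values")
    return M, names


def _response_matrix(Y) -> np.ndarray:
    if isinstance(Y, CountTable):
        M = Y.counts.astype(float)
    elif isinstance(Y, pd.DataFrame):
        M = Y.to_numpy(dtype=float)
    else:
        M = np.asarray(Y, dtype=float)
    if (M < 0).any():
        raise ValueError("response must be non-negative")
    M = M[:, M.sum(axis=0) > 0]  # empty species carry no inertia
    if (M.sum(axis=1) <= 0).any():
        raise ValueError("response rows must have positive totals")
    return M


def _chi_transform(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    return (P - E) / np.sqrt(E), r


def _weighted_basis(M: np.ndarray, r: np.ndarray,
                    project_out: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal basis of the row-weighted, centred constraint space."""
    means = r @ M
    Xw = (M - means) * np.sqrt(r)[:, None]
    if Xw.size == 0:
        return np.zeros((M.shape[0], 0))
    # rank cutoff is relative to the PRE-projection scale, so directions that
    # are numerically inside the projected-out span are not resurrected
    scale = float(np.linalg.norm(Xw, 2)) if Xw.shape[1] else 0.0
    if project_out is not None and project_out.shape[1]:
        Xw = Xw - project_out @ (project_out.T @ Xw)
    if scale <= 0:
        return np.zeros((M.shape[0], 0))
    U, s, _ = np.linalg.svd(Xw, full_matrices=False)
    rank = int((s > 1e-7 * scale).sum())
    return U[:, :rank]


def _check_full_rank(M: np.ndarray, names: list[str], r: np.ndarray) -> None:
    """Error naming dependent columns.  Columns that are constant (zero
    after weighted centring) are ignored; they carry no constraint."""
    means = r @ M
    Xw = (M - means) * np.sqrt(r)[:, None]
    norms = np.linalg.norm(Xw, axis=0)
    active = norms > _RANK_TOL * max(norms.max(), 1.0)
    cols = np.flatnonzero(active)
    basis = np.zeros((M.shape[0], 0))
    bad: list[str] = []
    for j in cols:
        v = Xw[:, j]
        res = v - basis @ (basis.T @ v)
        if np.linalg.norm(res) <= _RANK_TOL * np.linalg.norm(v):
            bad.append(names[j])
        else:
            basis = np.column_stack([basis, res / np.linalg.norm(res)])
    if bad:
        raise CollinearityError(f"collinear constraint column(s): {bad}")


def drop_collinear(X: pd.DataFrame, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Greedily keep a maximal linearly independent subset of columns
    (after centring, optionally row-weighted)."""
    M = X.to_numpy(dtype=float)
    r = np.full(M.shape[0], 1.0 / M.shape[0]) if weights is None else weights
    Xw = (M - r @ M) * np.sqrt(r)[:, None]
    basis = np.zeros((M.shape[0], 0))
    keep: list = []
    for j, col in enumerate(X.columns):
        v = Xw[:, j]
        nv = np.linalg.norm(v)
        if nv <= _RANK_TOL:
            continue
        res = v - basis @ (basis.T @ v)
        if np.linalg.norm(res) > _RANK_TOL * nv:
            basis = np.column_stack([basis, res / np.linalg.norm(res)])
            keep.append(col)
    return X[keep]


def _fit(Qbar: np.ndarray, r: np.ndarray, X: np.ndarray,
         Z: np.ndarray | None) -> tuple[float, float, float, np.ndarray, int, int]:
    total = float((Qbar ** 2).sum())
    if Z is not None and Z.shape[1]:
        Qz = _weighted_basis(Z, r)
    else:
        Qz = np.zeros((Qbar.shape[0], 0))
    proj_z = Qz @ (Qz.T @ Qbar)
    conditioned = float((proj_z ** 2).sum())
    Qres = Qbar - proj_z
    Qx = _weighted_basis(X, r, project_out=Qz)
    fitted = Qx @ (Qx.T @ Qres)
    constrained = float((fitted ** 2).sum())
    if Qx.shape[1]:
        s = np.linalg.svd(fitted, compute_uv=False)
        eig = s[s > _RANK_TOL * max(s[0], 1e-300)] ** 2
    else:
        eig = np.array([])
    return total, constrained, conditioned, eig, Qx.shape[1], Qz.shape[1]


def cca(Y, X, Z=None, check_rank: bool = True) -> CcaResult:
    """Constrained correspondence analysis of ``Y`` on ``X``, optionally
    partialling out ``Z``.

    ``r2`` is constrained inertia over total inertia after removing the
    conditioned fraction.  Raises :class:`CollinearityError` when ``X`` is
    rank-deficient after centring (constant columns are tolerated and carry
    no constraint).
    """
    M = _response_matrix(Y)
    Xm, xnames = _as_matrix(X, M.shape[0])
    Zm, _ = _as_matrix(Z, M.shape[0])
    Qbar, r = _chi_transform(M)
    if check_rank:
        _check_full_rank(Xm, xnames, r)
    total, constrained, conditioned, eig, q, zr = _fit(Qbar, r, Xm, Zm)
    residual = total - constrained - conditioned
    assert abs(total - (constrained + conditioned + residual)) <= _REL_TOL * max(total, 1.0)
    denom = total - conditioned
    r2 = constrained / denom if denom > _RANK_TOL else 0.0
    return CcaResult(
        total_inertia=total,
        constrained_inertia=constrained,
        conditioned_inertia=conditioned,
        residual_inertia=residual,
        r2=min(max(r2, 0.0), 1.0),
        eigenvalues=tuple(float(e) for e in eig),
        rank=q,
        n_samples=M.shape[0],
        condition_rank=zr,
    )


# ----------------------------------------------------------------------------
# permutation test
# ----------------------------------------------------------------------------

def _pseudo_f(constrained: float, residual: float, q: int, z: int, n: int) -> float:
    df_res = max(n - q - z - 1, 1)
    if q == 0 or residual <= 0:
        return np.inf if residual <= 0 and constrained > 0 else 0.0
    return (constrained / q) / (residual / df_res)


def permutation_test(Y, X, Z=None, n_perm: int = 199, seed: int = 0) -> float:
    """Permutation p-value for the (partial) CCA pseudo-F.

    Without ``Z`` the rows of ``Y`` are permuted and the model refitted;
    with ``Z`` the residuals of the reduced (condition-only) model are
    permuted in transform space.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    M = _response_matrix(Y)
    n = M.shape[0]
    Xm, _ = _as_matrix(X, n)
    Zm, _ = _as_matrix(Z, n)
    Qbar, r = _chi_transform(M)
    total, cons, cond, _, q, zr = _fit(Qbar, r, Xm, Zm)
    f_obs = _pseudo_f(cons, total - cons - cond, q, zr, n)
    count = 0
    if Zm is None or not Zm.shape[1]:
        for _ in range(n_perm):
            perm = rng.permutation(n)
            t_p, c_p, _, _, q_p, _ = _fit(Qbar[perm], r[perm], Xm, None)
            f_p = _pseudo_f(c_p, t_p - c_p, q_p, 0, n)
            if f_p >= f_obs:
                count += 1
    else:
        Qz = _weighted_basis(Zm, r)
        Qx = _weighted_basis(Xm, r, project_out=Qz)
        fitted_z = Qz @ (Qz.T @ Qbar)
        resid = Qbar - fitted_z
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Qp = fitted_z + resid[perm]
            tot_p = float((Qp ** 2).sum())
            cond_p = float(((Qz.T @ Qp) ** 2).sum()) if Qz.shape[1] else 0.0
            cons_p = float(((Qx.T @ Qp) ** 2).sum()) if Qx.shape[1] else 0.0
            f_p = _pseudo_f(cons_p, tot_p - cond_p - cons_p, q, zr, n)
            if f_p >= f_obs:
                count += 1
    return (1 + count) / (1 + n_perm)


# ----------------------------------------------------------------------------
# PCNM
# ----------------------------------------------------------------------------

def pcnm(dist: np.ndarray, truncation: float | None = None) -> PcnmResult:
    """Principal Coordinates of Neighbour Matrices.

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree) are replaced by four times the threshold; the
    truncated matrix is double-centred and eigendecomposed, and the
    eigenvectors with positive eigenvalues are returned in eigenvalue order.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square distance matrix over >= 3 points")
    if not np.allclose(D, D.T, atol=1e-10) or (D < 0).any():
        raise ValueError("distances must be symmetric and non-negative")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
        if truncation <= 0:
            raise ValueError("cannot derive a truncation threshold (all-zero MST)")
    W = np.where(D > truncation, 4.0 * truncation, D)
    np.fill_diagonal(W, 0.0)
    A = -0.5 * W ** 2
    H = np.eye(n) - np.ones((n, n)) / n
    G = H @ A @ H
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-8 * max(abs(vals).max(), 1.0)
    return PcnmResult(vectors=vecs[:, keep], eigenvalues=vals[keep],
                      threshold=truncation)


# ----------------------------------------------------------------------------
# VIF
# ----------------------------------------------------------------------------

def vif_filter(X: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Iteratively remove the column with the largest variance inflation
    factor until every VIF is <= threshold."""
    X = X.astype(float).copy()
    while X.shape[1] >= 2:
        vifs = {}
        for col in X.columns:
            others = X.drop(columns=[col]).to_numpy()
            design = np.column_stack([np.ones(len(X)), others])
            y = X[col].to_numpy()
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
            sst = float(((y - y.mean()) ** 2).sum())
            if sst == 0:
                vifs[col] = 1.0
                continue
            r2 = 1.0 - float((resid ** 2).sum()) / sst
            vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda c: vifs[c])
        if vifs[worst] <= threshold:
            break
        X = X.drop(columns=[worst])
    return X


# ----------------------------------------------------------------------------
# forward selection
# ----------------------------------------------------------------------------

def forward_select(
    Y,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_exit: float = 0.1,
    n_perm: int = 199,
    seed: int = 0,
) -> list[str]:
    """Stepwise forward selection of single-column variables by partial
    permutation tests; after each addition, included variables whose
    marginal (conditional) p exceeds ``p_exit`` are dropped.  Ties on p are
    broken by larger added inertia, then input order.  Variables collinear
    with the current selection are never co-selected."""
    M = _response_matrix(Y)
    n = M.shape[0]
    Qbar, r = _chi_transform(M)
    selected: list[str] = []
    seen_states: set[tuple[str, ...]] = set()
    rng = np.random.default_rng(seed)
    while True:
        state = tuple(selected)
        if state in seen_states:
            break
        seen_states.add(state)
        Zsel = candidates[selected] if selected else None
        best: tuple[float, float, int, str] | None = None
        for order, name in enumerate(candidates.columns):
            if name in selected:
                continue
            col = candidates[[name]]
            # rank guard: skip candidates inside the span of the selection
            Zb = _weighted_basis(Zsel.to_numpy(dtype=float), r) if Zsel is not None \
                else np.zeros((n, 0))
            if _weighted_basis(col.to_numpy(dtype=float), r,
                               project_out=Zb).shape[1] == 0:
                continue
            p = permutation_test(M, col, Z=Zsel, n_perm=n_perm,
                                 seed=int(rng.integers(2**31)))
            _, cons, _, _, _, _ = _fit(Qbar, r, col.to_numpy(dtype=float),
                                       Zsel.to_numpy(dtype=float) if Zsel is not None else None)
            key = (p, -cons, order, name)
            if best is None or key < best:
                best = key
        changed = False
        if best is not None and best[0] <= p_enter:
            selected.append(best[3])
            changed = True
        # backward pass
        for name in list(selected):
            others = [s for s in selected if s != name]
            p = permutation_test(
                M, candidates[[name]],
                Z=candidates[others] if others else None,
                n_perm=n_perm, seed=int(rng.integers(2**31)))
            if p > p_exit:
                selected.remove(name)
                changed = True
        if not changed:
            break
    return selected


# ----------------------------------------------------------------------------
# variation partitioning
# ----------------------------------------------------------------------------

def _r2_of_total(Qbar, r, X) -> float:
    total, cons, _, _, _, _ = _fit(Qbar, r, X, None)
    return cons / total


def _adjusted_r2_perm(M, Qbar, r, X, n_perm, rng) -> float:
    """Permutation-corrected R2: 1 - (1 - R2)/(1 - mean permuted R2)."""
    r2 = _r2_of_total(Qbar, r, X)
    perms = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(M.shape[0])
        perms[i] = _r2_of_total(Qbar[perm], r[perm], X)
    denom = 1.0 - perms.mean()
    return 1.0 - (1.0 - r2) / denom if denom > 1e-12 else float("nan")


def varpart2(Y, X_host, X_env, n_perm: int = 999, seed: int = 0) -> VarpartResult:
    """Two-set CCA variation partitioning into host-unique, environment-
    unique, shared and residual fractions of total inertia, with
    permutation-adjusted R2 and permutation significance of the unique
    fractions."""
    M = _response_matrix(Y)
    n = M.shape[0]
    Xh, hnames = _as_matrix(X_host, n)
    Xe, enames = _as_matrix(X_env, n)
    union = np.column_stack([Xh, Xe])
    Qbar, r = _chi_transform(M)
    _check_full_rank(union, hnames + enames, r)
    total, cons_full, _, _, _, _ = _fit(Qbar, r, union, None)
    r2_full = cons_full / total
    _, cons_hu, _, _, _, _ = _fit(Qbar, r, Xh, Xe)
    _, cons_eu, _, _, _, _ = _fit(Qbar, r, Xe, Xh)
    hu = cons_hu / total
    eu = cons_eu / total
    shared = r2_full - hu - eu
    fractions = {
        "host_unique": hu,
        "env_unique": eu,
        "shared": shared,
        "residual": 1.0 - r2_full,
    }
    rng = np.random.default_rng(seed)
    adj_full = _adjusted_r2_perm(M, Qbar, r, union, n_perm, rng)
    adj_h = _adjusted_r2_perm(M, Qbar, r, Xh, n_perm, rng)
    adj_e = _adjusted_r2_perm(M, Qbar, r, Xe, n_perm, rng)
    adjusted = {
        "host_unique": adj_full - adj_e,
        "env_unique": adj_full - adj_h,
        "shared": adj_h + adj_e - adj_full,
        "residual": 1.0 - adj_full,
    }
    p_host = permutation_test(M, Xh, Z=Xe, n_perm=max(n_perm, 99),
                              seed=int(rng.integers(2**31)))
    p_env = permutation_test(M, Xe, Z=Xh, n_perm=max(n_perm, 99),
                             seed=int(rng.integers(2**31)))
    return VarpartResult(fractions=fractions, adjusted=adjusted,
                         p_host=p_host, p_env=p_env)


# ----------------------------------------------------------------------------
# sample-type CCA
# ----------------------------------------------------------------------------

def station_dummies(frame: SampleFrame, sample_ids: list[str]) -> pd.DataFrame:
    stations = [frame.station_of(s) for s in sample_ids]
    levels = sorted(set(stations))
    data = {f"station_{lev}": [1.0 if s == lev else 0.0 for s in stations]
            for lev in levels[:-1]}  # drop last level: full-rank coding
    return pd.DataFrame(data, index=sample_ids)


def sample_type_cca(
    table: CountTable,
    frame: SampleFrame,
    use_incidence: bool = True,
    n_perm: int | None = 199,
    seed: int = 0,
) -> CcaResult:
    """Fraction of community variation attributable to the source-vs-culture
    distinction after conditioning on station.  Stations holding only one
    sample kind are dropped with a warning."""
    kinds = {s: str(frame.data.loc[s, "kind"]) for s in table.sample_ids}
    by_station: dict[str, set[str]] = {}
    for s in table.sample_ids:
        by_station.setdefault(frame.station_of(s), set()).add(kinds[s])
    good = {st for st, ks in by_station.items() if len(ks) == 2}
    bad = sorted(set(by_station) - good)
    if bad:
        warnings.warn(f"station(s) with a single sample kind dropped: {bad}",
                      stacklevel=2)
    keep = [s for s in table.sample_ids if frame.station_of(s) in good]
    if not keep:
        raise ValueError("no station holds both sample kinds")
    sub = table.select_samples(keep)
    Y = (sub.counts > 0).astype(float) if use_incidence else sub.counts
    X = pd.DataFrame(
        {"is_culture": [1.0 if kinds[s] == "culture" else 0.0 for s in keep]},
        index=keep)
    Z = station_dummies(frame, keep)
    result = cca(Y, X, Z=Z)
    if n_perm:
        p = permutation_test(Y, X, Z=Z, n_perm=n_perm, seed=seed)
        result = CcaResult(**{**result.__dict__, "permutation_p": p})
    return result
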
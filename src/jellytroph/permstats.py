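"""Distance matrices, permutational multivariate ANOVA, and SIMPER.

PERMANOVA partitions a distance matrix by a crossed fixed-factor design (up
to three factors with all interactions) using the direct multivariate
construction: with D the distance matrix, A = -D^2/2, and G = JAJ its
double-centered (Gower) form, the sum of squares of a model term is
trace(H_term G), where H_term is the sequential (Type I) projection increment
of that term's design columns. Pseudo-F = MS_term / MS_residual; significance
comes from unrestricted permutation of sample labels with the observed
statistic included in the null set (p = (#{F* >= F} + 1)/(n_perm + 1)), or
from exhaustive enumeration of all label orderings for tiny n. On Euclidean
distances with one factor this reproduces classical ANOVA exactly.

SIMPER decomposes the average between-group Bray-Curtis dissimilarity into
additive per-variable contributions: for groups A and B the contribution of
variable v is the cross-pair average of |x_iv - x_kv| / sum_w (x_iw + x_kw),
and the contributions sum to the average dissimilarity by construction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric: str  # euclidean | braycurtis
    transform: str  # log1p | none
    ids: tuple[str, ...] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _apply_transform(X: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log1p":
        return np.log1p(X)  # natural log of (1 + x)
    if transform == "none":
        return X
    raise ValueError(f"unknown transform {transform!r}")


def distance_matrix(data, metric: str = "braycurtis", transform: str = "none",
                    ) -> DistanceMatrix:
    """Pairwise distances after an elementwise transform.

    Bray-Curtis requires non-negative data; a pair of all-zero rows has an
    indeterminate Bray-Curtis distance and is defined here as 0 (identical
    emptiness) with a warning.
    """
    ids = None
    if isinstance(data, pd.DataFrame):
        ids = tuple(str(i) for i in data.index)
        X = data.to_numpy(float)
    else:
        X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two samples")
    if metric == "braycurtis" and np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative data")
    X = _apply_transform(X, transform)
    if metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif metric == "braycurtis":
        with np.errstate(invalid="ignore"):
            D = squareform(pdist(X, metric="braycurtis"))
        if np.isnan(D).any():
            warnings.warn("all-zero row pair(s): Bray-Curtis distance set to 0",
                          stacklevel=2)
            D = np.nan_to_num(D, nan=0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(values=D, metric=metric, transform=transform, ids=ids)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    return U[:, s > tol]


def _design_terms(design: pd.DataFrame, factors: Sequence[str]
                  ) -> list[tuple[str, np.ndarray]]:
    """Sequential term design blocks: mains in given order, then 2-way
    interactions (factor-order combinations), then the 3-way interaction."""
    dummies = {}
    for f in factors:
        lv = pd.get_dummies(design[f].astype(str))
        if lv.shape[1] < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        dummies[f] = lv.to_numpy(float)
    terms: list[tuple[str, np.ndarray]] = [(f, dummies[f]) for f in factors]
    for r in (2, 3):
        for combo in itertools.combinations(factors, r):
            if len(combo) > len(factors):
                continue
            cols = [dummies[f] for f in combo]
            block = cols[0]
            for c in cols[1:]:
                block = np.einsum("ij,ik->ijk", block, c).reshape(len(block), -1)
            terms.append(("*".join(combo), block))
    return terms


def _check_balanced(design: pd.DataFrame, factors: Sequence[str]) -> None:
    counts = design.groupby([design[f].astype(str) for f in factors]).size()
    full = math.prod(design[f].astype(str).nunique() for f in factors)
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError(
            "unbalanced multiway design: every factor-level combination must "
            "have the same number of samples (use separate one-way analyses)")


@dataclass
class PermanovaTable:
    table: pd.DataFrame  # term, df, SS, MS, pseudo_F, p
    n_perm: int
    seed: int | None
    exhaustive: bool
    degenerate: bool = False  # total SS ~ 0; statistics undefined

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def permanova(d: DistanceMatrix, design: pd.DataFrame,
              factors: Sequence[str] | None = None, n_perm: int = 999,
              seed: int | None = None, exhaustive: bool = False,
              ) -> PermanovaTable:
    """Sequential-SS PERMANOVA for 1-3 crossed fixed factors.

    ``design`` holds one column per factor (rows aligned with the distance
    matrix). Multiway designs must be balanced. ``exhaustive=True`` enumerates
    all n! label orderings (only for small n) instead of Monte Carlo sampling.
    """
    factors = list(factors or design.columns)
    if not 1 <= len(factors) <= 3:
        raise ValueError("between one and three factors supported")
    n = d.n
    if len(design) != n:
        raise ValueError("design rows must match distance matrix size")
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if len(factors) > 1:
        _check_balanced(design, factors)

    G = _gower_center(d.values)
    ss_total = float(np.trace(G))
    terms = _design_terms(design, factors)

    # Sequential projections: intercept first, then each term's increment.
    ones = np.ones((n, 1))
    Q_prev = _orthonormal_basis(ones)
    H_terms, dfs, names = [], [], []
    X_acc = ones
    for name, block in terms:
        X_acc = np.hstack([X_acc, block])
        Q_cur = _orthonormal_basis(X_acc)
        H = Q_cur @ Q_cur.T - Q_prev @ Q_prev.T
        df = Q_cur.shape[1] - Q_prev.shape[1]
        if df < 1:
            raise ValueError(f"term {name!r} adds no degrees of freedom "
                             "(confounded design)")
        H_terms.append(H)
        dfs.append(df)
        names.append(name)
        Q_prev = Q_cur
    H_res = np.eye(n) - Q_prev @ Q_prev.T
    df_res = n - Q_prev.shape[1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    degenerate = ss_total <= 1e-12
    def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(H * Gm)) for H in H_terms])
        ss_res = float(np.sum(H_res * Gm))
        ms_res = ss_res / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / np.array(dfs)) / ms_res
        return F, ss_res

    F_obs, ss_res = stats_for(G)
    ss_obs = np.array([float(np.sum(H * G)) for H in H_terms])

    if degenerate:
        p_vals = np.full(len(names), np.nan)
        F_obs = np.full(len(names), np.nan)
        n_used = 0
    elif exhaustive:
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        geq = np.zeros(len(names))
        count = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            Fp, _ = stats_for(G[np.ix_(idx, idx)])
            geq += (Fp >= F_obs - 1e-12)
            count += 1
        p_vals = geq / count
        n_used = count
    else:
        rng = np.random.default_rng(seed)
        geq = np.zeros(len(names))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Fp, _ = stats_for(G[np.ix_(idx, idx)])
            geq += (Fp >= F_obs - 1e-12)
        p_vals = (geq + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    rows = []
    for name, df, ss, F, p in zip(names, dfs, ss_obs, F_obs, p_vals):
        rows.append({"term": name, "df": df, "SS": ss, "MS": ss / df,
                     "pseudo_F": F, "p": p})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "MS": ss_res / df_res, "pseudo_F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "MS": np.nan, "pseudo_F": np.nan, "p": np.nan})
    return PermanovaTable(table=pd.DataFrame(rows), n_perm=n_used, seed=seed,
                          exhaustive=exhaustive, degenerate=degenerate)


@dataclass
class SimperTable:
    """Per-variable contributions to one group pair's average dissimilarity."""

    table: pd.DataFrame  # variable, average_contribution, pct, cum_pct
    group_a: str
    group_b: str
    overall_dissimilarity: float


def simper(data, groups: Sequence, transform: str = "none",
           variables: Sequence[str] | None = None) -> dict[tuple[str, str], SimperTable]:
    """Bray-Curtis SIMPER decomposition for every pair of groups.

    Contributions are additive: their sum equals the cross-pair average
    Bray-Curtis dissimilarity exactly. Variables are reported sorted by
    decreasing contribution with cumulative percentages.
    """
    if isinstance(data, pd.DataFrame):
        variables = variables or [str(c) for c in data.columns]
        X = data.to_numpy(float)
    else:
        X = np.asarray(data, float)
        variables = variables or [f"v{i}" for i in range(X.shape[1])]
    if np.any(X < 0):
        raise ValueError("SIMPER requires non-negative data")
    X = _apply_transform(X, transform)
    groups = np.asarray([str(g) for g in groups])
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("SIMPER needs at least two groups")
    out: dict[tuple[str, str], SimperTable] = {}
    for ga, gb in itertools.combinations(labels, 2):
        A = X[groups == ga]
        B = X[groups == gb]
        contribs = np.zeros(X.shape[1])
        n_pairs = 0
        for xa in A:
            for xb in B:
                denom = float(np.sum(xa + xb))
                if denom <= 0:
                    continue  # empty-vs-empty pair: zero dissimilarity
                contribs += np.abs(xa - xb) / denom
                n_pairs += 1
        n_total_pairs = len(A) * len(B)
        contribs = contribs / n_total_pairs if n_total_pairs else contribs
        overall = float(contribs.sum())
        if overall > 0:
            pct = 100.0 * contribs / overall
        else:
            pct = np.zeros_like(contribs)
        tab = pd.DataFrame({"variable": variables,
                            "average_contribution": contribs, "pct": pct})
        tab = tab.sort_values("average_contribution", ascending=False,
                              kind="stable").reset_index(drop=True)
        tab["cum_pct"] = tab["pct"].cumsum()
        out[(ga, gb)] = SimperTable(table=tab, group_a=ga, group_b=gb,
                                    overall_dissimilarity=overall)
    return out
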
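"""Ordination and permutation tests for community structure.

PCoA, PERMANOVA and PERMDISP are implemented from their definitions on the
Gower-centered dissimilarity matrix (McArdle-Anderson style projection
operators), because the analysis reports sequential (Type-I) partial R^2 per
term and order-robustness of the conclusions is itself a finding worth
re-checking. The permutation scheme is free permutation of sample rows (no
strata: only one mouse per cage is ever sampled, so cages are not blocks),
and p-values use the (1+b)/(1+m) convention so p is never zero.

PERMDISP follows the standard construction: embed by PCoA keeping real and
imaginary axes, measure each sample's distance to its *group centroid*
(positive-part squared distance minus the imaginary-part correction), then
permute group labels on the distances around a one-way ANOVA F.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import canonical_meta, design_matrix
from .exceptions import InvalidParameterError

_EPS = 1e-10


def _check_dissimilarity(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidParameterError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InvalidParameterError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise InvalidParameterError("dissimilarity matrix must have a zero diagonal")


def _gower(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported, not corrected)
    proportion_explained: np.ndarray  # per positive axis, relative to sum of positive eigenvalues
    neg_coordinates: np.ndarray  # imaginary-axis coordinates (for dispersion corrections)


def pcoa(D: pd.DataFrame | np.ndarray) -> PCoAResult:
    """Principal coordinates via eigendecomposition of the double-centered Gower matrix."""
    index = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(len(D))
    D = np.asarray(D, dtype=float)
    _check_dissimilarity(D)
    G = _gower(D)
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > _EPS
    neg = vals < -_EPS
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    neg_coords = vecs[:, neg] * np.sqrt(-vals[neg])
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(pd.DataFrame(coords, index=index, columns=cols), vals, prop, neg_coords)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _term_projectors(meta: pd.DataFrame, terms) -> tuple[list[np.ndarray], list[int], np.ndarray, int]:
    """Sequential-SS projection operators, per-term dfs, residual projector, residual df."""
    n = len(meta)
    X = np.ones((n, 1))
    H_prev = _hat(X)
    rank_prev = 1
    projectors, dfs = [], []
    for term in terms:
        cols = design_matrix(meta, [term], intercept=False, drop_first=True).to_numpy(float)
        X = np.hstack([X, cols])
        rank = np.linalg.matrix_rank(X)
        if rank == rank_prev:
            raise InvalidParameterError(f"model term {term!r} has no variation")
        H = _hat(X)
        projectors.append(H - H_prev)
        dfs.append(rank - rank_prev)
        H_prev, rank_prev = H, rank
    residual = np.eye(n) - H_prev
    return projectors, dfs, residual, n - rank_prev


def permanova(
    D: pd.DataFrame | np.ndarray,
    meta: pd.DataFrame,
    terms,
    n_perm: int = 999,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA with per-term partial R^2, pseudo-F and permutation p.

    ``permutations`` may supply explicit row permutations (m x n integer array),
    e.g. the full non-identity enumeration for an exact test; otherwise
    ``n_perm`` free permutations are drawn from ``seed``. Rows of ``D`` must be
    in the same order as ``meta``.
    """
    if isinstance(D, pd.DataFrame):
        if list(D.index) != list(meta.index):
            D = D.loc[meta.index, meta.index]
    D = np.asarray(D, dtype=float)
    _check_dissimilarity(D)
    meta = canonical_meta(meta)
    G = _gower(D)
    sst = np.trace(G)
    projectors, dfs, residual, df_res = _term_projectors(meta, terms)
    if df_res <= 0:
        raise InvalidParameterError("no residual degrees of freedom")

    def term_F(Gmat: np.ndarray) -> np.ndarray:
        ss_res = np.einsum("ij,ji->", residual, Gmat)
        ss = np.array([np.einsum("ij,ji->", P, Gmat) for P in projectors])
        return (ss / np.asarray(dfs)) / (ss_res / df_res), ss, ss_res

    F_obs, ss_obs, ss_res_obs = term_F(G)
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(len(D)) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
    exceed = np.zeros(len(terms))
    for p in permutations:
        Gp = G[np.ix_(p, p)]
        F_perm, _, _ = term_F(Gp)
        exceed += F_perm >= F_obs - 1e-12
    m = len(permutations)
    pvals = (1.0 + exceed) / (1.0 + m)
    out = pd.DataFrame(
        {
            "df": dfs + [df_res],
            "sum_sq": list(ss_obs) + [ss_res_obs],
            "partial_R2": list(ss_obs / sst) + [ss_res_obs / sst],
            "pseudo_F": list(F_obs) + [np.nan],
            "p": list(pvals) + [np.nan],
        },
        index=list(terms) + ["Residual"],
    )
    out.attrs["n_permutations"] = m
    return out


def dispersion_distances(D: pd.DataFrame | np.ndarray, groups) -> pd.Series:
    """Distance of each sample to its group centroid in the full PCoA embedding."""
    groups = pd.Series(np.asarray(groups), index=(D.index if isinstance(D, pd.DataFrame) else None))
    res = pcoa(D)
    pos = res.coordinates.to_numpy()
    neg = res.neg_coordinates
    dist = np.empty(len(groups))
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        if mask.sum() < 2:
            raise InvalidParameterError(f"group {g!r} has fewer than 2 samples")
        cpos = pos[mask].mean(axis=0)
        cneg = neg[mask].mean(axis=0) if neg.size else np.zeros(0)
        d2 = ((pos[mask] - cpos) ** 2).sum(axis=1)
        if neg.size:
            d2 = d2 - ((neg[mask] - cneg) ** 2).sum(axis=1)
        dist[mask] = np.sqrt(np.clip(d2, 0.0, None))
    return pd.Series(dist, index=groups.index, name="dist_to_centroid")


@dataclass
class PermdispResult:
    distances: pd.Series
    F: float
    p: float
    n_permutations: int


def permdisp(
    D: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> PermdispResult:
    """Homogeneity-of-dispersion test: ANOVA F on centroid distances, p by label permutation."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise InvalidParameterError("permdisp requires at least two groups")
    dist = dispersion_distances(D, groups)
    d = dist.to_numpy()

    def anova_F(labels: np.ndarray) -> float:
        groups_list = [d[labels == g] for g in np.unique(labels)]
        return stats.f_oneway(*groups_list).statistic

    F_obs = anova_F(groups)
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(len(d)) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
    exceed = 0
    for p in permutations:
        exceed += anova_F(groups[p]) >= F_obs - 1e-12
    m = len(permutations)
    return PermdispResult(dist, float(F_obs), (1.0 + exceed) / (1.0 + m), m)
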
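"""Nonparametric montage-level statistics.

Family-wise error control over channels (or channel x bin grids) uses
cluster-based Monte-Carlo permutation: element-wise t statistics are
thresholded at ``cluster_alpha``, supra-threshold elements are joined into
signed clusters through the adjacency relation (singletons allowed — the
minimum-neighbor requirement is zero on this sparse montage), the cluster
statistic is its size (member count, the max-size criterion), and the
null is the distribution of the maximum cluster size over random label
exchanges (independent groups), sign flips (paired), or behavioral-score
permutations (correlations).  Monte-Carlo p values carry the +1
correction, p = (b + 1) / (n_perm + 1), so they are valid and bounded
below by 1/(n_perm + 1).

Correlations are Spearman rank correlations transformed to t values via
t = rho * sqrt((n - 2) / (1 - rho^2)); partial rank correlations
residualize the rank-transformed variables on the rank-transformed
covariates before correlating.  Cluster effect sizes are the mean Cohen's
d (or mean rho) over cluster members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata, t as t_dist

from .montage import Adjacency

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "cluster_corrected_spearman",
    "partial_spearman",
    "cohens_d",
    "cohens_d_cluster",
    "grid_adjacency",
]

_T_CAP = 1e6  # stand-in for infinite t at |rho| = 1


@dataclass
class Cluster:
    members: tuple               # element indices
    polarity: int                # +1 / -1
    size: int
    p: float
    effect_size: float
    labels: tuple = ()

    @property
    def significant(self):
        return self.p < 0.05


@dataclass
class ClusterResult:
    clusters: list
    stat: np.ndarray             # element-wise observed t values
    elementwise: np.ndarray      # element-wise effect (d or rho)
    null_max_size: np.ndarray
    n_permutations: int
    cluster_alpha: float
    tail: str

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "tail": self.tail,
            "clusters": [
                {"members": list(c.labels or c.members), "polarity": c.polarity,
                 "size": c.size, "p": c.p, "effect_size": c.effect_size}
                for c in self.clusters],
        }


def _adj_matrix(adjacency, n_elements: int) -> sparse.csr_matrix:
    if isinstance(adjacency, Adjacency):
        m = adjacency.matrix
    else:
        m = np.asarray(adjacency, dtype=bool)
    if m.shape != (n_elements, n_elements):
        raise ValueError("adjacency shape does not match the number of elements")
    return sparse.csr_matrix(m)


def _clusters_from_mask(mask: np.ndarray, adj: sparse.csr_matrix):
    idx = np.where(mask)[0]
    if idx.size == 0:
        return []
    sub = adj[idx][:, idx]
    n, labels = connected_components(sub, directed=False)
    return [tuple(idx[labels == k]) for k in range(n)]


def _max_cluster_size(tvals: np.ndarray, tcrit: float, adj, signs) -> int:
    best = 0
    for s in signs:
        for comp in _clusters_from_mask(s * tvals > tcrit, adj):
            best = max(best, len(comp))
    return best


def _signs_for(tail: str):
    return {"two": (1, -1), "pos": (1,), "neg": (-1,)}[tail]


def _tcrit(alpha: float, df: int, tail: str) -> float:
    q = 1 - alpha / 2 if tail == "two" else 1 - alpha
    return float(t_dist.ppf(q, df))


def cohens_d(a: np.ndarray, b: np.ndarray, paired: bool = False) -> np.ndarray:
    """Element-wise Cohen's d (pooled SD; for paired data, d of differences)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if paired:
        d = a - b
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, d.mean(axis=0) / sd, np.nan)
    na, nb = a.shape[0], b.shape[0]
    sp = np.sqrt(((na - 1) * a.var(axis=0, ddof=1)
                  + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sp > 0, (a.mean(axis=0) - b.mean(axis=0)) / sp, np.nan)


def cohens_d_cluster(values_a, values_b, members, paired: bool = False) -> float:
    """Mean Cohen's d over cluster members; zero-SD members are skipped."""
    members = list(members)
    if not members:
        raise ValueError("cluster has no members")
    d = cohens_d(np.atleast_2d(values_a)[:, members],
                 np.atleast_2d(values_b)[:, members], paired=paired)
    if np.isnan(d).any():
        warnings.warn("skipping cluster member(s) with zero pooled SD",
                      RuntimeWarning, stacklevel=2)
    if np.isnan(d).all():
        return float("nan")
    return float(np.nanmean(d))


def _t_independent(a, b):
    na, nb = a.shape[0], b.shape[0]
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) \
        / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / denom, 0.0)
    return t


def _t_paired_from_d(d):
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, d.mean(axis=0) / (sd / np.sqrt(n)), 0.0)


def cluster_permutation_test(group_a, group_b, adjacency, *, paired: bool = False,
                             cluster_alpha: float = 0.05,
                             n_permutations: int = 1000, seed: int | None = None,
                             tail: str = "two",
                             labels=None) -> ClusterResult:
    """Cluster-based Monte-Carlo permutation test between two samples.

    ``group_a``/``group_b`` are (subjects, elements) arrays; for paired
    data both must have the same subject order (the null flips each
    pair's sign).  Elements may be channels or any flattened grid with a
    matching ``adjacency``.  Deterministic given ``seed`` and invariant
    to element ordering.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the element dimension")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired test needs equally many subjects per condition")
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("need at least 2 subjects (or pairs) per group")
    n_elem = a.shape[1]
    adj = _adj_matrix(adjacency, n_elem)
    signs = _signs_for(tail)
    rng = np.random.default_rng(seed)

    if paired:
        d = a - b
        # canonical subject order: results invariant to input row order
        d = d[np.lexsort(d.T[::-1])]
        n = d.shape[0]
        tobs = _t_paired_from_d(d)
        df = n - 1
        tcrit = _tcrit(cluster_alpha, df, tail)
        flips = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        msq = (d**2).mean(axis=0)
        mean_p = flips @ d / n                                  # (P, e)
        var_p = (msq[None, :] - mean_p**2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tperm = np.where(var_p > 0, mean_p / np.sqrt(var_p / n), 0.0)
    else:
        na, nb = a.shape[0], b.shape[0]
        # canonical order within each group (permutation-realization
        # invariance to subject ordering)
        X = np.concatenate([a[np.lexsort(a.T[::-1])],
                            b[np.lexsort(b.T[::-1])]], axis=0)
        tobs = _t_independent(a, b)
        df = na + nb - 2
        tcrit = _tcrit(cluster_alpha, df, tail)
        perms = np.array([rng.permutation(na + nb) for _ in range(n_permutations)])
        Xp = X[perms]                                            # (P, n, e)
        tperm = np.empty((n_permutations, n_elem))
        for p in range(n_permutations):
            tperm[p] = _t_independent(Xp[p, :na], Xp[p, na:])

    null = np.array([_max_cluster_size(tperm[p], tcrit, adj, signs)
                     for p in range(n_permutations)])
    ew = cohens_d(a, b, paired=paired)
    clusters = []
    for s in signs:
        for comp in _clusters_from_mask(s * tobs > tcrit, adj):
            p = float(((null >= len(comp)).sum() + 1) / (n_permutations + 1))
            eff = cohens_d_cluster(a, b, comp, paired=paired)
            clusters.append(Cluster(
                comp, s, len(comp), p, eff,
                tuple(labels[i] for i in comp) if labels is not None else ()))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters, tobs, ew, null, n_permutations,
                         cluster_alpha, tail)


def _std_ranks(x: np.ndarray) -> np.ndarray:
    r = np.apply_along_axis(rankdata, 0, x) if x.ndim > 1 else rankdata(x)
    r = r - r.mean(axis=0)
    sd = r.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, r / sd, 0.0)


def _residualize(z: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, z, rcond=None)
    return z - design @ beta


def _rho_to_t(rho: np.ndarray, n: int, warn: bool = True) -> np.ndarray:
    r = np.asarray(rho, dtype=float)
    capped = np.abs(r) >= 1 - 1e-12
    if capped.any() and warn:
        warnings.warn("|rho| = 1: capping the t transform", RuntimeWarning,
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    return np.where(capped, np.sign(r) * _T_CAP, t)


def cluster_corrected_spearman(x, y, adjacency, *, covariates=None,
                               cluster_alpha: float = 0.05,
                               n_permutations: int = 1000,
                               seed: int | None = None, tail: str = "two",
                               labels=None) -> ClusterResult:
    """Cluster-corrected Spearman correlation of per-channel x with scalar y.

    ``x`` is (subjects, channels), ``y`` (subjects,).  Per channel the
    Spearman rho is transformed to a t value and thresholded at
    ``cluster_alpha``; supra-threshold channels are clustered in space
    and compared to the maximum cluster size under permutations of the
    subject-to-y assignment.  With ``covariates`` (subjects, k) the rank
    correlations are partial (ranks residualized on rank covariates; the
    permutation exchanges the y residuals).  Cluster effect size is the
    mean rho over members.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n, n_elem = x.shape
    if y.shape != (n,):
        raise ValueError("y must be one value per subject")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    adj = _adj_matrix(adjacency, n_elem)
    signs = _signs_for(tail)
    rng = np.random.default_rng(seed)

    # canonical subject order (joint): permutation realization does not
    # depend on how the caller ordered the subjects
    order = np.lexsort(np.column_stack([y, x]).T[::-1])
    x, y = x[order], y[order]

    Rx = _std_ranks(x)
    ry = _std_ranks(y)
    n_cov = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        n_cov = cov.shape[1]
        if n <= n_cov + 2:
            raise ValueError("need n > number of covariates + 2")
        design = np.column_stack([np.ones(n), _std_ranks(cov)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("collinear covariates")
        Rx = _residualize(Rx, design)
        ry = _residualize(ry, design)

    def rho_of(yvec):
        denom = np.sqrt((Rx**2).sum(axis=0) * (yvec**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, Rx.T @ yvec / denom, 0.0)
        return r

    rho_obs = rho_of(ry)
    df = n - 2 - n_cov
    tobs = _rho_to_t(rho_obs, df + 2)
    tcrit = _tcrit(cluster_alpha, df, tail)

    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        tp = _rho_to_t(rho_of(ry[perms[p]]), df + 2, warn=False)
        null[p] = _max_cluster_size(tp, tcrit, adj, signs)

    clusters = []
    for s in signs:
        for comp in _clusters_from_mask(s * tobs > tcrit, adj):
            pval = float(((null >= len(comp)).sum() + 1) / (n_permutations + 1))
            clusters.append(Cluster(
                comp, s, len(comp), pval, float(np.mean(rho_obs[list(comp)])),
                tuple(labels[i] for i in comp) if labels is not None else ()))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters, tobs, rho_obs, null, n_permutations,
                         cluster_alpha, tail)


def partial_spearman(x, y, covariates=None) -> float:
    """Spearman correlation of x and y after removing rank covariates.

    All variables are rank-transformed; the covariates are linearly
    removed from the ranked x and y, and the residuals correlated.  With
    no covariates this reduces exactly to the ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    rx, ry = _std_ranks(x), _std_ranks(y)
    if (rx == 0).all() or (ry == 0).all():
        raise ValueError("constant input: correlation undefined")
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
        if x.size <= cov.shape[1] + 2:
            raise ValueError("need n > number of covariates + 2")
        design = np.column_stack([np.ones(x.size), _std_ranks(cov)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("collinear covariates")
        rx = _residualize(rx, design)
        ry = _residualize(ry, design)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom < 1e-12 * x.size:
        # a variable fully explained by the covariates has nothing left to
        # correlate: the partial association is zero by construction
        return 0.0
    return float(rx @ ry / denom)


def grid_adjacency(channel_adjacency, n_bins: int) -> sparse.csr_matrix:
    """Adjacency of a channels x bins grid, flattened channel-major.

    Elements are adjacent when they share the channel and sit in
    consecutive bins, or share the bin and are neighboring channels.
    """
    if isinstance(channel_adjacency, Adjacency):
        ca = channel_adjacency.matrix
    else:
        ca = np.asarray(channel_adjacency, dtype=bool)
    n_ch = ca.shape[0]
    eye_b = sparse.eye(n_bins, dtype=bool, format="csr")
    chain = sparse.diags([np.ones(n_bins - 1, dtype=bool)] * 2, [1, -1],
                         format="csr", dtype=bool)
    return (sparse.kron(sparse.csr_matrix(ca), eye_b)
            + sparse.kron(sparse.eye(n_ch, dtype=bool), chain)).tocsr()
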
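"""Ordination and variation partitioning.

Bray-Curtis dissimilarity feeds a nonmetric multidimensional scaling (NMDS)
ordination that minimizes Kruskal stress-1 by SMACOF-style majorization with
monotone (isotonic) regression of configuration distances on the observed
dissimilarities.  Variation partitioning decomposes the multivariate
explained variance of a feature matrix into unique and shared fractions of
2-3 predictor blocks using adjusted R-squared from redundancy analysis
(multivariate least squares), with marginal permutation F tests per block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.isotonic import IsotonicRegression

from .spatial import DistanceMatrix

__all__ = [
    "Ordination", "VarpartResult", "bray_curtis", "nmds", "encode_predictors",
    "redundancy_rsq", "varpart", "permutation_f_test",
]


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``d_ij = sum |x_i - x_j| / sum (x_i + x_j)`` over features; accepts a
    FeatureTable, DataFrame, or array of non-negative intensities.
    """
    if hasattr(table, "intensities"):
        df = table.intensities
    else:
        df = pd.DataFrame(table)
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("Bray-Curtis requires non-negative intensities")
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total intensity")
    d = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(list(df.index), d)


@dataclass
class Ordination:
    """NMDS solution: centred scores rotated to principal axes."""

    scores: pd.DataFrame
    stress: float
    converged: bool
    seed: int
    restarts: int
    stress_trace: list = field(default_factory=list)


def _pcoa_init(d: np.ndarray, k: int) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=0)
    g = a - row[None, :] - row[:, None] + a.mean()
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)[None, :]


def _stress1(d_conf: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_conf ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.sqrt(((d_conf - disparities) ** 2).sum() / denom))


def _nmds_single(d_obs: np.ndarray, x0: np.ndarray, max_iter: int, tol: float):
    """One NMDS descent; returns (config, stress, trace, converged)."""
    n = d_obs.shape[0]
    iu = np.triu_indices(n, 1)
    delta = d_obs[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    x = x0 - x0.mean(axis=0)
    best_x, best_stress = x, np.inf
    trace: list[float] = []
    converged = False
    rank_pos = np.arange(delta.size, dtype=float)
    for _ in range(max_iter):
        d_conf = squareform(pdist(x))
        dv = d_conf[iu]
        dhat = np.empty_like(dv)
        dhat[order] = iso.fit_transform(rank_pos, dv[order])
        stress = _stress1(dv, dhat)
        if stress >= best_stress - tol:
            converged = stress >= best_stress or (best_stress - stress) < tol
            if stress < best_stress:
                best_x, best_stress = x, stress
                trace.append(stress)
            break
        best_x, best_stress = x, stress
        trace.append(stress)
        # Guttman transform towards the disparities
        dhat_m = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_conf > 0, dhat_m / np.where(d_conf > 0, d_conf, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        x -= x.mean(axis=0)
    return best_x, best_stress, trace, converged


def nmds(dist: DistanceMatrix, k: int = 2, restarts: int = 20,
         max_iter: int = 300, seed: int = 0, tol: float = 1e-7) -> Ordination:
    """Best-of-restarts NMDS in ``k`` dimensions.

    Restart 0 starts from the principal-coordinates configuration; the rest
    from seeded random configurations.  The returned scores are centred and
    rotated to principal axes, with a deterministic sign convention.
    """
    d = dist.values
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(restarts, 1)):
        x0 = _pcoa_init(d, k) if r == 0 else rng.standard_normal((n, k))
        x, stress, trace, conv = _nmds_single(d, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, trace, conv)
    x, stress, trace, conv = best
    x = x - x.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(k):
        nz = np.flatnonzero(np.abs(x[:, j]) > 1e-12)
        if nz.size and x[nz[0], j] < 0:
            x[:, j] = -x[:, j]
    scores = pd.DataFrame(x, index=dist.labels,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return Ordination(scores, stress, conv, seed, restarts, trace)


def encode_predictors(block: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix for a predictor block (no intercept).

    Categorical columns become treatment contrasts with the alphabetically
    first level as reference; numeric columns pass through.
    """
    block = pd.DataFrame(block)
    cols = []
    for c in block.columns:
        s = block[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float)[:, None])
        else:
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float)[:, None])
    if not cols:
        raise ValueError("empty predictor block")
    return np.hstack(cols)


def redundancy_rsq(y, x) -> tuple[float, float]:
    """Redundancy-analysis R-squared of a multivariate response on predictors.

    ``y`` is column-centred; ``x`` (encoded, no intercept) is augmented with
    an intercept.  Returns ``(R2, adjusted R2)`` where the adjustment is
    Ezekiel's ``1 - (1 - R2) (n - 1) / (n - p - 1)``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    p = x.shape[1]
    if n <= p + 1:
        raise ValueError("need n > p + 1 samples")
    xi = np.hstack([np.ones((n, 1)), x])
    if np.linalg.matrix_rank(xi) < xi.shape[1]:
        raise ValueError("rank-deficient predictor matrix")
    yc = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xi, yc, rcond=None)
    fit = xi @ beta
    ss_tot = (yc ** 2).sum()
    if ss_tot <= 0:
        raise ValueError("response has zero variance")
    r2 = float((fit ** 2).sum() / ss_tot)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, adj


@dataclass
class VarpartResult:
    """Adjusted-R2 variation partitioning over named predictor blocks.

    ``adj_r2`` maps every non-empty block union (a sorted tuple of names) to
    its adjusted R2; ``fractions`` holds the Venn cells (unique and shared)
    solved by inclusion-exclusion; ``residual`` is 1 minus the full-model
    adjusted R2.  ``tests`` holds per-block marginal (block-alone) F and
    permutation p.
    """

    block_names: list
    adj_r2: dict
    r2: dict
    fractions: dict
    residual: float
    tests: dict
    n_perm: int
    seed: int

    def unique(self, name: str) -> float:
        return self.fractions[(name,)]


def varpart(y, blocks: dict, n_perm: int = 999, seed: int = 0) -> VarpartResult:
    """Partition the variance of ``y`` among 2-3 predictor blocks.

    ``blocks`` maps block name -> DataFrame of raw predictors (encoded
    internally).  Venn-cell fractions are solved from the adjusted R2 of all
    block unions; per-block marginal significance comes from
    :func:`permutation_f_test` on the block alone.
    """
    names = list(blocks)
    if not 2 <= len(names) <= 3:
        raise ValueError("varpart supports 2 or 3 blocks")
    y = np.asarray(y, dtype=float)
    encoded = {n: encode_predictors(b) for n, b in blocks.items()}
    subsets = []
    for r in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, r))
    adj_r2, r2 = {}, {}
    for s in subsets:
        x = np.hstack([encoded[n] for n in s])
        r2[s], adj_r2[s] = redundancy_rsq(y, x)
    # solve R(U) = sum of cells x_S over S intersecting U
    cells = subsets  # index cells by the same non-empty subsets
    a = np.zeros((len(subsets), len(cells)))
    for i, u in enumerate(subsets):
        for j, s in enumerate(cells):
            if set(s) & set(u):
                a[i, j] = 1.0
    sol = np.linalg.solve(a, np.array([adj_r2[s] for s in subsets]))
    fractions = {s: float(v) for s, v in zip(cells, sol)}
    residual = 1.0 - adj_r2[tuple(names)]
    rng = np.random.default_rng(seed)
    tests = {}
    for nme in names:
        f, p = permutation_f_test(y, encoded[nme], n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31 - 1)))
        tests[nme] = {"F": f, "p": p}
    return VarpartResult(names, adj_r2, r2, fractions, residual, tests,
                         n_perm, seed)


def permutation_f_test(y, x_block, n_perm: int = 999, seed: int = 0):
    """Marginal permutation F test of one predictor block.

    ``F = (R2/p) / ((1-R2)/(n-p-1))``; the null distribution comes from
    permuting the rows of ``y``; ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(x_block, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = y.shape[0], x.shape[1]

    def fstat(yy) -> float:
        r2, _ = redundancy_rsq(yy, x)
        r2 = min(r2, 1.0 - 1e-12)
        return (r2 / p) / ((1.0 - r2) / (n - p - 1))

    f_obs = fstat(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if fstat(y[perm]) >= f_obs:
            count += 1
    return float(f_obs), (1 + count) / (1 + n_perm)
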
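"""Co-occurrence networks over selected metabolic features.

Nodes are features (typically the set significant for geographic region);
edges connect feature pairs whose Spearman rank correlation across samples
meets a significance-equivalent threshold, keeping positive correlations
only.  Node attributes carry per-region mean normalized abundance profiles,
so regionally restricted clusters appear as connected components.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoocNetwork", "spearman_matrix", "critical_rho", "build_network",
    "region_profiles", "cooccurrence_network",
]

_EXACT_N_MAX = 8


@lru_cache(maxsize=None)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """Sorted Spearman rho values over all rank permutations (no ties)."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))
    return np.sort(rho)


def _exact_p_two_sided(rho: float, n: int) -> float:
    dist = _exact_rho_distribution(n)
    return float(np.mean(np.abs(dist) >= abs(rho) - 1e-12))


def spearman_matrix(table):
    """Spearman rank correlation (and p) between all feature pairs.

    Needs >= 3 samples and >= 2 features.  p-values use the t approximation;
    for n <= 8 without ties in either feature, the exact permutation
    distribution is used instead.  Constant features yield NaN rows/columns.
    """
    df = table.intensities if hasattr(table, "intensities") else pd.DataFrame(table)
    n, m = df.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if m < 2:
        raise ValueError("need at least 2 features")
    vals = df.to_numpy(dtype=float)
    constant = vals.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(vals)
    if m == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    if n <= _EXACT_N_MAX:
        ranks = pd.DataFrame(vals).rank()
        no_ties = (ranks.nunique() == n).to_numpy()
        for i in range(m):
            for j in range(i + 1, m):
                if no_ties[i] and no_ties[j] and not (constant[i] or constant[j]):
                    p[i, j] = p[j, i] = _exact_p_two_sided(rho[i, j], n)
    cols = df.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def critical_rho(n: int, alpha: float, two_sided: bool = True) -> float:
    """Smallest rho whose p-value is at or below ``alpha`` at sample size n.

    Exact enumeration over rank permutations for n <= 8, otherwise inverted
    from the t approximation.  The study's published network used the fixed
    constant 0.372 instead (pass it directly to :func:`build_network`).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n <= _EXACT_N_MAX:
        dist = _exact_rho_distribution(n)
        for r in np.unique(np.abs(dist)):
            tail = (np.mean(np.abs(dist) >= r - 1e-12) if two_sided
                    else np.mean(dist >= r - 1e-12))
            if tail <= alpha:
                return float(r)
        return np.inf
    q = 1.0 - alpha / 2.0 if two_sided else 1.0 - alpha
    t_crit = stats.t.ppf(q, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit ** 2))


@dataclass
class CoocNetwork:
    """Positive co-occurrence graph over features."""

    graph: nx.Graph
    nodes: pd.DataFrame
    edges: pd.DataFrame
    threshold: float
    n_samples: int

    @property
    def n_components(self) -> int:
        return int(self.nodes["component"].nunique())

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edge_list(self, path, sep: str = "\t") -> None:
        self.edges.to_csv(path, sep=sep, index=False)


def build_network(rho: pd.DataFrame, threshold: float,
                  positive_only: bool = True,
                  p: pd.DataFrame | None = None,
                  n_samples: int = 0) -> CoocNetwork:
    """Threshold a rho matrix into an undirected co-occurrence graph.

    An edge joins features i != j when ``rho_ij >= threshold`` (and
    ``rho_ij > 0`` if ``positive_only``); NaN correlations never form edges.
    Isolated nodes are retained and connected components labelled.
    """
    if not rho.index.equals(rho.columns):
        raise ValueError("rho matrix must be square with matching labels")
    g = nx.Graph()
    g.add_nodes_from(rho.index)
    edge_rows = []
    feats = list(rho.index)
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            r = rho.loc[a, b]
            if np.isnan(r) or r < threshold or (positive_only and r <= 0):
                continue
            attrs = {"rho": float(r)}
            if p is not None:
                attrs["p"] = float(p.loc[a, b])
            g.add_edge(a, b, **attrs)
            edge_rows.append({"feature_a": a, "feature_b": b, **attrs})
    comp = {}
    for label, members in enumerate(sorted(nx.connected_components(g),
                                           key=lambda s: sorted(s)[0])):
        for node in members:
            comp[node] = label
    nodes = pd.DataFrame({"feature_id": feats,
                          "component": [comp[f] for f in feats]}).set_index("feature_id")
    edges = pd.DataFrame(edge_rows, columns=["feature_a", "feature_b", "rho"]
                         + (["p"] if p is not None else []))
    return CoocNetwork(g, nodes, edges, float(threshold), int(n_samples))


def region_profiles(table, meta: pd.DataFrame, feature_ids) -> pd.DataFrame:
    """Mean abundance of each feature per geographic region.

    Returns a features x regions DataFrame of arithmetic means of the
    (normalized) intensities; raises if a region has no samples.
    """
    df = table.intensities if hasattr(table, "intensities") else pd.DataFrame(table)
    feature_ids = list(feature_ids)
    meta = meta.loc[df.index]
    regions = sorted(pd.unique(meta["region"].dropna().astype(str)))
    if any((meta["region"] == r).sum() == 0 for r in regions):
        raise ValueError("empty region")
    prof = df[feature_ids].groupby(meta["region"].astype(str)).mean().T
    prof.index.name = "feature_id"
    return prof[regions]


def cooccurrence_network(table, meta: pd.DataFrame, feature_ids,
                         threshold: float = 0.372,
                         positive_only: bool = True) -> CoocNetwork:
    """Spearman matrix + thresholding + per-region node profiles in one call.

    The default threshold is the study's published constant (0.372,
    equivalent to p < 0.01 at this sample size under the t approximation);
    use :func:`critical_rho` to recompute one from n and alpha.
    """
    feature_ids = list(feature_ids)
    sub = table.intensities[feature_ids] if hasattr(table, "intensities") else \
        pd.DataFrame(table)[feature_ids]
    rho, p = spearman_matrix(sub)
    net = build_network(rho, threshold, positive_only=positive_only, p=p,
                        n_samples=len(sub))
    prof = region_profiles(table, meta, feature_ids)
    net.nodes = net.nodes.join(prof)
    net.nodes["mean_abundance"] = sub.mean(axis=0)
    for fid in net.graph.nodes:
        for col in prof.columns:
            net.graph.nodes[fid][f"mean_{col}"] = float(prof.loc[fid, col])
        net.graph.nodes[fid]["mean_abundance"] = float(sub[fid].mean())
        net.graph.nodes[fid]["component"] = int(net.nodes.loc[fid, "component"])
    return net
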
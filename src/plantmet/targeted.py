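"""Targeted screening of known compounds in the unfiltered feature table.

Chemical standards (iridoid and phenylethanoid glycosides in the original
survey) are matched to features by retention-time and m/z windows; matched
intensities are then compared between undamaged and herbivore-damaged
leaves with Mann-Whitney U tests.  Matching runs on the *unfiltered* table:
QC-RSD filtering is designed for untargeted discovery and may well remove a
known compound that targeted screening should still find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TargetDefinition", "read_targets", "match_targets",
           "mann_whitney_u", "screen_targets"]


@dataclass(frozen=True)
class TargetDefinition:
    """A known compound and its expected chromatographic coordinates."""

    name: str
    rt: float  # minutes
    mz: float  # Daltons
    rt_tol: float = 0.20
    mz_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.rt_tol <= 0 or self.mz_tol <= 0:
            raise ValueError("tolerances must be positive")


def read_targets(path, sep: str = "\t") -> list[TargetDefinition]:
    """Read target definitions (name, rt, mz[, rt_tol, mz_tol]) from text."""
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, r in df.iterrows():
        kwargs = {}
        if "rt_tol" in df.columns and not pd.isna(r.get("rt_tol")):
            kwargs["rt_tol"] = float(r["rt_tol"])
        if "mz_tol" in df.columns and not pd.isna(r.get("mz_tol")):
            kwargs["mz_tol"] = float(r["mz_tol"])
        out.append(TargetDefinition(str(r["name"]), float(r["rt"]),
                                    float(r["mz"]), **kwargs))
    return out


def match_targets(table, targets) -> pd.DataFrame:
    """Match each target to features inside its RT / m/z window.

    A feature matches when ``|rt - expected| <= rt_tol`` and
    ``|mz - expected| <= mz_tol``.  All matches are reported, ranked by the
    combined normalized distance
    ``sqrt((d_rt/rt_tol)^2 + (d_mz/mz_tol)^2)``; rank 0 is the closest.
    Unmatched targets get a row with a missing feature id.
    """
    feats = table.features
    rows = []
    for t in targets:
        d_rt = (feats["rt"] - t.rt).abs()
        d_mz = (feats["mz"] - t.mz).abs()
        inside = (d_rt <= t.rt_tol) & (d_mz <= t.mz_tol)
        if not inside.any():
            rows.append({"compound": t.name, "feature_id": None,
                         "distance": np.nan, "rank": np.nan})
            continue
        dist = np.sqrt((d_rt[inside] / t.rt_tol) ** 2
                       + (d_mz[inside] / t.mz_tol) ** 2)
        for rank, (fid, d) in enumerate(dist.sort_values().items()):
            rows.append({"compound": t.name, "feature_id": fid,
                         "distance": float(d), "rank": rank})
    return pd.DataFrame(rows, columns=["compound", "feature_id", "distance", "rank"])


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent groups.

    Exact null distribution when both groups have <= 8 observations and no
    ties across groups; otherwise the tie-corrected normal approximation.
    Returns ``(U, p)`` with U computed for the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def screen_targets(table, meta: pd.DataFrame, targets) -> pd.DataFrame:
    """Match targets, then test damaged vs undamaged leaf intensities.

    ``table``/``meta`` should be replicate-averaged biological samples.  For
    each detected compound the closest matching feature is tested with an
    unpaired two-sided Mann-Whitney U between leaf-status groups.
    """
    matches = match_targets(table, targets)
    closest = matches[(matches["rank"] == 0)]
    intens = table.intensities
    status = meta.loc[intens.index, "leaf_status"]
    rows = []
    for t in targets:
        hit = closest[closest["compound"] == t.name]
        if hit.empty:
            rows.append({"compound": t.name, "detected": False,
                         "feature_id": None, "U": np.nan, "p": np.nan})
            continue
        fid = hit["feature_id"].iloc[0]
        vals = intens[fid]
        u, p = mann_whitney_u(vals[status == "undamaged"],
                              vals[status == "damaged"])
        rows.append({"compound": t.name, "detected": True, "feature_id": fid,
                     "U": u, "p": p})
    return pd.DataFrame(rows)
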
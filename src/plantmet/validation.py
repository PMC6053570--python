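"""Simulation-based validation experiments with known ground truth.

These routines quantify the statistical behaviour of the pipeline under the
synthetic study design: false-discovery control on null data, recovery of
planted effects, exactness of the QC filter, agreement of the numerical
primitives with brute-force oracles, and recovery of planted variance
fractions in variation partitioning.  They are used by the test suite and
the acceptance script; all sizes are arguments so callers choose their own
compute budget.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import feature_table as ft
from . import multivariate as mv
from . import spatial
from .cln import CLNSpec, fdr_bh, prepare_design, run_factor_analysis
from .network import spearman_matrix
from .spatial import DistanceMatrix
from .synthetic import SimulationConfig, generate_null_study, generate_study
from .targeted import mann_whitney_u

__all__ = [
    "preprocess_study", "null_fdr_simulation", "null_pvalue_uniformity",
    "effect_recovery", "qc_filter_exactness", "oracle_equivalence",
    "varpart_recovery", "nmds_stress_checks",
]


def preprocess_study(table, meta, qc_filter: bool = True):
    """normalize -> (QC filter) -> average; returns (table, leaf_meta, design)."""
    norm = ft.normalize_total_intensity(table)
    if qc_filter:
        qc_ids = meta.index[meta["role"] == ft.ROLE_QC]
        norm, _ = ft.qc_rsd_filter(norm, qc_ids)
    averaged, leaf_meta = ft.average_replicates(norm, meta)
    pops = leaf_meta.groupby("population")[["latitude", "longitude"]].first()
    axes = spatial.pcnm(spatial.euclidean_distance(pops))
    design = prepare_design(leaf_meta, axes.to_frame())
    return averaged, leaf_meta, design


def null_fdr_simulation(n_replicates: int = 50, n_features: int = 40,
                        factor: str = "region", seed: int = 0) -> dict:
    """Mean false-discovery proportion of q<0.20 calls on null studies.

    Every discovery on a null study is false, so the per-replicate FDP is
    ``V / max(R, 1)``; BH at q = 0.20 controls its expectation at 0.20.
    """
    fdps = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + rep, n_features=n_features,
                               n_rsd_violators=0)
        table, meta, _ = generate_null_study(cfg)
        averaged, _, design = preprocess_study(table, meta, qc_filter=False)
        res, _ = run_factor_analysis(averaged, design, CLNSpec(factor=factor))
        n_disc = int((res["q"] < 0.20).sum())
        fdps.append(1.0 if n_disc > 0 else 0.0)
    return {"mean_fdp": float(np.mean(fdps)),
            "n_replicates": n_replicates, "n_features": n_features}


def null_pvalue_uniformity(n_features: int = 60, n_replicates: int = 3,
                           factor: str = "region", seed: int = 0) -> dict:
    """Kolmogorov-Smirnov check of null p-values against Uniform(0, 1).

    p-values are pooled over several independent null studies: within one
    study all features share the realized design and the total-intensity
    normalization couples them weakly, so a single-study KS over-rejects;
    pooling across replicate studies restores (approximate) independence.
    """
    ps = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + rep, n_features=n_features,
                               n_rsd_violators=0)
        table, meta, _ = generate_null_study(cfg)
        averaged, _, design = preprocess_study(table, meta, qc_filter=False)
        res, _ = run_factor_analysis(averaged, design, CLNSpec(factor=factor))
        ps.append(res["p"].dropna().to_numpy())
    p = np.concatenate(ps)
    ks = stats.kstest(p, "uniform")
    return {"n_pvalues": int(p.size), "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue),
            "prop_p_lt_05": float(np.mean(p < 0.05))}


def effect_recovery(n_replicates: int = 3, seed: int = 0) -> dict:
    """Recovery of planted effects under the study-shaped default design.

    Returns region sensitivity at q<0.20, the fraction of region
    discoveries not planted for region, and the fraction of planted pH
    features whose fitted quadratic coefficients are sign-correct (with the
    planted truth reparameterized to the model's pH centring).
    """
    region_hits = region_planted = region_disc = region_unplanted = 0
    ph_ok = ph_total = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + rep)
        table, meta, truth = generate_study(cfg)
        averaged, leaf_meta, design = preprocess_study(table, meta)

        res, _ = run_factor_analysis(averaged, design, CLNSpec(factor="region"))
        planted = set(truth.affected("region")) & set(res.index)
        called = set(res.index[res["q"] < 0.20])
        region_hits += len(called & planted)
        region_planted += len(planted)
        region_disc += len(called)
        region_unplanted += len(called - planted)

        res_ph, fits_ph = run_factor_analysis(averaged, design,
                                              CLNSpec(factor="soil_ph"))
        shift = leaf_meta["soil_ph"].mean() - truth.ph_center
        for fid in set(truth.affected("ph")) & set(fits_ph):
            row = truth.features.loc[fid]
            b1_true = row["beta1"] + 2.0 * row["beta2"] * shift
            coefs = dict(zip(fits_ph[fid].pos_fit_full.colnames,
                             fits_ph[fid].pos_fit_full.beta))
            ok = (np.sign(coefs.get("ph_c", 0.0)) == np.sign(b1_true)
                  and np.sign(coefs.get("ph_c2", 0.0)) == np.sign(row["beta2"]))
            ph_ok += bool(ok)
            ph_total += 1
    return {
        "region_sensitivity": region_hits / max(region_planted, 1),
        "region_unplanted_fraction": region_unplanted / max(region_disc, 1),
        "ph_sign_correct_rate": ph_ok / max(ph_total, 1),
        "n_replicates": n_replicates,
    }


def qc_filter_exactness(n_seeds: int = 100, n_features: int = 120,
                        n_violators: int = 20, seed: int = 0) -> dict:
    """Planted RSD violators must be removed exactly, across many seeds."""
    false_removals = false_retentions = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(seed=seed + s, n_features=n_features,
                               n_rsd_violators=n_violators,
                               n_region_features=10, n_ph_features=4,
                               n_habitat_features=2, n_leafarea_features=2)
        table, meta, truth = generate_study(cfg)
        norm = ft.normalize_total_intensity(table)
        qc_ids = meta.index[meta["role"] == ft.ROLE_QC]
        _, removed = ft.qc_rsd_filter(norm, qc_ids)
        removed_set = set(removed["feature_id"])
        planted = set(truth.rsd_violators)
        false_removals += len(removed_set - planted)
        false_retentions += len(planted - removed_set)
    return {"false_removals": false_removals,
            "false_retentions": false_retentions, "n_seeds": n_seeds}


def _bray_oracle(x, y):
    return np.abs(x - y).sum() / (x + y).sum()


def oracle_equivalence(seed: int = 0) -> dict:
    """Max absolute error of each primitive against brute-force oracles."""
    rng = np.random.default_rng(seed)
    errors = {}

    # Bray-Curtis vs the hand formula
    mat = rng.gamma(2.0, 5.0, size=(8, 6))
    d = mv.bray_curtis(mat).values
    err = 0.0
    for i, j in itertools.combinations(range(8), 2):
        err = max(err, abs(d[i, j] - _bray_oracle(mat[i], mat[j])))
    errors["bray_curtis"] = err

    # BH q-values vs the manual step-up
    p = rng.uniform(size=25)
    order = np.argsort(p)
    manual = np.empty_like(p)
    running = 1.0
    for rank in range(p.size, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * p.size / rank)
        manual[i] = running
    errors["fdr_bh"] = float(np.abs(fdr_bh(p) - manual).max())

    # exact Mann-Whitney vs enumeration
    a = list(rng.normal(size=4))
    b = list(rng.normal(size=4))
    u_obs, p_mw = mann_whitney_u(a, b)
    pooled = sorted(a + b)
    hits = total = 0
    u_alt = len(a) * len(b) - u_obs
    for combo in itertools.combinations(range(8), 4):
        aa = [pooled[i] for i in combo]
        bb = [pooled[i] for i in range(8) if i not in combo]
        u = sum(1 for x in aa for y in bb if x > y)
        total += 1
        if min(u, 16 - u) <= min(u_obs, u_alt):
            hits += 1
    errors["mann_whitney_exact_p"] = abs(p_mw - hits / total)

    # Spearman rho vs the rank-difference formula (no ties)
    x = rng.permutation(9).astype(float)
    y = rng.permutation(9).astype(float)
    rho, _ = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_hand = 1 - 6 * ((rx - ry) ** 2).sum() / (9 * 80)
    errors["spearman_rho"] = abs(rho.loc["x", "y"] - rho_hand)

    # PCNM vs brute-force double-centred eigendecomposition
    coords = pd.DataFrame({"latitude": rng.uniform(54, 58, 8),
                           "longitude": rng.uniform(8, 13, 8)})
    dist = spatial.euclidean_distance(coords)
    axes = spatial.pcnm(dist)
    w = dist.values.copy()
    w[w > axes.truncation] = 4 * axes.truncation
    n = w.shape[0]
    jmat = np.eye(n) - np.ones((n, n)) / n
    g = jmat @ (-0.5 * w ** 2) @ jmat
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9 * abs(vals[0])
    err = float(np.abs(axes.eigenvalues - vals[keep]).max())
    expected = vecs[:, keep] * np.sqrt(vals[keep])
    for j in range(expected.shape[1]):
        err = max(err, min(
            float(np.abs(axes.scores[:, j] - expected[:, j]).max()),
            float(np.abs(axes.scores[:, j] + expected[:, j]).max())))
    errors["pcnm"] = err

    # adjusted R^2 vs manual OLS + Ezekiel
    yy = rng.normal(size=(12, 3))
    xx = rng.normal(size=(12, 2))
    r2, adj = mv.redundancy_rsq(yy, xx)
    xi = np.hstack([np.ones((12, 1)), xx])
    yc = yy - yy.mean(0)
    fit = xi @ np.linalg.lstsq(xi, yc, rcond=None)[0]
    r2_hand = (fit ** 2).sum() / (yc ** 2).sum()
    adj_hand = 1 - (1 - r2_hand) * 11 / 9
    errors["adjusted_r2"] = float(max(abs(r2 - r2_hand), abs(adj - adj_hand)))

    errors = {k: float(v) for k, v in errors.items()}
    errors["max_abs_error"] = max(errors.values())
    return errors


def varpart_recovery(n: int = 500, shares=(0.05, 0.08), n_features: int = 20,
                     seed: int = 0) -> dict:
    """Recovery of planted variance shares by two orthogonal blocks.

    Y mixes two exactly orthonormalized latent predictors scaled so block 1
    and block 2 carry the requested fractions of every feature's variance.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = shares
    z1 = rng.standard_normal(n)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = rng.standard_normal(n)
    z2 -= z1 * (z1 @ z2) / (z1 @ z1)
    z2 = (z2 - z2.mean()) / z2.std()
    noise = rng.standard_normal((n, n_features))
    y = (np.sqrt(s1) * z1[:, None] + np.sqrt(s2) * z2[:, None]
         + np.sqrt(1 - s1 - s2) * noise)
    vp = mv.varpart(y, {"b1": pd.DataFrame(z1), "b2": pd.DataFrame(z2)},
                    n_perm=99, seed=seed)
    return {"unique_b1": vp.fractions[("b1",)],
            "unique_b2": vp.fractions[("b2",)],
            "target_b1": s1, "target_b2": s2, "n": n}


def nmds_stress_checks(n: int = 15, seed: int = 0) -> dict:
    """Zero-stress limit on an exactly embeddable configuration plus the
    monotone-trace property on a non-trivial dissimilarity."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ord_planar = mv.nmds(DistanceMatrix(list(range(n)), d), k=2,
                         restarts=4, seed=seed)
    mat = rng.gamma(2.0, 5.0, size=(n, 12))
    ord_rough = mv.nmds(mv.bray_curtis(mat), k=2, restarts=4, seed=seed)
    trace = np.asarray(ord_rough.stress_trace)
    return {"planar_stress": float(ord_planar.stress),
            "trace_monotone": bool((np.diff(trace) <= 1e-12).all()),
            "rough_stress": float(ord_rough.stress)}
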
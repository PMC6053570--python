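"""Conditional log-normal (two-part hurdle) modelling of metabolic features.

Untargeted LC-MS feature intensities are non-negative with many exact zeros
(features absent or below detection).  The conditional log-normal model
splits each feature into

* a **binary part**: presence/absence regressed on the factor of interest
  plus covariates (logit link), and
* a **positive part**: log intensity, conditional on presence, regressed on
  the same terms with plant-within-population random intercepts
  (:mod:`plantmet._lmm`), fitted by maximum likelihood.

Because the likelihood factorizes, the likelihood-ratio statistics of the
two parts add, as do their degrees of freedom; each factor is tested by the
combined LR against a chi-squared reference, and p-values across features
are converted to q-values by Benjamini-Hochberg.  Tukey post hoc contrasts
on the positive-part scale are available for categorical factors.

Every analysis corrects for log leaf area and soil pH (linear + quadratic,
centred), except when the factor of interest is that covariate itself.
The binary part uses no random effects: frequentist ML logistic mixed
models are not estimable at this design size, so presence is modelled with
fixed effects only, and perfect separation drops the binary contribution
for that feature (degrees of freedom then come from the positive part
alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._lmm import LMMFit, _drop_collinear, fit_nested_lmm

__all__ = [
    "CLNSpec", "CLNFit", "FACTORS", "prepare_design", "eligibility",
    "fit_cln", "combined_lr_test", "fdr_bh", "tukey_posthoc",
    "run_factor_analysis", "significance_summary",
]

#: factor name -> (kind, design columns)
FACTORS = {
    "region": ("categorical", ["region"]),
    "distance": ("continuous", ["PCNM1", "PCNM2"]),
    "habitat": ("categorical", ["habitat"]),
    "light": ("categorical", ["light"]),
    "phenology": ("categorical", ["phenology"]),
    "leaf_status": ("categorical", ["leaf_status"]),
    "soil_ph": ("continuous", ["ph_c", "ph_c2"]),
    "leaf_area": ("continuous", ["log_area_c"]),
}

_COVARIATE_COLS = ["log_area_c", "ph_c", "ph_c2"]


@dataclass
class CLNSpec:
    """Analysis settings: factor of interest, test method, eligibility.

    ``method`` selects how the two parts are turned into one p-value:

    * ``"fisher_f"`` (default): conditional F test of the factor in the
      positive part with between-within (containment) denominator degrees
      of freedom, combined with the binary-part likelihood-ratio p by
      Fisher's method.  This keeps the test calibrated at the design's
      actual replication level (factors that vary between populations are
      judged against between-population variation, not the leaf count).
    * ``"lr_chi2"``: additive likelihood-ratio statistic over both parts
      against chi-squared with the summed degrees of freedom (the plain
      factorized-likelihood combination; anticonservative for
      population-level factors at this design size).
    """

    factor: str = "region"
    min_positive_per_level: int = 2
    min_total_positives: int = 5
    include_binary_part: bool = True
    method: str = "fisher_f"

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}; "
                             f"choose from {sorted(FACTORS)}")
        if self.method not in ("fisher_f", "lr_chi2"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def kind(self) -> str:
        return FACTORS[self.factor][0]

    @property
    def factor_cols(self) -> list[str]:
        return FACTORS[self.factor][1]

    @property
    def covariate_cols(self) -> list[str]:
        return [c for c in _COVARIATE_COLS if c not in self.factor_cols]


def prepare_design(meta: pd.DataFrame, pcnm_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Leaf-level design frame with centred covariates and PCNM axes.

    ``meta`` is replicate-averaged metadata (one row per leaf).  Soil pH is
    centred at the sample mean; leaf area enters as centred log area.  PCNM
    axes (indexed by population) are merged in when provided.
    """
    d = meta.copy()
    d["ph_c"] = d["soil_ph"] - d["soil_ph"].mean()
    d["ph_c2"] = d["ph_c"] ** 2
    d["log_area_c"] = np.log(d["leaf_area_cm2"])
    d["log_area_c"] -= d["log_area_c"].mean()
    if pcnm_scores is not None:
        for col in pcnm_scores.columns[:2]:
            d[col] = d["population"].map(pcnm_scores[col]).astype(float)
    return d


def _design_matrix(design: pd.DataFrame, cat_cols, num_cols):
    """Intercept + treatment-coded dummies + numeric columns."""
    cols = [np.ones(len(design))]
    names = ["Intercept"]
    for c in cat_cols:
        s = design[c].astype(str)
        levels = sorted(pd.unique(s))
        for lev in levels[1:]:
            cols.append((s == lev).to_numpy(float))
            names.append(f"{c}[{lev}]")
    for c in num_cols:
        cols.append(design[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


def _factor_terms(spec: CLNSpec):
    if spec.kind == "categorical":
        return spec.factor_cols, []
    return [], spec.factor_cols


def eligibility(values: np.ndarray, design: pd.DataFrame, spec: CLNSpec):
    """Decide whether a feature supports the model for this factor.

    Eligible iff the feature has at least ``min_total_positives`` positive
    observations and, for a categorical factor, at least
    ``min_positive_per_level`` positives in every factor level.
    """
    values = np.asarray(values, dtype=float)
    pos = values > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        return False, "all_zero"
    if n_pos < spec.min_total_positives:
        return False, "insufficient_positives"
    if spec.kind == "categorical":
        col = design[spec.factor_cols[0]].astype(str)
        for lev in sorted(pd.unique(col)):
            if int(pos[(col == lev).to_numpy()].sum()) < spec.min_positive_per_level:
                return False, f"level_without_enough_positives:{lev}"
    return True, "ok"


@dataclass
class CLNFit:
    """Per-feature two-part fit and combined factor test."""

    feature_id: str
    factor: str
    statistic: float
    df: int
    p: float
    p_bin: float
    p_pos: float
    lr_bin: float
    df_bin: int
    df_pos: int
    n_pos: int
    binary_degenerate: bool
    binary_dropped: bool
    converged: bool
    lr_pos: float = float("nan")
    f_pos: float = float("nan")
    df_denom: float = float("nan")
    pos_fit_full: LMMFit | None = field(default=None, repr=False)
    design_pos: pd.DataFrame | None = field(default=None, repr=False)


def _fit_logit(z: np.ndarray, x: np.ndarray, names):
    x, names = _drop_collinear(x, list(names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(z, x).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise PerfectSeparationError("logit did not converge")
    if np.max(np.abs(res.params)) > 30:
        raise PerfectSeparationError("quasi-separation")
    return float(res.llf), x.shape[1]


def combined_lr_test(ll_full, ll_reduced, df: int):
    """Combined likelihood-ratio test over the factorized parts.

    ``ll_full`` / ``ll_reduced`` are sequences of per-part log-likelihoods;
    the statistic is ``2 * sum(ll_full - ll_reduced)`` against chi2(df).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    lr = 2.0 * (float(np.sum(ll_full)) - float(np.sum(ll_reduced)))
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return lr, df, p


def _column_stratum(col: np.ndarray, pop: np.ndarray, plant: np.ndarray) -> int:
    """Design stratum whose variation dominates a column.

    0 = constant (intercept), 1 = between populations, 2 = between plants
    within populations, 3 = between leaves within plants.  The sum-of-squares
    decomposition assigns each column the stratum carrying its largest
    variance share; for classical categorical designs this reduces to the
    level at which the column varies, while near-population-level covariates
    (e.g. soil pH with small within-site scatter) are judged against
    between-population replication.  Ties break towards the innermost level.
    """
    s = pd.Series(np.asarray(col, dtype=float))
    grand = s.mean()
    pop_mean = s.groupby(pop).transform("mean")
    plant_mean = s.groupby(plant).transform("mean")
    ss = np.array([
        ((pop_mean - grand) ** 2).sum(),
        ((plant_mean - pop_mean) ** 2).sum(),
        ((s - plant_mean) ** 2).sum(),
    ])
    if ss.sum() <= 1e-12 * max(s.abs().max() ** 2, 1.0):
        return 0
    return int(3 - np.argmax(ss[::-1]))


def _bw_denominator_df(x: np.ndarray, names: list, factor_names: list,
                       pop: np.ndarray, plant: np.ndarray) -> tuple[int, float]:
    """Between-within (containment) denominator df for the factor columns.

    Counts parameters per design stratum and assigns the factor the df of
    the innermost stratum it occupies:
    ``denDF_l = N_l - N_{l-1} - q_l`` with strata sizes N = (1, #pops,
    #plants, #leaves) and q_l the fixed-effect parameters in stratum l.
    """
    strata = {n: _column_stratum(x[:, j], pop, plant)
              for j, n in enumerate(names)}
    q = {1: 0, 2: 0, 3: 0}
    for n, l in strata.items():
        if l > 0:
            q[l] += 1
    n_lev = {0: 1, 1: pd.Series(pop).nunique(), 2: pd.Series(plant).nunique(),
             3: x.shape[0]}
    level = max((strata[n] for n in factor_names if n in strata), default=0)
    if level == 0:
        return 0, 1.0
    den = n_lev[level] - n_lev[level - 1] - q[level]
    return level, float(max(den, 1))


def _fisher_combine(p_values) -> float:
    ps = [min(max(p, 1e-300), 1.0) for p in p_values if np.isfinite(p)]
    if not ps:
        return np.nan
    if len(ps) == 1:
        return float(ps[0])
    x = -2.0 * float(np.sum(np.log(ps)))
    return float(stats.chi2.sf(x, 2 * len(ps)))


def fit_cln(values: np.ndarray, design: pd.DataFrame, spec: CLNSpec,
            feature_id: str = "") -> CLNFit:
    """Fit the two-part model for one eligible feature and test the factor.

    With ``method="fisher_f"`` the positive part is judged by a conditional
    F test (between-within denominator df) and combined with the binary
    likelihood-ratio p by Fisher's method; with ``method="lr_chi2"`` both
    parts contribute an additive likelihood ratio against chi-squared.
    The positive-part full fit is retained for post hoc contrasts.
    """
    values = np.asarray(values, dtype=float)
    pos = values > 0
    n_pos = int(pos.sum())
    f_cat, f_num = _factor_terms(spec)
    cov_num = spec.covariate_cols

    # ---- binary part (likelihood ratio, logit link)
    lr_bin, df_bin, p_bin = 0.0, 0, np.nan
    binary_degenerate = bool(pos.all())
    binary_dropped = False
    if spec.include_binary_part and not binary_degenerate:
        z = pos.astype(float)
        try:
            x_full, nm_full = _design_matrix(design, f_cat, f_num + cov_num)
            x_red, nm_red = _design_matrix(design, [], cov_num)
            ll_full, k_full = _fit_logit(z, x_full, nm_full)
            ll_red, k_red = _fit_logit(z, x_red, nm_red)
            df_bin = k_full - k_red
            if df_bin < 1:
                raise PerfectSeparationError("factor not estimable")
            lr_bin = 2.0 * (ll_full - ll_red)
            if lr_bin < -1e-6:
                raise PerfectSeparationError("negative binary LR")
            lr_bin = max(lr_bin, 0.0)
            p_bin = float(stats.chi2.sf(lr_bin, df_bin))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            lr_bin, df_bin, p_bin = 0.0, 0, np.nan
            binary_dropped = True

    # ---- positive part (nested random-intercept LMM)
    design_pos = design.iloc[np.flatnonzero(pos)]
    y = np.log(values[pos])
    pop = design_pos["population"].to_numpy()
    plant = design_pos["plant_id"].to_numpy()
    x_full, nm_full = _design_matrix(design_pos, f_cat, f_num + cov_num)
    fit_full = fit_nested_lmm(y, x_full, pop, plant, nm_full,
                              reml=(spec.method == "fisher_f"))
    factor_prefixes = tuple(f"{c}[" for c in f_cat)
    factor_names = [n for n in fit_full.colnames
                    if n in f_num or n.startswith(factor_prefixes)]
    df_pos = len(factor_names)
    converged = fit_full.converged

    lr_pos, f_pos, df_den, p_pos = np.nan, np.nan, np.nan, np.nan
    if df_pos >= 1 and converged:
        if spec.method == "lr_chi2":
            x_red, nm_red = _design_matrix(design_pos, [], cov_num)
            fit_red = fit_nested_lmm(y, x_red, pop, plant, nm_red)
            df_pos = fit_full.rank - fit_red.rank
            lr_pos = 2.0 * (fit_full.llf - fit_red.llf)
            converged = converged and fit_red.converged and lr_pos > -1e-4
            lr_pos = max(lr_pos, 0.0)
            p_pos = float(stats.chi2.sf(lr_pos, max(df_pos, 1)))
        else:
            idx = [fit_full.colnames.index(n) for n in factor_names]
            beta_l = fit_full.beta[idx]
            cov_l = fit_full.cov_beta[np.ix_(idx, idx)]
            try:
                wald = float(beta_l @ np.linalg.solve(cov_l, beta_l))
            except np.linalg.LinAlgError:
                wald, converged = np.nan, False
            if converged:
                _, df_den = _bw_denominator_df(x_full, fit_full.colnames,
                                               factor_names, pop, plant)
                f_pos = wald / df_pos
                p_pos = float(stats.f.sf(f_pos, df_pos, df_den))

    df = df_bin + max(df_pos, 0)
    if df < 1 or not converged or not np.isfinite(p_pos) and df_bin < 1:
        return CLNFit(feature_id, spec.factor, np.nan, max(df, 0), np.nan,
                      p_bin, p_pos, lr_bin, df_bin, df_pos, n_pos,
                      binary_degenerate, binary_dropped, False,
                      lr_pos, f_pos, df_den, fit_full, design_pos)
    if spec.method == "lr_chi2":
        statistic = lr_bin + (lr_pos if np.isfinite(lr_pos) else 0.0)
        p = float(stats.chi2.sf(statistic, df))
    else:
        parts = [p for p in (p_bin, p_pos) if np.isfinite(p)]
        statistic = f_pos if np.isfinite(f_pos) else lr_bin
        p = _fisher_combine(parts)
    return CLNFit(feature_id, spec.factor, statistic, df, p, p_bin, p_pos,
                  lr_bin, df_bin, df_pos, n_pos, binary_degenerate,
                  binary_dropped, True, lr_pos, f_pos, df_den,
                  fit_full, design_pos)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def tukey_posthoc(fit: CLNFit, spec: CLNSpec, all_levels=None) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts on the positive-part scale.

    Uses the studentized-range distribution over the number of factor levels
    with positive observations; levels without positive observations are
    reported untestable.  For a two-level factor the adjusted p equals the
    unadjusted two-sided contrast p.
    """
    if spec.kind != "categorical":
        raise ValueError("post hoc contrasts require a categorical factor")
    col = spec.factor_cols[0]
    lmm = fit.pos_fit_full
    present_levels = sorted(pd.unique(fit.design_pos[col].astype(str)))
    present = set(present_levels)
    if all_levels is None:
        all_levels = present_levels
    else:
        all_levels = sorted(all_levels)
    names = lmm.colnames
    coef = {n: b for n, b in zip(names, lmm.beta)}
    cov = pd.DataFrame(lmm.cov_beta, index=names, columns=names)
    k = len(present)
    dof = max(lmm.n - lmm.rank, 1)
    rows = []
    for i, la in enumerate(all_levels):
        for lb in all_levels[i + 1:]:
            ca, cb = f"{col}[{la}]", f"{col}[{lb}]"
            ref = present_levels[0]
            testable = (la in present and lb in present
                        and (ca in coef or la == ref)
                        and (cb in coef or lb == ref))
            if not testable:
                rows.append({"level_a": la, "level_b": lb, "estimate": np.nan,
                             "se": np.nan, "p_adj": np.nan, "testable": False})
                continue
            c = pd.Series(0.0, index=names)
            if ca in coef:
                c[ca] = 1.0
            if cb in coef:
                c[cb] = -1.0
            est = float(c @ pd.Series(coef))
            se = float(np.sqrt(c @ cov @ c))
            if se == 0:
                p_adj = np.nan
            else:
                q = abs(est) / se * np.sqrt(2.0)
                p_adj = float(stats.studentized_range.sf(q, k, dof))
            rows.append({"level_a": la, "level_b": lb, "estimate": est,
                         "se": se, "p_adj": p_adj, "testable": True})
    return pd.DataFrame(rows)


def run_factor_analysis(table, design: pd.DataFrame, spec: CLNSpec):
    """Run the conditional log-normal analysis of one factor over all features.

    ``table`` is a replicate-averaged FeatureTable whose rows align with
    ``design``.  Returns ``(results, fits)``: a per-feature DataFrame with
    eligibility, the combined LR test and BH q-values, and the per-feature
    fits (for post hoc use).
    """
    intens = table.intensities if hasattr(table, "intensities") else pd.DataFrame(table)
    design = design.loc[intens.index]
    design = design.reset_index(drop=True)
    rows, fits = [], {}
    for fid in intens.columns:
        values = intens[fid].to_numpy(dtype=float)
        ok, reason = eligibility(values, design, spec)
        row = {"feature_id": fid, "factor": spec.factor, "eligible": ok,
               "reason": reason, "statistic": np.nan, "df": 0, "p": np.nan,
               "p_bin": np.nan, "p_pos": np.nan,
               "n_pos": int((values > 0).sum()), "binary_dropped": False,
               "binary_degenerate": False, "tested": False}
        if ok:
            fit = fit_cln(values, design, spec, feature_id=fid)
            fits[fid] = fit
            row.update(statistic=fit.statistic, df=fit.df, p=fit.p,
                       p_bin=fit.p_bin, p_pos=fit.p_pos,
                       binary_dropped=fit.binary_dropped,
                       binary_degenerate=fit.binary_degenerate,
                       tested=fit.converged)
            if not fit.converged:
                row["reason"] = "nonconvergence"
        rows.append(row)
    res = pd.DataFrame(rows).set_index("feature_id")
    res["q"] = fdr_bh(res["p"])
    return res, fits


def significance_summary(res: pd.DataFrame) -> dict:
    """Tallies mirroring the per-factor reporting table."""
    p, q = res["p"], res["q"]
    return {
        "n_features": int(len(res)),
        "n_eligible": int(res["eligible"].sum()),
        "n_tested": int(res["tested"].sum()),
        "q_lt_0.20": int((q < 0.20).sum()),
        "q_lt_0.10": int((q < 0.10).sum()),
        "q_lt_0.05": int((q < 0.05).sum()),
        "p_lt_0.001": int((p < 0.001).sum()),
        "p_lt_0.01": int((p < 0.01).sum()),
        "p_lt_0.05": int((p < 0.05).sum()),
    }
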
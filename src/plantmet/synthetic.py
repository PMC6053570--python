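"""Synthetic study generator with known ground truth.

Emulates the sampling design of the Danish *Plantago major* survey: 15
populations in 3 broad regions, 3 plants per population, 2 leaves per plant
(one undamaged, one herbivore-damaged), each leaf extract injected in
triplicate across 2 batches, plus pooled-QC injections.  Feature intensities
follow a zero-inflated (hurdle) log-normal model:

    presence  Z ~ Bernoulli(pi_j)                       (per leaf, per feature)
    intensity | present = exp(eta + eps),  eps ~ N(0, sigma_resid^2)

where ``eta`` contains a per-feature baseline, population and plant random
intercepts, and any planted fixed effects: region log-fold shifts applied to
disjoint per-region feature blocks, a quadratic soil-pH response (on pH
centred at the range midpoint), a habitat shift, and a slope on centred
log leaf area.  Injection replicates multiply the leaf-level value by
log-normal technical noise with a per-feature coefficient of variation;
planted QC-RSD "violator" features get a large CV so that pooled-QC
filtering removes exactly them.  QC injections are the pooled mean of all
biological leaf-level values times the same technical noise.

Defaults mirror the study shape: 541 features of which 344 are planted RSD
violators (so filtering keeps 197), and effect-set sizes 30 (region),
8 (soil pH), 4 (habitat), 3 (leaf area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, make_feature_id
from .sites import PHENOLOGY_STAGES, REGIONS, site_table

__all__ = ["SimulationConfig", "GroundTruth", "generate_study", "generate_null_study"]

_PH_CENTER_DEFAULT = 6.25


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.  See module docstring for the model."""

    # sampling design
    n_plants_per_population: int = 3
    leaves_per_plant: int = 2
    n_injections: int = 3
    n_batches: int = 2
    n_qc_per_batch: int = 24

    # feature panel
    n_features: int = 541
    n_rsd_violators: int = 344

    # intensity model (natural-log scale)
    baseline_log_mean_loc: float = 5.0
    baseline_log_mean_scale: float = 1.2
    sigma_resid: float = 0.5
    sigma_pop: float = 0.4
    sigma_plant: float = 0.3
    presence_prob_range: tuple[float, float] = (0.65, 1.0)

    # technical (injection-level) noise, as coefficient of variation
    technical_cv: float = 0.10
    violator_cv: float = 0.80

    # planted effects
    n_region_features: int = 30
    delta_region: float = 2.0
    n_ph_features: int = 8
    ph_beta: tuple[float, float] = (0.5, -0.4)
    n_habitat_features: int = 4
    delta_habitat: float = 1.5
    habitat_level: str = "forest"
    n_leafarea_features: int = 3
    leafarea_slope: float = 1.0

    # covariate models
    soil_ph_range: tuple[float, float] = (4.5, 8.0)
    soil_ph_within_sd: float = 0.15
    soil_ec_spearman: float = 0.49
    soil_cn_spearman: float = 0.39
    leaf_log_area_mean: float = 3.4  # log cm^2, ~30 cm^2
    leaf_log_area_sd: float = 0.4
    damage_beta: tuple[float, float] = (2.0, 20.0)  # damaged-leaf damage fraction

    # optional known-standard features planted at given (rt, mz) coordinates
    planted_targets: tuple[tuple[float, float], ...] = ()

    seed: int = 0
    sites: pd.DataFrame = field(default_factory=site_table)

    def validate(self) -> None:
        if min(self.n_plants_per_population, self.n_injections,
               self.n_batches, self.n_qc_per_batch, self.n_features) < 1:
            raise ValueError("all design counts must be positive")
        if self.leaves_per_plant != 2:
            raise ValueError("the paired design requires 2 leaves per plant")
        lo, hi = self.presence_prob_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("presence probabilities must lie in (0, 1]")
        n_effects = (self.n_region_features + self.n_ph_features
                     + self.n_habitat_features + self.n_leafarea_features)
        if self.n_rsd_violators + n_effects + len(self.planted_targets) > self.n_features:
            raise ValueError("effect/violator sets exceed the feature panel")

    @property
    def n_leaves(self) -> int:
        return len(self.sites) * self.n_plants_per_population * self.leaves_per_plant

    @property
    def n_biological_rows(self) -> int:
        return self.n_leaves * self.n_injections


@dataclass
class GroundTruth:
    """Planted truth for a generated study.

    ``features`` is indexed by feature id with columns: ``affected_by``
    (region / ph / habitat / leaf_area / none), ``region_block``, ``delta``,
    ``beta1``, ``beta2``, ``slope``, ``presence_prob``, ``baseline_log_mean``,
    ``technical_cv`` and ``is_rsd_violator``.
    """

    features: pd.DataFrame
    ph_center: float

    def affected(self, factor: str) -> list[str]:
        return list(self.features.index[self.features["affected_by"] == factor])

    @property
    def rsd_violators(self) -> list[str]:
        return list(self.features.index[self.features["is_rsd_violator"]])


def _feature_coordinates(cfg: SimulationConfig, rng: np.random.Generator):
    """Unique feature ids over the chromatographic run / scan range."""
    ids: list[str] = []
    rts: list[float] = []
    mzs: list[float] = []
    seen = set()
    for rt, mz in cfg.planted_targets:
        fid = make_feature_id(rt, mz)
        if fid in seen:
            raise ValueError(f"duplicate planted target {fid}")
        seen.add(fid)
        ids.append(fid); rts.append(rt); mzs.append(mz)
    while len(ids) < cfg.n_features:
        rt = round(float(rng.uniform(0.35, 6.70)), 4)
        mz = round(float(rng.uniform(100.0, 1000.0)), 4)
        fid = make_feature_id(rt, mz)
        if fid in seen:
            continue
        seen.add(fid)
        ids.append(fid); rts.append(rt); mzs.append(mz)
    return ids, np.array(rts), np.array(mzs)


def _gaussian_copula_partner(z: np.ndarray, spearman_target: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Standard-normal scores rank-correlated with ``z`` at the target level."""
    r = 2.0 * math.sin(spearman_target * math.pi / 6.0)  # Spearman -> Pearson
    noise = rng.standard_normal(z.size)
    return r * z + math.sqrt(max(1.0 - r * r, 0.0)) * noise


def _make_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per leaf (biological sample before injection expansion)."""
    rows = []
    sites = cfg.sites
    ph_pop = rng.uniform(*cfg.soil_ph_range, size=len(sites))
    for p_idx, site in sites.reset_index(drop=True).iterrows():
        for plant_no in range(1, cfg.n_plants_per_population + 1):
            plant_id = f"P{p_idx + 1:02d}_{plant_no}"
            soil_ph = float(ph_pop[p_idx] + rng.normal(0.0, cfg.soil_ph_within_sd))
            phenology = str(rng.choice(PHENOLOGY_STAGES))
            for status in ("undamaged", "damaged"):
                area = float(np.exp(rng.normal(cfg.leaf_log_area_mean,
                                               cfg.leaf_log_area_sd)))
                if status == "damaged":
                    frac = float(rng.beta(*cfg.damage_beta))
                    damage_area = frac * area
                else:
                    damage_area = 0.0
                rows.append({
                    "leaf_id": f"{plant_id}_{status}",
                    "role": "biological",
                    "population": site["population"],
                    "region": site["region"],
                    "habitat": site["habitat"],
                    "light": site["light"],
                    "phenology": phenology,
                    "plant_id": plant_id,
                    "leaf_status": status,
                    "leaf_area_cm2": area,
                    "damage_area_cm2": damage_area,
                    "damage_pct": 100.0 * damage_area / area,
                    "soil_ph": soil_ph,
                    "latitude": site["latitude"],
                    "longitude": site["longitude"],
                })
    leaves = pd.DataFrame(rows)
    # soil EC / C:N correlated with pH through a Gaussian copula (plant level)
    plant_ph = leaves.groupby("plant_id", sort=True)["soil_ph"].first()
    z = (plant_ph - plant_ph.mean()) / plant_ph.std()
    z_ec = _gaussian_copula_partner(z.to_numpy(), cfg.soil_ec_spearman, rng)
    z_cn = _gaussian_copula_partner(z.to_numpy(), cfg.soil_cn_spearman, rng)
    ec = pd.Series(80.0 * np.exp(0.5 * z_ec), index=plant_ph.index)
    cn = pd.Series(13.0 * np.exp(0.25 * z_cn), index=plant_ph.index)
    leaves["soil_ec"] = leaves["plant_id"].map(ec)
    leaves["soil_cn"] = leaves["plant_id"].map(cn)
    return leaves


def _plant_effect_sets(cfg: SimulationConfig, feature_ids: list[str],
                       rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_features
    truth = pd.DataFrame({
        "affected_by": np.repeat("none", n).astype(object),
        "region_block": np.repeat("", n).astype(object),
        "delta": np.zeros(n),
        "beta1": np.zeros(n),
        "beta2": np.zeros(n),
        "slope": np.zeros(n),
        "is_rsd_violator": np.zeros(n, dtype=bool),
    }, index=pd.Index(feature_ids, name="feature_id"))

    # planted targets are kept clean (never violators / effect carriers)
    reserved = len(cfg.planted_targets)
    pool = rng.permutation(np.arange(reserved, n))
    k = cfg.n_rsd_violators
    violators, pool = pool[:k], pool[k:]
    truth.iloc[violators, truth.columns.get_loc("is_rsd_violator")] = True

    def take(count: int) -> np.ndarray:
        nonlocal pool
        sel, pool = pool[:count], pool[count:]
        return sel

    region_sel = take(cfg.n_region_features)
    blocks = np.array_split(region_sel, len(REGIONS))
    for region, block in zip(REGIONS, blocks):
        truth.iloc[block, truth.columns.get_loc("affected_by")] = "region"
        truth.iloc[block, truth.columns.get_loc("region_block")] = region
        truth.iloc[block, truth.columns.get_loc("delta")] = cfg.delta_region
    ph_sel = take(cfg.n_ph_features)
    truth.iloc[ph_sel, truth.columns.get_loc("affected_by")] = "ph"
    truth.iloc[ph_sel, truth.columns.get_loc("beta1")] = cfg.ph_beta[0]
    truth.iloc[ph_sel, truth.columns.get_loc("beta2")] = cfg.ph_beta[1]
    hab_sel = take(cfg.n_habitat_features)
    truth.iloc[hab_sel, truth.columns.get_loc("affected_by")] = "habitat"
    truth.iloc[hab_sel, truth.columns.get_loc("delta")] = cfg.delta_habitat
    la_sel = take(cfg.n_leafarea_features)
    truth.iloc[la_sel, truth.columns.get_loc("affected_by")] = "leaf_area"
    truth.iloc[la_sel, truth.columns.get_loc("slope")] = cfg.leafarea_slope
    return truth


def generate_study(cfg: SimulationConfig):
    """Generate ``(FeatureTable, metadata, GroundTruth)`` for one study.

    The feature table is at injection level (biological triplicates plus QC
    injections), unnormalized.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    feature_ids, rts, mzs = _feature_coordinates(cfg, rng)
    truth = _plant_effect_sets(cfg, feature_ids, rng)
    leaves = _make_metadata(cfg, rng)
    n_leaf, n_feat = len(leaves), cfg.n_features

    # per-feature parameters
    mu = rng.normal(cfg.baseline_log_mean_loc, cfg.baseline_log_mean_scale, n_feat)
    lo, hi = cfg.presence_prob_range
    pi = rng.uniform(lo, hi, n_feat)
    truth["presence_prob"] = pi
    truth["baseline_log_mean"] = mu
    cv = np.where(truth["is_rsd_violator"], cfg.violator_cv, cfg.technical_cv)
    truth["technical_cv"] = cv

    # random intercepts: population and plant, independent per feature
    pops = leaves["population"].to_numpy()
    plants = leaves["plant_id"].to_numpy()
    pop_levels, pop_idx = np.unique(pops, return_inverse=True)
    plant_levels, plant_idx = np.unique(plants, return_inverse=True)
    b_pop = rng.normal(0.0, cfg.sigma_pop, (len(pop_levels), n_feat))
    b_plant = rng.normal(0.0, cfg.sigma_plant, (len(plant_levels), n_feat))

    eta = mu[None, :] + b_pop[pop_idx] + b_plant[plant_idx]

    # planted fixed effects
    ph_center = _PH_CENTER_DEFAULT
    ph_c = leaves["soil_ph"].to_numpy() - ph_center
    log_area_c = np.log(leaves["leaf_area_cm2"].to_numpy()) - cfg.leaf_log_area_mean
    for j, (fid, row) in enumerate(truth.iterrows()):
        if row["affected_by"] == "region":
            eta[:, j] += np.where(leaves["region"] == row["region_block"],
                                  row["delta"], 0.0)
        elif row["affected_by"] == "ph":
            eta[:, j] += row["beta1"] * ph_c + row["beta2"] * ph_c ** 2
        elif row["affected_by"] == "habitat":
            eta[:, j] += np.where(leaves["habitat"] == cfg.habitat_level,
                                  row["delta"], 0.0)
        elif row["affected_by"] == "leaf_area":
            eta[:, j] += row["slope"] * log_area_c

    present = rng.random((n_leaf, n_feat)) < pi[None, :]
    eps = rng.normal(0.0, cfg.sigma_resid, (n_leaf, n_feat))
    leaf_intensity = np.where(present, np.exp(eta + eps), 0.0)

    sigma_tech = np.sqrt(np.log1p(cv ** 2))

    # expand to injections; triplicate 1 -> batch 1, 3 -> batch 2, 2 split
    bio_rows, bio_meta = [], []
    for rep in range(1, cfg.n_injections + 1):
        noise = np.exp(rng.normal(0.0, 1.0, (n_leaf, n_feat)) * sigma_tech[None, :])
        bio_rows.append(leaf_intensity * noise)
        if rep == 1 or cfg.n_batches == 1:
            batch = np.repeat("B1", n_leaf)
        elif rep == cfg.n_injections:
            batch = np.repeat(f"B{cfg.n_batches}", n_leaf)
        else:
            batch = np.where(np.arange(n_leaf) % 2 == 0, "B1", "B2")
        m = leaves.copy()
        m["sample_id"] = m["leaf_id"] + f"_r{rep}"
        m["injection_replicate"] = rep
        m["batch"] = batch
        bio_meta.append(m)
    intensities = np.vstack(bio_rows)
    meta = pd.concat(bio_meta, ignore_index=True)

    # pooled QC injections
    qc_base = leaf_intensity.mean(axis=0)
    qc_rows, qc_meta = [], []
    for b in range(1, cfg.n_batches + 1):
        for i in range(1, cfg.n_qc_per_batch + 1):
            noise = np.exp(rng.normal(0.0, 1.0, n_feat) * sigma_tech)
            qc_rows.append(qc_base * noise)
            qc_meta.append({"sample_id": f"QC_B{b}_{i:02d}", "role": "qc",
                            "injection_replicate": i, "batch": f"B{b}"})
    intensities = np.vstack([intensities] + [np.vstack(qc_rows)])
    meta = pd.concat([meta, pd.DataFrame(qc_meta)], ignore_index=True)
    meta = meta.set_index("sample_id", drop=False)

    table = FeatureTable(
        pd.DataFrame(intensities, index=meta.index, columns=feature_ids),
        pd.DataFrame({"rt": rts, "mz": mzs}, index=pd.Index(feature_ids)),
    )
    return table, meta, GroundTruth(truth, ph_center)


def generate_null_study(cfg: SimulationConfig):
    """Same design with every planted effect set empty (for calibration)."""
    null_cfg = replace(cfg, n_region_features=0, n_ph_features=0,
                       n_habitat_features=0, n_leafarea_features=0)
    return generate_study(null_cfg)
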
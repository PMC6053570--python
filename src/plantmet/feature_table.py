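"""Feature-table data model, I/O and preprocessing.

A *feature table* is a wide samples x features matrix of non-negative LC-MS
intensities.  Each feature is identified by a ``"<rt>_<mz>"`` string that
encodes its retention time (minutes) and mass-to-charge ratio (Daltons),
e.g. ``"2.41_343.82"``.  Sample metadata carries the study design (population,
region, habitat, light, phenology, plant, leaf status), per-leaf covariates
(leaf area, herbivory damage), soil covariates, coordinates, and the
injection bookkeeping (role, replicate, batch).

Preprocessing follows the standard untargeted-metabolomics chain:

1. total-intensity normalization of every injection,
2. relative-standard-deviation (RSD) filtering of features against pooled-QC
   injections,
3. averaging of triplicate injections to one row per biological leaf sample,
4. optional within-plant paired differencing (undamaged minus damaged leaf)
   for the herbivory analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PairedDifferenceTable",
    "ROLE_BIOLOGICAL",
    "ROLE_QC",
    "ROLE_CONDITIONING",
    "make_feature_id",
    "parse_feature_id",
    "read_feature_table",
    "normalize_total_intensity",
    "qc_rsd_filter",
    "average_replicates",
    "paired_difference",
]

ROLE_BIOLOGICAL = "biological"
ROLE_QC = "qc"
ROLE_CONDITIONING = "conditioning"

#: Metadata columns required for a full study design.
METADATA_COLUMNS = [
    "sample_id", "role", "population", "region", "habitat", "light",
    "phenology", "plant_id", "leaf_status", "leaf_id", "leaf_area_cm2",
    "damage_area_cm2", "damage_pct", "soil_ph", "soil_ec", "soil_cn",
    "latitude", "longitude", "injection_replicate", "batch",
]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus per-feature RT / m/z.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with one column per feature id.
    features
        DataFrame indexed by feature id with columns ``rt`` (minutes) and
        ``mz`` (Daltons), aligned with the intensity columns.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.intensities.shape[1] == 0:
            raise ValueError("no features")
        if self.features is None:
            rt, mz = zip(*(parse_feature_id(c) for c in self.intensities.columns))
            self.features = pd.DataFrame(
                {"rt": rt, "mz": mz}, index=self.intensities.columns
            )
        if not self.intensities.columns.equals(self.features.index):
            raise ValueError("feature metadata does not match intensity columns")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        vals = self.intensities.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite intensity")
        if (vals < 0).any():
            raise ValueError("negative intensity")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def values(self) -> np.ndarray:
        return self.intensities.to_numpy()

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return FeatureTable(
            self.intensities[feature_ids], self.features.loc[feature_ids]
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = list(sample_ids)
        return FeatureTable(
            self.intensities.loc[sample_ids], self.features.copy()
        )

    def to_csv(self, path, sep: str = "\t") -> None:
        self.intensities.to_csv(path, sep=sep, index_label="sample_id")


@dataclass
class PairedDifferenceTable:
    """Within-plant contrasts: undamaged-leaf minus damaged-leaf values.

    ``diff_intensities`` has one row per plant (may be negative);
    ``plant_meta`` carries ``diff_leaf_area_cm2`` (undamaged minus damaged
    leaf area) and ``damage_pct`` of the damaged leaf, plus the plant-level
    design columns.
    """

    diff_intensities: pd.DataFrame
    plant_meta: pd.DataFrame

    @property
    def plant_ids(self) -> list[str]:
        return list(self.diff_intensities.index)


def make_feature_id(rt: float, mz: float, precision: int = 4) -> str:
    """Build the ``"<rt>_<mz>"`` identifier for a feature.

    Retention time (minutes) and m/z (Daltons) are rounded to at most
    ``precision`` decimals; trailing zeros are dropped so that
    ``make_feature_id(2.41, 343.82) == "2.41_343.82"``.
    """
    for name, v in (("rt", rt), ("mz", mz)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive, got {v!r}")

    def fmt(v: float) -> str:
        s = f"{round(v, precision):.{precision}f}".rstrip("0").rstrip(".")
        return s if s else "0"

    return f"{fmt(rt)}_{fmt(mz)}"


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Parse ``"<rt>_<mz>"`` back into ``(rt, mz)`` floats."""
    parts = str(feature_id).split("_")
    if len(parts) != 2:
        raise ValueError(f"unparseable feature id {feature_id!r}")
    try:
        rt, mz = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ValueError(f"unparseable feature id {feature_id!r}") from exc
    if not (math.isfinite(rt) and math.isfinite(mz)):
        raise ValueError(f"non-finite feature id {feature_id!r}")
    return rt, mz


def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample-metadata table; validates ids and controlled values."""
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta.set_index("sample_id", drop=False)


def read_feature_table(path, metadata_path=None, sep: str = "\t"):
    """Read a wide feature table (first column = sample id) and its metadata.

    Returns ``(FeatureTable, metadata)``; ``metadata`` is ``None`` when no
    metadata path is given.  Every biological or QC sample in the table must
    be present in the metadata.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.shape[1] == 0:
        raise ValueError("no features")
    table = FeatureTable(df)
    meta = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path, sep=sep)
        missing = set(table.sample_ids) - set(meta.index)
        if missing:
            raise ValueError(
                f"samples without metadata: {sorted(missing)[:5]}"
            )
    return table, meta


def normalize_total_intensity(table: FeatureTable, target_sum: float = 10_000.0) -> FeatureTable:
    """Scale every sample so its total intensity equals ``target_sum``.

    Zeros are preserved; an all-zero sample is an error because its scale is
    undefined.
    """
    vals = table.values
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"all-zero sample(s): {bad[:5]}")
    scaled = vals * (target_sum / totals)[:, None]
    out = table.intensities.copy()
    out.loc[:, :] = scaled
    return FeatureTable(out, table.features.copy())


def qc_rsd_filter(
    table: FeatureTable,
    qc_sample_ids,
    threshold_pct: float = 30.0,
):
    """Remove features whose QC relative standard deviation exceeds a threshold.

    RSD = 100 * sd / mean over the pooled-QC injections, with the sample
    (n-1) standard deviation.  Features with RSD above ``threshold_pct`` or
    with undefined RSD (QC mean of zero) are removed.  Returns the filtered
    table and a removal report (DataFrame with ``feature_id`` and ``rsd_pct``,
    NaN where undefined).
    """
    qc_sample_ids = list(qc_sample_ids)
    if len(qc_sample_ids) < 2:
        raise ValueError("QC-RSD filtering needs at least 2 QC samples")
    qc = table.intensities.loc[qc_sample_ids].to_numpy()
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, 100.0 * sd / np.where(mean > 0, mean, 1.0), np.nan)
    removed_mask = ~(rsd <= threshold_pct)  # NaN compares False -> removed
    removed = pd.DataFrame(
        {
            "feature_id": np.asarray(table.feature_ids)[removed_mask],
            "rsd_pct": rsd[removed_mask],
        }
    )
    kept = [f for f, bad in zip(table.feature_ids, removed_mask) if not bad]
    if not kept:
        raise ValueError("QC-RSD filter removed every feature")
    return table.subset_features(kept), removed


def _leaf_id(meta: pd.DataFrame) -> pd.Series:
    if "leaf_id" in meta.columns and meta["leaf_id"].notna().all():
        return meta["leaf_id"].astype(str)
    return meta["plant_id"].astype(str) + "_" + meta["leaf_status"].astype(str)


def average_replicates(table: FeatureTable, meta: pd.DataFrame):
    """Collapse injection replicates to one row per biological leaf sample.

    Returns ``(FeatureTable, collapsed_metadata)``: arithmetic means across a
    leaf's injections, indexed by leaf id; QC/conditioning rows are excluded.
    The collapsed metadata keeps the per-leaf design columns and drops the
    injection-level ones (replicate, batch).
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    bio = meta[meta["role"] == ROLE_BIOLOGICAL]
    if bio.empty:
        raise ValueError("no biological samples to average")
    leaf = _leaf_id(bio)
    sub = table.intensities.loc[bio.index]
    averaged = sub.groupby(leaf.values).mean()
    averaged.index.name = "sample_id"
    drop = [c for c in ("injection_replicate", "batch", "sample_id") if c in bio.columns]
    collapsed = bio.drop(columns=drop).groupby(leaf.values).first()
    collapsed.index.name = "sample_id"
    collapsed.insert(0, "sample_id", collapsed.index)
    # keep a deterministic order: by population, plant, leaf status
    order = collapsed.sort_values(["population", "plant_id", "leaf_status"]).index
    return (
        FeatureTable(averaged.loc[order], table.features.copy()),
        collapsed.loc[order],
    )


def paired_difference(table: FeatureTable, meta: pd.DataFrame) -> PairedDifferenceTable:
    """Within-plant differencing: undamaged minus damaged leaf, per feature.

    ``table``/``meta`` must be replicate-averaged (one row per leaf).  Every
    plant must have exactly one undamaged and one damaged leaf.  The
    herbivory covariates become ``diff_leaf_area_cm2`` (undamaged minus
    damaged area) and the damaged leaf's ``damage_pct``.
    """
    meta = meta.loc[table.sample_ids]
    plants = meta["plant_id"].astype(str)
    rows = []
    meta_rows = []
    for plant, grp in meta.groupby(plants, sort=True):
        statuses = set(grp["leaf_status"])
        if statuses != {"undamaged", "damaged"} or len(grp) != 2:
            raise ValueError(
                f"plant {plant!r} does not have exactly one undamaged and one "
                f"damaged leaf (got {sorted(grp['leaf_status'])})"
            )
        u = grp.index[grp["leaf_status"] == "undamaged"][0]
        d = grp.index[grp["leaf_status"] == "damaged"][0]
        rows.append(table.intensities.loc[u] - table.intensities.loc[d])
        mrow = grp.loc[u].drop(
            labels=[c for c in ("sample_id", "leaf_id", "leaf_status",
                                "leaf_area_cm2", "damage_area_cm2",
                                "damage_pct") if c in grp.columns]
        )
        mrow["plant_id"] = plant
        mrow["diff_leaf_area_cm2"] = (
            grp.loc[u, "leaf_area_cm2"] - grp.loc[d, "leaf_area_cm2"]
        )
        mrow["damage_pct"] = grp.loc[d, "damage_pct"]
        meta_rows.append(mrow)
    diff = pd.DataFrame(rows)
    diff.index = [m["plant_id"] for m in meta_rows]
    diff.index.name = "plant_id"
    plant_meta = pd.DataFrame(meta_rows)
    plant_meta.index = diff.index
    return PairedDifferenceTable(diff, plant_meta)
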
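"""Deterministic data preparation for the fire panel.

Operators here turn raw inputs (daily meteorology, decadal housing
densities, an event list) into the two modelling tables:

* a ``FireCatalog``: one row per retained fire event with its burned-area
  exceedance over the size threshold, and
* a ``SpaceTimePanel``: a complete region x month grid of covariates,
  area offsets, fire counts and a train/test split label.

All operators are deterministic and idempotent. Times are (year, month)
pairs mapped to a 1-based monthly index t = 12 * (year - year0) + month.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fire_extremes.hierarchy import EcoregionHierarchy

logger = logging.getLogger(__name__)

#: size threshold in hectares: events at or below it are discarded and the
#: response is the exceedance above it (1,000 acres ~ 405 ha).
THRESHOLD_HA = 405.0

COVARIATE_COLUMNS = (
    "humidity",
    "temperature",
    "precipitation",
    "precip_12mo",
    "wind_speed",
    "housing_density",
)

CATALOG_COLUMNS = ("event_id", "year", "month", "region", "size_ha", "exceedance_ha")


def month_index(year, month, year0: int):
    """1-based monthly time index t = 12 * (year - year0) + month."""
    return 12 * (np.asarray(year) - year0) + np.asarray(month)


def aggregate_daily_to_monthly(daily: pd.DataFrame, value_cols=None) -> pd.DataFrame:
    """Arithmetic mean of daily values per (region, year, month).

    ``daily`` must have columns region, year, month plus one or more value
    columns. Every region-month in the output grid (the cross product of
    observed regions and observed months) must have at least one daily
    value; an empty cell raises an error naming it.
    """
    required = {"region", "year", "month"}
    if not required.issubset(daily.columns):
        raise ValueError(f"daily table needs columns {sorted(required)}")
    if value_cols is None:
        value_cols = [c for c in daily.columns if c not in required and c != "day"]
    monthly = (
        daily.groupby(["region", "year", "month"], as_index=False)[list(value_cols)]
        .mean()
    )
    regions = monthly["region"].unique()
    months = monthly[["year", "month"]].drop_duplicates()
    full = months.merge(pd.DataFrame({"region": regions}), how="cross")
    merged = full.merge(monthly, on=["region", "year", "month"], how="left")
    missing = merged[merged[list(value_cols)].isna().any(axis=1)]
    if len(missing):
        cell = missing.iloc[0]
        raise ValueError(
            f"no daily values for region {cell['region']} in "
            f"{int(cell['year'])}-{int(cell['month']):02d}"
        )
    return merged.sort_values(["region", "year", "month"]).reset_index(drop=True)


def rolling_prior_12_sum(
    monthly: pd.DataFrame,
    value_col: str = "precipitation",
    out_col: str = "precip_12mo",
) -> pd.DataFrame:
    """Cumulative precipitation over the 12 months *preceding* each month.

    The value at month t is the sum over months t-12 .. t-1 (the current
    month is excluded). The first 12 months of each region's series have
    no support and come back as NaN, flagging them as unavailable.
    """
    if not {"region", "t", value_col}.issubset(monthly.columns):
        raise ValueError(f"monthly table needs columns ['region', 't', {value_col!r}]")
    out = monthly.sort_values(["region", "t"]).copy()
    lengths = out.groupby("region")["t"].size()
    if (lengths < 13).any():
        short = lengths[lengths < 13].index.tolist()
        raise ValueError(f"need at least 13 months per region; too short: {short}")
    rolled = (
        out.groupby("region")[value_col]
        .apply(lambda s: s.rolling(12).sum().shift(1))
        .reset_index(drop=True)
    )
    out[out_col] = rolled.to_numpy()
    return out.reset_index(drop=True)


def interpolate_housing(
    decadal: pd.DataFrame,
    years: np.ndarray,
    months: np.ndarray,
    unit_col: str = "region",
    value_col: str = "housing_density",
) -> pd.DataFrame:
    """Piecewise-linear interpolation of decadal densities to month midpoints.

    ``decadal`` has columns (unit, year, value) with at least two anchor
    years per unit. Evaluation times are continuous years at month
    midpoints, year + (month - 0.5) / 12. Beyond the last anchor the line
    through the last two anchors is extended (and symmetrically before the
    first anchor).
    """
    times = np.asarray(years, dtype=float) + (np.asarray(months, dtype=float) - 0.5) / 12.0
    rows = []
    for unit, grp in decadal.groupby(unit_col):
        grp = grp.sort_values("year")
        xs = grp["year"].to_numpy(dtype=float)
        ys = grp[value_col].to_numpy(dtype=float)
        if len(xs) < 2:
            raise ValueError(f"unit {unit}: need >= 2 decadal anchors to interpolate")
        vals = np.interp(times, xs, ys)
        before = times < xs[0]
        after = times > xs[-1]
        if before.any():
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            vals[before] = ys[0] + slope * (times[before] - xs[0])
        if after.any():
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            vals[after] = ys[-1] + slope * (times[after] - xs[-1])
        rows.append(
            pd.DataFrame(
                {unit_col: unit, "year": years, "month": months, value_col: vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


def filter_events(raw: pd.DataFrame, threshold_ha: float = THRESHOLD_HA) -> pd.DataFrame:
    """Retain events strictly larger than the threshold; compute exceedances.

    The same constant serves as the retention cutoff and the exceedance
    origin, so every retained event has exceedance_ha > 0 as required by
    all five size likelihoods.
    """
    if not {"year", "month", "region", "size_ha"}.issubset(raw.columns):
        raise ValueError("raw events need columns [year, month, region, size_ha]")
    sizes = raw["size_ha"].to_numpy(dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("fire sizes must be positive")
    kept = raw[sizes > threshold_ha].copy()
    kept["exceedance_ha"] = kept["size_ha"] - threshold_ha
    if "event_id" not in kept.columns:
        kept.insert(0, "event_id", np.arange(1, len(kept) + 1))
    return kept.reset_index(drop=True)


def assemble_panel(
    catalog: pd.DataFrame,
    covariates: pd.DataFrame,
    hierarchy: EcoregionHierarchy,
    split_month: int,
    year0: int | None = None,
) -> pd.DataFrame:
    """Build the complete S x T panel with counts, offsets and split labels.

    Months where any covariate is unavailable (notably the first 12, where
    the prior-12-month precipitation has no support) are dropped from the
    modelled panel. Counts are tallied from the catalog; cells with no
    events get zero. Months with t <= ``split_month`` are labelled train,
    later months test.
    """
    cov = covariates.copy()
    # outputs of a previous assembly are recomputed, not carried through
    cov = cov.drop(columns=[c for c in ("count", "split", "area_km2") if c in cov.columns])
    if "t" in cov.columns and year0 is None:
        # recover the origin from the existing index so re-assembly of a
        # trimmed panel maps events consistently
        first = cov.iloc[0]
        year0 = int(first["year"] - (first["t"] - first["month"]) // 12)
    if year0 is None:
        year0 = int(cov["year"].min())
    if "t" not in cov.columns:
        cov["t"] = month_index(cov["year"], cov["month"], year0)
    have = [c for c in COVARIATE_COLUMNS if c in cov.columns]
    usable = cov.groupby("t")[have].apply(lambda g: g.notna().all().all())
    keep_t = usable[usable].index
    dropped = sorted(set(cov["t"]) - set(keep_t))
    if dropped:
        logger.info("dropping %d months with unavailable covariates: %s", len(dropped), dropped)
    cov = cov[cov["t"].isin(keep_t)]

    regions = list(hierarchy.l3_ids)
    unknown = set(cov["region"]) - set(regions)
    if unknown:
        raise ValueError(f"covariates reference unknown regions: {sorted(unknown)}")
    grid = pd.MultiIndex.from_product([regions, sorted(keep_t)], names=["region", "t"])
    panel = cov.set_index(["region", "t"]).reindex(grid)
    if panel[have].isna().any().any():
        missing = panel[panel[have].isna().any(axis=1)].index.tolist()[:5]
        raise ValueError(f"covariate grid incomplete; first missing cells: {missing}")
    panel = panel.reset_index()

    year_of = cov.drop_duplicates("t").set_index("t")[["year", "month"]]
    panel["year"] = panel["t"].map(year_of["year"])
    panel["month"] = panel["t"].map(year_of["month"])

    if len(catalog):
        ev_t = month_index(catalog["year"], catalog["month"], year0)
        bad_region = ~catalog["region"].isin(regions)
        bad_t = ~pd.Series(ev_t).isin(keep_t)
        offenders = catalog[bad_region.to_numpy() | bad_t.to_numpy()]
        if len(offenders):
            raise ValueError(
                "events outside the panel (unknown region or month): "
                f"event_ids {offenders['event_id'].tolist()}"
            )
        tally = (
            pd.DataFrame({"region": catalog["region"], "t": ev_t})
            .value_counts()
            .rename("count")
            .reset_index()
        )
        panel = panel.merge(tally, on=["region", "t"], how="left")
        panel["count"] = panel["count"].fillna(0).astype(int)
    else:
        panel["count"] = 0

    panel["area_km2"] = panel["region"].map(hierarchy.area)
    lo, hi = panel["t"].min(), panel["t"].max()
    if not (lo <= split_month <= hi):
        raise ValueError(f"split_month {split_month} outside panel range [{lo}, {hi}]")
    panel["split"] = np.where(panel["t"] <= split_month, "train", "test")
    cols = ["region", "t", "year", "month", *have, "area_km2", "count", "split"]
    return panel[cols].sort_values(["t", "region"]).reset_index(drop=True)
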
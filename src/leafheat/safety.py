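"""Thermal safety margins: maximum leaf temperature, TSM, exceedance counts
and recovery-protocol comparisons.

The maximum operating leaf temperature of a species at a site (Tleafmax) is
summarised as the mean of the upper quartile of its measured midday leaf
temperatures; the thermal safety margin (TSM) is the heat-tolerance
threshold (T50 by default) minus Tleafmax, so negative margins flag species
whose sun leaves already exceed their tolerance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def compute_tleafmax(samples) -> float:
    """Mean of the upper quartile of a leaf-temperature sample.

    The 75th percentile uses linear interpolation and membership is
    inclusive (values >= Q3), a convention that is stable for small samples;
    e.g. for {1..8} the quartile is 6.25 and Tleafmax = mean{7, 8} = 7.5.
    Requires at least 4 samples.
    """
    arr = np.asarray(samples, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError(f"need at least 4 leaf-temperature samples, got {arr.size}")
    q3 = np.percentile(arr, 75, method="linear")
    return float(arr[arr >= q3].mean())


def tleafmax_table(leaf_temps: pd.DataFrame, per_campaign: bool = False) -> pd.DataFrame:
    """Tleafmax per species-site (campaigns pooled by default)."""
    keys = ["species", "site"] + (["campaign"] if per_campaign else [])
    out = (
        leaf_temps.groupby(keys, sort=True)["leaf_temperature"]
        .agg(tleafmax=compute_tleafmax, n_samples="size")
        .reset_index()
    )
    return out


def compute_tsm(
    thresholds: pd.DataFrame,
    tleafmax: pd.DataFrame,
    kind: str = "T50",
    basis: str = "leaf",
    air_tmax: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Thermal safety margin per species-site.

    ``thresholds`` is a fitted-threshold table (one row per species-site)
    carrying ``{kind}_boot_mean`` or ``{kind}_point`` columns, or a plain
    ``{kind}`` column.  With ``basis="leaf"`` the margin is measured against
    Tleafmax; with ``basis="air"`` against the per-site maximum air
    temperature supplied in ``air_tmax`` (columns site, max_air_temperature).
    Unmatched keys are reported and dropped; no overlap is an error.
    """
    thr = _threshold_column(thresholds, kind)
    if basis == "leaf":
        ref = tleafmax[["species", "site", "tleafmax"]]
        merged = thr.merge(ref, on=["species", "site"], how="outer", indicator=True)
    elif basis == "air":
        if air_tmax is None:
            raise ValueError("air basis requires an air_tmax table")
        ref = (
            air_tmax.groupby("site", sort=True)["max_air_temperature"]
            .max().rename("tleafmax").reset_index()
        )
        merged = thr.merge(ref, on="site", how="outer", indicator=True)
    else:
        raise ValueError(f"unknown basis {basis!r} (expected 'leaf' or 'air')")

    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        logger.warning(
            "%d species-site key(s) without a match dropped from TSM", len(unmatched)
        )
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    if merged.empty:
        raise ValueError("no overlapping species-site keys between thresholds and temperatures")
    merged["tsm"] = merged["threshold"] - merged["tleafmax"]
    merged["kind"] = kind
    merged["basis"] = basis
    return merged.reset_index(drop=True)


def _threshold_column(thresholds: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Extract one threshold kind, preferring the bootstrapped mean but
    falling back to the full-data point estimate where no replicate succeeded
    (e.g. point-fit-only runs)."""
    candidates = [c for c in (f"{kind}_boot_mean", f"{kind}_point", kind)
                  if c in thresholds.columns]
    if not candidates:
        raise KeyError(f"no {kind} column found in threshold table")
    vals = thresholds[candidates[0]].astype(float)
    for col in candidates[1:]:
        vals = vals.fillna(thresholds[col].astype(float))
    out = thresholds[["species", "site"]].copy()
    out["threshold"] = vals.to_numpy(dtype=float)
    return out


def count_exceedances(
    thresholds: pd.DataFrame,
    tleafmax: pd.DataFrame,
    kind: str = "T50",
) -> pd.DataFrame:
    """Per-site count of species whose Tleafmax strictly exceeds the threshold.

    Ties (Tleafmax exactly equal to the threshold) do not count.  Equivalent
    to counting species with a negative leaf-based TSM.
    """
    tsm = compute_tsm(thresholds, tleafmax, kind=kind, basis="leaf")
    out = (
        tsm.assign(exceeds=tsm["tsm"] < 0)
        .groupby("site", sort=True)["exceeds"]
        .agg(n_exceeding="sum", n_species="size")
        .reset_index()
    )
    out["n_exceeding"] = out["n_exceeding"].astype(int)
    out["kind"] = kind
    return out


def recovery_shift(
    direct: pd.DataFrame,
    recovered: pd.DataFrame,
    kinds: tuple[str, ...] = ("Tcrit", "T50", "T95"),
) -> pd.DataFrame:
    """Threshold shifts between the recovery and direct measurement protocols.

    Both inputs are fitted-threshold tables; the shift is
    threshold(recovered) - threshold(direct) per species-site and kind.
    Keys present in only one arm are reported and dropped, never imputed.
    """
    frames = []
    for kind in kinds:
        d = _threshold_column(direct, kind).rename(columns={"threshold": "direct"})
        r = _threshold_column(recovered, kind).rename(columns={"threshold": "recovered"})
        merged = d.merge(r, on=["species", "site"], how="outer", indicator=True)
        missing = merged[merged["_merge"] != "both"]
        if len(missing):
            logger.warning("%d key(s) present in only one protocol arm for %s", len(missing), kind)
        merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
        merged["kind"] = kind
        merged["delta"] = merged["recovered"] - merged["direct"]
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def pulse_decline_summary(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean percent Fv/Fm decline after a heat pulse, by recovery interval.

    Decline per leaf is ``(1 - fvfm/control_fvfm) * 100``; rows are grouped
    by protocol and recovery interval (hours, 0 for the direct measurement)
    and averaged across species means.
    """
    obs = observations.copy()
    if "recovery_hours" not in obs:
        obs["recovery_hours"] = np.where(obs["protocol"] == "direct", 0.0, np.nan)
    obs["decline_pct"] = (1.0 - obs["fvfm"] / obs["control_fvfm"]) * 100.0
    per_species = (
        obs.groupby(["protocol", "recovery_hours", "species"], sort=True)["decline_pct"]
        .mean().reset_index()
    )
    out = (
        per_species.groupby(["protocol", "recovery_hours"], sort=True)["decline_pct"]
        .agg(mean_decline_pct="mean", n_species="size")
        .reset_index()
    )
    return out
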
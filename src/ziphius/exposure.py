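"""Behaviour-sonar integration: overlap fractions, whale-source distances,
land-blocking, per-event and per-IDDI exposure summaries, and assembly of
the SOAR and Complete model tables.

Exposure of a behaviour to one sonar type is summarized as presence, the
distance to the nearest overlapping bout's start position (set to 500 km
when absent, a placeholder far beyond any plausible effect), and OL -- the
summed overlapping minutes across bouts divided by the behaviour duration,
clipped to 1 (the unclipped sum is kept as an auxiliary column). Exposures
whose whale-source path crosses emergent land are excluded: the sound would
have been blocked or severely attenuated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv
from .geo import ElevationGrid, great_circle_km, sample_path

__all__ = [
    "ABSENT_DISTANCE_KM", "overlap_fraction", "whale_bout_distance",
    "land_blocked", "summarize_event_exposure", "summarize_iddi_exposure",
    "summarize_windows", "assemble_model_table", "RESPONSES",
]

ABSENT_DISTANCE_KM = 500.0
SONAR_TYPES = ("high", "mid")
RESPONSES = ("deep_duration", "shallow_duration", "shallow_depth",
             "surface_interval", "iddi")


def overlap_fraction(event_interval, bout_intervals):
    """(clipped, raw) overlap: summed overlapping minutes / event duration.

    Simultaneous bouts can push the raw sum above 1; the clipped value is
    the modelling covariate.
    """
    start, end = (pd.Timestamp(event_interval[0]), pd.Timestamp(event_interval[1]))
    dur_s = (end - start).total_seconds()
    if dur_s <= 0:
        raise ValueError("zero-duration event")
    tot = 0.0
    for b0, b1 in bout_intervals:
        tot += max(0.0, (min(end, pd.Timestamp(b1)) - max(start, pd.Timestamp(b0))
                         ).total_seconds())
    raw = tot / dur_s
    return min(raw, 1.0), raw


def whale_bout_distance(whale_lat, whale_lon, bout_lat, bout_lon) -> float:
    """Great-circle km between the whale's modelled position and the bout's
    start position."""
    return float(great_circle_km(whale_lat, whale_lon, bout_lat, bout_lon))


def land_blocked(whale_pos, bout_pos, grid: ElevationGrid,
                 max_spacing_km: float = 0.5) -> bool:
    """True when the whale-source path crosses emergent land (max sampled
    elevation >= 0 m). Symmetric in its endpoints."""
    lats, lons = sample_path(whale_pos[0], whale_pos[1],
                             bout_pos[0], bout_pos[1], max_spacing_km)
    return bool(np.max(grid.sample(lats, lons)) >= 0.0)


class _BoutArrays:
    """Per-type bout fields unpacked to numpy for fast window sweeps."""

    def __init__(self, bouts: pd.DataFrame):
        self.by_type = {}
        for typ in SONAR_TYPES:
            tb = bouts[bouts["sonar_type"] == typ] if len(bouts) else bouts
            self.by_type[typ] = {
                "start": pd.to_datetime(tb["start_time"], utc=True)
                .astype("int64").to_numpy() if len(tb) else np.empty(0, dtype="int64"),
                "end": pd.to_datetime(tb["end_time"], utc=True)
                .astype("int64").to_numpy() if len(tb) else np.empty(0, dtype="int64"),
                "lat": tb["start_lat"].to_numpy(dtype=float) if len(tb) else np.empty(0),
                "lon": tb["start_lon"].to_numpy(dtype=float) if len(tb) else np.empty(0),
            }
        self._block_cache = {}

    def blocked(self, wlat, wlon, typ, k, grid):
        key = (round(float(wlat), 4), round(float(wlon), 4), typ, int(k))
        if key not in self._block_cache:
            b = self.by_type[typ]
            self._block_cache[key] = land_blocked(
                (wlat, wlon), (b["lat"][k], b["lon"][k]), grid)
        return self._block_cache[key]


def _summarize_one(start_ns, end_ns, wlat, wlon, arrays: _BoutArrays, grid):
    dur_s = (end_ns - start_ns) / 1e9
    if dur_s <= 0:
        raise ValueError("zero-duration window")
    out = {"n_blocked_excluded": 0}
    for typ in SONAR_TYPES:
        b = arrays.by_type[typ]
        over_s = np.maximum(
            0.0, (np.minimum(end_ns, b["end"]) - np.maximum(start_ns, b["start"])) / 1e9)
        idx = np.flatnonzero(over_s > 0)
        if grid is not None and idx.size and np.isfinite(wlat):
            keep = [k for k in idx
                    if np.isnan(b["lat"][k])
                    or not arrays.blocked(wlat, wlon, typ, k, grid)]
            out["n_blocked_excluded"] += idx.size - len(keep)
            idx = np.asarray(keep, dtype=int)
        present = idx.size > 0
        if present:
            raw = float(over_s[idx].sum() / dur_s)
            d = great_circle_km(wlat, wlon, b["lat"][idx], b["lon"][idx])
            dist = float(np.nanmin(np.atleast_1d(d)))
        else:
            raw, dist = 0.0, ABSENT_DISTANCE_KM
        out[f"present_{typ}"] = bool(present)
        out[f"n_bouts_{typ}"] = int(idx.size)
        out[f"dist_{typ}_km"] = dist if present else ABSENT_DISTANCE_KM
        out[f"ol_{typ}"] = min(raw, 1.0)
        out[f"ol_{typ}_raw"] = raw
    out["presence_cat"] = {(False, False): "none", (True, False): "high",
                           (False, True): "mid", (True, True): "both"}[
        (out["present_high"], out["present_mid"])]
    return out


def summarize_event_exposure(event, bouts: pd.DataFrame, whale_pos,
                             grid: ElevationGrid | None = None) -> dict:
    """Per-type exposure summary for one behavioural event.

    ``event``: mapping with 'start' and 'end'; ``whale_pos``: (lat, lon) of
    the nearest-in-time modelled track point. Land-blocked bouts are
    excluded before presence, distance and OL are computed.
    """
    arr = _BoutArrays(bouts)
    s = pd.Timestamp(event["start"])
    e = pd.Timestamp(event["end"])
    s = s.tz_localize("UTC") if s.tzinfo is None else s
    e = e.tz_localize("UTC") if e.tzinfo is None else e
    return _summarize_one(s.value, e.value, whale_pos[0], whale_pos[1], arr, grid)


def summarize_iddi_exposure(iddi_record, bouts: pd.DataFrame, whale_pos,
                            grid: ElevationGrid | None = None) -> dict:
    """Exposure for an inter-deep-dive interval over its deep-dive-cycle
    window: from the start of the preceding deep dive to the start of the
    deep dive ending the interval, so sonar at any point of the cycle
    counts. The OL denominator is the window duration."""
    return summarize_event_exposure(
        {"start": iddi_record["window_start"], "end": iddi_record["interval_end"]},
        bouts, whale_pos, grid)


def summarize_windows(windows: pd.DataFrame, bouts: pd.DataFrame,
                      grid: ElevationGrid | None = None,
                      start_col="start", end_col="end") -> pd.DataFrame:
    """Exposure summaries for a table of time windows.

    ``windows`` needs start/end columns plus 'lat'/'lon' (NaN positions are
    allowed; distance and blocking then cannot be evaluated and the row's
    exposure distances are NaN when present)."""
    arr = _BoutArrays(bouts)
    s_ns = pd.to_datetime(windows[start_col], utc=True).astype("int64").to_numpy()
    e_ns = pd.to_datetime(windows[end_col], utc=True).astype("int64").to_numpy()
    lat = windows["lat"].to_numpy(dtype=float) if "lat" in windows else \
        np.full(len(windows), np.nan)
    lon = windows["lon"].to_numpy(dtype=float) if "lon" in windows else \
        np.full(len(windows), np.nan)
    res = [_summarize_one(s_ns[i], e_ns[i], lat[i], lon[i], arr, grid)
           for i in range(len(windows))]
    return pd.DataFrame(res, index=windows.index)


def _window_confirmed_free(start, end, free_periods) -> bool:
    covered = iv.overlap_seconds((start, end), free_periods)
    return covered >= (end - start).total_seconds() - 1e-6


def assemble_model_table(events: pd.DataFrame, iddis: pd.DataFrame,
                         combined, grid: ElevationGrid | None,
                         label: str, response: str) -> pd.DataFrame:
    """Build the model table for one response variable and dataset.

    ``events`` must carry per-event covariates (diel, subarea, on_soar,
    surface_seq, lat/lon) from geographic annotation; ``combined`` is a
    fusion.CombinedSonarRecord.

    SOAR: whale on SOAR, exposures restricted to on-SOAR bouts, and
    unexposed windows admitted only when fully inside confirmed MFAS-free
    periods. Complete: all locations, land-blocked exposures excluded,
    sub-area kept as an extra covariate. Rows with no modelled location are
    excluded from both tables (count in ``table.attrs['n_no_location']``).
    """
    if label not in ("SOAR", "Complete"):
        raise ValueError("label must be 'SOAR' or 'Complete'")
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response}")

    bouts = combined.bouts
    if label == "SOAR":
        bouts = bouts[bouts["on_soar"]] if len(bouts) else bouts

    if response == "iddi":
        base = iddis[~iddis["contains_gap"]].copy()
        if base.empty:
            base.attrs["n_no_location"] = 0
            return base
        ev = events.set_index("event_id")
        for col in ("lat", "lon", "diel", "subarea", "on_soar"):
            if col in ev.columns:
                base[col] = base["preceding_deep_event_id"].map(ev[col])
        base["y"] = base["iddi_min"]
        base["time"] = base["window_start"]
        start_col, end_col = "window_start", "interval_end"
    else:
        sel = {
            "deep_duration": (events["kind"] == "dive") & (events["dive_class"] == "deep"),
            "shallow_duration": (events["kind"] == "dive") & (events["dive_class"] == "shallow"),
            "shallow_depth": (events["kind"] == "dive") & (events["dive_class"] == "shallow"),
            "surface_interval": (events["kind"] == "surfacing")
            & (~events["surface_seq"].isin(["unknown", "n/a"])),
        }[response]
        base = events[sel].copy()
        if base.empty:
            base.attrs["n_no_location"] = 0
            return base
        base["y"] = (base["max_depth_m"] if response == "shallow_depth"
                     else base["duration_min"])
        base["time"] = base["start"]
        start_col, end_col = "start", "end"

    n0 = len(base)
    base = base[np.isfinite(base["lat"].astype(float))].copy()
    n_no_location = n0 - len(base)
    if base.empty:
        base.attrs["n_no_location"] = n_no_location
        return base

    expo = summarize_windows(base, bouts, grid if label == "Complete" else None,
                             start_col=start_col, end_col=end_col)
    table = pd.concat([base, expo], axis=1)

    if label == "SOAR":
        on = table["on_soar"].astype(bool)
        unexposed = table["presence_cat"] == "none"
        confirmed = np.array([
            _window_confirmed_free(r[start_col], r[end_col],
                                   combined.mfas_free_periods)
            for _, r in table.iterrows()], dtype=bool) if len(table) else \
            np.empty(0, dtype=bool)
        keep = on & (~unexposed | confirmed)
        table = table[keep].copy()
        table = table.drop(columns=["subarea"], errors="ignore")
    table = table.reset_index(drop=True)
    table.attrs["n_no_location"] = n_no_location
    table.attrs["dataset"] = label
    table.attrs["response"] = response
    return table
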
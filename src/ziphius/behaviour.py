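"""Behaviour-Log processing: event validation, dive-shape and deep/shallow
classification, surface-sequence labels and inter-deep-dive intervals.

A Behaviour Log (BL) is a satellite tag's summarized stream of alternating
'Dive' and 'Surfacing' events. Dives qualify only above 50 m depth and 30 s
duration (strictly greater; boundary values are rejected). Dives are split
into per-individual 'deep' (presumed foraging) and 'shallow' classes by
2-means clustering on z-scored (max depth, duration), so whales with
different depth ranges are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ParseResult", "parse_behaviour_log", "classify_dive_shape",
    "classify_dives_kmeans", "label_surface_sequence", "build_iddis",
    "GAP_TOLERANCE_S", "MIN_DIVE_DEPTH_M", "MIN_DIVE_DURATION_MIN",
]

GAP_TOLERANCE_S = 60.0          # BL timestamps are rounded; contiguity slack
MIN_DIVE_DEPTH_M = 50.0         # dives must exceed this (strict)
MIN_DIVE_DURATION_MIN = 0.5     # 30 s (strict)
_KMEANS_MIN_DIVES = 10
_FALLBACK_DEPTH_M = 800.0       # global split when a whale has too few dives


@dataclass
class ParseResult:
    events: pd.DataFrame
    errors: list = field(default_factory=list)


def parse_behaviour_log(table: pd.DataFrame) -> ParseResult:
    """Validate and order raw BL rows; flag gaps.

    Returns time-sorted events with an ``after_gap`` flag set on any event
    whose start is more than 60 s after the previous event's end.
    Unparseable or invalid rows (sub-threshold dives, overlapping events)
    are collected in ``errors`` -- never silently dropped.
    """
    errors = []
    rows = []
    for i, row in table.reset_index(drop=True).iterrows():
        try:
            kind = str(row["kind"]).strip().lower()
            if kind not in ("dive", "surfacing"):
                raise ValueError(f"unknown kind {row['kind']!r}")
            start = pd.Timestamp(row["start"])
            end = pd.Timestamp(row["end"])
            if start.tzinfo is None:
                start = start.tz_localize("UTC")
            if end.tzinfo is None:
                end = end.tz_localize("UTC")
            if end <= start:
                raise ValueError("end_time must exceed start_time")
            duration_min = (end - start).total_seconds() / 60.0
            if "duration_min" in row.index and pd.notna(row.get("duration_min")):
                if abs(float(row["duration_min"]) - duration_min) > 1.0 / 60.0:
                    raise ValueError("duration inconsistent with start/end")
            depth = float(row["max_depth_m"]) if kind == "dive" else np.nan
            if kind == "dive":
                if not depth > MIN_DIVE_DEPTH_M:
                    raise ValueError(
                        f"dive max_depth {depth} m not > {MIN_DIVE_DEPTH_M} m")
                if not duration_min > MIN_DIVE_DURATION_MIN:
                    raise ValueError(
                        f"dive duration {duration_min} min not > 0.5 min")
            frac = row.get("shape_frac", np.nan)
            shape = (classify_dive_shape(float(frac))
                     if kind == "dive" and pd.notna(frac) else
                     ("unknown" if kind == "dive" else "n/a"))
            rows.append({
                "whale_id": row["whale_id"], "kind": kind,
                "start": start, "end": end, "duration_min": duration_min,
                "max_depth_m": depth,
                "shape_frac": float(frac) if pd.notna(frac) else np.nan,
                "shape": shape,
            })
        except (KeyError, ValueError, TypeError) as exc:
            errors.append({"row": int(i), "error": str(exc)})

    ev = pd.DataFrame(rows)
    if ev.empty:
        ev = pd.DataFrame(columns=[
            "whale_id", "kind", "start", "end", "duration_min", "max_depth_m",
            "shape_frac", "shape", "after_gap"])
        return ParseResult(ev, errors)
    ev = ev.sort_values(["whale_id", "start"], kind="stable").reset_index(drop=True)

    flags = np.zeros(len(ev), dtype=bool)
    keep = np.ones(len(ev), dtype=bool)
    for _, idx in ev.groupby("whale_id", sort=False).groups.items():
        idx = list(idx)
        for a, b in zip(idx[:-1], idx[1:]):
            gap_s = (ev.at[b, "start"] - ev.at[a, "end"]).total_seconds()
            if gap_s < -1.0:  # overlap beyond timestamp rounding
                errors.append({
                    "row": int(b),
                    "error": f"event overlaps previous by {-gap_s:.0f} s"})
                keep[b] = False
            elif gap_s > GAP_TOLERANCE_S:
                flags[b] = True
    ev["after_gap"] = flags
    ev = ev[keep].reset_index(drop=True)
    ev.insert(0, "event_id", np.arange(len(ev)))
    return ParseResult(ev, errors)


def classify_dive_shape(frac_below_80pct: float) -> str:
    """Dive shape from the fraction of dive time spent below 80% of max
    depth: square (>= 0.5), U (0.2 <= f < 0.5), V (< 0.2)."""
    if not 0.0 <= frac_below_80pct <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if frac_below_80pct >= 0.5:
        return "square"
    if frac_below_80pct >= 0.2:
        return "U"
    return "V"


def classify_dives_kmeans(events: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Assign each dive a 'deep' or 'shallow' class per individual.

    2-means on per-whale z-scored (max depth, duration), 25 k-means++
    restarts under a fixed seed; the cluster with the larger mean depth is
    'deep'. Whales with fewer than 10 dives fall back to a global 800 m
    depth split (with a warning); a whale whose dives are all identical
    gets a single class (with a warning). Surfacings are labelled 'n/a'.
    """
    ev = events.copy()
    ev["dive_class"] = "n/a"
    for wid, grp in ev.groupby("whale_id", sort=False):
        dives = grp[grp["kind"] == "dive"]
        if dives.empty:
            continue
        X = dives[["max_depth_m", "duration_min"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError(f"non-finite depth/duration for whale {wid}")
        if len(dives) < _KMEANS_MIN_DIVES:
            warnings.warn(
                f"whale {wid}: only {len(dives)} dives; using global "
                f"{_FALLBACK_DEPTH_M:.0f} m depth split instead of k-means")
            lab = np.where(X[:, 0] >= _FALLBACK_DEPTH_M, "deep", "shallow")
            ev.loc[dives.index, "dive_class"] = lab
            continue
        sd = X.std(axis=0)
        if np.all(sd == 0):
            warnings.warn(f"whale {wid}: all dives identical; single class")
            ev.loc[dives.index, "dive_class"] = "shallow"
            continue
        Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        km = KMeans(n_clusters=2, n_init=25, random_state=seed).fit(Z)
        deep_cluster = int(np.argmax(
            [X[km.labels_ == k, 0].mean() for k in (0, 1)]))
        lab = np.where(km.labels_ == deep_cluster, "deep", "shallow")
        ev.loc[dives.index, "dive_class"] = lab
    return ev


def label_surface_sequence(events: pd.DataFrame) -> pd.DataFrame:
    """Label each surfacing by its position in the deep dive cycle.

    post-deep (after a deep dive, before a shallow), pre-deep (after a
    shallow, before a deep), intermediate (between shallow dives),
    post-and-pre-deep (between back-to-back deep dives). Surfacings next
    to a recording gap, or at the record edge, are 'unknown' and excluded
    from surface-interval models.
    """
    ev = events.copy()
    ev["surface_seq"] = "n/a"
    for _, idx in ev.groupby("whale_id", sort=False).groups.items():
        idx = list(idx)
        for pos, i in enumerate(idx):
            if ev.at[i, "kind"] != "surfacing":
                continue
            prev_i = idx[pos - 1] if pos > 0 else None
            next_i = idx[pos + 1] if pos + 1 < len(idx) else None
            label = "unknown"
            if prev_i is not None and next_i is not None:
                gap = (ev.at[i, "after_gap"] or ev.at[next_i, "after_gap"])
                prev_c = ev.at[prev_i, "dive_class"]
                next_c = ev.at[next_i, "dive_class"]
                if (not gap and ev.at[prev_i, "kind"] == "dive"
                        and ev.at[next_i, "kind"] == "dive"):
                    if prev_c == "deep" and next_c == "deep":
                        label = "post-and-pre-deep"
                    elif prev_c == "deep":
                        label = "post-deep"
                    elif next_c == "deep":
                        label = "pre-deep"
                    else:
                        label = "intermediate"
            ev.at[i, "surface_seq"] = label
    return ev


def build_iddis(events: pd.DataFrame) -> pd.DataFrame:
    """Inter-deep-dive intervals: end of one deep dive to start of the next.

    ``contains_gap`` marks intervals spanning any post-gap event (behaviour
    in the interval is not fully documented); such records carry no weight
    and are excluded from model tables. Weights (IDDI / min retained IDDI,
    always >= 1) counteract the bias toward short intervals created by the
    gap exclusion, computed over the retained records only.
    """
    records = []
    for wid, grp in events.groupby("whale_id", sort=False):
        grp = grp.sort_values("start", kind="stable")
        deep = grp[(grp["kind"] == "dive") & (grp["dive_class"] == "deep")]
        if len(deep) < 2:
            continue
        for (_, d0), (_, d1) in zip(deep.iterrows(), deep.iloc[1:].iterrows()):
            between = grp[(grp["start"] > d0["start"]) & (grp["start"] <= d1["start"])]
            contains_gap = bool(between["after_gap"].any())
            iddi = (d1["start"] - d0["end"]).total_seconds() / 60.0
            if iddi <= 0:
                continue
            records.append({
                "whale_id": wid,
                "interval_start": d0["end"], "interval_end": d1["start"],
                "window_start": d0["start"],  # deep-dive-cycle exposure window
                "iddi_min": iddi,
                "preceding_deep_duration_min": d0["duration_min"],
                "preceding_deep_event_id": d0.get("event_id", -1),
                "contains_gap": contains_gap,
            })
    iddis = pd.DataFrame(records)
    if iddis.empty:
        return pd.DataFrame(columns=[
            "whale_id", "interval_start", "interval_end", "window_start",
            "iddi_min", "preceding_deep_duration_min",
            "preceding_deep_event_id", "contains_gap", "weight"])
    retained = iddis.loc[~iddis["contains_gap"], "iddi_min"]
    iddis["weight"] = np.nan
    if len(retained):
        iddis.loc[~iddis["contains_gap"], "weight"] = retained / retained.min()
    return iddis
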
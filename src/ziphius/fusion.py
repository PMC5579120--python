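"""Fusing the two sonar records: quality control of manually entered SPORTS
bout reports, deduplication against hydrophone-archive bouts, and assembly
of the combined record plus confirmed MFAS-free periods.

The archive is authoritative on the instrumented range (SOAR): it records
both sonar use and, crucially, verified absence of sonar. SPORTS is the
only record away from the range but is transcribed by hand, so records are
screened (never silently dropped) and duplicates of archive bouts removed:
bouts of one type whose start, end or duration differ by under 15 min and
whose start positions lie within 10 km are duplicate candidates; the
archive copy wins on SOAR, the SPORTS copy off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .geo import great_circle_km

__all__ = ["qc_sports", "find_duplicates", "resolve_duplicates",
           "assemble_combined", "CombinedSonarRecord",
           "DUP_TIME_WINDOW_MIN", "DUP_DIST_KM"]

DUP_TIME_WINDOW_MIN = 15.0
DUP_DIST_KM = 10.0
LONG_DURATION_MIN = 1440.0          # >= 24 h is never plausible
MAX_PLATFORM_SPEED_KMH = 300.0      # inter-report speed screen


def _dur_min(df):
    return (pd.to_datetime(df["end_time"], utc=True)
            - pd.to_datetime(df["start_time"], utc=True)).dt.total_seconds() / 60.0


def qc_sports(records: pd.DataFrame, max_plausible_min: dict | None = None
              ) -> pd.DataFrame:
    """Attach QC flags to SPORTS records; flags never drop records.

    Flags: 'exceeds_archive_max' (duration above the per-type archive
    maximum), 'long_duration' (>= 24 h), 'implausible_speed' (consecutive
    reports from one platform implying > 300 km/h). end < start is a hard
    error -- such a row is not a usable interval at all.
    """
    rec = records.copy().reset_index(drop=True)
    rec["start_time"] = pd.to_datetime(rec["start_time"], utc=True)
    rec["end_time"] = pd.to_datetime(rec["end_time"], utc=True)
    if (rec["end_time"] < rec["start_time"]).any():
        bad = rec.index[rec["end_time"] < rec["start_time"]].tolist()
        raise ValueError(f"SPORTS rows with end before start: {bad}")
    dur = _dur_min(rec)
    flags = [set() for _ in range(len(rec))]
    if max_plausible_min:
        for i, (typ, d) in enumerate(zip(rec["sonar_type"], dur)):
            if typ in max_plausible_min and d > max_plausible_min[typ]:
                flags[i].add("exceeds_archive_max")
    for i, d in enumerate(dur):
        if d >= LONG_DURATION_MIN:
            flags[i].add("long_duration")
    if "platform_id" in rec.columns:
        for _, grp in rec.dropna(subset=["platform_id"]).groupby("platform_id"):
            g = grp.sort_values("start_time")
            idx = g.index.to_list()
            for a, b in zip(idx[:-1], idx[1:]):
                d_km = great_circle_km(rec.at[a, "start_lat"], rec.at[a, "start_lon"],
                                       rec.at[b, "start_lat"], rec.at[b, "start_lon"])
                dt_h = max((rec.at[b, "start_time"]
                            - rec.at[a, "start_time"]).total_seconds() / 3600.0, 1e-9)
                if d_km / dt_h > MAX_PLATFORM_SPEED_KMH:
                    flags[b].add("implausible_speed")
    rec["qc_flags"] = [";".join(sorted(f)) for f in flags]
    return rec


def find_duplicates(archive_bouts: pd.DataFrame, sports_records: pd.DataFrame,
                    time_window_min: float = DUP_TIME_WINDOW_MIN,
                    dist_km: float = DUP_DIST_KM) -> pd.DataFrame:
    """Candidate duplicate pairs between archive bouts and SPORTS records.

    A pair qualifies iff the sonar types match AND any one time metric
    (start, end or duration) differs by less than ``time_window_min`` AND
    the start positions are within ``dist_km`` great-circle km.
    """
    pairs = []
    a = archive_bouts.reset_index(drop=True)
    s = sports_records.reset_index(drop=True)
    if a.empty or s.empty:
        return pd.DataFrame(columns=["archive_idx", "sports_idx",
                                     "dstart_min", "dist_km"])
    a_dur = _dur_min(a).to_numpy()
    s_dur = _dur_min(s).to_numpy()
    for i, ar in a.iterrows():
        for j, sr in s.iterrows():
            if ar["sonar_type"] != sr["sonar_type"]:
                continue
            dstart = abs((ar["start_time"] - sr["start_time"]).total_seconds()) / 60.0
            dend = abs((ar["end_time"] - sr["end_time"]).total_seconds()) / 60.0
            ddur = abs(a_dur[i] - s_dur[j])
            if min(dstart, dend, ddur) >= time_window_min:
                continue
            d = great_circle_km(ar["start_lat"], ar["start_lon"],
                                sr["start_lat"], sr["start_lon"])
            if d < dist_km:
                pairs.append({"archive_idx": int(i), "sports_idx": int(j),
                              "dstart_min": dstart, "dist_km": float(d)})
    return pd.DataFrame(pairs) if pairs else pd.DataFrame(
        columns=["archive_idx", "sports_idx", "dstart_min", "dist_km"])


def resolve_duplicates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Assign each SPORTS record to at most one archive bout.

    Greedy by smallest start-time difference, ties by start distance. An
    archive bout may absorb several SPORTS records (a 'lumped' archive bout
    matching 'split' SPORTS reports), but never vice versa.
    """
    if pairs.empty:
        return pairs.copy()
    order = pairs.sort_values(["dstart_min", "dist_km"], kind="stable")
    taken_sports = set()
    chosen = []
    for _, row in order.iterrows():
        if row["sports_idx"] in taken_sports:
            continue
        taken_sports.add(row["sports_idx"])
        chosen.append(row)
    return pd.DataFrame(chosen).reset_index(drop=True)


@dataclass
class CombinedSonarRecord:
    """The assembled sonar record: retained bouts, confirmed MFAS-free
    intervals on the range, archive coverage, and a per-input audit."""

    bouts: pd.DataFrame
    mfas_free_periods: list
    archive_coverage: list
    audit: dict = field(default_factory=dict)


def assemble_combined(archive_bouts: pd.DataFrame, sports_records: pd.DataFrame,
                      coverage: list) -> CombinedSonarRecord:
    """Assemble the combined sonar dataset and confirmed-free periods.

    Retains: all on-SOAR archive bouts; all off-SOAR SPORTS bouts not
    duplicating an archive bout; off-SOAR archive bouts unreported in
    SPORTS (low-accuracy positions); and on-SOAR SPORTS bouts only during
    archive outages. Drops on-SOAR SPORTS bouts that fall in confirmed-free
    periods (archive listening, nothing heard) and, with a contradiction
    report, those overlapping archive-covered time without a matching
    archive bout. Confirmed-free periods are coverage minus on-SOAR bout
    spans, exactly. Every input bout is accounted for in the audit.
    """
    a = archive_bouts.reset_index(drop=True).copy()
    s = sports_records.reset_index(drop=True).copy()
    for df, src in ((a, "archive"), (s, "sports")):
        df["source"] = src
        df["start_time"] = pd.to_datetime(df["start_time"], utc=True)
        df["end_time"] = pd.to_datetime(df["end_time"], utc=True)
    if "position_quality" not in a.columns:
        a["position_quality"] = "localized"
    s["position_quality"] = "reported"

    pairs = resolve_duplicates(find_duplicates(a, s))
    sports_dup_to_archive = {}  # sports_idx -> archive_idx
    if not pairs.empty:
        sports_dup_to_archive = dict(
            zip(pairs["sports_idx"].astype(int), pairs["archive_idx"].astype(int)))

    on_soar_archive = a[a["on_soar"]] if len(a) else a
    free = iv.subtract(coverage, [
        (r["start_time"], r["end_time"]) for _, r in on_soar_archive.iterrows()])

    decisions = []
    kept = []
    for i, r in a.iterrows():
        kept.append(r)
        reason = ("on_soar_archive" if r["on_soar"]
                  else "off_soar_archive_unreported"
                  if i not in set(sports_dup_to_archive.values())
                  else "off_soar_archive")
        decisions.append({"source": "archive", "idx": int(i),
                          "action": "kept", "reason": reason})
    # off-SOAR archive bouts duplicated in SPORTS: SPORTS wins off range
    off_dups = {ai for si, ai in sports_dup_to_archive.items()
                if not a.at[ai, "on_soar"]}
    kept_a, dec_a = [], []
    for r, d in zip(kept, decisions):
        if d["idx"] in off_dups:
            d.update(action="dropped", reason="duplicate_kept_in_sports")
            dec_a.append(d)
        else:
            kept_a.append(r)
            dec_a.append(d)
    decisions = dec_a
    kept = kept_a

    for j, r in s.iterrows():
        if j in sports_dup_to_archive:
            ai = sports_dup_to_archive[j]
            if a.at[ai, "on_soar"]:
                decisions.append({"source": "sports", "idx": int(j),
                                  "action": "dropped",
                                  "reason": "duplicate_kept_in_archive"})
                continue
            kept.append(r)
            decisions.append({"source": "sports", "idx": int(j),
                              "action": "kept", "reason": "off_soar_duplicate"})
            continue
        if not r.get("on_soar", False):
            kept.append(r)
            decisions.append({"source": "sports", "idx": int(j),
                              "action": "kept", "reason": "off_soar_sports"})
            continue
        span = [(r["start_time"], r["end_time"])]
        in_free = iv.total_seconds(iv.intersect(span, free))
        in_cov = iv.total_seconds(iv.intersect(span, coverage))
        if in_free > 0:
            decisions.append({"source": "sports", "idx": int(j),
                              "action": "dropped",
                              "reason": "inside_confirmed_free"})
        elif in_cov > 0:
            decisions.append({"source": "sports", "idx": int(j),
                              "action": "dropped",
                              "reason": "contradicts_archive"})
        else:
            kept.append(r)
            decisions.append({"source": "sports", "idx": int(j),
                              "action": "kept", "reason": "archive_outage"})

    cols = ["source", "sonar_type", "start_time", "end_time",
            "start_lat", "start_lon", "position_quality", "on_soar"]
    bouts = (pd.DataFrame(kept)[cols].sort_values("start_time")
             .reset_index(drop=True)) if kept else pd.DataFrame(columns=cols)

    audit = {
        "n_archive_in": int(len(a)), "n_sports_in": int(len(s)),
        "n_kept": int(len(bouts)),
        "decisions": decisions,
        "free_hours": iv.total_seconds(free) / 3600.0,
        "coverage_hours": iv.total_seconds(coverage) / 3600.0,
    }
    n_accounted = len([d for d in decisions])
    assert n_accounted == len(a) + len(s), "conservation violated"
    return CombinedSonarRecord(bouts=bouts, mfas_free_periods=free,
                               archive_coverage=iv.normalize(coverage),
                               audit=audit)
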
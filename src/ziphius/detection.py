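"""Sonar detection from hard-limited FFT reports: adaptive-threshold
binarization, ping extraction, clutter screening, bout segmentation,
TDOA localization and false-negative auditing.

Bottom-mounted hydrophones stream detection reports: one report per FFT
frame per hydrophone, carrying hard-limited (0/1) frequency bins. Sonar
pings appear as runs of consecutive in-band frames longer than 1 s; real
transmissions repeat at regular 20-30 s intervals, which separates them
from dolphin-whistle clutter. A transmission bout is continuous while the
inter-detection interval on any single hydrophone stays under 3 min.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import intervals as iv
from .geo import LocalProjection

__all__ = [
    "DetectorConfig", "stft_bin_width_hz", "stft_frame_step_s",
    "frame_step_from_bin_width_s", "hard_limit", "detect_pings",
    "screen_false_positives", "segment_bouts", "localize_bout",
    "estimate_false_negative_rate", "reports_to_ndjson", "reports_from_ndjson",
]

SOUND_SPEED_MS = 1500.0  # nominal; configurable where used


# ---------------------------------------------------------------------------
# STFT bookkeeping
# ---------------------------------------------------------------------------

def stft_bin_width_hz(fs: float, nfft: int) -> float:
    """Frequency resolution of an nfft-point FFT at sampling rate fs."""
    return fs / nfft


def stft_frame_step_s(fs: float, nfft: int, overlap: float = 0.5) -> float:
    """Time advance between frames for the given overlap fraction."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    return nfft * (1.0 - overlap) / fs

def frame_step_from_bin_width_s(bin_width_hz: float, overlap: float = 0.5) -> float:
    """Frame step implied by a bin width at the given overlap: with 50%
    overlap the step is 1 / (2 * bin width), independent of fs."""
    return (1.0 - overlap) / bin_width_hz


@dataclass
class DetectorConfig:
    band_lo_hz: float = 2500.0
    band_hi_hz: float = 5000.0
    min_ping_s: float = 1.0
    ema_alpha: float = 0.995          # per-frame smoothing of the noise floor
    threshold_factor: float = 3.0     # multiplier on the exponential average
    idi_regular_lo_s: float = 20.0
    idi_regular_hi_s: float = 30.0
    idi_tolerance: float = 0.25       # +/- band around the regular IDI range
    bout_continuity_s: float = 180.0  # < 3 min on any one hydrophone
    min_train: int = 3
    cross_hydro_link_s: float = 10.0  # same ping arriving on several phones
    switch_rate_per_min: float = 4.0  # closest-hydrophone churn -> multi-source
    switch_sustain_s: float = 120.0
    type_level_split_db: float = 150.0  # bout median ping level: high vs mid

    def __post_init__(self):
        if not self.band_lo_hz < self.band_hi_hz:
            raise ValueError("band_lo must be < band_hi")


# ---------------------------------------------------------------------------
# Hard limiting
# ---------------------------------------------------------------------------

def hard_limit(frames, config: DetectorConfig | None = None) -> pd.DataFrame:
    """Binarize spectral frames with a per-bin adaptive threshold.

    ``frames``: dict with keys hydrophone_id, fs, nfft, times (frame start
    times, UTC) and power ((n_frames, nfft//2) linear power). A per-bin
    exponential moving average T tracks the noise floor; a bin is set to 1
    when its power exceeds threshold_factor * T (the average *before* the
    current frame, so an isolated impulse registers). Returns one report
    per frame. Reports with no bins set are retained (they define archive
    coverage) unless ``frames['sparse']`` is true.
    """
    config = config or DetectorConfig()
    fs = float(frames["fs"])
    nfft = int(frames["nfft"])
    power = np.asarray(frames["power"], dtype=float)
    times = pd.to_datetime(pd.Index(frames["times"]), utc=True)
    if power.shape[0] != len(times):
        raise ValueError("times and power frame counts differ")
    if power.shape[1] != nfft // 2:
        raise ValueError("power must have nfft/2 bins")
    alpha = config.ema_alpha
    ema = power[0].copy()
    bin_hz = stft_bin_width_hz(fs, nfft)
    freqs = np.arange(nfft // 2) * bin_hz
    rows = []
    for i in range(power.shape[0]):
        p = power[i]
        hot = p > config.threshold_factor * ema
        ema = alpha * ema + (1.0 - alpha) * p
        idx = np.flatnonzero(hot)
        if idx.size:
            k = idx[np.argmax(p[idx])]
        else:
            k = int(np.argmax(p))
        rows.append({
            "time": times[i], "hydrophone_id": frames["hydrophone_id"],
            "fs": fs, "nfft": nfft,
            "bins_above": idx,
            "n_bins_above": int(idx.size),
            "peak_freq_hz": float(freqs[k]),
            "peak_level_db": float(10.0 * math.log10(max(p[k], 1e-300))),
        })
    reports = pd.DataFrame(rows)
    if frames.get("sparse"):
        reports = reports[reports["n_bins_above"] > 0].reset_index(drop=True)
    return reports


def reports_to_ndjson(reports: pd.DataFrame, path):
    with open(path, "w") as fh:
        for _, r in reports.iterrows():
            fh.write(json.dumps({
                "time": r["time"].isoformat(),
                "hydrophone_id": r["hydrophone_id"],
                "fs": r["fs"], "nfft": int(r["nfft"]),
                "bins_above": [int(b) for b in r["bins_above"]],
                "peak_freq_hz": r["peak_freq_hz"],
                "peak_level_db": r["peak_level_db"],
            }) + "\n")


def reports_from_ndjson(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            d["time"] = pd.Timestamp(d["time"])
            d["bins_above"] = np.asarray(d["bins_above"], dtype=int)
            d["n_bins_above"] = int(d["bins_above"].size)
            rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ping extraction
# ---------------------------------------------------------------------------

def detect_pings(reports: pd.DataFrame, config: DetectorConfig | None = None
                 ) -> pd.DataFrame:
    """Extract pings: runs of consecutive frames with in-band bins set.

    Frames are consecutive when their indices (time / frame step) are
    adjacent; a single clear frame ends the run (no bridging). Duration is
    n_frames * frame step; only runs longer than min_ping_s are emitted.
    Frames absent from a sparse stream count as clear.
    """
    config = config or DetectorConfig()
    pings = []
    if reports.empty:
        return pd.DataFrame(columns=[
            "hydrophone_id", "start_time", "duration_s",
            "peak_freq_hz", "peak_level_db"])
    for hid, grp in reports.groupby("hydrophone_id", sort=True):
        grp = grp.sort_values("time")
        fs = float(grp["fs"].iloc[0])
        nfft = int(grp["nfft"].iloc[0])
        if (grp["fs"] != fs).any() or (grp["nfft"] != nfft).any():
            raise ValueError(f"inconsistent fs/nfft on hydrophone {hid}")
        step = stft_frame_step_s(fs, nfft)
        bin_hz = stft_bin_width_hz(fs, nfft)
        lo = int(np.ceil(config.band_lo_hz / bin_hz))
        hi = int(np.floor(config.band_hi_hz / bin_hz))
        t0 = grp["time"].iloc[0]
        fidx = np.round(
            (grp["time"] - t0).dt.total_seconds().to_numpy() / step).astype(int)
        inband = np.array([
            np.any((b >= lo) & (b <= hi)) for b in grp["bins_above"]])
        run_start = None
        prev = None
        levels, freqs = [], []
        rows = list(zip(fidx, inband, grp["time"],
                        grp["peak_level_db"], grp["peak_freq_hz"]))
        rows.append((fidx[-1] + 2, False, None, None, None))  # sentinel
        for fi, band, t, lev, fr in rows:
            contiguous = prev is not None and fi == prev + 1
            if band and run_start is not None and contiguous:
                levels.append(lev)
                freqs.append(fr)
            elif band:
                if run_start is not None:
                    _emit(pings, hid, run_start, len(levels), step,
                          levels, freqs, config)
                run_start, levels, freqs = t, [lev], [fr]
            else:
                if run_start is not None:
                    _emit(pings, hid, run_start, len(levels), step,
                          levels, freqs, config)
                run_start, levels, freqs = None, [], []
            prev = fi if t is not None else prev + 2
    return pd.DataFrame(pings).sort_values(
        ["start_time", "hydrophone_id"]).reset_index(drop=True) if pings else \
        pd.DataFrame(columns=["hydrophone_id", "start_time", "duration_s",
                              "peak_freq_hz", "peak_level_db"])


def _emit(pings, hid, start, n_frames, step, levels, freqs, config):
    dur = n_frames * step
    if dur > config.min_ping_s:
        k = int(np.argmax(levels))
        pings.append({
            "hydrophone_id": hid, "start_time": start, "duration_s": dur,
            "peak_freq_hz": float(freqs[k]), "peak_level_db": float(levels[k]),
        })


# ---------------------------------------------------------------------------
# Clutter screening
# ---------------------------------------------------------------------------

def screen_false_positives(pings: pd.DataFrame,
                           config: DetectorConfig | None = None) -> pd.DataFrame:
    """Keep pings that belong to regular trains; drop whistle-like clutter.

    Per hydrophone, pings are grouped into candidate trains wherever the
    gap to the previous ping is under the 3-min continuity window. A train
    survives only if it has >= min_train pings and a median inter-detection
    interval inside the regular MFAS band [20, 30] s widened by +/-25%.
    Isolated pings and irregular clusters are dropped.
    """
    config = config or DetectorConfig()
    if pings.empty:
        return pings.copy()
    lo = config.idi_regular_lo_s * (1.0 - config.idi_tolerance)
    hi = config.idi_regular_hi_s * (1.0 + config.idi_tolerance)
    kept = []
    for _, grp in pings.groupby("hydrophone_id", sort=True):
        grp = grp.sort_values("start_time")
        t = grp["start_time"]
        gaps = t.diff().dt.total_seconds().to_numpy()
        train_id = np.cumsum(~(gaps <= config.bout_continuity_s))
        for _, train in grp.groupby(train_id):
            if len(train) < config.min_train:
                continue
            idi = train["start_time"].diff().dt.total_seconds().dropna()
            med = float(idi.median())
            if lo <= med <= hi:
                kept.append(train)
    if not kept:
        return pings.iloc[:0].copy()
    return pd.concat(kept).sort_values(
        ["start_time", "hydrophone_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bout segmentation
# ---------------------------------------------------------------------------

def bout_linked(p, q, config: DetectorConfig) -> bool:
    """Pair predicate: same transmission period. Same hydrophone within the
    3-min continuity window, or any two hydrophones within the propagation
    window (one ping heard on several phones)."""
    dt = abs((p["start_time"] - q["start_time"]).total_seconds())
    if p["hydrophone_id"] == q["hydrophone_id"]:
        return dt < config.bout_continuity_s
    return dt < config.cross_hydro_link_s


def segment_bouts(pings: pd.DataFrame, config: DetectorConfig | None = None
                  ) -> pd.DataFrame:
    """Group screened pings into transmission bouts.

    Bouts are the transitive closure of `bout_linked`. Because both linkage
    rules are pure time-difference thresholds, linking each ping to its
    immediate predecessor per hydrophone (3-min rule) and globally
    (propagation rule) yields exactly the all-pairs transitive closure.
    Each bout records the closest-hydrophone sequence (loudest phone per
    ping cluster) and a multi-source flag when that sequence churns faster
    than the configured switch rate for a sustained period.
    """
    config = config or DetectorConfig()
    if pings.empty:
        return pd.DataFrame(columns=[
            "bout_id", "start_time", "end_time", "n_pings", "sonar_type",
            "median_level_db", "closest_hydrophone_sequence", "multi_source"])
    p = pings.sort_values(["start_time", "hydrophone_id"]).reset_index(drop=True)
    n = len(p)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def link(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    t = p["start_time"]
    secs = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    last_on = {}
    for i in range(n):
        hid = p.at[i, "hydrophone_id"]
        if hid in last_on and secs[i] - secs[last_on[hid]] < config.bout_continuity_s:
            link(last_on[hid], i)
        last_on[hid] = i
        if i > 0 and secs[i] - secs[i - 1] < config.cross_hydro_link_s:
            link(i - 1, i)

    p["bout_key"] = [find(i) for i in range(n)]
    bouts = []
    for bid, (key, grp) in enumerate(p.groupby("bout_key", sort=True)):
        grp = grp.sort_values("start_time")
        seq, switch_times = _closest_sequence(grp, config)
        multi = _rapid_switching(switch_times, config) or _idi_bimodal(grp, config)
        start = grp["start_time"].min()
        end = (grp["start_time"] + pd.to_timedelta(grp["duration_s"], unit="s")).max()
        med_level = float(grp["peak_level_db"].median())
        dur_min = (end - start).total_seconds() / 60.0
        sonar_type = "high" if med_level >= config.type_level_split_db else "mid"
        bouts.append({
            "bout_id": bid, "start_time": start, "end_time": end,
            "n_pings": len(grp), "sonar_type": sonar_type,
            "median_level_db": med_level, "duration_min": dur_min,
            "closest_hydrophone_sequence": seq, "multi_source": bool(multi),
        })
    return pd.DataFrame(bouts)


def _closest_sequence(grp, config):
    """Loudest hydrophone per ping cluster over the bout (clusters are pings
    within the propagation window); returns the deduplicated sequence and
    the times of closest-hydrophone switches."""
    g = grp.sort_values("start_time")
    t = g["start_time"]
    gaps = t.diff().dt.total_seconds().to_numpy()
    cluster = np.cumsum(~(gaps < config.cross_hydro_link_s))
    seq, switch_times = [], []
    for _, cl in g.groupby(cluster):
        hid = cl.loc[cl["peak_level_db"].idxmax(), "hydrophone_id"]
        if not seq or seq[-1] != hid:
            if seq:
                switch_times.append(cl["start_time"].min())
            seq.append(hid)
    return seq, switch_times


def _rapid_switching(switch_times, config):
    if len(switch_times) < 2:
        return False
    st = pd.Series(switch_times)
    window = pd.Timedelta(seconds=config.switch_sustain_s)
    need = config.switch_rate_per_min * config.switch_sustain_s / 60.0
    for i in range(len(st)):
        n_in = int(((st >= st[i]) & (st < st[i] + window)).sum())
        if n_in >= need:
            return True
    return False


def _idi_bimodal(grp, config):
    """Crude bimodality screen on one-hydrophone IDIs: a large spread of the
    IDI distribution relative to its median flags interleaved sources."""
    flags = []
    for _, g in grp.groupby("hydrophone_id"):
        idi = g["start_time"].sort_values().diff().dt.total_seconds().dropna()
        idi = idi[idi < config.bout_continuity_s]
        if len(idi) >= 6:
            q1, q3 = idi.quantile([0.25, 0.75])
            flags.append((q3 - q1) > 0.8 * idi.median())
    return any(flags)


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

def _collinear(xy, tol=1e-3):
    c = xy - xy.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size < 2 or s[1] < tol * max(s[0], 1e-12)


def localize_bout(arrivals: dict, layout: dict, c: float = SOUND_SPEED_MS):
    """TDOA source position from ping arrival times on >= 3 hydrophones.

    ``arrivals``: hydrophone_id -> arrival time (s, shared clock);
    ``layout``: hydrophone_id -> (lat, lon). Returns
    (lat, lon, position_quality) where quality is 'localized' or
    'nearest_edge_phone' (fewer than 3 usable phones, collinear geometry,
    or a divergent solve -- position of the earliest-arrival phone).
    """
    hydros = [h for h in arrivals if h in layout]
    if not hydros:
        raise ValueError("no arrival has a known hydrophone position")
    nearest = min(hydros, key=lambda h: arrivals[h])
    fallback = (layout[nearest][0], layout[nearest][1], "nearest_edge_phone")
    if len(hydros) < 3:
        return fallback
    lat0 = float(np.mean([layout[h][0] for h in hydros]))
    lon0 = float(np.mean([layout[h][1] for h in hydros]))
    proj = LocalProjection(lat0, lon0)
    xy = np.array([proj.forward(*layout[h]) for h in hydros], dtype=float)
    if _collinear(xy):
        return fallback
    t = np.array([arrivals[h] for h in hydros], dtype=float)
    ref = int(np.argmin(t))
    ckm = c / 1000.0  # km/s

    def resid(pos):
        d = np.hypot(xy[:, 0] - pos[0], xy[:, 1] - pos[1])
        return (d - d[ref]) / ckm - (t - t[ref])

    x0 = xy[ref]
    sol = least_squares(resid, x0, method="lm", max_nfev=200)
    span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
    if (not sol.success or not np.all(np.isfinite(sol.x))
            or np.hypot(*(sol.x - xy.mean(axis=0))) > 50.0 * max(span, 1.0)):
        return fallback
    lat, lon = proj.inverse(sol.x[0], sol.x[1])
    return float(lat), float(lon), "localized"


# ---------------------------------------------------------------------------
# False-negative audit
# ---------------------------------------------------------------------------

def estimate_false_negative_rate(detected_bouts, truth_bouts, coverage):
    """Fraction of truly ensonified time inside detector-declared quiet.

    All three arguments are interval lists [(start, end), ...]; quiet is
    coverage minus detected bout spans. Returns missed-time / quiet-time
    (0 when there is no quiet time).
    """
    quiet = iv.subtract(coverage, detected_bouts)
    quiet_s = iv.total_seconds(quiet)
    if quiet_s == 0:
        return 0.0
    missed_s = iv.total_seconds(iv.intersect(quiet, truth_bouts))
    return missed_s / quiet_s
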
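"""Synthetic study generator: whale tracks, Argos fixes, behaviour logs,
sonar schedules (hydrophone archive + hand-entered SPORTS reports) and
hard-limited detection reports, with known ground truth.

The default configuration IS the study condition set: ~3-week deployments
of 16 satellite-tagged whales over an instrumented range (SOAR) inside a
deep basin, a ~175-min mean deep-dive cycle (one ~60-min deep foraging dive
followed by a ~115-min inter-deep-dive interval of shallow dive/surfacing
pairs), two sonar types (high: long, ship-borne bouts, median ~67 min on
the range; mid: short, clustered bouts, median ~7 min), and planted
exposure responses: mid-type sonar within 5 km lengthens deep dives by
30 min (decaying to zero at 40 km) and doubles the inter-deep-dive
interval within 20 km (decaying to none at 100 km); the high type has no
planted behavioural effect. All stochastic draws go through one seeded
generator, so a scenario is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import ElevationGrid, LocalProjection, SubareaPolygons
from .movement import ou_transition, solar_elevation

__all__ = [
    "ScenarioConfig", "GroundTruth", "Scenario", "simulate_scenario",
    "gen_bathymetry", "gen_subareas", "gen_whale_track", "gen_behaviour_log",
    "gen_sonar_schedule", "gen_detection_reports", "lognormal_from_median",
]


def lognormal_from_median(rng, median, sigma, size=None):
    """Log-normal draws parameterized by their median and log-scale SD."""
    return median * np.exp(sigma * rng.standard_normal(size))


@dataclass
class ScenarioConfig:
    # study frame
    n_whales: int = 16
    days: float = 22.0
    start: str = "2011-01-10T00:00:00Z"
    center_lat: float = 33.25
    center_lon: float = -119.0
    # movement (CTCRW: velocity OU at rate beta, intensity sigma)
    ctcrw_beta: float = 1.0            # 1/h
    ctcrw_sigma: float = 1.5           # km/h^1.5
    track_step_min: float = 5.0
    argos_per_day: float = 12.0
    argos_class_probs: dict = field(default_factory=lambda: {
        "L3": 0.05, "L2": 0.10, "L1": 0.20, "L0": 0.25, "A": 0.20, "B": 0.20})
    argos_outlier_prob: float = 0.01   # gross mislocations for the speed filter
    # behaviour-log grammar (medians, minutes)
    deep_duration_min: float = 60.0
    deep_sigma: float = 0.15
    shallow_duration_min: float = 20.0
    shallow_sigma: float = 0.3
    surface_min: float = 2.5
    surface_sigma: float = 0.3
    n_shallow_pairs_mean: float = 5.0  # Poisson; cycle mean ~175 min
    deep_depth_m: float = 1100.0
    deep_depth_sigma: float = 0.15
    shallow_depth_m: float = 250.0
    shallow_depth_sigma: float = 0.35
    deep_day_extra_min: float = 6.0    # diel effect on deep-dive duration
    gap_rate: float = 0.04             # per-event message-loss probability
    # planted exposure responses (mid type only)
    mid_deep_extra_min: float = 30.0
    mid_deep_full_km: float = 5.0
    mid_deep_zero_km: float = 40.0
    iddi_multiplier: float = 2.0
    iddi_full_km: float = 20.0
    iddi_none_km: float = 100.0
    # sonar schedule
    high_rate_per_day: float = 1.0
    high_median_min: float = 67.0
    high_sigma: float = 0.5
    high_on_soar_frac: float = 0.8
    mid_clusters_per_day: float = 0.5
    mid_cluster_size_mean: float = 3.0   # 1 + Poisson
    mid_gap_median_min: float = 30.0
    mid_median_min: float = 7.0
    mid_sigma: float = 0.7
    mid_on_soar_frac: float = 0.6
    n_outages: int = 2
    outage_hours: float = 12.0
    # SPORTS corruption
    sports_report_prob: float = 0.8
    sports_start_jitter_min: float = 4.0
    sports_pos_jitter_km: float = 2.0
    sports_long_error_prob: float = 0.03   # +24 h transcribed end time
    # SOAR box half-extents (degrees)
    soar_half_lat: float = 0.25
    soar_half_lon: float = 0.30

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)

    @property
    def end_ts(self) -> pd.Timestamp:
        return self.start_ts + pd.Timedelta(days=self.days)


@dataclass
class GroundTruth:
    tracks: pd.DataFrame          # true positions, all whales
    events: pd.DataFrame          # every behaviour event, incl. lost messages
    bouts: pd.DataFrame           # every sonar bout, uncorrupted
    outages: list                 # archive outage intervals
    params: ScenarioConfig


@dataclass
class Scenario:
    config: ScenarioConfig
    grid: ElevationGrid
    polygons: SubareaPolygons
    argos: pd.DataFrame
    behaviour_log: pd.DataFrame
    archive_bouts: pd.DataFrame
    sports_records: pd.DataFrame
    coverage: list
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def gen_bathymetry(config: ScenarioConfig | None = None) -> ElevationGrid:
    """Deep basin (<= -1000 m) around the range with one emergent island
    (>= +10 m) to the northeast, on a 0.05-degree grid."""
    c = config or ScenarioConfig()
    lats = np.arange(c.center_lat - 3.0, c.center_lat + 3.0001, 0.05)
    lons = np.arange(c.center_lon - 3.5, c.center_lon + 3.5001, 0.05)
    LA, LO = np.meshgrid(lats, lons, indexing="ij")
    depth = -1200.0 - 600.0 * np.exp(
        -((LA - c.center_lat) ** 2 + (LO - c.center_lon) ** 2) / (2 * 0.8 ** 2))
    isl_lat, isl_lon = c.center_lat + 0.7, c.center_lon + 0.9
    island = 1800.0 * np.exp(
        -((LA - isl_lat) ** 2 + (LO - isl_lon) ** 2) / (2 * 0.06 ** 2))
    return ElevationGrid(lats, lons, depth + island)


def gen_subareas(config: ScenarioConfig | None = None) -> SubareaPolygons:
    c = config or ScenarioConfig()
    la, lo = c.center_lat, c.center_lon
    soar = box(lo - c.soar_half_lon, la - c.soar_half_lat,
               lo + c.soar_half_lon, la + c.soar_half_lat)
    basin = box(lo - 1.0, la - 0.8, lo + 1.0, la + 0.8)
    east = box(lo + 1.0, la - 0.8, lo + 2.5, la + 0.8)
    return SubareaPolygons({"SOAR": soar, "San Nic": basin, "East Basin": east})


def island_position(config: ScenarioConfig | None = None):
    c = config or ScenarioConfig()
    return c.center_lat + 0.7, c.center_lon + 0.9


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------

def gen_whale_track(config: ScenarioConfig, whale_id, rng):
    """(true_track, argos_fixes) for one whale.

    The true track is an exact simulation of the CTCRW (no Euler error) on
    a regular grid; Argos fixes thin it at a Poisson rate and add isotropic
    class-dependent Gaussian noise, with occasional gross outliers.
    """
    from .movement import ARGOS_CLASS_SD_KM

    c = config
    beta, sigma = c.ctcrw_beta, c.ctcrw_sigma
    dt_h = c.track_step_min / 60.0
    n = int(round(c.days * 24.0 / dt_h)) + 1
    T, Q = ou_transition(beta, sigma, dt_h)
    L = np.linalg.cholesky(Q + 1e-15 * np.eye(2))
    lat0 = c.center_lat + rng.normal(0.0, 0.15)
    lon0 = c.center_lon + rng.normal(0.0, 0.18)
    proj = LocalProjection(c.center_lat, c.center_lon)
    x0, y0 = proj.forward(lat0, lon0)
    v_sd = sigma / np.sqrt(2.0 * beta)
    state = np.array([[float(x0), float(y0)],
                      rng.normal(0.0, v_sd, size=2)])
    xs = np.empty((n, 2))
    xs[0] = state[0]
    z = rng.standard_normal((n - 1, 2, 2))
    for i in range(1, n):
        state = T @ state + L @ z[i - 1]
        xs[i] = state[0]
    times = c.start_ts + pd.to_timedelta(np.arange(n) * c.track_step_min, unit="min")
    lat, lon = proj.inverse(xs[:, 0], xs[:, 1])
    track = pd.DataFrame({"whale_id": whale_id, "time": times,
                          "lat": lat, "lon": lon})

    n_fix = rng.poisson(c.argos_per_day * c.days)
    idx = np.sort(rng.integers(0, n, size=max(n_fix, 2)))
    classes = list(c.argos_class_probs)
    probs = np.array([c.argos_class_probs[k] for k in classes])
    cls = rng.choice(classes, size=idx.size, p=probs / probs.sum())
    sd = np.array([ARGOS_CLASS_SD_KM[k] for k in cls])
    ex = rng.normal(0.0, sd)
    ey = rng.normal(0.0, sd)
    gross = rng.random(idx.size) < c.argos_outlier_prob
    ex = np.where(gross, ex + rng.choice([-1.0, 1.0], idx.size) * 120.0, ex)
    flat, flon = proj.inverse(xs[idx, 0] + ex, xs[idx, 1] + ey)
    fixes = pd.DataFrame({
        "whale_id": whale_id, "time": times[idx], "lat": flat, "lon": flon,
        "location_class": cls,
    }).drop_duplicates(subset="time").reset_index(drop=True)
    return track, fixes


def _track_interp(track: pd.DataFrame):
    t = pd.to_datetime(track["time"], utc=True).astype("int64").to_numpy() / 1e9
    lat = track["lat"].to_numpy()
    lon = track["lon"].to_numpy()

    def at(ts: pd.Timestamp):
        s = ts.value / 1e9
        return (float(np.interp(s, t, lat)), float(np.interp(s, t, lon)))

    return at


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def _ramp(dist_km, full_km, zero_km):
    """1 at <= full_km, linear to 0 at zero_km, 0 beyond."""
    if dist_km <= full_km:
        return 1.0
    if dist_km >= zero_km:
        return 0.0
    return (zero_km - dist_km) / (zero_km - full_km)


class _MidBouts:
    """Mid-type bout fields as numpy arrays for fast activity lookups."""

    def __init__(self, bouts: pd.DataFrame, epoch: pd.Timestamp):
        mb = bouts[bouts["sonar_type"] == "mid"] if len(bouts) else bouts
        if len(mb):
            self.start_s = ((mb["start_time"] - epoch)
                            .dt.total_seconds().to_numpy())
            self.end_s = (mb["end_time"] - epoch).dt.total_seconds().to_numpy()
            self.lat = mb["start_lat"].to_numpy(dtype=float)
            self.lon = mb["start_lon"].to_numpy(dtype=float)
        else:
            self.start_s = self.end_s = np.empty(0)
            self.lat = self.lon = np.empty(0)

    def nearest_overlap(self, t0_s: float, t1_s: float, pos):
        """Distance (km) to the nearest mid bout overlapping the window
        [t0_s, t1_s); None when no mid bout overlaps."""
        from .geo import great_circle_km

        act = (self.start_s < t1_s) & (self.end_s > t0_s)
        if not act.any():
            return None
        d = great_circle_km(pos[0], pos[1], self.lat[act], self.lon[act])
        return float(np.min(np.atleast_1d(d)))


def gen_behaviour_log(config: ScenarioConfig, whale_id, track: pd.DataFrame,
                      truth_bouts: pd.DataFrame, rng):
    """(raw_bl_table, truth_events) for one whale.

    The grammar alternates deep dives with inter-deep-dive sequences of
    surfacing + Poisson-many (shallow dive, surfacing) pairs. Durations are
    log-normal around their medians. Planted responses act through the
    whale's true distance to the nearest active mid-type bout: deep dives
    extend while exposed at depth; the following inter-deep components all
    stretch by the interval multiplier. Messages are lost independently at
    ``gap_rate`` (truth keeps every event)."""
    c = config
    at = _track_interp(track)
    epoch = c.start_ts
    mids = _MidBouts(truth_bouts, epoch)
    span_s = c.days * 86400.0
    t = float(rng.uniform(0, 30)) * 60.0  # seconds since epoch
    kinds, starts, durs, depths, fracs, classes = [], [], [], [], [], []

    def emit(kind, start_s, dur_min, depth=np.nan, frac=np.nan, cls="n/a"):
        classes.append(cls)
        kinds.append(kind)
        starts.append(start_s)
        durs.append(dur_min)
        depths.append(depth)
        fracs.append(frac)
        return start_s + dur_min * 60.0

    def pos_at(t_s):
        return at(epoch + pd.Timedelta(seconds=t_s))

    while t < span_s:
        deep_start = t
        pos = pos_at(t)
        el, rising = solar_elevation(epoch + pd.Timedelta(seconds=t),
                                     pos[0], pos[1])
        dur = float(lognormal_from_median(rng, c.deep_duration_min, c.deep_sigma))
        if el > 6.0:
            dur += c.deep_day_extra_min
        # effect fires when a mid bout overlaps the dive (the exposure
        # window the analysis uses), graded by distance at the dive start
        d_mid = mids.nearest_overlap(t, t + dur * 60.0, pos)
        if d_mid is not None:
            dur += c.mid_deep_extra_min * _ramp(
                d_mid, c.mid_deep_full_km, c.mid_deep_zero_km)
        depth = float(lognormal_from_median(rng, c.deep_depth_m, c.deep_depth_sigma))
        t = emit("dive", t, dur, depth, float(rng.uniform(0.45, 0.75)),
                 cls="deep")

        # inter-deep-dive interval: draw the unexposed component durations,
        # then stretch them all when a mid bout overlaps the deep-dive-cycle
        # window (preceding deep start to next deep start)
        comps = [("surfacing", float(lognormal_from_median(
            rng, c.surface_min, c.surface_sigma)), np.nan, np.nan, "n/a")]
        for _ in range(rng.poisson(c.n_shallow_pairs_mean)):
            sdur = float(lognormal_from_median(rng, c.shallow_duration_min,
                                               c.shallow_sigma))
            sdep = float(lognormal_from_median(rng, c.shallow_depth_m,
                                               c.shallow_depth_sigma))
            comps.append(("dive", sdur, max(sdep, 60.0),
                          float(rng.uniform(0.05, 0.45)), "shallow"))
            comps.append(("surfacing", float(lognormal_from_median(
                rng, c.surface_min, c.surface_sigma)), np.nan, np.nan, "n/a"))
        base_total_s = sum(dur_i for _, dur_i, _, _, _ in comps) * 60.0
        d_mid = mids.nearest_overlap(deep_start, t + base_total_s, pos_at(t))
        f = 1.0
        if d_mid is not None:
            f = 1.0 + (c.iddi_multiplier - 1.0) * _ramp(
                d_mid, c.iddi_full_km, c.iddi_none_km)
        for kind_i, dur_i, dep_i, frac_i, cls_i in comps:
            t = emit(kind_i, t, f * dur_i, dep_i, frac_i, cls=cls_i)

    start_ts = (epoch + pd.to_timedelta(np.asarray(starts), unit="s")).round("s")
    end_ts = (epoch + pd.to_timedelta(
        np.asarray(starts) + np.asarray(durs) * 60.0, unit="s")).round("s")
    truth = pd.DataFrame({
        "whale_id": whale_id, "kind": kinds, "start": start_ts, "end": end_ts,
        "max_depth_m": depths, "shape_frac": fracs,
        "true_class": classes,
    })
    truth["duration_min"] = (truth["end"] - truth["start"]).dt.total_seconds() / 60.0
    lost = rng.random(len(truth)) < c.gap_rate
    observed = truth[~lost].drop(columns=["duration_min"]).reset_index(drop=True)
    truth = truth.assign(lost=lost)
    return observed, truth


# ---------------------------------------------------------------------------
# Sonar schedule
# ---------------------------------------------------------------------------

def gen_sonar_schedule(config: ScenarioConfig, polygons: SubareaPolygons, rng):
    """(truth_bouts, archive_bouts, sports_records, coverage, outages).

    Truth bouts: high type, ~daily, mostly on the range, long (median
    ~67 min); mid type, clustered short bouts (median ~7 min). The archive
    holds on-range bouts during its coverage (full period minus outages),
    localized exactly. SPORTS holds independently reported bouts with
    start/position jitter, occasional 24-h transcription errors, and
    omissions -- so archive/SPORTS duplicates satisfy the 15-min/10-km rule.
    """
    c = config
    span_min = c.days * 24.0 * 60.0
    la, lo = c.center_lat, c.center_lon
    proj = LocalProjection(la, lo)

    def rand_pos(on_soar):
        if on_soar:
            return (la + rng.uniform(-c.soar_half_lat, c.soar_half_lat) * 0.9,
                    lo + rng.uniform(-c.soar_half_lon, c.soar_half_lon) * 0.9)
        side = rng.choice([-1.0, 1.0])
        return (la + rng.uniform(-0.7, 0.7),
                lo + side * rng.uniform(c.soar_half_lon + 0.1, 1.2))

    bouts = []
    n_high = rng.poisson(c.high_rate_per_day * c.days)
    for _ in range(n_high):
        on = rng.random() < c.high_on_soar_frac
        plat, plon = rand_pos(on)
        start = c.start_ts + pd.Timedelta(minutes=float(rng.uniform(0, span_min)))
        dur = float(lognormal_from_median(rng, c.high_median_min, c.high_sigma))
        bouts.append(("high", start, dur, plat, plon))
    n_cl = rng.poisson(c.mid_clusters_per_day * c.days)
    for _ in range(n_cl):
        on = rng.random() < c.mid_on_soar_frac
        plat, plon = rand_pos(on)
        t = c.start_ts + pd.Timedelta(minutes=float(rng.uniform(0, span_min)))
        for _ in range(1 + rng.poisson(c.mid_cluster_size_mean - 1.0)):
            dur = float(lognormal_from_median(rng, c.mid_median_min, c.mid_sigma))
            bouts.append(("mid", t, dur, plat, plon))
            t = (t + pd.Timedelta(minutes=dur)
                 + pd.Timedelta(minutes=float(
                     lognormal_from_median(rng, c.mid_gap_median_min, 0.4))))

    truth = pd.DataFrame([{
        "sonar_type": typ, "start_time": s.round("s"),
        "end_time": (s + pd.Timedelta(minutes=d)).round("s"),
        "start_lat": plat, "start_lon": plon,
        "on_soar": polygons.on_soar(plat, plon),
    } for typ, s, d, plat, plon in bouts]).sort_values(
        "start_time").reset_index(drop=True)
    truth = truth[truth["end_time"] <= c.end_ts].reset_index(drop=True)
    truth["truth_idx"] = np.arange(len(truth))  # provenance for audits

    outages = []
    for _ in range(c.n_outages):
        s = c.start_ts + pd.Timedelta(
            minutes=float(rng.uniform(0, span_min - c.outage_hours * 60.0)))
        outages.append((s.round("s"),
                        (s + pd.Timedelta(hours=c.outage_hours)).round("s")))
    from . import intervals as ivl
    outages = ivl.normalize(outages)
    coverage = ivl.subtract([(c.start_ts, c.end_ts)], outages)

    def covered(s, e):
        return ivl.overlap_seconds((s, e), coverage) >= (e - s).total_seconds() - 1.0

    arch = truth[truth["on_soar"]
                 & truth.apply(lambda r: covered(r["start_time"],
                                                 r["end_time"]), axis=1)].copy()
    arch["position_quality"] = "localized"
    arch = arch.reset_index(drop=True)

    sp_rows = []
    for _, r in truth.iterrows():
        if rng.random() >= c.sports_report_prob:
            continue
        js = pd.Timedelta(minutes=float(rng.normal(0, c.sports_start_jitter_min)))
        je = pd.Timedelta(minutes=float(rng.normal(0, c.sports_start_jitter_min)))
        start = (r["start_time"] + js).round("s")
        end = max((r["end_time"] + je).round("s"),
                  start + pd.Timedelta(minutes=1))
        if rng.random() < c.sports_long_error_prob:
            end = end + pd.Timedelta(hours=24)  # transcription error
        x, y = proj.forward(r["start_lat"], r["start_lon"])
        x += rng.normal(0, c.sports_pos_jitter_km / np.sqrt(2))
        y += rng.normal(0, c.sports_pos_jitter_km / np.sqrt(2))
        plat, plon = proj.inverse(x, y)
        sp_rows.append({
            "sonar_type": r["sonar_type"], "start_time": start, "end_time": end,
            "start_lat": float(plat), "start_lon": float(plon),
            "platform_id": f"P{int(rng.integers(1, 6))}",
            "on_soar": polygons.on_soar(float(plat), float(plon)),
            "truth_idx": int(r["truth_idx"]),
        })
    sports = pd.DataFrame(sp_rows).sort_values("start_time").reset_index(drop=True) \
        if sp_rows else pd.DataFrame(columns=[
            "sonar_type", "start_time", "end_time", "start_lat", "start_lon",
            "platform_id", "on_soar", "truth_idx"])
    return truth, arch, sports, coverage, outages


# ---------------------------------------------------------------------------
# Detection reports
# ---------------------------------------------------------------------------

def hydrophone_layout(config: ScenarioConfig | None = None, n: int = 9) -> dict:
    """A 3x3 grid of range hydrophones across the SOAR box."""
    c = config or ScenarioConfig()
    side = int(round(np.sqrt(n)))
    lats = np.linspace(c.center_lat - 0.8 * c.soar_half_lat,
                       c.center_lat + 0.8 * c.soar_half_lat, side)
    lons = np.linspace(c.center_lon - 0.8 * c.soar_half_lon,
                       c.center_lon + 0.8 * c.soar_half_lon, side)
    return {f"H{i * side + j:02d}": (float(lats[i]), float(lons[j]))
            for i in range(side) for j in range(side)}


def gen_detection_reports(bouts: pd.DataFrame, layout: dict, rng,
                          fs: float = 96000.0, nfft: int = 2048,
                          ping_interval_s: float = 25.0,
                          ping_duration_s: float = 1.5,
                          max_range_km: float = 60.0,
                          clutter_per_hour: float = 10.0,
                          sound_speed_ms: float = 1500.0,
                          span=None) -> pd.DataFrame:
    """Sparse hard-limited detection reports for a schedule of bouts.

    One report per active FFT frame per hydrophone (clear frames are not
    streamed). Pings recur at the bout's regular interval; each hydrophone
    within range receives the ping after its propagation delay, at a level
    falling off with log-distance (high-type sources are louder). Whistle
    clutter -- short irregular trains, in band -- is added per hydrophone.
    Frame times are aligned to a per-stream frame grid.
    """
    from .geo import great_circle_km
    from .detection import stft_frame_step_s, stft_bin_width_hz

    step = stft_frame_step_s(fs, nfft)
    bin_hz = stft_bin_width_hz(fs, nfft)
    if span is None:
        if bouts.empty:
            raise ValueError("need bouts or an explicit span")
        span = (pd.Timestamp(bouts["start_time"].min()),
                pd.Timestamp(bouts["end_time"].max()))
    epoch = pd.Timestamp(span[0]).floor("s")
    n_frames_ping = int(round(ping_duration_s / step))
    rows = []

    def frames(hid, t_arrival_s, n_fr, level_db, freq_hz):
        k0 = int(round(t_arrival_s / step))
        bin0 = int(round(freq_hz / bin_hz))
        for k in range(k0, k0 + n_fr):
            rows.append({
                "time": epoch + pd.Timedelta(seconds=k * step),
                "hydrophone_id": hid, "fs": fs, "nfft": nfft,
                "bins_above": np.array([bin0, bin0 + 1]),
                "n_bins_above": 2,
                "peak_freq_hz": bin0 * bin_hz,
                "peak_level_db": level_db,
            })

    for _, b in bouts.iterrows():
        t = pd.Timestamp(b["start_time"])
        end = pd.Timestamp(b["end_time"])
        base = 175.0 if b["sonar_type"] == "high" else 142.0
        freq = 3500.0 if b["sonar_type"] == "high" else 3000.0
        while t < end:
            for hid, (hla, hlo) in layout.items():
                d_km = max(great_circle_km(b["start_lat"], b["start_lon"],
                                           hla, hlo), 0.1)
                if d_km > max_range_km:
                    continue
                arr = (t - epoch).total_seconds() + d_km * 1000.0 / sound_speed_ms
                level = base - 10.0 * np.log10(d_km) + rng.normal(0, 1.0)
                frames(hid, arr, n_frames_ping, float(level), freq)
            t += pd.Timedelta(seconds=ping_interval_s + float(rng.uniform(-1, 1)))

    span_h = (pd.Timestamp(span[1]) - epoch).total_seconds() / 3600.0
    for hid in layout:
        n_cl = rng.poisson(clutter_per_hour * span_h)
        for _ in range(n_cl):
            t0 = float(rng.uniform(0, span_h * 3600.0))
            # whistle trains: over-long-enough pings but irregular IDI
            n_w = int(rng.integers(1, 6))
            for w in range(n_w):
                frames(hid, t0, int(round(1.2 / step)),
                       float(rng.uniform(120, 135)), 4000.0)
                t0 += float(rng.uniform(4.0, 15.0))

    if not rows:
        return pd.DataFrame(columns=["time", "hydrophone_id", "fs", "nfft",
                                     "bins_above", "n_bins_above",
                                     "peak_freq_hz", "peak_level_db"])
    rep = pd.DataFrame(rows).sort_values(
        ["hydrophone_id", "time"]).reset_index(drop=True)
    # one report per frame per stream: keep the louder on collisions
    rep = rep.sort_values(["hydrophone_id", "time", "peak_level_db"])
    rep = rep.drop_duplicates(subset=["hydrophone_id", "time"], keep="last")
    return rep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig | None = None,
                      seed: int = 0) -> Scenario:
    """Generate a complete synthetic study under one seed."""
    c = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    grid = gen_bathymetry(c)
    polygons = gen_subareas(c)
    truth_bouts, arch, sports, coverage, outages = gen_sonar_schedule(
        c, polygons, rng)
    tracks, fixes, bls, truth_events = [], [], [], []
    for i in range(c.n_whales):
        wid = f"Zc{i + 1:02d}"
        track, fx = gen_whale_track(c, wid, rng)
        bl, tev = gen_behaviour_log(c, wid, track, truth_bouts, rng)
        tracks.append(track)
        fixes.append(fx)
        bls.append(bl)
        truth_events.append(tev)
    truth = GroundTruth(
        tracks=pd.concat(tracks, ignore_index=True),
        events=pd.concat(truth_events, ignore_index=True),
        bouts=truth_bouts, outages=outages, params=c)
    return Scenario(
        config=c, grid=grid, polygons=polygons,
        argos=pd.concat(fixes, ignore_index=True),
        behaviour_log=pd.concat(bls, ignore_index=True),
        archive_bouts=arch, sports_records=sports,
        coverage=coverage, truth=truth)

# ---------------------------------------------------------------------------
# Ground-truth model tables
# ---------------------------------------------------------------------------

def _truth_positions(events: pd.DataFrame, tracks: pd.DataFrame):
    """True position at each event start, linearly interpolated per whale."""
    lat = np.full(len(events), np.nan)
    lon = np.full(len(events), np.nan)
    for wid, grp in events.groupby("whale_id", sort=False):
        tr = tracks[tracks["whale_id"] == wid]
        tt = tr["time"].astype("int64").to_numpy() / 1e9
        et = grp["start"].astype("int64").to_numpy() / 1e9
        idx = events.index.get_indexer(grp.index)
        lat[idx] = np.interp(et, tt, tr["lat"].to_numpy())
        lon[idx] = np.interp(et, tt, tr["lon"].to_numpy())
    return lat, lon


def truth_model_table(scenario: Scenario, response: str = "deep_duration"
                      ) -> pd.DataFrame:
    """Exposure-response model table built entirely from ground truth.

    Uses true event classes, true positions and the uncorrupted bout list
    (no detection, fusion or track-modelling noise), so fitted effects can
    be compared against the planted ones. Supports the 'deep_duration' and
    'iddi' responses.
    """
    from . import exposure
    from .movement import classify_diel

    ev = scenario.truth.events
    tracks = scenario.truth.tracks
    bouts = scenario.truth.bouts
    if response == "deep_duration":
        base = ev[ev["true_class"] == "deep"].copy()
        base["y"] = base["duration_min"]
        start_col, end_col = "start", "end"
        base["time"] = base["start"]
    elif response == "iddi":
        rows = []
        for wid, grp in ev[ev["true_class"] == "deep"].groupby(
                "whale_id", sort=False):
            g = grp.sort_values("start")
            for (_, d0), (_, d1) in zip(g.iterrows(), g.iloc[1:].iterrows()):
                rows.append({
                    "whale_id": wid, "start": d0["start"],  # window start
                    "end": d1["start"],
                    "y": (d1["start"] - d0["end"]).total_seconds() / 60.0,
                    "preceding_deep_duration_min": d0["duration_min"],
                })
        base = pd.DataFrame(rows)
        base["time"] = base["start"]
        start_col, end_col = "start", "end"
    else:
        raise ValueError(f"unsupported response {response!r}")
    base = base.reset_index(drop=True)
    lat, lon = _truth_positions(base, tracks)
    base["lat"] = lat
    base["lon"] = lon
    el, rising = solar_elevation(base["start"], lat, lon)
    base["diel"] = classify_diel(el, rising)
    expo = exposure.summarize_windows(base, bouts,
                                      start_col=start_col, end_col=end_col)
    out = pd.concat([base, expo], axis=1)
    if response == "iddi":
        out = out[out["y"] > 0].copy()
        out["weight"] = out["y"] / out["y"].min()
    return out
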
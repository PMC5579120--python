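"""Independent cross-checks of the analysis pipeline.

Each function here re-derives a quantity produced elsewhere in the package
through a deliberately different route (brute force, per-second
discretization, an alternative ephemeris, Monte-Carlo truth) and reports a
comparison metric. They back both the acceptance test suite and
``scripts/acceptance.py``.

All random draws use seeds derived as ``(base * 1000003 + i) % 2**31``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import behaviour, detection, exposure, fusion, intervals as iv
from . import simulate
from .detection import DetectorConfig
from .gamm import all_subsets_selection
from .movement import CTCRW, classify_diel, ou_transition, solar_elevation
from .simulate import ScenarioConfig

__all__ = [
    "deep_dives_per_day", "stft_roundtrip", "bout_segmentation_agreement",
    "overlap_oracle_max_scaled_err", "kmeans_oracle_agreement",
    "kmeans_planted_recovery", "ctcrw_recovery", "gamm_selection_rate",
    "duplicate_precision_recall", "detector_miss_fraction",
    "solar_oracle_max_abs_err", "diel_boundaries_exact",
]


def _child_seed(base: int, i: int) -> int:
    return (int(base) * 1000003 + int(i)) % (2 ** 31)


# ---------------------------------------------------------------------------
# 1-2: printed worked-example identities
# ---------------------------------------------------------------------------

def deep_dives_per_day(cycle_min: float = 175.0) -> float:
    """Deep-dive rate implied by the mean deep-dive cycle length."""
    return 1440.0 / cycle_min


def stft_roundtrip(fs: float = 96000.0, nfft: int = 2048):
    """(bin width Hz, frame step ms, step ms recomputed from the bin width)."""
    bin_hz = detection.stft_bin_width_hz(fs, nfft)
    step_ms = detection.stft_frame_step_s(fs, nfft) * 1000.0
    step_ms_inv = detection.frame_step_from_bin_width_s(bin_hz) * 1000.0
    return bin_hz, step_ms, step_ms_inv


# ---------------------------------------------------------------------------
# 3: bout segmentation vs O(n^2) transitive closure
# ---------------------------------------------------------------------------

def _closure_oracle(pings: pd.DataFrame, config: DetectorConfig):
    """All-pairs transitive closure over the linkage predicate."""
    n = len(pings)
    rows = [pings.iloc[i] for i in range(n)]
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] != labels[j] and \
                        detection.bout_linked(rows[i], rows[j], config):
                    lo, hi = sorted((labels[i], labels[j]))
                    labels = [lo if l == hi else l for l in labels]
                    changed = True
    sizes = {}
    for l in labels:
        sizes[l] = sizes.get(l, 0) + 1
    return sorted(sizes.values())


def bout_segmentation_agreement(n_configs: int = 1000, seed: int = 0) -> float:
    """Fraction of random ping configurations on which segment_bouts yields
    exactly the brute-force transitive-linkage partition."""
    rng = np.random.default_rng(_child_seed(seed, 3))
    config = DetectorConfig()
    agree = 0
    epoch = pd.Timestamp("2011-01-01", tz="UTC")
    for _ in range(n_configs):
        n = int(rng.integers(2, 13))
        t = np.sort(rng.uniform(0, 1500, n))
        pings = pd.DataFrame({
            "hydrophone_id": rng.choice(["H1", "H2", "H3"], n),
            "start_time": epoch + pd.to_timedelta(t, unit="s"),
            "duration_s": 1.3, "peak_freq_hz": 3500.0,
            "peak_level_db": rng.uniform(140, 170, n)})
        bouts = detection.segment_bouts(pings, config)
        p = pings.sort_values(["start_time", "hydrophone_id"]
                              ).reset_index(drop=True)
        want = _closure_oracle(p, config)
        got = sorted(bouts["n_pings"].tolist())
        agree += int(got == want)
    return agree / n_configs


# ---------------------------------------------------------------------------
# 4: overlap fraction vs per-second discretization
# ---------------------------------------------------------------------------

def overlap_oracle_max_scaled_err(n_layouts: int = 1000, seed: int = 0) -> float:
    """max over layouts of |OL - per-second OL| * duration_s.

    The per-second oracle counts whole seconds (on the event's own 1-s
    grid; event durations are integer seconds) whose midpoints fall inside
    the bout; its error against the exact fraction is at most one second,
    so the scaled error must be <= 1."""
    rng = np.random.default_rng(_child_seed(seed, 4))
    epoch = pd.Timestamp("2011-01-01", tz="UTC")
    worst = 0.0
    for _ in range(n_layouts):
        dur = float(rng.integers(30, 7200))
        e0 = float(rng.uniform(0, 86400.0))
        b0 = e0 + float(rng.uniform(-dur, dur))
        b1 = b0 + float(rng.uniform(1.0, 2.0 * dur))
        ev = (epoch + pd.Timedelta(seconds=e0),
              epoch + pd.Timedelta(seconds=e0 + dur))
        bout = [(epoch + pd.Timedelta(seconds=b0),
                 epoch + pd.Timedelta(seconds=b1))]
        _, raw = exposure.overlap_fraction(ev, bout)
        mids = e0 + np.arange(int(np.floor(dur))) + 0.5
        oracle = float(np.sum((mids >= b0) & (mids < b1))) / dur
        worst = max(worst, abs(raw - oracle) * dur)
    return worst


# ---------------------------------------------------------------------------
# 5: k-means labels vs exhaustive 2-partition optimum / planted classes
# ---------------------------------------------------------------------------

def _brute_force_2means(Z: np.ndarray):
    best, best_ss = None, np.inf
    n = len(Z)
    for mask in itertools.product([0, 1], repeat=n):
        m = np.array(mask, dtype=bool)
        if m.all() or (~m).all():
            continue
        ss = (((Z[m] - Z[m].mean(axis=0)) ** 2).sum()
              + ((Z[~m] - Z[~m].mean(axis=0)) ** 2).sum())
        if ss < best_ss - 1e-12:
            best_ss, best = ss, m
    return best


def _dive_frame(depths, durations):
    t0 = pd.Timestamp("2011-01-01", tz="UTC")
    rows = []
    t = 0.0
    for d, u in zip(depths, durations):
        rows.append({"whale_id": "W1", "kind": "dive",
                     "start": t0 + pd.Timedelta(minutes=t),
                     "end": t0 + pd.Timedelta(minutes=t + u),
                     "duration_min": u, "max_depth_m": d, "after_gap": False})
        t += u + 2.0
    return pd.DataFrame(rows)


def kmeans_oracle_agreement(n_instances: int = 200, seed: int = 0) -> float:
    """Fraction of random instances (n <= 12) on which the k-means labels
    equal the exhaustive minimum within-cluster-SS 2-partition."""
    rng = np.random.default_rng(_child_seed(seed, 5))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(10, 13))
        X = rng.normal(0, 1, size=(n, 2)) + rng.choice([0.0, 4.0], size=(n, 1))
        depths = 800 + 300 * X[:, 0]
        durs = 40 + 10 * X[:, 1]
        ev = behaviour.classify_dives_kmeans(_dive_frame(depths, durs), seed=0)
        lab = (ev["dive_class"] == "deep").to_numpy()
        Z = np.column_stack([depths, durs])
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        oracle = _brute_force_2means(Z)
        agree += int((lab == oracle).all() or (lab == ~oracle).all())
    return agree / n_instances


def kmeans_planted_recovery(n_instances: int = 100, seed: int = 0) -> float:
    """Per-dive recovery rate of planted deep/shallow classes at typical
    beaked-whale separations (deep ~1400 m / 60 min vs ~250 m / 20 min)."""
    rng = np.random.default_rng(_child_seed(seed, 55))
    correct = total = 0
    for _ in range(n_instances):
        n = 30
        depths = np.r_[rng.normal(1400, 150, n), rng.normal(250, 80, n)]
        durs = np.r_[rng.normal(60, 9, n), rng.normal(20, 6, n)]
        ev = behaviour.classify_dives_kmeans(_dive_frame(depths, durs), seed=0)
        lab = ev["dive_class"].to_numpy()
        truth = np.r_[np.full(n, "deep"), np.full(n, "shallow")]
        correct += int(np.sum(lab == truth))
        total += 2 * n
    return correct / total


# ---------------------------------------------------------------------------
# 6: CTCRW parameter recovery and smoother CI coverage
# ---------------------------------------------------------------------------

def ctcrw_recovery(n_reps: int = 50, n_fixes: int = 500, seed: int = 0,
                   beta: float = 1.0, sigma: float = 3.0,
                   fix_dt_min: float = 30.0, noise_km: float = 0.3) -> dict:
    """Median relative errors of (beta, sigma) and pooled 95% CI coverage.

    Truth is simulated exactly on a grid twice as fine as the fixes; the
    smoother is evaluated at the intermediate (unobserved) times and its
    per-axis 1.96-SD intervals scored against the true positions."""
    from .geo import LocalProjection

    betas, sigmas = [], []
    hits = 0
    tries = 0
    dt_h = fix_dt_min / 120.0              # fine grid: half the fix spacing
    n_fine = 2 * n_fixes - 1
    T, Q = ou_transition(beta, sigma, dt_h)
    L = np.linalg.cholesky(Q)
    proj = LocalProjection(33.0, -119.0)
    t0 = pd.Timestamp("2011-06-01", tz="UTC")
    times = t0 + pd.to_timedelta(np.arange(n_fine) * fix_dt_min / 2.0,
                                 unit="min")
    for rep in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, 600 + rep))
        st = np.column_stack([np.zeros(2),
                              rng.normal(0, sigma / np.sqrt(2 * beta), 2)]).T
        xs = np.empty((n_fine, 2))
        xs[0] = st[0]
        for i in range(1, n_fine):
            st = T @ st + L @ rng.standard_normal((2, 2))
            xs[i] = st[0]
        even = np.arange(0, n_fine, 2)
        odd = np.arange(1, n_fine, 2)
        lat, lon = proj.inverse(xs[even, 0] + rng.normal(0, noise_km, even.size),
                                xs[even, 1] + rng.normal(0, noise_km, even.size))
        fixes = pd.DataFrame({"whale_id": "W1", "time": times[even],
                              "lat": lat, "lon": lon, "location_class": "G"})
        res = CTCRW(fixes, measurement_sd={"G": noise_km}).fit()
        betas.append(res.beta)
        sigmas.append(res.sigma)
        pred = res.predict(times[odd])
        plat = pred["lat"].to_numpy()
        plon = pred["lon"].to_numpy()
        tlat, tlon = proj.inverse(xs[odd, 0], xs[odd, 1])
        tlat, tlon = np.asarray(tlat), np.asarray(tlon)
        km_per_deg = 111.19492664455873
        dx = (plon - tlon) * km_per_deg * np.cos(np.radians(tlat))
        dy = (plat - tlat) * km_per_deg
        half = 1.96 * pred["sd_x_km"].to_numpy()
        hits += int(np.sum(np.abs(dx) <= half) + np.sum(np.abs(dy) <= half))
        tries += 2 * len(pred)
    return {
        "beta_median": float(np.median(betas)),
        "sigma_median": float(np.median(sigmas)),
        "beta_median_rel_err": abs(float(np.median(betas)) - beta) / beta,
        "sigma_median_rel_err": abs(float(np.median(sigmas)) - sigma) / sigma,
        "ci95_coverage": hits / tries,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# 7: GAMM selection power / type-I on ground-truth tables
# ---------------------------------------------------------------------------

def gamm_selection_rate(n_reps: int = 20, seed: int = 0,
                        planted: bool = True) -> float:
    """Fraction of replicates in which AIC selection gets it right.

    With the scenario's planted mid-sonar effects, 'right' means the best
    model carries the MFAS distance smooth; with the effects disabled,
    'right' means the no-MFAS model wins. Fits use the ground-truth model
    table so only selection (not detection/fusion noise) is under test."""
    if planted:
        cfg = ScenarioConfig()
    else:
        cfg = ScenarioConfig(mid_deep_extra_min=0.0, iddi_multiplier=1.0)
    hits = 0
    for rep in range(n_reps):
        sc = simulate.simulate_scenario(
            cfg, _child_seed(seed, (700 if planted else 7000) + rep))
        tab = simulate.truth_model_table(sc, "deep_duration")
        sel = all_subsets_selection(tab, "deep_duration", "Complete",
                                    terms=("diel",),
                                    mfas_options=("none", "distance"))
        best = sel.best_spec.mfas
        hits += int(best == ("distance" if planted else "none"))
    return hits / n_reps


# ---------------------------------------------------------------------------
# 8: duplicate reconciliation on planted pairs
# ---------------------------------------------------------------------------

def duplicate_precision_recall(n_pairs: int = 30, n_lone_archive: int = 10,
                               n_lone_sports: int = 10, seed: int = 0):
    """(precision, recall) of resolved duplicates against planted pairs.

    Archive bouts sit hours apart; each planted SPORTS twin is jittered
    within the 15-min/10-km rule; lone records are placed far away in time
    or space so they match nothing."""
    rng = np.random.default_rng(_child_seed(seed, 8))
    t0 = pd.Timestamp("2011-03-01", tz="UTC")
    arch_rows, sports_rows, want = [], [], set()
    for i in range(n_pairs + n_lone_archive):
        start = t0 + pd.Timedelta(hours=3.0 * i + float(rng.uniform(0, 1)))
        dur = float(rng.uniform(20, 90))
        typ = "high" if i % 2 == 0 else "mid"
        lat = 33.0 + float(rng.uniform(-0.2, 0.2))
        lon = -119.0 + float(rng.uniform(-0.2, 0.2))
        arch_rows.append({
            "sonar_type": typ, "start_time": start,
            "end_time": start + pd.Timedelta(minutes=dur),
            "start_lat": lat, "start_lon": lon, "on_soar": True})
        if i < n_pairs:
            js = float(rng.uniform(-10, 10))
            dx = float(rng.uniform(-3, 3)) / 111.0
            sports_rows.append({
                "sonar_type": typ,
                "start_time": start + pd.Timedelta(minutes=js),
                "end_time": start + pd.Timedelta(minutes=dur + js),
                "start_lat": lat + dx, "start_lon": lon,
                "on_soar": True})
            want.add((i, len(sports_rows) - 1))
    for j in range(n_lone_sports):
        # far offset in space (> 10 km from every archive position)
        start = t0 + pd.Timedelta(hours=3.0 * j + 1.5)
        sports_rows.append({
            "sonar_type": "mid", "start_time": start,
            "end_time": start + pd.Timedelta(minutes=40),
            "start_lat": 35.5, "start_lon": -117.0, "on_soar": False})
    arch = pd.DataFrame(arch_rows)
    sports = pd.DataFrame(sports_rows)
    pairs = fusion.resolve_duplicates(fusion.find_duplicates(arch, sports))
    got = {(int(r["archive_idx"]), int(r["sports_idx"]))
           for _, r in pairs.iterrows()}
    tp = len(got & want)
    precision = tp / len(got) if got else 1.0
    recall = tp / len(want) if want else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# 9: detector miss fraction on the default synthetic stream
# ---------------------------------------------------------------------------

def detector_miss_fraction(seed: int = 0, window_hours: float = 24.0) -> dict:
    """Fraction of truly ensonified time the detector chain fails to cover.

    Runs the full chain (reports -> pings -> screening -> bouts) on the
    default scenario's on-range schedule over a window starting at the
    first on-range bout."""
    cfg = ScenarioConfig()
    rng = np.random.default_rng(_child_seed(seed, 9))
    polys = simulate.gen_subareas(cfg)
    truth, *_ = simulate.gen_sonar_schedule(cfg, polys, rng)
    on = truth[truth["on_soar"]]
    t0 = on["start_time"].min()
    window = (t0, t0 + pd.Timedelta(hours=window_hours))
    sel = on[(on["start_time"] < window[1]) & (on["end_time"] > window[0])].copy()
    sel["end_time"] = sel["end_time"].clip(upper=window[1])
    sel["start_time"] = sel["start_time"].clip(lower=window[0])
    layout = simulate.hydrophone_layout(cfg)
    reports = simulate.gen_detection_reports(sel, layout, rng, span=window)
    pings = detection.detect_pings(reports)
    screened = detection.screen_false_positives(pings)
    bouts = detection.segment_bouts(screened)
    detected = [(r["start_time"], r["end_time"]) for _, r in bouts.iterrows()]
    ensonified = iv.normalize(
        [(r["start_time"], r["end_time"]) for _, r in sel.iterrows()])
    enso_s = iv.total_seconds(ensonified)
    missed_s = iv.total_seconds(iv.subtract(ensonified, detected))
    return {"miss_fraction": missed_s / enso_s if enso_s else 0.0,
            "ensonified_hours": enso_s / 3600.0,
            "n_truth_bouts": int(len(sel)),
            "n_detected_bouts": int(len(bouts))}


# ---------------------------------------------------------------------------
# 10: solar elevation vs an independent low-precision almanac
# ---------------------------------------------------------------------------

def _almanac_elevation(time: pd.Timestamp, lat: float, lon: float) -> float:
    """Solar elevation by the Astronomical Almanac's approximate ephemeris
    (right ascension / declination + sidereal time), independent of the
    equation-of-time formulation used by the production code."""
    t = pd.Timestamp(time)
    t = t.tz_localize("UTC") if t.tzinfo is None else t.tz_convert("UTC")
    jd = t.value / 1e9 / 86400.0 + 2440587.5
    n = jd - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    ra = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam)))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    ut_hours = (t.value / 1e9 % 86400.0) / 3600.0
    gmst = (6.697375 + 0.0657098242 * (np.floor(n + 0.5) - 0.5)
            + 1.00273790935 * ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = np.radians((lmst * 15.0 - ra + 540.0) % 360.0 - 180.0)
    latr = np.radians(lat)
    sin_el = (np.sin(latr) * np.sin(dec)
              + np.cos(latr) * np.cos(dec) * np.cos(ha))
    return float(np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0))))


def solar_oracle_max_abs_err() -> float:
    """Max |elevation difference| (degrees) over a space-time grid."""
    lats = [-50.0, -20.0, 0.0, 33.25, 55.0]
    lons = [-170.0, -119.0, -30.0, 45.0, 150.0]
    worst = 0.0
    for day in range(2, 365, 13):
        for hour in (0, 5, 11, 17, 22):
            t = (pd.Timestamp("2011-01-01", tz="UTC")
                 + pd.Timedelta(days=day, hours=hour, minutes=17))
            for la in lats:
                for lo in lons:
                    el, _ = solar_elevation(t, la, lo)
                    worst = max(worst, abs(el - _almanac_elevation(t, la, lo)))
    return worst


def diel_boundaries_exact() -> bool:
    """Boundary behaviour of the diel classifier: -12/+6 inclusive to
    twilight, rising selects Dawn, setting Dusk."""
    checks = [
        (classify_diel(6.0001, True) == "Day"),
        (classify_diel(6.0, True) == "Dawn"),
        (classify_diel(6.0, False) == "Dusk"),
        (classify_diel(-12.0, True) == "Dawn"),
        (classify_diel(-12.0, False) == "Dusk"),
        (classify_diel(-12.0001, False) == "Night"),
        (classify_diel(0.0, True) == "Dawn"),
        (classify_diel(0.0, False) == "Dusk"),
        (classify_diel(45.0, False) == "Day"),
        (classify_diel(-40.0, True) == "Night"),
    ]
    return all(checks)
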
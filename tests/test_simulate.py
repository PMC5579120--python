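import numpy as np
import pandas as pd
import pytest

from ziphius import behaviour, fusion, simulate
from ziphius.movement import ou_transition
from ziphius.simulate import ScenarioConfig, island_position


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def test_bathymetry_basin_and_island():
    cfg = ScenarioConfig()
    grid = simulate.gen_bathymetry(cfg)
    assert grid.sample(cfg.center_lat, cfg.center_lon) <= -1000.0
    isl = island_position(cfg)
    assert grid.sample(*isl) >= 10.0


def test_subareas_cover_range():
    cfg = ScenarioConfig()
    polys = simulate.gen_subareas(cfg)
    assert polys.on_soar(cfg.center_lat, cfg.center_lon)
    assert polys.subarea(cfg.center_lat, cfg.center_lon) == "San Nic"
    assert polys.subarea(cfg.center_lat, cfg.center_lon + 1.5) == "East Basin"


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_scenario_seed_determinism():
    cfg = ScenarioConfig(n_whales=1, days=2.0)
    s1 = simulate.simulate_scenario(cfg, seed=7)
    s2 = simulate.simulate_scenario(cfg, seed=7)
    pd.testing.assert_frame_equal(s1.behaviour_log, s2.behaviour_log)
    pd.testing.assert_frame_equal(s1.argos, s2.argos)
    pd.testing.assert_frame_equal(s1.sports_records, s2.sports_records)
    s3 = simulate.simulate_scenario(cfg, seed=8)
    assert not s3.behaviour_log.equals(s1.behaviour_log)


def test_detection_report_stream_deterministic(small_scenario):
    layout = simulate.hydrophone_layout(small_scenario.config)
    bouts = small_scenario.truth.bouts.head(3)
    r1 = simulate.gen_detection_reports(bouts, layout,
                                        np.random.default_rng(5))
    r2 = simulate.gen_detection_reports(bouts, layout,
                                        np.random.default_rng(5))
    pd.testing.assert_frame_equal(
        r1.drop(columns="bins_above"), r2.drop(columns="bins_above"))


# ---------------------------------------------------------------------------
# movement statistics
# ---------------------------------------------------------------------------

def test_ou_transition_closed_forms():
    beta, sigma, dt = 0.8, 2.5, 0.25
    T, Q = ou_transition(beta, sigma, dt)
    e = np.exp(-beta * dt)
    assert T[0, 0] == pytest.approx(1.0)
    assert T[0, 1] == pytest.approx((1 - e) / beta)
    assert T[1, 1] == pytest.approx(e)
    assert T[1, 0] == 0.0
    s2 = sigma ** 2
    assert Q[1, 1] == pytest.approx(s2 * (1 - e ** 2) / (2 * beta))
    assert Q[0, 1] == pytest.approx(s2 / (2 * beta ** 2) * (1 - e) ** 2)
    assert Q[0, 0] == pytest.approx(
        s2 / beta ** 2 * (dt - 2 * (1 - e) / beta + (1 - e ** 2) / (2 * beta)))
    # Q must be a valid covariance
    assert np.all(np.linalg.eigvalsh(Q) > 0)


def test_track_displacement_statistics():
    """Sample displacement variance/lag-1 covariance match the integrated-OU
    closed forms: d_i = a v_i + w_i with a = (1-e^{-b dt})/b and
    Var(v) = sigma^2/(2 beta)."""
    cfg = ScenarioConfig(n_whales=1, days=2.0, ctcrw_beta=1.0, ctcrw_sigma=1.5)
    rng = np.random.default_rng(0)
    disp = []
    from ziphius.geo import LocalProjection
    proj = LocalProjection(cfg.center_lat, cfg.center_lon)
    for rep in range(60):
        track, _ = simulate.gen_whale_track(cfg, f"W{rep}", rng)
        x, y = proj.forward(track["lat"].to_numpy(), track["lon"].to_numpy())
        disp.append(np.column_stack([np.diff(x), np.diff(y)]))
    d = np.vstack(disp)          # ~ 2 * 60 * 575 samples over both axes
    dt = cfg.track_step_min / 60.0
    beta, sigma = cfg.ctcrw_beta, cfg.ctcrw_sigma
    T, Q = ou_transition(beta, sigma, dt)
    a = T[0, 1]
    vvar = sigma ** 2 / (2 * beta)
    var_want = a ** 2 * vvar + Q[0, 0]
    cov1_want = a ** 2 * vvar * np.exp(-beta * dt) + a * Q[0, 1]
    var_got = d.var()
    cov1_got = np.mean([np.mean(di[:-1] * di[1:]) for col in range(2)
                        for di in [d[:, col]]])
    assert var_got == pytest.approx(var_want, rel=0.05)
    assert cov1_got == pytest.approx(cov1_want, rel=0.08)


# ---------------------------------------------------------------------------
# behaviour grammar
# ---------------------------------------------------------------------------

def test_behaviour_log_contiguous_without_loss():
    cfg = ScenarioConfig(n_whales=1, days=3.0, gap_rate=0.0)
    s = simulate.simulate_scenario(cfg, seed=3)
    res = behaviour.parse_behaviour_log(s.behaviour_log)
    assert not res.errors
    assert not res.events["after_gap"].any()
    kinds = res.events["kind"].to_numpy()
    assert (kinds[:-1] != kinds[1:]).all()  # strict dive/surfacing alternation


def test_behaviour_log_deep_dive_rate(small_scenario):
    ev = small_scenario.truth.events
    deep = ev[ev["true_class"] == "deep"]
    days = small_scenario.config.days * small_scenario.config.n_whales
    rate = len(deep) / days
    assert 6.0 < rate < 10.0  # ~ 1440 / 175 per whale-day


def _stationary_track(cfg, lat, lon):
    n = int(cfg.days * 24 * 60 / cfg.track_step_min) + 1
    times = cfg.start_ts + pd.to_timedelta(
        np.arange(n) * cfg.track_step_min, unit="min")
    return pd.DataFrame({"whale_id": "W0", "time": times,
                         "lat": lat, "lon": lon})


def test_planted_deep_effect_sample_mean_oracle():
    cfg = ScenarioConfig(n_whales=1, days=20.0)
    track = _stationary_track(cfg, cfg.center_lat, cfg.center_lon)
    always_on = pd.DataFrame([{
        "sonar_type": "mid", "start_time": cfg.start_ts,
        "end_time": cfg.end_ts, "start_lat": cfg.center_lat,
        "start_lon": cfg.center_lon, "on_soar": True}])
    none = always_on.iloc[:0]
    _, exposed = simulate.gen_behaviour_log(
        cfg, "W0", track, always_on, np.random.default_rng(1))
    _, quiet = simulate.gen_behaviour_log(
        cfg, "W0", track, none, np.random.default_rng(1))
    de = exposed[exposed["true_class"] == "deep"]["duration_min"]
    dq = quiet[quiet["true_class"] == "deep"]["duration_min"]
    # whale at distance 0: full +30 min on every deep dive
    assert de.mean() - dq.mean() == pytest.approx(
        cfg.mid_deep_extra_min, abs=4.0)
    # and the whole inter-deep interval doubles
    def iddi_mean(ev):
        g = ev[ev["true_class"] == "deep"].sort_values("start")
        return np.mean([(s1 - e0).total_seconds() / 60.0 for e0, s1 in
                        zip(g["end"].iloc[:-1], g["start"].iloc[1:])])
    assert iddi_mean(exposed) / iddi_mean(quiet) == pytest.approx(
        cfg.iddi_multiplier, rel=0.15)


def test_planted_effect_vanishes_beyond_ramp():
    cfg = ScenarioConfig(n_whales=1, days=20.0)
    # whale ~ 167 km from the bout: beyond both ramps
    track = _stationary_track(cfg, cfg.center_lat + 1.5, cfg.center_lon)
    far_bout = pd.DataFrame([{
        "sonar_type": "mid", "start_time": cfg.start_ts,
        "end_time": cfg.end_ts, "start_lat": cfg.center_lat,
        "start_lon": cfg.center_lon, "on_soar": True}])
    _, far = simulate.gen_behaviour_log(
        cfg, "W0", track, far_bout, np.random.default_rng(1))
    _, quiet = simulate.gen_behaviour_log(
        cfg, "W0", track, far_bout.iloc[:0], np.random.default_rng(1))
    de = far[far["true_class"] == "deep"]["duration_min"]
    dq = quiet[quiet["true_class"] == "deep"]["duration_min"]
    assert de.mean() - dq.mean() == pytest.approx(0.0, abs=3.0)


# ---------------------------------------------------------------------------
# sonar schedule
# ---------------------------------------------------------------------------

def test_bout_duration_calibration():
    cfg = ScenarioConfig(days=300.0)  # schedule only: cheap at any length
    polys = simulate.gen_subareas(cfg)
    truth, arch, sports, coverage, outages = simulate.gen_sonar_schedule(
        cfg, polys, np.random.default_rng(2))
    mid = truth[truth["sonar_type"] == "mid"]
    high = truth[truth["sonar_type"] == "high"]
    assert len(mid) > 200
    mid_dur = (mid["end_time"] - mid["start_time"]).dt.total_seconds() / 60.0
    high_dur = (high["end_time"] - high["start_time"]).dt.total_seconds() / 60.0
    assert 5.0 <= mid_dur.median() <= 10.0
    assert 50.0 <= high_dur.median() <= 85.0


def test_archive_is_on_soar_covered_truth(small_scenario):
    s = small_scenario
    arch = s.archive_bouts
    assert arch["on_soar"].all()
    from ziphius import intervals as iv
    for _, r in arch.iterrows():
        ov = iv.overlap_seconds((r["start_time"], r["end_time"]), s.coverage)
        assert ov >= (r["end_time"] - r["start_time"]).total_seconds() - 1.0


def test_planted_duplicates_found_exactly():
    cfg = ScenarioConfig(days=60.0)
    polys = simulate.gen_subareas(cfg)
    truth, arch, sports, _, _ = simulate.gen_sonar_schedule(
        cfg, polys, np.random.default_rng(9))
    pairs = fusion.resolve_duplicates(fusion.find_duplicates(arch, sports))
    resolved = {int(r["sports_idx"]): int(r["archive_idx"])
                for _, r in pairs.iterrows()}
    arch_truth = arch.reset_index(drop=True)["truth_idx"]
    truth_to_arch = {int(t): int(i) for i, t in arch_truth.items()}
    # every SPORTS record whose source bout is archived resolves to exactly
    # that archive bout (extra matches can only involve unarchived sources)
    for sj, t in sports["truth_idx"].items():
        if int(t) in truth_to_arch:
            assert resolved.get(int(sj)) == truth_to_arch[int(t)]
    for sj, ai in resolved.items():
        t = int(sports.at[sj, "truth_idx"])
        if t in truth_to_arch:
            assert ai == truth_to_arch[t]


def test_outages_inside_study_period(small_scenario):
    c = small_scenario.config
    for s, e in small_scenario.truth.outages:
        assert c.start_ts <= s < e <= c.end_ts


# ---------------------------------------------------------------------------
# detection reports
# ---------------------------------------------------------------------------

def test_arrival_time_differences_match_ranges():
    cfg = ScenarioConfig()
    layout = simulate.hydrophone_layout(cfg)
    bout = pd.DataFrame([{
        "sonar_type": "mid", "start_time": pd.Timestamp("2011-01-10T06:00:00Z"),
        "end_time": pd.Timestamp("2011-01-10T06:00:20Z"),
        "start_lat": cfg.center_lat + 0.05, "start_lon": cfg.center_lon - 0.1,
        "on_soar": True}])
    rep = simulate.gen_detection_reports(bout, layout,
                                         np.random.default_rng(3),
                                         clutter_per_hour=0.0)
    first = rep.groupby("hydrophone_id")["time"].min()
    from ziphius.geo import great_circle_km
    from ziphius.detection import stft_frame_step_s
    step = stft_frame_step_s(96000.0, 2048)
    d = {h: great_circle_km(bout["start_lat"][0], bout["start_lon"][0], *p)
         for h, p in layout.items() if h in first.index}
    h0 = min(d, key=d.get)
    for h in d:
        dt_got = (first[h] - first[h0]).total_seconds()
        dt_want = (d[h] - d[h0]) * 1000.0 / 1500.0
        assert dt_got == pytest.approx(dt_want, abs=1.5 * step)


def test_detection_levels_by_type():
    cfg = ScenarioConfig()
    layout = {"H0": (cfg.center_lat, cfg.center_lon)}
    t0 = pd.Timestamp("2011-01-10T06:00:00Z")
    mk = lambda typ: pd.DataFrame([{
        "sonar_type": typ, "start_time": t0,
        "end_time": t0 + pd.Timedelta(minutes=5),
        "start_lat": cfg.center_lat + 0.05, "start_lon": cfg.center_lon,
        "on_soar": True}])
    rng = np.random.default_rng(4)
    hi = simulate.gen_detection_reports(mk("high"), layout, rng,
                                        clutter_per_hour=0.0)
    mid = simulate.gen_detection_reports(mk("mid"), layout, rng,
                                         clutter_per_hour=0.0)
    assert hi["peak_level_db"].median() > 160
    assert mid["peak_level_db"].median() < 150
    assert hi["peak_freq_hz"].median() == pytest.approx(3500, abs=50)
    assert mid["peak_freq_hz"].median() == pytest.approx(3000, abs=50)


# ---------------------------------------------------------------------------
# truth model tables
# ---------------------------------------------------------------------------

def test_truth_model_table_deep(small_scenario):
    tab = simulate.truth_model_table(small_scenario, "deep_duration")
    assert (tab["y"] > 0).all()
    assert set(tab["diel"]) <= {"Day", "Night", "Dawn", "Dusk"}
    assert {"dist_high_km", "dist_mid_km", "ol_mid", "presence_cat"} <= \
        set(tab.columns)
    assert np.isfinite(tab["lat"]).all()


def test_truth_model_table_iddi(small_scenario):
    tab = simulate.truth_model_table(small_scenario, "iddi")
    assert (tab["y"] > 0).all()
    assert tab["weight"].min() == pytest.approx(1.0)
    assert "preceding_deep_duration_min" in tab.columns


def test_truth_model_table_unknown_response(small_scenario):
    with pytest.raises(ValueError):
        simulate.truth_model_table(small_scenario, "dive_rate")
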
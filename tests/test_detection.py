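import numpy as np
import pandas as pd
import pytest

from ziphius import detection, intervals as iv
from ziphius.detection import DetectorConfig


FS = 96000.0
NFFT = 2048
STEP = detection.stft_frame_step_s(FS, NFFT)          # 10.666... ms
BIN = detection.stft_bin_width_hz(FS, NFFT)           # 46.875 Hz


def T(seconds):
    return pd.Timestamp("2011-01-01", tz="UTC") + pd.Timedelta(seconds=seconds)


# ---------------------------------------------------------------------------
# STFT bookkeeping
# ---------------------------------------------------------------------------

def test_bin_width_and_frame_step():
    assert BIN == pytest.approx(46.875)
    assert STEP * 1000 == pytest.approx(10.67, abs=0.01)
    # and the inverse relation at 50% overlap
    assert detection.frame_step_from_bin_width_s(46.875) == pytest.approx(STEP)


def test_frame_step_overlap_validation():
    with pytest.raises(ValueError):
        detection.stft_frame_step_s(FS, NFFT, overlap=1.0)


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(band_lo_hz=5000.0, band_hi_hz=2500.0)


# ---------------------------------------------------------------------------
# hard limiting
# ---------------------------------------------------------------------------

def _frames(power, hid="H1", sparse=False, t0=0.0):
    n = power.shape[0]
    return {"hydrophone_id": hid, "fs": FS, "nfft": NFFT, "sparse": sparse,
            "times": [T(t0 + i * STEP) for i in range(n)], "power": power}


def test_hard_limit_flags_impulse_over_noise_floor():
    rng = np.random.default_rng(0)
    power = rng.exponential(1.0, size=(200, NFFT // 2))
    k = int(3500 / BIN)
    power[100, k] = 500.0
    out = detection.hard_limit(_frames(power))
    assert k in out["bins_above"].iloc[100]
    assert out["peak_freq_hz"].iloc[100] == pytest.approx(k * BIN)


def test_hard_limit_stationary_noise_rarely_fires():
    rng = np.random.default_rng(1)
    power = rng.normal(1.0, 0.05, size=(300, NFFT // 2)).clip(min=0.01)
    out = detection.hard_limit(_frames(power))
    assert out["n_bins_above"].sum() == 0


def test_hard_limit_sparse_drops_empty_frames():
    rng = np.random.default_rng(2)
    power = rng.normal(1.0, 0.02, size=(50, NFFT // 2)).clip(min=0.01)
    power[10, 40] = 100.0
    out = detection.hard_limit(_frames(power, sparse=True))
    assert len(out) == 1 and out["time"].iloc[0] == T(10 * STEP)


def test_ndjson_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    power = rng.exponential(1.0, size=(20, NFFT // 2))
    power[5, 70] = 300.0
    out = detection.hard_limit(_frames(power))
    p = tmp_path / "r.ndjson"
    detection.reports_to_ndjson(out, p)
    back = detection.reports_from_ndjson(p)
    assert len(back) == len(out)
    assert (back["peak_freq_hz"] == out["peak_freq_hz"]).all()
    assert back["time"].equals(out["time"])


# ---------------------------------------------------------------------------
# ping extraction
# ---------------------------------------------------------------------------

def _report_stream(flags, hid="H1", freq=3500.0, level=160.0, t0=0.0):
    """Dense frame reports; flags[i] truthy -> in-band bin set."""
    k = int(freq / BIN)
    rows = []
    for i, f in enumerate(flags):
        rows.append({
            "time": T(t0 + i * STEP), "hydrophone_id": hid, "fs": FS,
            "nfft": NFFT,
            "bins_above": np.array([k] if f else [], dtype=int),
            "n_bins_above": 1 if f else 0,
            "peak_freq_hz": freq if f else 100.0,
            "peak_level_db": level if f else 80.0,
        })
    return pd.DataFrame(rows)


def test_ping_run_of_120_frames_detected():
    flags = [0] * 10 + [1] * 120 + [0] * 10   # 120 * 10.67 ms = 1.28 s
    pings = detection.detect_pings(_report_stream(flags))
    assert len(pings) == 1
    assert pings["duration_s"].iloc[0] == pytest.approx(120 * STEP)
    assert pings["start_time"].iloc[0] == T(10 * STEP)


def test_run_of_40_frames_too_short():
    flags = [0] * 10 + [1] * 40 + [0] * 10    # 0.43 s < 1 s
    assert detection.detect_pings(_report_stream(flags)).empty


def test_single_clear_frame_splits_run():
    flags = [1] * 120 + [0] + [1] * 120
    pings = detection.detect_pings(_report_stream(flags))
    assert len(pings) == 2
    assert np.allclose(pings["duration_s"], 120 * STEP)


def test_sparse_stream_missing_frames_count_clear():
    dense = _report_stream([1] * 120 + [0] * 5 + [1] * 120)
    sparse = dense[dense["n_bins_above"] > 0].reset_index(drop=True)
    pings = detection.detect_pings(sparse)
    assert len(pings) == 2


def test_out_of_band_run_ignored():
    pings = detection.detect_pings(_report_stream([1] * 200, freq=1000.0))
    assert pings.empty


# ---------------------------------------------------------------------------
# clutter screening
# ---------------------------------------------------------------------------

def _ping_table(times_s, hid="H1", level=160.0):
    return pd.DataFrame({
        "hydrophone_id": hid,
        "start_time": [T(s) for s in times_s],
        "duration_s": 1.3, "peak_freq_hz": 3500.0, "peak_level_db": level,
    })


def test_screen_keeps_regular_train():
    pings = _ping_table(np.arange(10) * 25.0)
    out = detection.screen_false_positives(pings)
    assert len(out) == 10


def test_screen_drops_irregular_cluster():
    # median IDI ~6 s: whistle-like
    pings = _ping_table(np.cumsum([0, 5, 7, 4, 8, 6, 5, 9]))
    assert detection.screen_false_positives(pings).empty


def test_screen_drops_isolated_pings():
    pings = _ping_table([0.0, 500.0, 1200.0])
    assert detection.screen_false_positives(pings).empty


def test_screen_tolerance_band():
    # median IDI 36 s: inside 30 * 1.25 = 37.5 -> kept
    kept = detection.screen_false_positives(_ping_table(np.arange(6) * 36.0))
    assert len(kept) == 6
    # median IDI 40 s: outside the widened band -> dropped
    gone = detection.screen_false_positives(_ping_table(np.arange(6) * 40.0))
    assert gone.empty


# ---------------------------------------------------------------------------
# bout segmentation
# ---------------------------------------------------------------------------

def test_single_bout_under_continuity():
    pings = _ping_table(np.arange(20) * 25.0)
    bouts = detection.segment_bouts(pings)
    assert len(bouts) == 1
    assert bouts["n_pings"].iloc[0] == 20


def test_gap_over_three_minutes_splits():
    t = np.r_[np.arange(10) * 25.0, 25.0 * 9 + 185.0 + np.arange(10) * 25.0]
    bouts = detection.segment_bouts(_ping_table(t))
    assert len(bouts) == 2


def test_cross_hydrophone_linking():
    a = _ping_table(np.arange(5) * 25.0, hid="H1")
    b = _ping_table(np.arange(5) * 25.0 + 2.0, hid="H2", level=150.0)
    bouts = detection.segment_bouts(pd.concat([a, b], ignore_index=True))
    assert len(bouts) == 1 and bouts["n_pings"].iloc[0] == 10


def test_type_split_on_median_level():
    hi = detection.segment_bouts(_ping_table(np.arange(5) * 25.0, level=170.0))
    mid = detection.segment_bouts(_ping_table(np.arange(5) * 25.0, level=140.0))
    assert hi["sonar_type"].iloc[0] == "high"
    assert mid["sonar_type"].iloc[0] == "mid"


def _oracle_bouts(pings, config):
    """O(n^2) transitive closure over bout_linked."""
    n = len(pings)
    labels = list(range(n))
    rows = [pings.iloc[i] for i in range(n)]
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                if detection.bout_linked(rows[i], rows[j], config) and \
                        labels[i] != labels[j]:
                    lo, hi = sorted((labels[i], labels[j]))
                    labels = [lo if l == hi else l for l in labels]
                    changed = True
    return labels


def _partition_sets(labels):
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


def test_segmentation_matches_oracle_random():
    rng = np.random.default_rng(7)
    config = DetectorConfig()
    for _ in range(60):
        n = int(rng.integers(2, 25))
        t = np.sort(rng.uniform(0, 1500, n))
        hids = rng.choice(["H1", "H2", "H3"], n)
        pings = pd.DataFrame({
            "hydrophone_id": hids, "start_time": [T(s) for s in t],
            "duration_s": 1.3, "peak_freq_hz": 3500.0,
            "peak_level_db": rng.uniform(140, 170, n)})
        bouts = detection.segment_bouts(pings, config)
        p = pings.sort_values(["start_time", "hydrophone_id"]
                              ).reset_index(drop=True)
        oracle = _partition_sets(_oracle_bouts(p, config))
        assert len(bouts) == len(oracle)
        got_sizes = sorted(bouts["n_pings"].tolist())
        assert got_sizes == sorted(len(s) for s in oracle)


def test_multi_source_flag_on_interleaved_trains():
    # two interleaved regular trains on one phone: IDI alternates 5 / 20 s
    t = np.sort(np.r_[np.arange(12) * 25.0, np.arange(12) * 25.0 + 5.0])
    bouts = detection.segment_bouts(_ping_table(t))
    assert bool(bouts["multi_source"].iloc[0])


def test_single_train_not_multi_source():
    bouts = detection.segment_bouts(_ping_table(np.arange(15) * 25.0))
    assert not bool(bouts["multi_source"].iloc[0])


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

LAYOUT = {"H1": (33.00, -119.00), "H2": (33.00, -118.90),
          "H3": (33.08, -118.95), "H4": (33.05, -119.05)}


def _arrivals(src_lat, src_lon, layout, c=1500.0):
    from ziphius.geo import great_circle_km
    return {h: great_circle_km(src_lat, src_lon, *p) * 1000.0 / c
            for h, p in layout.items()}


def test_localization_exact_within_100m():
    src = (33.04, -118.96)
    lat, lon, q = detection.localize_bout(_arrivals(*src, LAYOUT), LAYOUT)
    from ziphius.geo import great_circle_km
    assert q == "localized"
    assert great_circle_km(lat, lon, *src) < 0.1


def test_two_phone_fallback():
    two = {k: LAYOUT[k] for k in ["H1", "H2"]}
    arr = _arrivals(33.04, -118.96, two)
    lat, lon, q = detection.localize_bout(arr, two)
    assert q == "nearest_edge_phone"
    first = min(arr, key=arr.get)
    assert (lat, lon) == two[first]


def test_collinear_geometry_fallback():
    lay = {"H1": (33.0, -119.0), "H2": (33.0, -118.95), "H3": (33.0, -118.90)}
    arr = _arrivals(33.05, -118.95, lay)
    _, _, q = detection.localize_bout(arr, lay)
    assert q == "nearest_edge_phone"


def test_source_at_hydrophone():
    src = LAYOUT["H2"]
    lat, lon, q = detection.localize_bout(_arrivals(*src, LAYOUT), LAYOUT)
    from ziphius.geo import great_circle_km
    assert great_circle_km(lat, lon, *src) < 0.1


def test_no_known_phone_raises():
    with pytest.raises(ValueError):
        detection.localize_bout({"HX": 0.0}, LAYOUT)


# ---------------------------------------------------------------------------
# false-negative audit
# ---------------------------------------------------------------------------

def test_fnr_examples():
    def TT(m):
        return pd.Timestamp("2011-01-01", tz="UTC") + pd.Timedelta(minutes=m)

    coverage = [(TT(0), TT(100))]
    truth = [(TT(10), TT(30)), (TT(50), TT(60))]
    detected = [(TT(10), TT(30))]
    # quiet = 100 - 20 = 80 min; missed = 10 min inside quiet
    rate = detection.estimate_false_negative_rate(detected, truth, coverage)
    assert rate == pytest.approx(10.0 / 80.0)
    # perfect detection -> 0
    assert detection.estimate_false_negative_rate(truth, truth, coverage) == 0.0
    # no quiet time -> 0 by convention
    assert detection.estimate_false_negative_rate(
        coverage, truth, coverage) == 0.0
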
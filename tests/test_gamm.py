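import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

from ziphius import gamm
from ziphius.gamm import (CrSplineBasis, ExposureGAMM, ModelSpec,
                          aic_weights, all_subsets_selection,
                          candidate_terms, choose_time_block,
                          enumerate_specs, predict_effect)


def T(minutes):
    return pd.Timestamp("2011-05-01", tz="UTC") + pd.Timedelta(minutes=minutes)


# ---------------------------------------------------------------------------
# spline basis
# ---------------------------------------------------------------------------

KNOTS = np.array([0.0, 10.0, 25.0, 60.0, 100.0])


def test_basis_value_parametrization_identity_at_knots():
    b = CrSplineBasis(KNOTS)
    assert np.allclose(b.design(KNOTS), np.eye(5), atol=1e-10)


def test_basis_matches_natural_cubic_spline_oracle(rng):
    vals = rng.normal(0, 1, 5)
    b = CrSplineBasis(KNOTS)
    cs = CubicSpline(KNOTS, vals, bc_type="natural")
    x = np.linspace(0.0, 100.0, 73)
    assert np.allclose(b.design(x) @ vals, cs(x), atol=1e-9)


def test_basis_linear_extrapolation(rng):
    vals = rng.normal(0, 1, 5)
    b = CrSplineBasis(KNOTS)
    f = lambda x: b.design(np.atleast_1d(x)) @ vals
    # outside the knots the function is linear: equal successive differences
    lo = f([-30.0, -20.0, -10.0])
    hi = f([110.0, 120.0, 130.0])
    assert np.diff(lo, 2) == pytest.approx(0.0, abs=1e-9)
    assert np.diff(hi, 2) == pytest.approx(0.0, abs=1e-9)
    # and continuous at the boundary
    assert f([100.0])[0] == pytest.approx(vals[-1])


def test_penalty_raw_null_space_is_linear():
    b = CrSplineBasis(KNOTS, shrinkage=False)
    const = np.ones(5)
    lin = KNOTS.copy()
    assert const @ b.penalty @ const == pytest.approx(0.0, abs=1e-10)
    assert lin @ b.penalty @ lin == pytest.approx(0.0, abs=1e-6)
    assert b.penalty_rank == 3


def test_shrinkage_penalty_positive_definite():
    b = CrSplineBasis(KNOTS, shrinkage=True)
    vals = np.linalg.eigvalsh(b.penalty)
    assert vals.min() > 0
    assert b.penalty_rank == 5
    assert np.isfinite(b.penalty_logdet)


def test_quantile_knots_requires_enough_values():
    with pytest.raises(ValueError):
        CrSplineBasis.from_quantile_knots(np.array([1.0, 2.0, 3.0]), k=5)


# ---------------------------------------------------------------------------
# model table generators
# ---------------------------------------------------------------------------

def _table(rng, n_whales=8, n_per=40, whale_sd=0.0, block_sd=0.0,
           noise_sd=1.0, effect=None, block_h=6.0):
    rows = []
    for w in range(n_whales):
        uw = rng.normal(0, whale_sd)
        blocks = {}
        for i in range(n_per):
            t = T(w * 100000 + i * 30)
            bkey = int(i * 30 // (block_h * 60))
            if bkey not in blocks:
                blocks[bkey] = rng.normal(0, block_sd)
            present = rng.random() < 0.3
            dist = float(rng.uniform(2, 80)) if present else 500.0
            y = 60.0 + uw + blocks[bkey] + rng.normal(0, noise_sd)
            if effect is not None and present:
                y += effect(dist)
            rows.append({
                "whale_id": f"W{w}", "time": t, "y": y,
                "diel": rng.choice(["Day", "Night"]),
                "present_high": False, "present_mid": present,
                "dist_high_km": 500.0, "dist_mid_km": dist,
                "ol_high": 0.0, "ol_mid": 0.5 if present else 0.0,
                "presence_cat": "mid" if present else "none",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood against a dense mixed-model oracle
# ---------------------------------------------------------------------------

def _dense_neg2ll(y, X, Z, lam, w):
    """Marginal ML -2logLik of y ~ N(Xb, s2*(W^-1 + Z Z'/lam)), b and s2
    profiled out."""
    n = len(y)
    V = np.diag(1.0 / w) + Z @ Z.T / lam
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    Q = float(r @ Vi @ r)
    s2 = Q / n
    sign, logdetV = np.linalg.slogdet(V)
    return n * np.log(2 * np.pi * s2) + n + logdetV


@pytest.mark.parametrize("theta", [-1.0, 0.0, 1.5])
def test_loglik_matches_dense_oracle(rng, theta):
    d = _table(rng, n_whales=4, n_per=6, whale_sd=2.0)
    spec = ModelSpec(response="deep_duration", mfas="none", terms=("diel",))
    m = ExposureGAMM(d, spec)
    got = m._neg2loglik(np.array([theta]))
    whales, codes = np.unique(d["whale_id"], return_inverse=True)
    Z = np.zeros((len(d), whales.size))
    Z[np.arange(len(d)), codes] = 1.0
    want = _dense_neg2ll(m.y, m.X, Z, np.exp(theta), m.w)
    assert got == pytest.approx(want, rel=1e-8)


def test_loglik_matches_dense_oracle_weighted(rng):
    d = _table(rng, n_whales=4, n_per=6, whale_sd=2.0)
    d["weight"] = rng.uniform(0.5, 3.0, len(d))
    spec = ModelSpec(response="iddi", mfas="none", weight_col="weight")
    m = ExposureGAMM(d, spec)
    got = m._neg2loglik(np.array([0.3]))
    whales, codes = np.unique(d["whale_id"], return_inverse=True)
    Z = np.zeros((len(d), whales.size))
    Z[np.arange(len(d)), codes] = 1.0
    want = _dense_neg2ll(m.y, m.X, Z, np.exp(0.3), m.w)
    assert got == pytest.approx(want, rel=1e-8)


def test_infinite_smoothing_shrinks_smooth_to_zero(rng):
    d = _table(rng, effect=lambda dist: 30.0 * np.exp(-dist / 20.0))
    spec = ModelSpec(response="deep_duration", mfas="distance")
    m = ExposureGAMM(d, spec)
    # theta order follows m.blocks: smooths first, then whale RE
    names = [b[0] for b in m.blocks]
    theta_inf = np.array([25.0 if n.startswith("s(") else 0.0 for n in names])
    theta_0 = np.zeros(len(names))
    _, ex_inf = m._neg2loglik(theta_inf, want=True)
    _, ex_0 = m._neg2loglik(theta_0, want=True)
    off = m.p_fixed
    for (name, _, S, _, q) in m.blocks:
        if name.startswith("s("):
            big = np.max(np.abs(ex_0["delta"][off:off + q]))
            small = np.max(np.abs(ex_inf["delta"][off:off + q]))
            assert small < 1e-4 * big  # shrunk by >= 4 orders of magnitude
        off += q


# ---------------------------------------------------------------------------
# AIC and weights
# ---------------------------------------------------------------------------

def test_aic_identity(rng):
    d = _table(rng, whale_sd=3.0)
    res = ExposureGAMM(d, ModelSpec(response="deep_duration", mfas="none",
                                    terms=("diel",))).fit()
    assert res.edf == res.model.p_fixed + len(res.model.blocks) + 1
    assert res.aic == pytest.approx(-2.0 * res.loglik + 2.0 * res.edf)


def test_aic_weights_known_values():
    w = aic_weights([100.0, 102.0])
    assert w[0] == pytest.approx(0.7311, abs=1e-4)
    assert w[1] == pytest.approx(0.2689, abs=1e-4)
    assert w.sum() == pytest.approx(1.0)


def test_aic_weights_sum_to_one(rng):
    w = aic_weights(rng.uniform(500, 600, 12))
    assert w.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# enumeration and selection
# ---------------------------------------------------------------------------

def test_enumeration_no_mixed_parametrization():
    specs = enumerate_specs("deep_duration", "SOAR", terms=("diel", "ol_mid"))
    assert len(specs) == 4 * 3
    for s in specs:
        assert s.mfas in ("none", "distance", "presence")
    # every (terms, mfas) combination is unique
    assert len({(s.terms, s.mfas) for s in specs}) == len(specs)


def test_candidate_terms_rules():
    assert "subarea" in candidate_terms("deep_duration", "Complete")
    assert "subarea" not in candidate_terms("deep_duration", "SOAR")
    assert "ol_high" not in candidate_terms("surface_interval", "Complete")
    assert "surface_seq" in candidate_terms("surface_interval", "SOAR")


def test_enumeration_cap():
    with pytest.raises(ValueError, match="exceeds"):
        enumerate_specs("deep_duration", "Complete",
                        terms=tuple(f"t{i}" for i in range(9)))


def test_selection_prefers_distance_when_planted(rng):
    d = _table(rng, n_whales=10, n_per=60, whale_sd=2.0, noise_sd=2.0,
               effect=lambda dist: 30.0 * np.clip(1 - dist / 40.0, 0, None))
    sel = all_subsets_selection(d, "deep_duration", "Complete",
                                terms=("diel",),
                                mfas_options=("none", "distance"))
    assert sel.best_spec.mfas == "distance"
    assert sel.table["delta_aic"].iloc[0] == 0.0
    assert sel.table["aic_weight"].iloc[0] == sel.table["aic_weight"].max()


def test_selection_order_invariance(rng):
    d = _table(rng, n_whales=6, n_per=25, whale_sd=2.0)
    s1 = all_subsets_selection(d, "deep_duration", "Complete", terms=("diel",),
                               mfas_options=("none", "presence"))
    d2 = d.sample(frac=1.0, random_state=3).reset_index(drop=True)
    s2 = all_subsets_selection(d2, "deep_duration", "Complete",
                               terms=("diel",),
                               mfas_options=("none", "presence"))
    assert list(s1.table["label"]) == list(s2.table["label"])
    assert np.allclose(s1.table["aic"].to_numpy(), s2.table["aic"].to_numpy(),
                       atol=1e-3)


def test_selection_records_failures(rng):
    d = _table(rng, n_whales=4, n_per=10)
    d["bad"] = np.nan  # a term column of NaNs breaks those fits
    with pytest.warns(UserWarning, match="failed"):
        sel = all_subsets_selection(d, "deep_duration", "Complete",
                                    terms=("bad",),
                                    mfas_options=("none",))
    assert len(sel.failures) == 1
    assert len(sel.table) == 1


# ---------------------------------------------------------------------------
# time blocks
# ---------------------------------------------------------------------------

def test_time_block_triggered_by_autocorrelation(rng):
    d = _table(rng, n_whales=6, n_per=80, whale_sd=1.0, block_sd=4.0,
               noise_sd=0.7)
    spec = ModelSpec(response="deep_duration", mfas="none", terms=("diel",))
    block, diag = choose_time_block(d, spec, candidates=(3.0, 6.0, 12.0))
    assert diag["acf_whale_only"] > gamm.ACF_TRIGGER
    assert block in (3.0, 6.0, 12.0)
    assert diag["aic_by_block"]


def test_time_block_not_added_when_iid(rng):
    # enough pairs that the null ACF (SE ~ 0.02) sits well under the trigger
    d = _table(rng, n_whales=8, n_per=150, whale_sd=1.0, noise_sd=1.0)
    spec = ModelSpec(response="deep_duration", mfas="none")
    block, diag = choose_time_block(d, spec)
    assert block is None
    assert diag["aic_by_block"] == {}


# ---------------------------------------------------------------------------
# recovery and prediction
# ---------------------------------------------------------------------------

def test_whale_variance_recovery(rng):
    d = _table(rng, n_whales=20, n_per=50, whale_sd=5.0, noise_sd=2.0)
    res = ExposureGAMM(d, ModelSpec(response="deep_duration", mfas="none")).fit()
    assert np.sqrt(res.re_variance["whale"]) == pytest.approx(5.0, rel=0.3)
    assert np.sqrt(res.sigma2) == pytest.approx(2.0, rel=0.15)


def test_distance_curve_recovers_planted_effect(rng):
    d = _table(rng, n_whales=12, n_per=60, whale_sd=2.0, noise_sd=2.0,
               effect=lambda dist: 30.0 * np.clip(1 - dist / 40.0, 0, None))
    res = ExposureGAMM(d, ModelSpec(response="deep_duration",
                                    mfas="distance")).fit()
    curve = predict_effect(res, "dist_mid", grid=np.array([5.0, 70.0]))
    assert curve.mean[0] - curve.mean[1] == pytest.approx(
        30.0 * (1 - 5.0 / 40.0), abs=6.0)
    assert (curve.ci_hi >= curve.mean).all()
    assert curve.in_support.all()


def test_prediction_unexposed_row_ignores_smooth(rng):
    d = _table(rng, effect=lambda dist: 20.0 * np.exp(-dist / 30.0))
    res = ExposureGAMM(d, ModelSpec(response="deep_duration",
                                    mfas="distance")).fit()
    base = gamm._baseline_row(res)
    row = pd.DataFrame([base])
    pred = res.predict(row)[0]
    # baseline has both types absent: prediction is the fixed part only
    C = res.design_for(row)
    assert np.allclose(C[0, res.model.p_fixed:], 0.0)
    assert pred == pytest.approx(float(C[0, :res.model.p_fixed]
                                       @ res.params.to_numpy()))


def test_predict_effect_fixed_covariates_recorded(rng):
    d = _table(rng, effect=lambda dist: 20.0 * np.exp(-dist / 30.0))
    res = ExposureGAMM(d, ModelSpec(response="deep_duration", mfas="distance",
                                    terms=("diel",))).fit()
    curve = predict_effect(res, "dist_mid")
    assert curve.fixed["diel"] == "Night"
    assert curve.fixed["dist_high_km"] == gamm.ABSENT_PLACEHOLDER_KM
    assert len(curve.grid) == len(curve.mean) == 50
    assert curve.rug.size > 0


def test_presence_effect_curve(rng):
    d = _table(rng, effect=lambda dist: 15.0)
    res = ExposureGAMM(d, ModelSpec(response="deep_duration",
                                    mfas="presence")).fit()
    curve = predict_effect(res, "presence_cat")
    assert curve.fixed["levels"] == ["none", "mid"]
    assert curve.mean[1] - curve.mean[0] == pytest.approx(15.0, abs=3.0)


def test_empty_table_raises():
    with pytest.raises(ValueError, match="empty"):
        ExposureGAMM(pd.DataFrame(columns=["y", "whale_id", "time"]),
                     ModelSpec(response="deep_duration"))


def test_nonpositive_weights_raise(rng):
    d = _table(rng, n_whales=3, n_per=5)
    d["weight"] = 0.0
    with pytest.raises(ValueError, match="weights"):
        ExposureGAMM(d, ModelSpec(response="iddi", weight_col="weight"))
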
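"""Exposure-response GAMMs: Gaussian additive mixed models with shrinkage
cubic regression splines, whale (and optional nested time-block) random
intercepts, marginal maximum-likelihood fitting, all-subsets AIC selection
and prediction curves.

Model
-----
    y = X beta + sum_j f_j(x_j) * gate_j + Z b + eps

where each f_j is a cubic regression spline on k=5 quantile knots whose
penalty is modified so its null space (linear functions) is also shrunk:
as the smoothing parameter grows the whole term vanishes, letting AIC drop
an MFAS effect entirely. gate_j is the 0/1 presence of that sonar type
(absent rows carry a 500 km placeholder distance and contribute exactly 0).
Random intercepts and spline coefficients are handled uniformly in the
mixed-model representation; variance and smoothing parameters maximize the
marginal (ML, not REML) likelihood so AIC comparisons across fixed-effect
subsets are valid. MFAS parametrizations: 'distance' (one gated smooth per
sonar type), 'presence' (a 4-level factor none/high/mid/both), or 'none' --
a single model never mixes effect types across the two sonar types.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "SPLINE_K", "ABSENT_PLACEHOLDER_KM", "TIME_BLOCK_CANDIDATES_H",
    "CrSplineBasis", "ModelSpec", "ExposureGAMM", "GAMMResults",
    "SelectionResult", "aic_weights", "all_subsets_selection",
    "choose_time_block", "candidate_terms", "predict_effect", "PredictionCurve",
]

SPLINE_K = 5
ABSENT_PLACEHOLDER_KM = 500.0
TIME_BLOCK_CANDIDATES_H = (2, 3, 4, 6, 12)
ACF_TRIGGER = 0.10
MAX_MODELS = 512
_CATEGORICAL_ORDERS = {
    "diel": ["Night", "Day", "Dawn", "Dusk"],
    "presence_cat": ["none", "high", "mid", "both"],
    "surface_seq": ["intermediate", "post-deep", "pre-deep", "post-and-pre-deep"],
}


# ---------------------------------------------------------------------------
# Shrinkage cubic regression spline basis
# ---------------------------------------------------------------------------

class CrSplineBasis:
    """Cubic regression spline on fixed knots, value-based parametrization.

    Coefficients are the spline's values at the knots; the curvature
    penalty is the integrated squared second derivative. The shrinkage
    variant replaces the penalty's two null-space eigenvalues (constant and
    linear functions) with a tenth of its smallest positive eigenvalue, so
    an infinite smoothing parameter shrinks the whole term to zero.
    Evaluation outside the knot range extrapolates linearly.
    """

    def __init__(self, knots, shrinkage: bool = True):
        knots = np.unique(np.asarray(knots, dtype=float))
        if knots.size < 3:
            raise ValueError("need at least 3 distinct knots")
        self.knots = knots
        k = knots.size
        h = np.diff(knots)
        B = np.zeros((k - 2, k - 2))
        D = np.zeros((k - 2, k))
        for i in range(k - 2):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i > 0:
                B[i, i - 1] = h[i] / 6.0
            if i < k - 3:
                B[i, i + 1] = h[i + 1] / 6.0
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        F = np.linalg.solve(B, D)
        self._Fplus = np.vstack([np.zeros(k), F, np.zeros(k)])  # knot 2nd derivs
        self.penalty_raw = D.T @ F  # = D' B^{-1} D, rank k-2
        if shrinkage:
            vals, vecs = np.linalg.eigh(self.penalty_raw)
            vals = vals[::-1].copy()
            vecs = vecs[:, ::-1]
            pos = vals[vals > 1e-10 * vals[0]]
            eps = 0.1 * pos.min()
            vals[vals <= 1e-10 * vals[0]] = eps
            self.penalty = (vecs * vals) @ vecs.T
        else:
            self.penalty = self.penalty_raw
        sign, logdet = np.linalg.slogdet(self.penalty) if shrinkage else (0, 0.0)
        self.penalty_logdet = float(logdet) if shrinkage else None
        self.penalty_rank = k if shrinkage else k - 2

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        kn = self.knots
        k = kn.size
        lo, hi = kn[0], kn[-1]
        xc = np.clip(x, lo, hi)
        rows = self._design_inside(xc)
        below = x < lo
        above = x > hi
        if below.any():
            rows[below] += (x[below] - lo)[:, None] * self._deriv_at(lo)
        if above.any():
            rows[above] += (x[above] - hi)[:, None] * self._deriv_at(hi)
        return rows

    def _design_inside(self, x):
        kn = self.knots
        j = np.clip(np.searchsorted(kn, x, side="right") - 1, 0, kn.size - 2)
        h = kn[j + 1] - kn[j]
        am = (kn[j + 1] - x) / h
        ap = (x - kn[j]) / h
        cm = ((kn[j + 1] - x) ** 3 / h - h * (kn[j + 1] - x)) / 6.0
        cp = ((x - kn[j]) ** 3 / h - h * (x - kn[j])) / 6.0
        rows = np.zeros((x.size, kn.size))
        idx = np.arange(x.size)
        rows[idx, j] += am
        rows[idx, j + 1] += ap
        rows += cm[:, None] * self._Fplus[j] + cp[:, None] * self._Fplus[j + 1]
        return rows

    def _deriv_at(self, x0):
        kn = self.knots
        j = min(max(int(np.searchsorted(kn, x0, side="right") - 1), 0), kn.size - 2)
        if x0 >= kn[-1]:
            j = kn.size - 2
        h = kn[j + 1] - kn[j]
        row = np.zeros(kn.size)
        row[j] += -1.0 / h
        row[j + 1] += 1.0 / h
        dcm = (-3.0 * (kn[j + 1] - x0) ** 2 / h + h) / 6.0
        dcp = (3.0 * (x0 - kn[j]) ** 2 / h - h) / 6.0
        row += dcm * self._Fplus[j] + dcp * self._Fplus[j + 1]
        return row

    @classmethod
    def from_quantile_knots(cls, x, k: int = SPLINE_K, shrinkage: bool = True):
        x = np.asarray(x, dtype=float)
        ux = np.unique(x)
        if ux.size < k:
            raise ValueError(f"need >= {k} distinct values for {k} knots, "
                             f"got {ux.size}")
        knots = np.quantile(x, np.linspace(0.0, 1.0, k))
        knots = np.unique(knots)
        if knots.size < k:  # heavy ties: fall back to evenly spaced uniques
            knots = ux[np.linspace(0, ux.size - 1, k).round().astype(int)]
        return cls(knots, shrinkage=shrinkage)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate GAMM: response/dataset labels, the MFAS
    parametrization shared by both sonar types, the optional fixed terms,
    the random structure and the observation-weight column."""

    response: str
    dataset: str = "Complete"
    mfas: str = "none"                      # none | distance | presence
    terms: tuple = ()                       # optional fixed-term columns
    time_block_h: float | None = None       # nested whale/time-block RE
    weight_col: str | None = None
    spline_k: int = SPLINE_K

    def __post_init__(self):
        if self.mfas not in ("none", "distance", "presence"):
            raise ValueError("mfas must be none|distance|presence")

    def label(self) -> str:
        parts = [f"mfas={self.mfas}"] + list(self.terms)
        if self.time_block_h:
            parts.append(f"block={self.time_block_h}h")
        return "+".join(parts)


def candidate_terms(response: str, dataset: str) -> tuple:
    """Optional fixed-effect candidates per response. The within-dive
    partner covariate (depth for durations, duration for depth), diel
    class, sub-area (Complete only), surface-sequence position and the
    preceding deep-dive duration; per-type OL everywhere except surface
    intervals (whose OL values are nearly all 1)."""
    base = {
        "deep_duration": ["max_depth_m", "diel", "ol_high", "ol_mid"],
        "shallow_duration": ["max_depth_m", "diel", "ol_high", "ol_mid"],
        "shallow_depth": ["duration_min", "diel", "ol_high", "ol_mid"],
        "surface_interval": ["diel", "surface_seq"],
        "iddi": ["preceding_deep_duration_min", "diel", "ol_high", "ol_mid"],
    }[response]
    if dataset == "Complete":
        base = base + ["subarea"]
    return tuple(base)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _dummies(series: pd.Series, name: str) -> pd.DataFrame:
    order = _CATEGORICAL_ORDERS.get(name)
    cats = [c for c in (order or sorted(series.dropna().unique()))
            if c in set(series.dropna().unique())]
    cols = {}
    for c in cats[1:]:
        cols[f"{name}[{c}]"] = (series == c).astype(float).to_numpy()
    return pd.DataFrame(cols, index=series.index)


class ExposureGAMM:
    """Gaussian exposure-response GAMM for one model table.

    Parameters
    ----------
    data : model table (one row per behaviour) with columns 'y',
        'whale_id', 'time', the ModelSpec's term columns, and for MFAS terms
        'present_high'/'present_mid', 'dist_high_km'/'dist_mid_km'.
    spec : ModelSpec
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self._build()

    # -- design construction ------------------------------------------------
    def _build(self):
        d = self.data
        spec = self.spec
        n = len(d)
        if n == 0:
            raise ValueError("empty model table")
        self.y = d["y"].to_numpy(dtype=float)
        if spec.weight_col:
            w = d[spec.weight_col].to_numpy(dtype=float)
            if np.any(~np.isfinite(w)) or np.any(w <= 0):
                raise ValueError("weights must be positive and finite")
        else:
            w = np.ones(n)
        self.w = w

        X_cols = {"Intercept": np.ones(n)}
        for t in spec.terms:
            s = d[t]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                for cname, col in _dummies(s, t).items():
                    X_cols[cname] = col
            else:
                X_cols[t] = s.to_numpy(dtype=float)
        if spec.mfas == "presence":
            for cname, col in _dummies(d["presence_cat"], "presence_cat").items():
                X_cols[cname] = col
        self.X = np.column_stack(list(X_cols.values()))
        self.X_names = list(X_cols.keys())

        # penalized / random blocks
        self.blocks = []  # (name, matrix, penalty or None(identity), logdet, rank)
        self.smooths = {}
        if spec.mfas == "distance":
            for typ in ("high", "mid"):
                gate = d[f"present_{typ}"].to_numpy(dtype=bool)
                x = d[f"dist_{typ}_km"].to_numpy(dtype=float)
                if gate.sum() == 0:
                    continue  # no exposures of this type: term drops out
                basis = CrSplineBasis.from_quantile_knots(
                    x[gate], k=spec.spline_k)
                Bm = np.zeros((n, basis.knots.size))
                Bm[gate] = basis.design(x[gate])
                self.blocks.append((f"s(dist_{typ})", Bm, basis.penalty,
                                    basis.penalty_logdet, basis.knots.size))
                self.smooths[f"s(dist_{typ})"] = basis

        self.group_codes = {}
        whale, codes = np.unique(d["whale_id"].to_numpy(), return_inverse=True)
        Zw = np.zeros((n, whale.size))
        Zw[np.arange(n), codes] = 1.0
        self.blocks.append(("whale", Zw, None, 0.0, whale.size))
        self.group_codes["whale"] = codes
        if spec.time_block_h:
            t = pd.to_datetime(d["time"], utc=True).astype("int64").to_numpy()
            block = t // int(spec.time_block_h * 3.6e12)
            keys = d["whale_id"].astype(str).to_numpy().astype(object)
            keys = np.char.add(keys.astype(str), block.astype(str))
            levels, codes_b = np.unique(keys, return_inverse=True)
            Zb = np.zeros((n, levels.size))
            Zb[np.arange(n), codes_b] = 1.0
            self.blocks.append(("whale/block", Zb, None, 0.0, levels.size))
            self.group_codes["whale/block"] = codes_b

        self.B = np.hstack([b[1] for b in self.blocks]) if self.blocks else \
            np.zeros((n, 0))
        C = np.hstack([self.X, self.B])
        sw = np.sqrt(w)
        Cw = C * sw[:, None]
        yw = self.y * sw
        self.CtWC = Cw.T @ Cw
        self.CtWy = Cw.T @ yw
        self.ytWy = float(yw @ yw)
        self.sum_log_w = float(np.sum(np.log(w)))
        self.n = n
        self.p_fixed = self.X.shape[1]
        self._C = C

    # -- likelihood ---------------------------------------------------------
    def _penalty(self, theta):
        pu = self.B.shape[1]
        P = np.zeros((pu, pu))
        logdet_lambda = 0.0
        off = 0
        for (name, M, S, slogdet, q), th in zip(self.blocks, theta):
            lam = np.exp(th)
            if S is None:
                P[off:off + q, off:off + q] = lam * np.eye(q)
                logdet_lambda += q * th
            else:
                P[off:off + q, off:off + q] = lam * S
                logdet_lambda += q * th + slogdet
            off += q
        return P, logdet_lambda

    def _neg2loglik(self, theta, want=None):
        n, pX = self.n, self.p_fixed
        P, logdet_lambda = self._penalty(theta)
        A = self.CtWC.copy()
        A[pX:, pX:] += P
        try:
            cA = cho_factor(A + 1e-10 * np.eye(A.shape[0]))
        except np.linalg.LinAlgError:
            return np.inf if want is None else (np.inf, None)
        delta = cho_solve(cA, self.CtWy)
        Q = max(self.ytWy - float(delta @ self.CtWy), 1e-12)
        Auu = self.CtWC[pX:, pX:] + P
        sign, logdet_Auu = np.linalg.slogdet(Auu)
        if sign <= 0:
            return np.inf if want is None else (np.inf, None)
        sigma2 = Q / n
        n2ll = (n * np.log(2.0 * np.pi * sigma2) + n - self.sum_log_w
                + logdet_Auu - logdet_lambda)
        if want is None:
            return n2ll
        extras = {"delta": delta, "sigma2": sigma2, "A": A, "cA": cA, "Q": Q}
        return n2ll, extras

    def fit(self, maxiter: int = 500) -> "GAMMResults":
        """Maximize the marginal ML over smoothing/variance parameters."""
        n_theta = len(self.blocks)
        if n_theta == 0:
            theta = np.empty(0)
        else:
            x0 = np.zeros(n_theta)

            def obj(th):
                return self._neg2loglik(np.clip(th, -25.0, 25.0))

            res = minimize(obj, x0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-4,
                                    "fatol": 1e-6})
            theta = np.clip(res.x, -25.0, 25.0)
            if not np.isfinite(res.fun):
                raise RuntimeError("GAMM fit failed: non-finite deviance")
        n2ll, ex = self._neg2loglik(theta, want=True)
        if ex is None:
            raise RuntimeError("GAMM fit failed at the optimum")
        return GAMMResults(self, theta, -0.5 * n2ll, ex)


class GAMMResults:
    """Fitted GAMM: coefficients, variance components, AIC, diagnostics."""

    def __init__(self, model: ExposureGAMM, theta, loglik, extras):
        self.model = model
        self.spec = model.spec
        self.theta = np.asarray(theta, dtype=float)
        self.loglik = float(loglik)
        self.sigma2 = float(extras["sigma2"])
        self._delta = extras["delta"]
        self._A = extras["A"]
        self.params = pd.Series(self._delta[:model.p_fixed],
                                index=model.X_names)
        # variance components: sigma2 / lambda for identity blocks
        self.smoothing = {}
        self.re_variance = {}
        for (name, M, S, _, q), th in zip(model.blocks, self.theta):
            lam = float(np.exp(th))
            if S is None:
                self.re_variance[name] = self.sigma2 / lam
            else:
                self.smoothing[name] = lam
        # edf: fixed coefficients + variance/smoothing params + residual var
        self.edf = model.p_fixed + len(self.theta) + 1
        self.aic = -2.0 * self.loglik + 2.0 * self.edf
        # conditional (trace) edf per penalized block, as a diagnostic
        Ainv_CtWC = np.linalg.solve(self._A, model.CtWC)
        tr = np.diag(Ainv_CtWC)
        self.edf_trace = {}
        off = model.p_fixed
        for name, M, S, _, q in model.blocks:
            self.edf_trace[name] = float(np.sum(tr[off:off + q]))
            off += q
        self.fittedvalues = model._C @ self._delta
        self.resid = model.y - self.fittedvalues

    # -- standard errors / covariance ---------------------------------------
    def cov_params(self) -> np.ndarray:
        """Posterior covariance of all coefficients (fixed + penalized)."""
        return self.sigma2 * np.linalg.inv(self._A)

    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params()))[:self.model.p_fixed]
        return pd.Series(se, index=self.model.X_names)

    # -- diagnostics ----------------------------------------------------------
    def resid_lag1_acf(self) -> float:
        """Pooled lag-1 autocorrelation of conditional residuals within
        whales (events in time order)."""
        d = self.model.data
        r = self.resid
        pairs_a, pairs_b = [], []
        for _, idx in d.groupby("whale_id", sort=False).groups.items():
            order = d.loc[idx].sort_values("time").index.to_numpy()
            rr = r[order]
            if rr.size >= 2:
                pairs_a.append(rr[:-1])
                pairs_b.append(rr[1:])
        if not pairs_a:
            return 0.0
        a = np.concatenate(pairs_a)
        b = np.concatenate(pairs_b)
        denom = np.std(a) * np.std(b)
        if denom == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / denom)

    # -- prediction -----------------------------------------------------------
    def design_for(self, newdata: pd.DataFrame) -> np.ndarray:
        m = self.model
        n = len(newdata)
        cols = []
        for name in m.X_names:
            if name == "Intercept":
                cols.append(np.ones(n))
            elif "[" in name:
                var, lev = name[:-1].split("[")
                cols.append((newdata[var] == lev).astype(float).to_numpy())
            else:
                cols.append(newdata[name].to_numpy(dtype=float))
        X = np.column_stack(cols)
        Bs = []
        for name, M, S, _, q in m.blocks:
            if S is None:
                Bs.append(np.zeros((n, q)))  # random effects at 0
            else:
                typ = "high" if "high" in name else "mid"
                gate = newdata[f"present_{typ}"].to_numpy(dtype=bool)
                x = newdata[f"dist_{typ}_km"].to_numpy(dtype=float)
                Bm = np.zeros((n, q))
                if gate.any():
                    Bm[gate] = m.smooths[name].design(x[gate])
                Bs.append(Bm)
        return np.hstack([X] + Bs) if Bs else X

    def predict(self, newdata: pd.DataFrame, se: bool = False):
        C = self.design_for(newdata)
        mean = C @ self._delta
        if not se:
            return mean
        V = self.cov_params()
        se_arr = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, V, C), 0.0))
        return mean, se_arr

    def summary(self) -> str:
        lines = [
            f"Gaussian exposure-response GAMM: {self.spec.response} "
            f"[{self.spec.dataset}]",
            f"  model: {self.spec.label()}",
            f"  n obs: {self.model.n}   log-likelihood (ML): {self.loglik:.3f}",
            f"  AIC: {self.aic:.3f}   edf: {self.edf}",
            f"  residual SD: {np.sqrt(self.sigma2):.4f}   "
            f"lag-1 resid ACF: {self.resid_lag1_acf():.3f}",
            "  fixed effects (estimate, SE):",
        ]
        se = self.bse()
        for name in self.model.X_names:
            lines.append(f"    {name:30s} {self.params[name]:10.4f} "
                         f"{se[name]:10.4f}")
        for name, v in self.re_variance.items():
            lines.append(f"  random intercept {name}: SD {np.sqrt(v):.4f}")
        for name, lam in self.smoothing.items():
            lines.append(f"  smooth {name}: lambda {lam:.4g} "
                         f"(trace edf {self.edf_trace[name]:.2f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Time-block choice and model selection
# ---------------------------------------------------------------------------

def choose_time_block(data: pd.DataFrame, full_spec: ModelSpec,
                      candidates=TIME_BLOCK_CANDIDATES_H):
    """Nested time-block random effect for the full model, if needed.

    Fits the whale-only full model first; when its pooled lag-1 residual
    autocorrelation exceeds 0.10, every candidate block length is fitted
    and the AIC-minimizing one returned. Otherwise no block is added.
    Returns (selected_block_or_None, diagnostics dict).
    """
    base = ExposureGAMM(data, replace(full_spec, time_block_h=None)).fit()
    acf0 = base.resid_lag1_acf()
    diag = {"acf_whale_only": acf0, "aic_by_block": {}}
    if acf0 <= ACF_TRIGGER:
        return None, diag
    best, best_aic = None, np.inf
    for h in candidates:
        res = ExposureGAMM(data, replace(full_spec, time_block_h=h)).fit()
        diag["aic_by_block"][h] = res.aic
        if res.aic < best_aic:
            best, best_aic = h, res.aic
    return best, diag


def aic_weights(aics) -> np.ndarray:
    aics = np.asarray(aics, dtype=float)
    delta = aics - np.nanmin(aics)
    w = np.exp(-delta / 2.0)
    return w / np.nansum(w)


@dataclass
class SelectionResult:
    table: pd.DataFrame            # ranked: label, mfas, terms, aic, delta, weight
    specs: list = field(default_factory=list)
    best: GAMMResults | None = None
    failures: list = field(default_factory=list)

    @property
    def best_spec(self) -> ModelSpec:
        return self.specs[int(self.table.index[0])]


def enumerate_specs(response: str, dataset: str, terms=None,
                    mfas_options=("none", "distance", "presence"),
                    time_block_h=None, weight_col=None) -> list:
    """All admissible candidate models: every subset of the optional terms
    crossed with the MFAS parametrizations. The same effect type applies to
    both sonar types within a model by construction."""
    terms = candidate_terms(response, dataset) if terms is None else tuple(terms)
    specs = []
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            for m in mfas_options:
                specs.append(ModelSpec(
                    response=response, dataset=dataset, mfas=m, terms=sub,
                    time_block_h=time_block_h, weight_col=weight_col))
    if len(specs) > MAX_MODELS:
        raise ValueError(f"candidate set of {len(specs)} exceeds {MAX_MODELS}")
    return specs


def all_subsets_selection(data: pd.DataFrame, response: str, dataset: str,
                          terms=None,
                          mfas_options=("none", "distance", "presence"),
                          time_block_h=None, weight_col=None,
                          keep_fits: bool = False) -> SelectionResult:
    """Fit every candidate model, rank by AIC and compute AIC weights.

    A model whose fit fails is recorded and excluded from the ranking with
    a warning. The ranking is independent of enumeration order (ties broken
    by the model label for determinism)."""
    specs = enumerate_specs(response, dataset, terms, mfas_options,
                            time_block_h, weight_col)
    rows, fits, failures = [], {}, []
    for i, spec in enumerate(specs):
        try:
            res = ExposureGAMM(data, spec).fit()
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            failures.append({"spec": spec, "error": str(exc)})
            warnings.warn(f"model {spec.label()} failed: {exc}")
            continue
        rows.append({"idx": i, "label": spec.label(), "mfas": spec.mfas,
                     "terms": "+".join(spec.terms), "loglik": res.loglik,
                     "edf": res.edf, "aic": res.aic})
        if keep_fits:
            fits[i] = res
    if not rows:
        raise RuntimeError("every candidate model failed")
    tab = pd.DataFrame(rows).set_index("idx")
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab["aic_weight"] = aic_weights(tab["aic"].to_numpy())
    tab = tab.sort_values(["aic", "label"], kind="stable")
    best_idx = int(tab.index[0])
    best = fits.get(best_idx)
    if best is None:
        best = ExposureGAMM(data, specs[best_idx]).fit()
    return SelectionResult(table=tab, specs=specs, best=best, failures=failures)


# ---------------------------------------------------------------------------
# Prediction curves
# ---------------------------------------------------------------------------

@dataclass
class PredictionCurve:
    variable: str
    grid: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    fixed: dict
    in_support: np.ndarray
    rug: np.ndarray


def _baseline_row(results: GAMMResults) -> dict:
    """Fixed covariates for prediction: medians (numeric) / modes
    (categorical) over no-sonar rows; diel fixed at Night; sub-area fixed at
    San Nic when present in the model."""
    d = results.model.data
    base = d[d["presence_cat"] == "none"] if "presence_cat" in d else d
    if base.empty:
        base = d
    row = {}
    for name in results.model.X_names:
        var = name[:-1].split("[")[0] if "[" in name else name
        if var in row or var == "Intercept":
            continue
        s = base[var] if var in base else d[var]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            row[var] = s.mode().iloc[0]
        else:
            row[var] = float(s.median())
    if "diel" in row:
        row["diel"] = "Night"
    if "subarea" in row and "San Nic" in set(d.get("subarea", pd.Series([]))):
        row["subarea"] = "San Nic"
    row["present_high"] = False
    row["present_mid"] = False
    row["dist_high_km"] = ABSENT_PLACEHOLDER_KM
    row["dist_mid_km"] = ABSENT_PLACEHOLDER_KM
    row["presence_cat"] = "none"
    return row


def predict_effect(results: GAMMResults, variable: str,
                   grid=None, n_grid: int = 50) -> PredictionCurve:
    """Prediction curve for one MFAS predictor with everything else fixed.

    ``variable``: 'dist_high', 'dist_mid', 'ol_high', 'ol_mid' or
    'presence_cat'. Distance curves gate the corresponding smooth on and
    fix that type's OL at its median over exposed rows. Random effects are
    set to zero; the CI is +/- 1.96 posterior SE. Grid points outside the
    observed support are emitted but flagged, with the observed values
    returned as rug data.
    """
    d = results.model.data
    base = _baseline_row(results)
    if variable in ("dist_high", "dist_mid"):
        typ = variable.split("_")[1]
        obs = d.loc[d[f"present_{typ}"].astype(bool), f"dist_{typ}_km"].to_numpy()
        if obs.size == 0:
            raise ValueError(f"no exposures of type {typ} in the data")
        if grid is None:
            grid = np.linspace(obs.min(), obs.max(), n_grid)
        grid = np.asarray(grid, dtype=float)
        rows = pd.DataFrame([dict(base) for _ in grid])
        rows[f"present_{typ}"] = True
        rows[f"dist_{typ}_km"] = grid
        rows["presence_cat"] = typ
        olc = f"ol_{typ}"
        if olc in rows.columns or olc in results.model.X_names:
            exposed = d.loc[d[f"present_{typ}"].astype(bool), olc]
            rows[olc] = float(exposed.median()) if len(exposed) else 0.0
            base[olc] = rows[olc].iloc[0]
        rug = obs
    elif variable in ("ol_high", "ol_mid"):
        typ = variable.split("_")[1]
        sel = d[f"present_{typ}"].astype(bool)
        obs = d.loc[sel, variable].to_numpy()
        if grid is None:
            grid = np.linspace(0.0, max(obs.max(), 1e-6) if obs.size else 1.0,
                               n_grid)
        grid = np.asarray(grid, dtype=float)
        rows = pd.DataFrame([dict(base) for _ in grid])
        rows["presence_cat"] = typ
        rows[f"present_{typ}"] = True
        if sel.any():
            rows[f"dist_{typ}_km"] = float(d.loc[sel, f"dist_{typ}_km"].median())
        rows[variable] = grid
        rug = obs
    elif variable == "presence_cat":
        cats = [c for c in _CATEGORICAL_ORDERS["presence_cat"]
                if c in set(d["presence_cat"])]
        grid = np.arange(len(cats), dtype=float)
        rows = pd.DataFrame([dict(base) for _ in cats])
        rows["presence_cat"] = cats
        rows["present_high"] = [c in ("high", "both") for c in cats]
        rows["present_mid"] = [c in ("mid", "both") for c in cats]
        rug = grid
    else:
        raise ValueError(f"unknown effect variable {variable}")

    mean, se = results.predict(rows, se=True)
    lo_s, hi_s = (rug.min(), rug.max()) if np.size(rug) else (np.nan, np.nan)
    in_support = ((grid >= lo_s) & (grid <= hi_s)) if np.size(rug) else \
        np.zeros(len(grid), dtype=bool)
    fixed = dict(base)
    if variable == "presence_cat":
        fixed["levels"] = cats
    return PredictionCurve(variable=variable, grid=grid, mean=mean,
                           ci_lo=mean - 1.96 * se, ci_hi=mean + 1.96 * se,
                           fixed=fixed, in_support=in_support, rug=np.asarray(rug))
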
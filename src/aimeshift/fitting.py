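"""Concentration-response fitting, AIC model selection, hit-calls, BMD.

Each chemical×mode series of zero-centered fold-change responses is fit to
the ten-model suite by bounded maximum likelihood under a robust error
model (Student-t with 4 degrees of freedom, scale e^er estimated per fit).
The winning model minimizes AIC = 2k − 2·loglik (k counts the error scale).
Activity strength is a continuous hit-call in [0, 1], the product of three
probabilities: that some concentration's median response exceeds the
efficacy cutoff, that the winning curve's top exceeds the cutoff, and that
the winner beats the constant (no-response) model on Akaike weight.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares, minimize, minimize_scalar
from scipy.special import gammaln

from .errors import FittingError
from .models import (
    MODEL_NAMES,
    eval_model,
    eval_model_vector,
    model_bounds,
    model_jacobian,
    model_param_names,
    model_starts,
)
from .normalize import BaselineStats

_T4_CONST = float(gammaln(2.5) - gammaln(2.0) - 0.5 * np.log(4.0 * np.pi))
_T4_DF = 4.0
_ER_MIN = math.log(1e-8)


@dataclass(frozen=True)
class ConcResponseSeries:
    """Paired concentrations (µM, > 0) and normalized responses."""

    chemical_id: str
    mode: str
    conc: np.ndarray
    resp: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, float)
        resp = np.asarray(self.resp, float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "resp", resp)
        if conc.shape != resp.shape:
            raise FittingError(
                f"{self.chemical_id}/{self.mode}: conc and resp lengths differ"
            )
        if np.any(conc <= 0):
            raise FittingError(f"{self.chemical_id}/{self.mode}: nonpositive concentration")

    @property
    def n_distinct_conc(self) -> int:
        return int(np.unique(self.conc).size)

    def medians(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-concentration (conc, median resp, replicate count)."""
        levels = np.unique(self.conc)
        meds = np.array([np.median(self.resp[self.conc == c]) for c in levels])
        ns = np.array([np.sum(self.conc == c) for c in levels])
        return levels, meds, ns


@dataclass(frozen=True)
class ModelFit:
    """One model's maximum-likelihood fit to a series."""

    model_name: str
    params: dict[str, float]        # curve parameters plus 'er' (log scale)
    loglik: float
    aic: float
    top: float                      # signed extreme of f over tested range
    rmse: float
    n_params: int                   # free parameters incl. error scale
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        curve = {k: v for k, v in self.params.items() if k != "er"}
        return eval_model(self.model_name, curve, x)


@dataclass(frozen=True)
class CurveResult:
    """Winning fit plus derived activity metrics for one series."""

    chemical_id: str
    mode: str
    winner: ModelFit | None
    fits: tuple[ModelFit, ...]
    hitc: float                     # NaN when the series was unfit
    hit_class: str                  # negative / equivocal / positive / unfit
    max_med: float
    bmd: float                      # µM; NaN = no cutoff crossing in range
    cutoff: float
    conc_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    ``bmr_factor`` scales bmad into the benchmark response (default 1.349,
    the ToxCast-family benchmark); ``activity_threshold`` is the positive
    hit-call band edge.
    """

    seed: int = 0
    n_deterministic_starts: int = 5
    n_random_starts: int = 5
    n_polish: int = 2               # best LS candidates polished by full ML
    bmr_factor: float = 1.349
    activity_threshold: float = 0.9
    xtol: float = 1e-8
    models: tuple[str, ...] = MODEL_NAMES


# ---------------------------------------------------------------------------
# likelihood

def _t4_nll(resid: np.ndarray, er: float) -> float:
    """Negative log-likelihood of residuals under scaled t (df=4)."""
    s2 = math.exp(2.0 * er)
    z2 = resid * resid / s2
    return float(-np.sum(_T4_CONST - 2.5 * np.log1p(z2 / _T4_DF) - er))


def _fit_er(resid: np.ndarray) -> tuple[float, float]:
    """Profile the error scale for fixed residuals -> (er, loglik)."""
    rms = float(np.sqrt(np.mean(resid * resid)))
    hi = math.log(max(10.0 * rms, 1e-6))
    res = minimize_scalar(
        lambda er: _t4_nll(resid, er), bounds=(_ER_MIN, max(hi, _ER_MIN + 1.0)),
        method="bounded", options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun)


def _series_rng(cfg: FitConfig, series: ConcResponseSeries) -> np.random.Generator:
    # keyed by chemical only: identical data fit in either mode gets the
    # same starts, so swapping mode labels is exactly antisymmetric in ΔAUC
    tag = zlib.crc32(series.chemical_id.encode()) % (2**31)
    return np.random.default_rng([cfg.seed % (2**31), tag])


def _fit_one_model(
    name: str, conc: np.ndarray, resp: np.ndarray, rng: np.random.Generator,
    cfg: FitConfig,
) -> ModelFit:
    names = model_param_names(name)
    if not names:  # constant: only the error scale is free
        er, ll = _fit_er(resp)
        return ModelFit("constant", {"er": er}, ll, 2.0 * 1 - 2.0 * ll,
                        top=0.0, rmse=float(np.sqrt(np.mean(resp**2))), n_params=1)

    lo, hi = model_bounds(name, conc, resp)
    starts = model_starts(name, conc, resp, rng,
                          cfg.n_deterministic_starts, cfg.n_random_starts)

    def resid_fn(theta: np.ndarray) -> np.ndarray:
        pred = eval_model_vector(name, theta, conc)
        bad = ~np.isfinite(pred)
        if np.any(bad):
            pred = np.where(bad, 1e6, pred)
        return pred - resp

    def jac_fn(theta: np.ndarray) -> np.ndarray:
        J = model_jacobian(name, theta, conc)
        return np.where(np.isfinite(J), J, 0.0)

    # screen starts cheaply: every form is linear in its amplitude (the
    # first parameter), so the optimal amplitude given the other start
    # values has a closed form; rank starts by that profiled SSE and run
    # the full bounded least-squares pass only from the most promising.
    screened: list[tuple[float, np.ndarray]] = []
    for x0 in starts:
        theta = x0.copy()
        theta[0] = 1.0
        g = eval_model_vector(name, theta, conc)
        gg = float(np.dot(g, g))
        if gg > 0 and np.all(np.isfinite(g)):
            theta[0] = float(np.clip(np.dot(g, resp) / gg, lo[0], hi[0]))
        else:
            theta[0] = x0[0]
        sse = float(np.sum(resid_fn(theta) ** 2))
        screened.append((sse if math.isfinite(sse) else math.inf, theta))
    screened.sort(key=lambda t: t[0])

    candidates: list[tuple[float, np.ndarray]] = []
    for _, x0 in screened[: max(cfg.n_polish + 1, 3)]:
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                sol = least_squares(
                    resid_fn, x0, jac=jac_fn, bounds=(lo, hi), method="trf",
                    xtol=cfg.xtol, ftol=cfg.xtol, gtol=cfg.xtol, max_nfev=200,
                )
        except Exception:
            continue
        candidates.append((float(sol.cost), sol.x))
        if sol.cost < 1e-16:  # exact fit: further starts cannot improve
            break
    if not candidates:
        return ModelFit(name, {}, -math.inf, math.inf, 0.0, math.inf,
                        n_params=len(names) + 1, converged=False)
    candidates.sort(key=lambda t: t[0])

    # joint (curve params + error scale) ML polish of the best LS candidates
    best: tuple[float, np.ndarray, float] | None = None
    er_hi = max(math.log(10.0 * max(np.max(np.abs(resp)), 1e-3)), _ER_MIN + 1.0)

    def nll_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        theta, er = z[:-1], float(z[-1])
        r = resid_fn(theta)
        val = _t4_nll(r, er)
        if not math.isfinite(val):
            return 1e10, np.zeros_like(z)
        s2 = math.exp(2.0 * er)
        w = 5.0 * r / (4.0 * s2 + r * r)       # d/dr of the t4 penalty
        g_theta = jac_fn(theta).T @ w
        z2 = r * r / s2
        g_er = float(np.sum(1.0 - 5.0 * z2 / (4.0 + z2)))
        return val, np.append(g_theta, g_er)

    for _, theta0 in candidates[: cfg.n_polish]:
        r0 = resid_fn(theta0)
        er0 = math.log(max(float(np.sqrt(np.mean(r0 * r0))), 1e-8))
        er0 = min(max(er0, _ER_MIN), er_hi)
        z0 = np.append(theta0, er0)
        try:
            sol = minimize(
                nll_grad, z0, method="L-BFGS-B", jac=True,
                bounds=[(l, h) for l, h in zip(lo, hi)] + [(_ER_MIN, er_hi)],
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 300},
            )
            cand = (float(sol.fun), sol.x[:-1], float(sol.x[-1]))
        except Exception:
            cand = (nll_grad(z0)[0], theta0, er0)
        if best is None or cand[0] < best[0]:
            best = cand
    nll_val, theta, er = best
    ll = -nll_val
    params = dict(zip(names, (float(v) for v in theta)))
    params["er"] = er
    k = len(names) + 1
    resid = resid_fn(theta)
    top = _top_of_curve(name, params, float(np.min(conc)), float(np.max(conc)))
    return ModelFit(name, params, ll, 2.0 * k - 2.0 * ll, top=top,
                    rmse=float(np.sqrt(np.mean(resid * resid))), n_params=k)


def _top_of_curve(name: str, params: dict[str, float], cmin: float, cmax: float,
                  n_grid: int = 200) -> float:
    """Signed extreme of the fitted curve over the tested range."""
    grid = np.logspace(np.log10(cmin), np.log10(cmax), n_grid)
    curve = {k: v for k, v in params.items() if k != "er"}
    y = eval_model(name, curve, grid)
    return float(y[np.argmax(np.abs(y))])


def fit_all_models(series: ConcResponseSeries, cfg: FitConfig | None = None) -> list[ModelFit]:
    """Fit every model in the suite to one series (multi-start bounded ML)."""
    cfg = cfg or FitConfig()
    if series.n_distinct_conc < 4:
        raise FittingError(
            f"{series.chemical_id}/{series.mode}: needs >= 4 distinct "
            f"concentrations, has {series.n_distinct_conc}"
        )
    rng = _series_rng(cfg, series)
    fits = [_fit_one_model(m, series.conc, series.resp, rng, cfg) for m in cfg.models]
    if not any(f.converged for f in fits):
        raise FittingError(f"{series.chemical_id}/{series.mode}: no model converged")
    return fits


def select_winner(fits: list[ModelFit]) -> ModelFit:
    """Minimum-AIC fit; ties go to fewer parameters, then suite order."""
    converged = [f for f in fits if f.converged and math.isfinite(f.aic)]
    if not converged:
        raise FittingError("no converged fits to select from")
    order = {m: i for i, m in enumerate(MODEL_NAMES)}

    def key(f: ModelFit):
        return (round(f.aic, 9), f.n_params, order.get(f.model_name, 99))

    return min(converged, key=key)


def _t4_cdf(x: float) -> float:
    from scipy.stats import t as t_dist

    return float(t_dist.cdf(x, _T4_DF))


def continuous_hitcall(
    fits: list[ModelFit],
    winner: ModelFit,
    series: ConcResponseSeries,
    cutoff: float,
) -> float:
    """Continuous hit-call: product of three probabilities.

    P1 — at least one concentration's median response exceeds the cutoff,
    under the winner's fitted t(4) error model (median standard error
    σ/√n_i); P2 — the winner's |top| exceeds the cutoff; P3 — the winner
    outperforms the constant model, from the pairwise Akaike weight.
    A constant winner is a hit-call of exactly 0.
    """
    if winner.model_name == "constant" or not winner.converged:
        return 0.0
    sigma = math.exp(winner.params.get("er", _ER_MIN))
    _, meds, ns = series.medians()
    with np.errstate(divide="ignore"):
        p_below = [
            _t4_cdf((cutoff - abs(m)) / (sigma / math.sqrt(n)) if sigma > 0
                    else math.copysign(math.inf, cutoff - abs(m)))
            for m, n in zip(meds, ns)
        ]
    p1 = 1.0 - float(np.prod(p_below))
    p2 = 1.0 - _t4_cdf((cutoff - abs(winner.top)) / sigma if sigma > 0
                       else math.copysign(math.inf, cutoff - abs(winner.top)))
    const = next((f for f in fits if f.model_name == "constant"), None)
    if const is None or not math.isfinite(const.aic):
        p3 = 1.0
    else:
        d = (winner.aic - const.aic) / 2.0
        p3 = 1.0 / (1.0 + math.exp(min(d, 700.0)))
    return float(p1 * p2 * p3)


def classify_hitcall(hitc: float, threshold: float = 0.9) -> str:
    """Map a hit-call to its band: 0 negative, [threshold, 1] positive,
    anything strictly between equivocal."""
    if math.isnan(hitc):
        return "unfit"
    if hitc == 0.0:
        return "negative"
    if hitc >= threshold:
        return "positive"
    return "equivocal"


def benchmark_dose(
    winner: ModelFit,
    bmr: float,
    conc_range: tuple[float, float],
    n_grid: int = 1000,
) -> float:
    """Smallest concentration where |fitted response| reaches ``bmr``.

    Scans a log-spaced grid over the tested range for the first bracketing
    interval and refines it by root finding. Returns NaN when the curve
    never reaches the benchmark response within the range ("> top tested
    concentration" in reports).
    """
    if bmr <= 0:
        raise FittingError("benchmark response must be positive")
    if winner is None or winner.model_name == "constant":
        return math.nan
    lo, hi = conc_range
    if not lo < hi:
        raise FittingError(f"bad concentration range {conc_range}")
    u = np.linspace(np.log10(lo), np.log10(hi), n_grid)

    def g(ulog: float) -> float:
        return float(np.abs(winner.predict(10.0 ** np.asarray(ulog)))) - bmr

    y = np.abs(winner.predict(10.0 ** u)) - bmr
    if y[0] >= 0.0:
        return float(lo)
    idx = np.nonzero(y >= 0.0)[0]
    if idx.size == 0:
        return math.nan
    i = int(idx[0])
    root = brentq(g, u[i - 1], u[i], xtol=1e-12, rtol=1e-14)
    return float(10.0 ** root)


def max_median_response(series: ConcResponseSeries) -> float:
    """Efficacy: the per-concentration median of maximal absolute value,
    sign retained."""
    _, meds, _ = series.medians()
    if meds.size == 0:
        return 0.0
    return float(meds[np.argmax(np.abs(meds))])


def fit_series(
    series: ConcResponseSeries,
    baseline: BaselineStats,
    cfg: FitConfig | None = None,
) -> CurveResult:
    """Full per-series analysis: fit suite, select winner, derive metrics.

    Series with fewer than four distinct concentrations are reported
    unfit (hit-call NaN) rather than fitted.
    """
    cfg = cfg or FitConfig()
    crange = (float(np.min(series.conc)), float(np.max(series.conc)))
    mm = max_median_response(series)
    if series.n_distinct_conc < 4:
        return CurveResult(series.chemical_id, series.mode, None, (), math.nan,
                           "unfit", mm, math.nan, baseline.cutoff, crange,
                           int(series.conc.size))
    fits = fit_all_models(series, cfg)
    winner = select_winner(fits)
    hitc = continuous_hitcall(fits, winner, series, baseline.cutoff)
    bmr = cfg.bmr_factor * baseline.bmad
    bmd = benchmark_dose(winner, bmr, crange) if bmr > 0 else math.nan
    return CurveResult(
        series.chemical_id, series.mode, winner, tuple(fits), hitc,
        classify_hitcall(hitc, cfg.activity_threshold), mm, bmd,
        baseline.cutoff, crange, int(series.conc.size),
    )
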
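"""Model fitting, AIC selection, hit-calls, BMD and efficacy metrics."""

import math

import numpy as np
import pytest

from aimeshift.errors import FittingError
from aimeshift.fitting import (
    ConcResponseSeries,
    FitConfig,
    ModelFit,
    benchmark_dose,
    classify_hitcall,
    continuous_hitcall,
    fit_all_models,
    fit_series,
    max_median_response,
    select_winner,
)
from aimeshift.models import eval_model
from aimeshift.normalize import BaselineStats

from conftest import make_series


def _fit(name, params, er=-2.0, aic=0.0, top=None, n_params=None):
    k = n_params if n_params is not None else len(params) + 1
    p = dict(params)
    p["er"] = er
    return ModelFit(name, p, loglik=0.0, aic=aic, top=top if top is not None else 0.0,
                    rmse=0.1, n_params=k)


class TestFitRecovery:
    def test_hill_recovered_from_noiseless_data(self, conc_design, hill_params):
        s = make_series("hill", hill_params, conc_design)
        winner = select_winner(fit_all_models(s))
        assert winner.model_name == "hill"
        for key, val in hill_params.items():
            assert winner.params[key] == pytest.approx(val, rel=1e-3)

    def test_constant_wins_on_zero_series(self, conc_design):
        s = ConcResponseSeries("null", "MetNeg", conc_design,
                               np.zeros_like(conc_design))
        winner = select_winner(fit_all_models(s))
        assert winner.model_name == "constant"

    def test_exp4_beats_coarse_grid_search(self, conc_design):
        # the optimizer must at least match a brute-force scan of the
        # exp4 parameter box under the same likelihood
        s = make_series("exp4", {"tp": 1.8, "ga": 25.0}, conc_design,
                        noise_sd=0.1, seed=3)
        fits = fit_all_models(s)
        exp4 = next(f for f in fits if f.model_name == "exp4")
        from aimeshift.fitting import _fit_er

        best_grid = math.inf
        for tp in np.linspace(-4, 4, 17):
            for ga in np.logspace(-3, 4, 15):
                resid = eval_model("exp4", {"tp": tp, "ga": ga}, s.conc) - s.resp
                _, ll = _fit_er(resid)
                aic = 2 * 3 - 2 * ll
                best_grid = min(best_grid, aic)
        assert exp4.aic <= best_grid + 1e-6

    def test_too_few_concentrations_raises(self):
        s = ConcResponseSeries("x", "MetNeg", np.array([1.0, 2.0, 4.0] * 3),
                               np.zeros(9))
        with pytest.raises(FittingError):
            fit_all_models(s)

    def test_gain_loss_loglik_dominates_nested_hill(self, conc_design, hill_params):
        # hill is gain_loss with the loss phase switched off: the richer
        # model's optimized log-likelihood cannot be (much) worse
        s = make_series("hill", hill_params, conc_design, noise_sd=0.1, seed=9)
        fits = {f.model_name: f for f in fit_all_models(s)}
        assert fits["gain_loss"].loglik >= fits["hill"].loglik - 0.05


class TestSelectWinner:
    def test_argmin(self):
        fits = [_fit("hill", {"tp": 1, "ga": 1, "p": 1}, aic=10.0),
                _fit("exp4", {"tp": 1, "ga": 1}, aic=12.0),
                _fit("linear", {"a": 1}, aic=9.0)]
        assert select_winner(fits).model_name == "linear"

    def test_tie_prefers_fewer_parameters(self):
        fits = [_fit("hill", {"tp": 1, "ga": 1, "p": 1}, aic=10.0),
                _fit("linear", {"a": 1}, aic=10.0)]
        assert select_winner(fits).model_name == "linear"

    def test_matches_exhaustive_argmin(self):
        rng = np.random.default_rng(0)
        names = ["linear", "power", "hill", "exp4", "exp5"]
        for _ in range(50):
            aics = rng.uniform(-50, 50, len(names))
            fits = [_fit(n, dict.fromkeys(
                        {"linear": ["a"], "power": ["a", "p"],
                         "hill": ["tp", "ga", "p"], "exp4": ["tp", "ga"],
                         "exp5": ["tp", "ga", "p"]}[n], 1.0), aic=a)
                    for n, a in zip(names, aics)]
            assert select_winner(fits).aic == min(aics)


class TestHitcall:
    def test_constant_winner_forces_zero(self, conc_design):
        s = ConcResponseSeries("x", "MetNeg", conc_design, np.zeros_like(conc_design))
        fits = fit_all_models(s)
        winner = select_winner(fits)
        assert continuous_hitcall(fits, winner, s, cutoff=0.1) == 0.0

    def test_strong_signal_saturates(self, conc_design, hill_params):
        s = make_series("hill", hill_params, conc_design, noise_sd=0.05, seed=1)
        fits = fit_all_models(s)
        winner = select_winner(fits)
        hitc = continuous_hitcall(fits, winner, s, cutoff=0.2)
        assert hitc > 0.99

    def test_monotone_nonincreasing_in_cutoff(self, conc_design, hill_params):
        s = make_series("hill", hill_params, conc_design, noise_sd=0.1, seed=2)
        fits = fit_all_models(s)
        winner = select_winner(fits)
        cuts = np.linspace(0.0, 3.0, 13)
        hits = [continuous_hitcall(fits, winner, s, c) for c in cuts]
        assert all(a >= b - 1e-12 for a, b in zip(hits, hits[1:]))

    def test_bands_partition_unit_interval(self):
        assert classify_hitcall(0.0) == "negative"
        assert classify_hitcall(math.nan) == "unfit"
        grid = np.linspace(1e-9, 1.0, 101)
        labels = {classify_hitcall(h) for h in grid}
        assert labels == {"equivocal", "positive"}
        # boundary: exactly 0.9 is positive, just below is equivocal
        assert classify_hitcall(0.9) == "positive"
        assert classify_hitcall(0.9 - 1e-9) == "equivocal"


class TestBenchmarkDose:
    def test_hill_half_max_crossing_is_ga(self):
        w = _fit("hill", {"tp": 2.0, "ga": 10.0, "p": 1.0})
        bmd = benchmark_dose(w, bmr=1.0, conc_range=(0.01, 200.0))
        assert bmd == pytest.approx(10.0, rel=1e-6)

    def test_flat_curve_below_bmr_is_nan(self):
        w = _fit("linear", {"a": 1e-6})
        assert math.isnan(benchmark_dose(w, bmr=1.0, conc_range=(0.01, 200.0)))

    def test_matches_dense_grid_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tp = rng.uniform(0.5, 3.0) * rng.choice([-1.0, 1.0])
            ga = 10.0 ** rng.uniform(-1.0, 2.0)
            p = rng.uniform(0.5, 3.0)
            w = _fit("hill", {"tp": tp, "ga": ga, "p": p})
            bmr = abs(tp) * rng.uniform(0.1, 0.9)
            bmd = benchmark_dose(w, bmr, (0.01, 200.0))
            u = np.linspace(np.log10(0.01), np.log10(200.0), 200_001)
            y = np.abs(w.predict(10.0 ** u))
            idx = np.nonzero(y >= bmr)[0]
            if idx.size == 0:
                assert math.isnan(bmd)
            else:
                expect = 10.0 ** u[idx[0]]
                assert bmd == pytest.approx(expect, rel=1e-3)


class TestMaxMed:
    def test_single_replicate_pointwise(self):
        s = ConcResponseSeries("x", "MetNeg", np.array([1.0, 3.0, 10.0, 30.0]),
                               np.array([0.1, 0.5, -0.8, 0.2]))
        assert max_median_response(s) == -0.8

    def test_sign_retained_on_medians(self):
        conc = np.repeat([1.0, 3.0, 10.0], 3)
        resp = np.concatenate([[0.1, 0.1, 0.1], [0.5, 0.5, 0.5], [-0.8, -0.8, -0.8]])
        s = ConcResponseSeries("x", "MetNeg", conc, resp)
        assert max_median_response(s) == -0.8

    def test_all_zero(self):
        s = ConcResponseSeries("x", "MetNeg", np.array([1.0, 2.0, 4.0, 8.0]),
                               np.zeros(4))
        assert max_median_response(s) == 0.0


class TestFitSeries:
    def test_unfit_below_four_concentrations(self):
        s = ConcResponseSeries("x", "MetNeg", np.array([1.0, 2.0, 4.0]),
                               np.array([0.0, 0.1, 0.2]))
        res = fit_series(s, BaselineStats(0.05, 0.15, 10))
        assert res.hit_class == "unfit"
        assert math.isnan(res.hitc)

    def test_full_result_on_strong_hill(self, conc_design, hill_params):
        s = make_series("hill", hill_params, conc_design, noise_sd=0.08, seed=4)
        res = fit_series(s, BaselineStats(0.08, 0.24, 10), FitConfig(seed=1))
        assert res.hit_class == "positive"
        assert res.max_med == pytest.approx(2.0, abs=0.3)
        assert 0.1 < res.bmd < 10.0  # curve reaches bmr well before ga

    def test_deterministic_given_seed(self, conc_design, hill_params):
        s = make_series("hill", hill_params, conc_design, noise_sd=0.1, seed=6)
        r1 = fit_series(s, BaselineStats(0.07, 0.21, 10), FitConfig(seed=3))
        r2 = fit_series(s, BaselineStats(0.07, 0.21, 10), FitConfig(seed=3))
        assert r1.hitc == r2.hitc
        assert r1.winner.params == r2.winner.params
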
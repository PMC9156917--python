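import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clinemap as cm
from clinemap.cline import _Cell, _ParamSpace


class TestClineValue:
    def test_sigmoid_midpoint(self):
        assert cm.cline_value(1000.0, cm.ClineParams(c=1000.0, w=300.0)) == 0.5

    def test_quarter_width_offset(self):
        p = cm.cline_value(1075.0, cm.ClineParams(c=1000.0, w=300.0))
        assert math.isclose(p, 1.0 / (1.0 + math.exp(-1.0)), rel_tol=1e-12)

    def test_scaling_maps_onto_band(self):
        params = cm.ClineParams(c=0.0, w=100.0, pmin=0.2, pmax=0.8)
        spec = cm.ClineModelSpec(scaling="free")
        assert math.isclose(cm.cline_value(0.0, params, spec), 0.5, rel_tol=1e-12)
        assert cm.cline_value(-1e6, params, spec) >= 0.2 - 1e-12
        assert cm.cline_value(1e6, params, spec) <= 0.8 + 1e-12

    def test_tail_junction_value_and_derivative_continuous(self):
        """With tau = 1 the exponential tails continue the sigmoid smoothly:
        value and first derivative match at both junctions (finite differences)."""
        params = cm.ClineParams(c=1000.0, w=300.0, deltaL=200.0, deltaR=200.0,
                                tauL=1.0, tauR=1.0)
        spec = cm.ClineModelSpec(tails="both")
        h = 1e-4
        for x0 in (params.c - params.deltaL, params.c + params.deltaR):
            below = cm.cline_value(x0 - h, params, spec)
            above = cm.cline_value(x0 + h, params, spec)
            assert math.isclose(below, above, abs_tol=1e-6)
            d_below = (cm.cline_value(x0 - h, params, spec)
                       - cm.cline_value(x0 - 3 * h, params, spec)) / (2 * h)
            d_above = (cm.cline_value(x0 + 3 * h, params, spec)
                       - cm.cline_value(x0 + h, params, spec)) / (2 * h)
            assert math.isclose(d_below, d_above, rel_tol=1e-3)

    def test_tail_junction_value_continuous_any_tau(self):
        params = cm.ClineParams(c=500.0, w=200.0, deltaL=150.0, deltaR=80.0,
                                tauL=0.3, tauR=0.7)
        spec = cm.ClineModelSpec(tails="both")
        for x0 in (params.c - params.deltaL, params.c + params.deltaR):
            assert math.isclose(
                cm.cline_value(x0 - 1e-9, params, spec),
                cm.cline_value(x0 + 1e-9, params, spec),
                abs_tol=1e-8,
            )

    @given(
        c=st.floats(-1000, 4000), w=st.floats(10, 5000),
        dL=st.floats(0, 2000), dR=st.floats(0, 2000),
        tL=st.floats(0, 1), tR=st.floats(0, 1),
        pmin=st.floats(0, 0.45), pmax=st.floats(0.55, 1),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_nondecreasing(self, c, w, dL, dR, tL, tR, pmin, pmax):
        params = cm.ClineParams(c=c, w=w, pmin=pmin, pmax=pmax,
                                deltaL=dL, deltaR=dR, tauL=tL, tauR=tR)
        spec = cm.ClineModelSpec(scaling="free", tails="both")
        x = np.linspace(c - 3 * (w + dL) - 10, c + 3 * (w + dR) + 10, 400)
        p = cm.cline_value(x, params, spec)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            cm.cline_value(0.0, cm.ClineParams(c=0, w=-5))
        with pytest.raises(ValueError):
            cm.cline_value(0.0, cm.ClineParams(c=0, w=5, pmin=0.9, pmax=0.3))


class TestLogLikelihood:
    def test_single_cell_arithmetic(self):
        cells = [_Cell(0.0, 0.5, 10)]
        ll = cm.log_likelihood(cm.ClineParams(c=0.0, w=100.0), cm.ClineModelSpec(), cells)
        assert math.isclose(ll, 20.0 * math.log(0.5), rel_tol=1e-12)

    def test_perfect_fit_attains_entropy_bound(self):
        params = cm.ClineParams(c=500.0, w=300.0)
        x = np.linspace(0, 1000, 7)
        cells = [_Cell(xi, cm.cline_value(xi, params), 50) for xi in x]
        ll_true = cm.log_likelihood(params, cm.ClineModelSpec(), cells)
        for dc in (-150.0, 80.0):
            shifted = cm.ClineParams(c=500.0 + dc, w=300.0)
            assert cm.log_likelihood(shifted, cm.ClineModelSpec(), cells) < ll_true

    def test_duplicated_cell_doubles_contribution(self):
        params = cm.ClineParams(c=100.0, w=50.0)
        one = [_Cell(120.0, 0.7, 30)]
        ll1 = cm.log_likelihood(params, cm.ClineModelSpec(), one)
        ll2 = cm.log_likelihood(params, cm.ClineModelSpec(), one * 2)
        assert math.isclose(ll2, 2 * ll1, rel_tol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        params = cm.ClineParams(c=700.0, w=400.0, pmin=0.1, pmax=0.9,
                                deltaL=100.0, deltaR=50.0, tauL=0.4, tauR=0.9)
        spec = cm.ClineModelSpec(scaling="free", tails="both")
        cells = [_Cell(float(x), float(q), int(n)) for x, q, n in zip(
            rng.uniform(0, 2000, 40), rng.uniform(0, 1, 40), rng.integers(1, 200, 40))]
        expected = 0.0
        for cell in cells:  # independent per-cell scalar accumulation
            p = min(max(cm.cline_value(cell.along_km, params, spec), 1e-6), 1 - 1e-6)
            expected += 2 * cell.n_scored * (
                cell.q_hat * math.log(p) + (1 - cell.q_hat) * math.log(1 - p)
            )
        assert math.isclose(cm.log_likelihood(params, spec, cells), expected, abs_tol=1e-9)

    def test_allele_count_convention_switch(self):
        cells = [_Cell(0.0, 0.5, 10)]
        ll_n = cm.log_likelihood(cm.ClineParams(c=0.0, w=100.0), cm.ClineModelSpec(),
                                 cells, allele_counts="n")
        assert math.isclose(ll_n, 10.0 * math.log(0.5), rel_tol=1e-12)


class TestAicc:
    @pytest.mark.parametrize(
        "logL,k,n,expected",
        [(-100.0, 2, 20, 204.7058823529412), (-100.0, 6, 20, 218.46153846153845)],
    )
    def test_arithmetic(self, logL, k, n, expected):
        assert math.isclose(cm.aicc(logL, k, n), expected, rel_tol=1e-12)

    def test_unit_logL_gain_drops_aicc_by_two(self):
        assert math.isclose(cm.aicc(-99.0, 2, 20), cm.aicc(-100.0, 2, 20) - 2.0)

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            cm.aicc(-10.0, 6, 7)


class TestFitML:
    def test_noiseless_recovery(self):
        truth = cm.ClineParams(c=1500.0, w=400.0)
        x = np.arange(0, 3100, 100.0)
        cells = [_Cell(xi, cm.cline_value(xi, truth), 1000) for xi in x]
        params, logL, inc = cm.fit_ml(cm.ClineModelSpec(), cells)
        assert inc
        assert abs(params.c - 1500.0) < 1.0
        assert abs(params.w - 400.0) < 5.0

    def test_decreasing_data_fitted_on_complement(self, cline_cells):
        cells, _ = cline_cells(seed=4, decreasing=True)
        params, _, inc = cm.fit_ml(cm.ClineModelSpec(), cells)
        assert not inc
        assert abs(params.c - 1500.0) < 100.0

    def test_flat_data_flagged_degenerate(self):
        cells = [_Cell(xi, 0.5, 100) for xi in np.linspace(0, 3000, 20)]
        with pytest.warns(RuntimeWarning, match="width"):
            cm.fit_ml(cm.ClineModelSpec(), cells)

    def test_too_few_cells_raises(self):
        cells = [_Cell(0.0, 0.1, 10), _Cell(100.0, 0.9, 10)]
        with pytest.raises(ValueError, match="cells"):
            cm.fit_ml(cm.ClineModelSpec(), cells)

    def test_translation_equivariance(self, cline_cells):
        cells, _ = cline_cells(seed=9)
        p0, _, _ = cm.fit_ml(cm.ClineModelSpec(), cells)
        shifted = [_Cell(c.along_km + 500.0, c.q_hat, c.n_scored) for c in cells]
        p1, _, _ = cm.fit_ml(cm.ClineModelSpec(), shifted)
        assert abs((p1.c - p0.c) - 500.0) < 5.0
        assert abs(p1.w - p0.w) < 5.0


class TestCompareModels:
    def test_six_models_ranked(self, cline_cells):
        cells, _ = cline_cells(seed=1)
        table = cm.compare_models(cells)
        assert len(table) == 6
        assert table["aicc"].is_monotonic_increasing
        assert table.iloc[0]["best"] and not table["best"][1:].any()

    def test_forced_model_bypasses_selection(self, cline_cells):
        cells, _ = cline_cells(seed=2)
        f = cm.fitter_from_cells(cells, scaling="fixed", tails="both", run_mcmc=False)
        assert f.get_params()["scaling"] == "fixed"
        assert f.params_.pmin == min(c.q_hat for c in cells)
        assert f.params_.pmax == max(c.q_hat for c in cells)


class TestMCMC:
    def test_seed_determinism(self, cline_cells):
        cells, _ = cline_cells(seed=6)
        kw = dict(chains=2, burn_in=200, generations=1000, seed=42)
        a = cm.mcmc_sample(cm.ClineModelSpec(), cells, **kw)
        b = cm.mcmc_sample(cm.ClineModelSpec(), cells, **kw)
        assert a["draws"].equals(b["draws"])
        assert np.array_equal(a["acceptance"], b["acceptance"])

    def test_posterior_concentrates_near_truth(self, cline_cells):
        cells, truth = cline_cells(seed=8)
        res = cm.mcmc_sample(cm.ClineModelSpec(), cells, chains=3,
                             burn_in=2000, generations=10_000, seed=8)
        assert abs(res["draws"]["c"].median() - truth.c) < 50.0
        assert abs(res["draws"]["w"].median() - truth.w) / truth.w < 0.25
        assert all(v < 1.1 for v in res["rhat"].values())

    def test_credible_region_degenerate_posterior(self, cline_cells):
        cells, _ = cline_cells(seed=1)
        import pandas as pd

        post = pd.DataFrame({"c": np.full(2000, 1500.0), "w": np.full(2000, 400.0)})
        space = _ParamSpace(cm.ClineModelSpec(), np.array([0.0, 3000.0]),
                            np.array([0.0, 1.0]))
        centre_ci, width_ci, env = cm.credible_region(
            post, np.linspace(0, 3000, 50), cm.ClineModelSpec(), space)
        assert centre_ci[0] == centre_ci[1] == 1500.0
        assert width_ci[0] == width_ci[1] == 400.0
        assert np.allclose(env["p_lo"], env["p_hi"])
        assert ((env[["p_lo", "p_med", "p_hi"]] >= 0).all().all()
                and (env[["p_lo", "p_med", "p_hi"]] <= 1).all().all())

    def test_credible_region_needs_enough_draws(self):
        import pandas as pd

        post = pd.DataFrame({"c": np.zeros(10), "w": np.ones(10)})
        space = _ParamSpace(cm.ClineModelSpec(), np.array([0.0, 100.0]),
                            np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="1000"):
            cm.credible_region(post, [0, 50], cm.ClineModelSpec(), space)


class TestCentreOffset:
    def _fit(self, cells, seed):
        return cm.fitter_from_cells(cells, burn_in=500, generations=3000, seed=seed)

    def test_identical_posteriors_give_zero_offset(self, cline_cells):
        cells, _ = cline_cells(seed=3)
        f = self._fit(cells, 1)
        off = cm.centre_offset(f, f, rng=0)
        assert off["offset_km"] == 0.0
        assert off["interval_km"][0] <= 0.0 <= off["interval_km"][1]

    def test_offset_between_separated_clines(self, cline_cells):
        a, _ = cline_cells(seed=4, c=1000.0)
        b, _ = cline_cells(seed=5, c=2500.0)
        fa, fb = self._fit(a, 2), self._fit(b, 3)
        off = cm.centre_offset(fa, fb, rng=1)
        assert abs(off["offset_km"] - 1500.0) < 100.0
        assert off["interval_km"][0] <= off["offset_km"] <= off["interval_km"][1]
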
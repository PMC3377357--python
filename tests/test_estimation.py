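"""Log-space cost, simplex fitting, error reporting, identifiability."""

import numpy as np
import pytest

from bcmpbpk.datasets import ChamberDataset, ChamberSeries, generate_dataset
from bcmpbpk.errors import FitError
from bcmpbpk.estimation import (
    cost_log_sse,
    fit_metabolic_params,
    log_cost_hessian,
    metabolic_from_vector,
    rmse_tables,
)
from bcmpbpk.kinetics import MetabolicParamsTwoPathway
from bcmpbpk.model import ClosedChamberConfig, simulate

TRUTH = np.array([3.8, 0.35, 4.7])
C0_SMALL = (200.0, 1000.0, 4000.0)


@pytest.fixture(scope="module")
def small_ds():
    """Noise-free 3-series dataset on a coarse grid (fast fitting)."""
    obs = np.round(np.arange(0.25, 6.001, 0.25), 10)
    return generate_dataset(
        metabolic_from_vector("two_pathway", TRUTH), "two_pathway",
        c0_list=C0_SMALL, obs_times=obs, noise_cv=0.0, seed=0,
    )


@pytest.fixture
def base_cfg():
    return ClosedChamberConfig(hypothesis="two_pathway",
                               metabolic=metabolic_from_vector("two_pathway", TRUTH))


class TestCost:
    def test_zero_at_generating_truth(self, small_ds, base_cfg):
        assert cost_log_sse(TRUTH, small_ds, base_cfg) <= 1e-10

    def test_perturbation_increases_cost(self, small_ds, base_cfg):
        c0 = cost_log_sse(TRUTH, small_ds, base_cfg)
        for i in range(3):
            up = TRUTH.copy()
            up[i] *= 1.05
            assert cost_log_sse(up, small_ds, base_cfg) > c0

    def test_matches_naive_python_loop(self, small_ds, base_cfg):
        # independent oracle: explicit per-observation accumulation
        expected = 0.0
        cfg = base_cfg
        for s in small_ds:
            res = simulate(cfg.replace(c0_ppm=s.c0_ppm_nominal), t_grid=s.t_hr)
            for pred, obs in zip(res.chamber_ppm, s.c_ppm):
                expected += (np.log(pred) - np.log(obs)) ** 2
        # evaluate slightly off truth so the cost is non-trivial
        off = TRUTH * 1.1
        expected_off = 0.0
        cfg_off = cfg.replace(metabolic=metabolic_from_vector("two_pathway", off))
        for s in small_ds:
            res = simulate(cfg_off.replace(c0_ppm=s.c0_ppm_nominal), t_grid=s.t_hr)
            for pred, obs in zip(res.chamber_ppm, s.c_ppm):
                expected_off += (np.log(pred) - np.log(obs)) ** 2
        assert cost_log_sse(TRUTH, small_ds, cfg) == pytest.approx(expected, abs=1e-12)
        assert cost_log_sse(off, small_ds, cfg) == pytest.approx(expected_off, rel=1e-12)

    def test_unit_change_leaves_cost_invariant_for_linear_kinetics(self):
        # in the purely linear regime the model response scales with the dose,
        # so expressing data and dose in different (common) units cannot move
        # the log-space cost
        lin = MetabolicParamsTwoPathway(vmax=1e-12, km=0.35, kgst=4.7)
        obs = np.round(np.arange(0.5, 4.001, 0.5), 10)
        lam = 3.0
        cfg = ClosedChamberConfig(metabolic=lin)
        ds = generate_dataset(lin, "two_pathway", c0_list=(300.0,),
                              obs_times=obs, noise_cv=0.05, seed=1)
        scaled = ChamberDataset(
            series=(
                ChamberSeries(
                    "s1", ds.series[0].c0_ppm_nominal * lam,
                    ds.series[0].t_hr, ds.series[0].c_ppm * lam,
                ),
            )
        )
        params = np.array([1e-12, 0.35, 4.7])
        c_orig = cost_log_sse(params, ds, cfg)
        c_scaled = cost_log_sse(params, scaled, cfg)
        assert c_scaled == pytest.approx(c_orig, rel=1e-6)


class TestFit:
    def test_start_at_truth_stays_at_truth(self, small_ds, base_cfg):
        fit = fit_metabolic_params(small_ds, "two_pathway", TRUTH,
                                   base_config=base_cfg, xatol=1e-6, fatol=1e-9)
        assert fit.cost <= 1e-10
        assert fit.x == pytest.approx(TRUTH, rel=1e-3)
        assert fit.converged

    def test_multi_start_explores_and_returns_best(self, small_ds, base_cfg):
        fit = fit_metabolic_params(
            small_ds, "two_pathway", TRUTH * 1.3, base_config=base_cfg,
            restarts=2, seed=5, maxfev=150, xatol=1e-4, fatol=1e-6,
        )
        assert fit.n_starts == 3
        assert fit.n_evals > 150  # all starts actually ran
        assert fit.cost >= 0

    def test_bad_start_rejected(self, small_ds):
        with pytest.raises(FitError):
            fit_metabolic_params(small_ds, "two_pathway", [1.0, -1.0, 1.0])
        with pytest.raises(FitError):
            fit_metabolic_params(small_ds, "no_such_model", [1.0, 1.0, 1.0])


class TestRmse:
    def test_perfect_fit_has_zero_errors(self, small_ds, base_cfg):
        abs_err, rel_err = rmse_tables(TRUTH, small_ds, base_cfg)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in abs_err.values())
        assert all(v == pytest.approx(0.0, abs=1e-11) for v in rel_err.values())

    def test_printed_convention_two_norm_over_n(self, base_cfg):
        # four residuals of exactly +1 ppm: ||r||_2 / n = 2/4 = 0.5 ppm,
        # relative 0.5/100 = 0.005
        obs = np.array([0.5, 1.0, 1.5, 2.0])
        cfg = base_cfg.replace(c0_ppm=100.0)
        model = simulate(cfg, t_grid=obs).chamber_ppm
        ds = ChamberDataset(
            series=(ChamberSeries("s1", 100.0, obs, model + 1.0),)
        )
        abs_err, rel_err = rmse_tables(TRUTH, ds, base_cfg)
        assert abs_err["s1"] == pytest.approx(0.5, rel=1e-9)
        assert rel_err["s1"] == pytest.approx(0.005, rel=1e-9)


class TestIdentifiability:
    @pytest.mark.parametrize("hypothesis,truth", [
        ("two_pathway", np.array([3.8, 0.35, 4.7])),
        ("two_site", np.array([3.7, 0.3, 0.047])),
    ])
    def test_hessian_positive_definite_at_noise_free_optimum(self, hypothesis, truth):
        obs = np.round(np.arange(0.25, 6.001, 0.25), 10)
        ds = generate_dataset(
            metabolic_from_vector(hypothesis, truth), hypothesis,
            c0_list=C0_SMALL, obs_times=obs, noise_cv=0.0, seed=0,
        )
        cfg = ClosedChamberConfig(
            hypothesis=hypothesis, metabolic=metabolic_from_vector(hypothesis, truth)
        )
        h = log_cost_hessian(truth, ds, cfg)
        eig = np.linalg.eigvalsh(h)
        assert np.all(eig > 0)

    def test_each_hypothesis_describes_the_others_data(self, small_ds):
        # noise-free two-pathway data refit with the two-binding-site law (and
        # the reverse) both land within a fraction of a percent of the data —
        # the designs cannot distinguish the hypotheses
        from bcmpbpk.kinetics import MetabolicParamsTwoSite

        obs = np.round(np.arange(0.25, 6.001, 0.25), 10)
        ds_ts = generate_dataset(
            MetabolicParamsTwoSite(), "two_site",
            c0_list=C0_SMALL, obs_times=obs, noise_cv=0.0, seed=0,
        )
        cross1 = fit_metabolic_params(small_ds, "two_site", [3.8, 0.35, 0.05],
                                      xatol=1e-5, fatol=1e-8)
        cross2 = fit_metabolic_params(ds_ts, "two_pathway", [3.7, 0.3, 5.0],
                                      xatol=1e-5, fatol=1e-8)
        worst1 = max(cross1.per_series_rmse_rel.values())
        worst2 = max(cross2.per_series_rmse_rel.values())
        assert worst1 < 0.05
        assert worst2 < 0.05
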
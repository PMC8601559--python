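"""Occupancy likelihood, fitting, selection, simulation, GoF mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from landgrad.occupancy import (
    GLOBAL_PSI,
    OccupancyModel,
    candidate_detection_set,
    candidate_occupancy_set,
    count_params,
    mb_gof,
    selection_table,
    simulate,
    two_stage_select,
)


def enumeration_nll(beta, model):
    """Independent oracle: per-site marginalization over the latent
    occupancy state, log-domain throughout."""
    import math

    from scipy.special import log_expit

    kpsi = model.k_psi
    eta_psi = model.X @ beta[:kpsi]
    eta_p = model.V @ beta[kpsi:]
    site_logs = []
    for i in range(model.n_sites):
        sel = model.site_index == i
        y = model.y[sel]
        lp = log_expit(eta_p[sel])
        l1mp = log_expit(-eta_p[sel])
        # z = 1: occupied, Bernoulli visits; z = 0: only all-zero possible
        log_terms = [
            float(log_expit(eta_psi[i])) + math.fsum(np.where(y == 1, lp, l1mp))
        ]
        if y.sum() == 0:
            log_terms.append(float(log_expit(-eta_psi[i])))
        m = max(log_terms)
        site_logs.append(m + math.log(math.fsum(math.exp(t - m) for t in log_terms)))
    return -math.fsum(site_logs)


def _sim_sites(n, seed=0, n_cities=1):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "site_id": [f"s{i:05d}" for i in range(n)],
            "city": [f"city{i % n_cities:02d}" for i in range(n)],
            "HS": rng.standard_normal(n),
            "BG": rng.standard_normal(n),
        }
    )


class TestLikelihood:
    def test_hand_values(self):
        sites = _sim_sites(1)
        data = simulate("1", "1", [0.0, 0.0], sites, visit_dates={"s00000": [0.0]}, seed=0)
        data.visits["y"] = 1
        m = OccupancyModel(data, "1", "1")
        # one site, J=1, y=1, psi=p=0.5: -ln(0.25)
        assert m.nloglike_grad(np.zeros(2))[0] == pytest.approx(1.3862943611, abs=1e-9)
        data2 = simulate("1", "1", [0.0, 0.0], sites, visit_dates={"s00000": [0.0, 1.0]}, seed=0)
        data2.visits["y"] = 0
        m2 = OccupancyModel(data2, "1", "1")
        # J=2 all-zero: -ln(0.5*0.25 + 0.5)
        assert m2.nloglike_grad(np.zeros(2))[0] == pytest.approx(0.4700036292, abs=1e-9)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        sites = _sim_sites(20, seed=31, n_cities=2)
        plan = {sid: np.sort(rng.uniform(0, 18, rng.integers(1, 6))) for sid in sites["site_id"]}
        data = simulate("city+HS", "date+date2", [0.2, -0.4, 0.8, 0.3, 0.4, -0.05],
                        sites, visit_dates=plan, seed=31)
        m = OccupancyModel(data, "city+HS", "date+date2")
        for trial in range(5):
            beta = rng.normal(scale=0.7, size=m.k_params)
            assert m.nloglike_grad(beta)[0] == pytest.approx(
                enumeration_nll(beta, m), abs=1e-10
            )

    def test_analytic_gradient_matches_finite_difference(self):
        sites = _sim_sites(15, seed=33)
        data = simulate("HS", "date", [0.3, 0.5, -0.2, 0.1], sites, visit_dates=3, seed=33)
        m = OccupancyModel(data, "HS", "date")
        rng = np.random.default_rng(33)
        beta = rng.normal(size=m.k_params)
        _, grad = m.nloglike_grad(beta)
        eps = 1e-6
        for j in range(beta.size):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += eps
            bm[j] -= eps
            fd = (m.nloglike_grad(bp)[0] - m.nloglike_grad(bm)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-4)


class TestFit:
    def test_parameter_recovery_1000_sites(self):
        # psi intercept at logit^-1 = 0.6, p = 0.4, one gradient effect
        beta_true = np.array([logit(0.6), 0.8, logit(0.4)])
        sites = _sim_sites(1000, seed=1)
        data = simulate("HS", "1", beta_true, sites, visit_dates=4, seed=1)
        res = OccupancyModel(data, "HS", "1").fit(seed=1)
        assert res.converged
        assert np.all(np.abs(res.params - beta_true) < 3 * res.bse)

    def test_aicc_formula_arithmetic(self):
        # K=2, n=10, logLik=-5 -> AICc = 14 + 12/7
        k, n, ll = 2, 10, -5.0
        aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc == pytest.approx(15.714285714)
        sites = _sim_sites(10, seed=2)
        data = simulate("1", "1", [0.3, 0.0], sites, visit_dates=2, seed=2)
        res = OccupancyModel(data, "1", "1").fit()
        expected = -2 * res.llf + 2 * 2 + 2 * 2 * 3 / (10 - 2 - 1)
        assert res.aicc == pytest.approx(expected)

    def test_all_detected_boundary_flagged(self):
        sites = _sim_sites(50, seed=3)
        data = simulate("1", "1", [30.0, 30.0], sites, visit_dates=3, seed=3)
        assert data.visits["y"].all()
        res = OccupancyModel(data, "1", "1").fit()
        assert res.boundary or not res.converged
        psi_hat = expit(res.params[0])
        assert psi_hat > 0.99

    def test_oversaturated_model_flagged_not_raised(self):
        sites = _sim_sites(8, seed=4, n_cities=4)
        data = simulate("1", "1", [0.5, -0.3], sites, visit_dates=3, seed=4)
        res = OccupancyModel(data, "city*HS", "city+date").fit()  # K > n-1
        assert not res.converged
        assert np.isinf(res.aicc)


class TestCandidates:
    def test_detection_set_size_and_members(self):
        det = candidate_detection_set()
        assert len(det) == 26
        for printed in ("city*date+date2+HS+BG", "city*date+HS+BG", "city*HS",
                        "city", "date", "BG", "1", "HS"):
            assert printed in det

    def test_occupancy_set_is_table_enumeration(self):
        occ = candidate_occupancy_set()
        assert len(occ) == 16
        assert "city*(HS+BG)" in occ and GLOBAL_PSI in occ

    def test_user_configs(self):
        assert len(candidate_detection_set(["1", "date", "HS+BG", "city", "date+date2"])) == 5
        with pytest.raises(ValueError):
            candidate_occupancy_set([])

    def test_k_values_reproduce_selection_table(self):
        # ten-city design widths for the printed model structures
        assert count_params("city*HS+BG", "city*date+date2+HS+BG", 10) == 44
        assert count_params("1", "city*date+date2+HS+BG", 10) == 24
        assert count_params("city*(HS*BG)", "city*date+date2+HS+BG", 10) == 63
        assert count_params("city*(HS+BG)", "city*date+date2+HS+BG", 10) == 53
        # detection stage rows against the global occupancy structure
        assert count_params("city*(HS*BG)", "city*date+HS+BG", 10) == 62
        assert count_params("city*(HS*BG)", "city*HS", 10) == 60
        assert count_params("city*(HS*BG)", "date", 10) == 42
        assert count_params("city*(HS*BG)", "BG", 10) == 42
        assert count_params("city*(HS*BG)", "1", 10) == 41
        assert count_params("city*(HS*BG)", "HS", 10) == 42
        # occupancy stage rows with the best detection structure fixed
        assert count_params("city*HS", "city*date+date2+HS+BG", 10) == 43
        assert count_params("city+HS*BG", "city*date+date2+HS+BG", 10) == 36
        assert count_params("city+HS+BG", "city*date+date2+HS+BG", 10) == 35
        assert count_params("city+HS", "city*date+date2+HS+BG", 10) == 34
        assert count_params("city*BG+HS", "city*date+date2+HS+BG", 10) == 44
        assert count_params("HS*BG", "city*date+date2+HS+BG", 10) == 27
        assert count_params("city*BG", "city*date+date2+HS+BG", 10) == 43
        assert count_params("city+BG", "city*date+date2+HS+BG", 10) == 34
        assert count_params("city", "city*date+date2+HS+BG", 10) == 33
        assert count_params("BG", "city*date+date2+HS+BG", 10) == 25
        assert count_params("HS+BG", "city*date+date2+HS+BG", 10) == 26
        assert count_params("HS", "city*date+date2+HS+BG", 10) == 25


class TestSelection:
    def test_single_model_sets(self):
        sites = _sim_sites(60, seed=5)
        data = simulate("1", "1", [0.2, -0.2], sites, visit_dates=3, seed=5)
        sel = two_stage_select(data, ["1"], ["1"], global_psi="1")
        assert sel.best_detection == "1" and sel.best_occupancy == "1"
        assert sel.stage1["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self):
        sites = _sim_sites(120, seed=6)
        data = simulate("HS", "date", [0.3, 1.0, -0.2, 0.1], sites, visit_dates=4, seed=6)
        sel = two_stage_select(
            data, ["1", "date"], ["1", "HS", "BG", "HS+BG"], global_psi="HS+BG"
        )
        for table in (sel.stage1, sel.stage2):
            assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
            conv = table[table["converged"]]
            assert conv["dAICc"].iloc[0] == 0.0

    def test_recovers_generating_structure(self):
        # strong effects: psi driven by HS, detection by date
        beta_true = np.array([0.3, 1.6, 0.6, -0.25])
        sites = _sim_sites(800, seed=7)
        data = simulate("HS", "date", beta_true, sites, visit_dates=4, seed=7)
        sel = two_stage_select(
            data,
            ["1", "date", "BG"],
            ["1", "HS", "BG", "HS+BG"],
            global_psi="HS+BG",
            seed=7,
        )
        assert "date" in sel.best_detection
        assert "HS" in sel.best_occupancy
        weight = sel.stage2.set_index("model").loc[sel.best_occupancy, "weight"]
        assert weight > 0.5

    def test_nonconverged_listed_but_unranked(self):
        sites = _sim_sites(12, seed=8, n_cities=3)
        data = simulate("1", "1", [0.4, -0.3], sites, visit_dates=3, seed=8)
        sel = two_stage_select(data, ["1", "city*date+date2+HS+BG"], ["1", "HS"], global_psi="HS")
        bad = sel.stage1[~sel.stage1["converged"]]
        assert len(bad) >= 1
        assert bad["weight"].eq(0.0).all()


class TestSimulate:
    def test_certain_occupancy_and_zero_detection(self):
        sites = _sim_sites(200, seed=9)
        up = simulate("1", "1", [30.0, 0.0], sites, visit_dates=3, seed=9)
        assert up.visits.groupby("site_id")["y"].max().mean() > 0.8  # psi = 1
        down = simulate("1", "1", [0.0, -30.0], sites, visit_dates=3, seed=9)
        assert down.visits["y"].sum() == 0  # p = 0

    def test_naive_occupancy_closed_form(self):
        # psi=0.6, p=0.4, J=4: P(>=1 detection) = 0.6 * (1 - 0.6^4) = 0.52224
        sites = _sim_sites(10_000, seed=10)
        data = simulate("1", "1", [logit(0.6), logit(0.4)], sites, visit_dates=4, seed=10)
        assert data.naive_occupancy() == pytest.approx(0.52224, abs=0.02)

    def test_deterministic_and_dimension_checked(self):
        sites = _sim_sites(30, seed=11)
        a = simulate("HS", "1", [0.1, 0.2, 0.3], sites, visit_dates=3, seed=11)
        b = simulate("HS", "1", [0.1, 0.2, 0.3], sites, visit_dates=3, seed=11)
        pd.testing.assert_frame_equal(a.visits, b.visits)
        with pytest.raises(ValueError):
            simulate("HS", "1", [0.1, 0.2], sites, visit_dates=3, seed=11)


class TestPredict:
    def test_intercept_only_backtransform(self):
        sites = _sim_sites(300, seed=12)
        data = simulate("1", "1", [0.5, 0.2], sites, visit_dates=3, seed=12)
        res = OccupancyModel(data, "1", "1").fit()
        pred = res.predict(pd.DataFrame({"dummy": [0]}), kind="psi")
        assert pred["estimate"].iloc[0] == pytest.approx(expit(res.params[0]))
        assert 0 < pred["ci_low"].iloc[0] < pred["estimate"].iloc[0] < pred["ci_high"].iloc[0] < 1

    def test_zero_coefficients_give_half(self):
        sites = _sim_sites(50, seed=13)
        data = simulate("HS", "1", [0.0, 0.0, 0.0], sites, visit_dates=2, seed=13)
        res = OccupancyModel(data, "HS", "1").fit()
        res.params[:] = 0.0
        pred = res.predict(pd.DataFrame({"HS": [1.7]}), kind="psi")
        assert pred["estimate"].iloc[0] == pytest.approx(0.5)

    def test_monotone_over_gradient_grid(self):
        beta_true = np.array([0.2, 1.2, -0.9, 0.3])
        sites = _sim_sites(800, seed=14)
        data = simulate("HS+BG", "1", beta_true, sites, visit_dates=4, seed=14)
        res = OccupancyModel(data, "HS+BG", "1").fit()
        assert res.converged
        grid = pd.DataFrame({"HS": np.linspace(-2, 2, 9), "BG": 0.0})
        est = res.predict(grid, kind="psi")["estimate"].to_numpy()
        assert np.all(np.diff(est) > 0)  # fitted HS effect is positive
        grid2 = pd.DataFrame({"HS": 0.0, "BG": np.linspace(-2, 2, 9)})
        est2 = res.predict(grid2, kind="psi")["estimate"].to_numpy()
        assert np.all(np.diff(est2) < 0)


class TestGof:
    def test_deterministic_given_seed(self):
        sites = _sim_sites(80, seed=15)
        data = simulate("1", "1", [0.4, -0.4], sites, visit_dates=3, seed=15)
        res = OccupancyModel(data, "1", "1").fit()
        g1 = mb_gof(res, n_boot=25, seed=99)
        g2 = mb_gof(res, n_boot=25, seed=99)
        assert np.array_equal(g1.chi2_boot, g2.chi2_boot)
        assert g1.p_value == g2.p_value

    def test_statistic_and_chat_positive(self):
        sites = _sim_sites(80, seed=16)
        data = simulate("1", "1", [0.4, -0.4], sites, visit_dates=3, seed=16)
        res = OccupancyModel(data, "1", "1").fit()
        g = mb_gof(res, n_boot=25, seed=1)
        assert g.chi2_obs >= 0
        assert 0.0 <= g.p_value <= 1.0
        assert g.c_hat > 0

    def test_nboot_validation(self):
        sites = _sim_sites(20, seed=17)
        data = simulate("1", "1", [0.4, -0.4], sites, visit_dates=2, seed=17)
        res = OccupancyModel(data, "1", "1").fit()
        with pytest.raises(ValueError):
            mb_gof(res, n_boot=0)


def test_selection_table_requires_converged_model():
    class Dummy:
        k_params = 2
        aicc = float("inf")
        llf = -5.0
        converged = False

    with pytest.raises(ValueError):
        selection_table({"m": Dummy()})
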
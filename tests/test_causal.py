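import numpy as np
import pandas as pd
import pytest

from stressmet.causal import (
    BalanceError,
    MediationDesign,
    average_causal_effect,
    balancing_weights,
    encode_covariates,
    expand_counterfactuals,
    joint_mediation,
    natural_effects_fit,
    sensitivity_scan,
)
from stressmet.stats import CohortTable
from stressmet.synth import (
    COVARIATE_COLUMNS,
    EXPOSURE_NAME,
    MEDIATOR_NAMES,
    CohortConfig,
    generate_cohort,
)


def _simple_cov(rng, n):
    return pd.DataFrame(
        {
            "z1": rng.normal(size=n),
            "z2": rng.normal(size=n),
            "cat": rng.choice(["a", "b", "c"], n),
        }
    )


class TestBalancing:
    def test_independent_exposure_near_uniform(self, rng):
        n = 500
        cov = _simple_cov(rng, n)
        x = rng.normal(size=n)
        w = balancing_weights(x, cov)
        assert w.weights.sum() == pytest.approx(n)
        assert np.abs(w.balance_report["weighted_moment"]).max() < 1e-6
        assert w.effective_sample_size > 0.9 * n

    def test_balance_contract_auditable(self, rng):
        n = 400
        cov = _simple_cov(rng, n)
        x = rng.normal(size=n) + 0.5 * cov["z1"].to_numpy()
        w = balancing_weights(x, cov)
        # recompute a weighted covariance independently from the weights
        xs = (x - x.mean()) / x.std()
        z1 = cov["z1"].to_numpy()
        z1s = (z1 - z1.mean()) / z1.std()
        wc = np.sum(w.weights * xs * z1s) / n
        assert abs(wc) < 1e-8
        row = w.balance_report.set_index("constraint").loc["exposure*z1", "weighted_moment"]
        assert wc == pytest.approx(row, abs=1e-10)

    def test_collinear_covariate_infeasible(self, rng):
        n = 200
        x = rng.normal(size=n)
        cov = pd.DataFrame({"copy": x})
        with pytest.raises(BalanceError):
            balancing_weights(x, cov)

    def test_weights_positive(self, rng):
        n = 300
        cov = _simple_cov(rng, n)
        x = rng.normal(size=n) + 0.4 * cov["z2"].to_numpy()
        w = balancing_weights(x, cov)
        assert (w.weights > 0).all()

    def test_too_many_constraints(self, rng):
        cov = pd.DataFrame(rng.normal(size=(10, 8)), columns=[f"z{i}" for i in range(8)])
        with pytest.raises(BalanceError):
            balancing_weights(rng.normal(size=10), cov)

    def test_encode_covariates_dummies(self, rng):
        cov = _simple_cov(rng, 50)
        enc = encode_covariates(cov)
        assert "z1" in enc.columns
        assert any(c.startswith("cat_") for c in enc.columns)
        assert enc.select_dtypes(exclude="number").empty


class TestACE:
    def test_recovers_slope_no_confounding(self, rng):
        n = 1000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n) * 0.8
        w = balancing_weights(x, _simple_cov(rng, n))
        r = average_causal_effect(y, x, w)
        assert abs(r.effect - 0.5) < 3 * r.se

    def test_weighting_reduces_confounding_bias(self, rng):
        n = 2000
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n) * 0.5
        y = 0.5 * x + 0.8 * z + rng.normal(size=n) * 0.5
        cov = pd.DataFrame({"z": z})
        naive = average_causal_effect(y, x, np.ones(n))
        w = balancing_weights(x, cov)
        bal = average_causal_effect(y, x, w)
        assert abs(bal.effect - 0.5) < abs(naive.effect - 0.5)

    def test_zero_variance_exposure(self, rng):
        with pytest.raises(ValueError):
            average_causal_effect(rng.normal(size=10), np.ones(10), np.ones(10))

    def test_ci_contains_point(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r = average_causal_effect(y, x, np.ones(n))
        assert r.ci_95[0] <= r.effect <= r.ci_95[1]


class TestSensitivity:
    def test_corner_reproduces_base_exactly(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        s = sensitivity_scan(y, x, n_draws=3, seed=0)
        assert s.surface[0, 0] == s.base.effect

    def test_surface_monotone_on_diagonal_start(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n) * 0.8
        s = sensitivity_scan(y, x, n_draws=10, seed=1)
        d = s.diagonal["estimate"].to_numpy()
        assert d[0] > d[2] > d[4]

    def test_tau2_le_tau1_significant_design(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n) * 0.8
        s = sensitivity_scan(y, x, n_draws=10, seed=2)
        assert s.base.p < 0.05
        assert s.tau2 is not None and s.tau2 <= s.tau1

    def test_null_design_tau1_small(self, rng):
        n = 20000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        s = sensitivity_scan(y, x, n_draws=5, seed=3)
        assert s.tau1 < 0.1
        assert s.tau2 is None  # base not significant

    def test_coarse_grid_warns(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        with pytest.warns(UserWarning, match="coarser"):
            sensitivity_scan(y, x, grid=np.linspace(0, 1, 3), n_draws=2, seed=0)


class TestExpansion:
    def test_row_count(self, rng):
        x = rng.normal(size=50)
        exp = expand_counterfactuals(x, None)
        assert len(exp) == 100
        assert set(exp["idx"]) == set(range(50))

    def test_weights_positive_finite(self, rng):
        n = 80
        cov = _simple_cov(rng, n)
        x = rng.normal(size=n) + cov["z1"].to_numpy()
        exp = expand_counterfactuals(x, cov)
        w = exp["weight"].to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()

    def test_sample_at_mean_minimal_weight(self, rng):
        x = np.concatenate([[0.0], rng.normal(size=200) * 1.0])
        exp = expand_counterfactuals(x, None, truncate=(0, 100))
        w_per_sample = exp.groupby("idx")["weight"].first()
        # the sample exactly at the density mode has (near-)minimal weight
        assert w_per_sample.iloc[0] <= w_per_sample.quantile(0.05)

    def test_hypothetical_levels_shift(self, rng):
        x = rng.normal(size=10)
        exp = expand_counterfactuals(x, None, delta=0.01)
        d = (exp["x_hyp"] - exp["x_act"]).to_numpy()
        assert np.allclose(sorted(set(np.round(d, 10))), [-0.01, 0.01])


class TestNaturalEffects:
    def test_linear_sem_recovery(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n) * 0.6
        y = 0.3 * x + 0.8 * m + rng.standard_normal(n) * 0.7
        res = natural_effects_fit(y, x, m, n_boot=200, seed=0)
        assert abs(res.effect["psi_i"] - 0.4) < 3 * res.se["psi_i"]
        assert abs(res.effect["psi_d"] - 0.3) < 3 * res.se["psi_d"]

    def test_sum_rule_exact(self, rng):
        n = 300
        x = rng.standard_normal(n)
        m = 0.2 * x + rng.standard_normal(n)
        y = 0.1 * x + 0.5 * m + rng.standard_normal(n)
        res = natural_effects_fit(y, x, m, n_boot=50, seed=1)
        assert res.effect["psi_t"] - (res.effect["psi_d"] + res.effect["psi_i"]) == 0.0

    def test_null_mediator(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n) * 0.7
        res = natural_effects_fit(y, x, m, n_boot=200, seed=2)
        assert abs(res.effect["psi_i"]) < 3 * max(res.se["psi_i"], 1e-6)

    def test_aliased_columns_rejected(self, rng):
        n = 100
        x = rng.standard_normal(n)
        with pytest.raises(ValueError, match="aliased|singular"):
            natural_effects_fit(rng.standard_normal(n), x, np.column_stack([x, x]),
                                n_boot=10, seed=0)


class TestJointMediation:
    def test_design_validation(self):
        with pytest.raises(ValueError):
            MediationDesign(exposure="a", mediators=("a", "b"), outcomes=("y",))
        with pytest.raises(ValueError):
            MediationDesign(exposure="a", mediators=("m",), outcomes=("m",))

    def test_panel_bookkeeping(self):
        cfg = CohortConfig(n_outcomes=5)
        table, truth = generate_cohort(cfg, seed=11)
        design = MediationDesign(
            outcomes=tuple(table.metabolites), covariates=tuple(COVARIATE_COLUMNS)
        )
        panel = joint_mediation(design, table, n_boot=30, seed=0)
        assert len(panel) == 5
        assert {"psi_d", "psi_i", "psi_t", "q_i"} <= set(panel.columns)
        assert np.allclose(panel["psi_t"], panel["psi_d"] + panel["psi_i"])

    def test_null_mediation_cohort(self):
        cfg = CohortConfig.null(n_case=400, n_control=400, n_outcomes=3)
        table, truth = generate_cohort(cfg, seed=5)
        design = MediationDesign(
            outcomes=tuple(table.metabolites), covariates=tuple(COVARIATE_COLUMNS)
        )
        panel = joint_mediation(design, table, n_boot=60, seed=1)
        for _, row in panel.iterrows():
            assert abs(row["psi_i"]) < 4 * max(row["se_i"], 1e-8)

    def test_missing_columns_named(self):
        cfg = CohortConfig(n_outcomes=2)
        table, _ = generate_cohort(cfg, seed=0)
        design = MediationDesign(outcomes=("ghost",))
        with pytest.raises(ValueError, match="ghost"):
            joint_mediation(design, table, n_boot=5)


class TestConsistencyAcrossEstimators:
    def test_ace_matches_psi_t_on_synthetic(self):
        """With all confounders balanced, ACE ~ natural-effects total."""
        cfg = CohortConfig(n_case=600, n_control=600, n_outcomes=1)
        table, truth = generate_cohort(cfg, seed=21)
        df = table.data
        x = np.log(df[EXPOSURE_NAME].to_numpy())
        y = np.log(df["met_01"].to_numpy())
        cov = df[list(COVARIATE_COLUMNS)].copy()
        cov["g"] = (df["group"] == "PTSD").astype(float)
        w = balancing_weights(x, cov)
        ace = average_causal_effect(y, x, w)
        design = MediationDesign(
            outcomes=("met_01",), covariates=tuple(COVARIATE_COLUMNS)
        )
        med = joint_mediation(design, table, n_boot=100, seed=3)
        psi_t = med["psi_t"].iloc[0]
        joint_se = np.hypot(ace.se, med["se_t"].iloc[0])
        assert abs(ace.effect - psi_t) < 3 * joint_se
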
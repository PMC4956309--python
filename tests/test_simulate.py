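"""Synthetic cohort generator: analytic truth, determinism, causal structure."""

import numpy as np
import pytest
from scipy.special import expit, logit

from pascreen import (
    ConfounderSpec,
    SimulationSpec,
    evaluate_estimators,
    load_spec,
    save_spec,
    simulate,
    study_spec,
    true_values,
)


def two_stratum_spec(pi=(0.5, 0.5), e=(0.2, 0.8), m0=(0.2, 0.2), m1=(0.4, 0.4),
                     n=1000, seed=1):
    return SimulationSpec(
        confounders=(ConfounderSpec("g", ("a", "b"), "a"),),
        strata=np.array([[0], [1]]),
        pi=np.array(pi, dtype=float),
        alpha0=float(logit(e[0])),
        alpha=np.array([float(logit(e[1]) - logit(e[0]))]),
        m0=np.array(m0, dtype=float),
        m1=np.array(m1, dtype=float),
        n=n,
        seed=seed,
    )


class TestTrueValues:
    def test_single_stratum_hand_enumeration(self):
        spec = two_stratum_spec(pi=(1.0, 0.0), e=(0.8, 0.8), m0=(0.1, 0.1),
                                m1=(0.3, 0.3))
        t = true_values(spec)
        assert t.true_prevalence == pytest.approx(0.8, abs=1e-12)
        assert t.true_delta_att == pytest.approx(0.2, abs=1e-12)
        assert t.true_pa == pytest.approx(0.16, abs=1e-12)

    def test_two_strata_hand_enumeration(self):
        t = true_values(two_stratum_spec())
        assert t.true_delta_att == pytest.approx(0.2, abs=1e-12)
        assert t.true_prevalence == pytest.approx(0.5, abs=1e-12)
        assert t.true_pa == pytest.approx(0.1, abs=1e-12)

    def test_null_effect_gives_zero_pa(self):
        t = true_values(two_stratum_spec(m0=(0.2, 0.3), m1=(0.2, 0.3)))
        assert t.true_pa == 0.0

    def test_pa_is_product_of_fields(self):
        t = true_values(study_spec())
        assert t.true_pa == t.true_delta_att * t.true_prevalence

    def test_independent_reimplementation_in_reversed_order(self):
        spec = study_spec()
        t = true_values(spec)
        e = spec.e
        prev = 0.0
        rate = 0.0
        num = 0.0
        for i in reversed(range(spec.n_strata)):
            prev += spec.pi[i] * e[i]
            rate += spec.pi[i] * (e[i] * spec.m1[i] + (1 - e[i]) * spec.m0[i])
            num += (spec.m1[i] - spec.m0[i]) * spec.pi[i] * e[i]
        assert t.true_prevalence == pytest.approx(prev, abs=1e-15)
        assert t.true_outcome_rate == pytest.approx(rate, abs=1e-15)
        assert t.true_pa == pytest.approx(num, abs=1e-15)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            two_stratum_spec(pi=(0.6, 0.6))
        with pytest.raises(ValueError):
            two_stratum_spec(m0=(1.2, 0.1))


class TestSimulate:
    def test_fixed_seed_reproducible(self):
        spec = study_spec()
        d1 = simulate(spec, n=300, seed=5).to_frame()
        d2 = simulate(spec, n=300, seed=5).to_frame()
        assert d1.equals(d2)

    def test_study_layout(self):
        ds = simulate(study_spec(), n=200, seed=1)
        assert ds.confounders.shape[1] == 5
        assert ds.beliefs.shape[1] == 1
        assert set(np.unique(ds.outcome)) <= {0, 1}

    def test_consistency_observed_equals_selected_counterfactual(self):
        ds = simulate(study_spec(), n=2000, seed=8, keep_counterfactuals=True)
        cf = ds.counterfactuals
        a = ds.belief_exposure("workplace_smokefree")
        expected = np.where(a == 1, cf["y1"], cf["y0"])
        assert np.array_equal(ds.outcome, expected)

    def test_exchangeability_within_strata(self):
        """Potential outcomes are drawn independently of exposure given the
        stratum, so y0 means agree between exposed and unexposed per stratum."""
        spec = two_stratum_spec(n=200_000, seed=3)
        ds = simulate(spec, keep_counterfactuals=True)
        cf = ds.counterfactuals
        a = ds.belief_exposure("belief")
        for k in (0, 1):
            sel = cf["stratum"] == k
            y0_1 = cf.loc[sel & (a == 1), "y0"]
            y0_0 = cf.loc[sel & (a == 0), "y0"]
            se = np.hypot(y0_1.std() / np.sqrt(len(y0_1)),
                          y0_0.std() / np.sqrt(len(y0_0)))
            assert abs(y0_1.mean() - y0_0.mean()) < 3 * se

    def test_null_effect_monte_carlo(self):
        spec = two_stratum_spec(m0=(0.2, 0.3), m1=(0.2, 0.3), n=1_000_000, seed=4)
        ds = simulate(spec, keep_counterfactuals=True)
        cf = ds.counterfactuals
        a = ds.belief_exposure("belief")
        d = (cf["y1"] - cf["y0"])[a == 1]
        se = d.std() / np.sqrt(len(d))
        assert abs(d.mean()) < 3 * se

    def test_constant_propensity_prevalence(self):
        spec = two_stratum_spec(e=(0.7, 0.7), n=1_000_000, seed=6)
        ds = simulate(spec)
        p_hat = ds.beliefs["belief"].mean()
        se = np.sqrt(0.7 * 0.3 / 1_000_000)
        assert abs(p_hat - expit(spec.alpha0)) < 3 * se

    def test_monte_carlo_converges_to_analytic_truth(self):
        spec = study_spec(n=1_000_000, seed=10)
        truth = true_values(spec)
        ds = simulate(spec, keep_counterfactuals=True)
        n = ds.n
        a = ds.belief_exposure("workplace_smokefree")
        cf = ds.counterfactuals
        p_hat = a.mean()
        assert abs(p_hat - truth.true_prevalence) < 3 * np.sqrt(p_hat * (1 - p_hat) / n)
        rate_hat = ds.outcome_rate
        assert abs(rate_hat - truth.true_outcome_rate) < 3 * np.sqrt(
            rate_hat * (1 - rate_hat) / n
        )
        d = (cf["y1"] - cf["y0"])[a == 1]
        assert abs(d.mean() - truth.true_delta_att) < 3 * d.std() / np.sqrt(len(d))

    def test_paf_two_routes_agree(self):
        """PA/Pr(Y) equals the direct counterfactual contrast
        (Pr(Y) - Pr(Y0)) / Pr(Y) in a large cohort."""
        spec = study_spec(n=1_000_000, seed=14)
        truth = true_values(spec)
        ds = simulate(spec, keep_counterfactuals=True)
        y = ds.outcome.astype(float)
        y0 = ds.counterfactuals["y0"].to_numpy(dtype=float)
        d = y - y0
        pa_mc = d.mean()
        rate_mc = y.mean()
        paf_mc = pa_mc / rate_mc
        # delta-method MC error of the ratio
        n = ds.n
        cov = np.cov(d, y) / n
        grad = np.array([1 / rate_mc, -pa_mc / rate_mc**2])
        se = np.sqrt(grad @ cov @ grad)
        assert abs(paf_mc - truth.true_paf) < 3 * se


class TestEvaluateEstimators:
    def test_unconfounded_spec_both_methods_unbiased(self):
        spec = study_spec(confounding=0.0)
        tab = evaluate_estimators(spec, n_reps=200, n=2000, seed=9)
        truth = tab.attrs["truth"]
        assert truth.true_pa > 0
        for m in ("crude", "msm"):
            mcse = tab.loc[m, "empirical_se"] / np.sqrt(tab.loc[m, "n_ok"])
            assert abs(tab.loc[m, "bias"]) < 2 * mcse

    def test_failure_counting_not_fatal(self):
        # tiny cohorts occasionally produce constant exposure -> counted
        spec = two_stratum_spec(e=(0.95, 0.95), n=12)
        tab = evaluate_estimators(spec, n_reps=30, n=12, seed=2)
        assert (tab["n_ok"] + tab["n_fail"] == 30).all()


class TestSpecIO:
    def test_yaml_round_trip_preserves_truth(self, tmp_path):
        spec = study_spec()
        path = tmp_path / "spec.yaml"
        save_spec(spec, path)
        back = load_spec(path)
        t1, t2 = true_values(spec), true_values(back)
        assert t1.true_pa == pytest.approx(t2.true_pa, abs=1e-12)
        assert t1.true_outcome_rate == pytest.approx(t2.true_outcome_rate, abs=1e-12)
        assert back.n == spec.n and back.seed == spec.seed
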
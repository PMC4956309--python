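"""Propensity logistic fit and ATT odds weights."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from pascreen import (
    ConfounderSpec,
    EstimationError,
    att_weights,
    encode_confounders,
    fit_propensity,
)

from conftest import saturated_fixture


def design_from_labels(labels, levels=None, reference=None):
    labels = [str(v) for v in labels]
    levels = tuple(levels or sorted(set(labels)))
    reference = reference or levels[0]
    spec = ConfounderSpec("g", levels, reference)
    return encode_confounders(pd.DataFrame({"g": labels}), [spec])


class TestFitPropensity:
    def test_no_association_null(self):
        # exposure independent of a balanced binary confounder, Pr(A=1)=0.5
        x = np.repeat([0, 1], 40)
        a = np.tile([0, 1], 40)
        d = design_from_labels(x)
        m = fit_propensity(d, a)
        assert m.converged
        assert abs(m.alpha0) < 1e-6
        assert np.all(np.abs(m.alpha) < 1e-6)
        assert m.loglik <= 0

    def test_grid_search_mle_oracle(self):
        # 8-row fixture checked against a dense grid over (alpha0, alpha1)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        a = np.array([0, 0, 1, 1, 0, 1, 1, 1])
        d = design_from_labels(x)
        m = fit_propensity(d, a)

        def loglik(b0, b1):
            eta = b0 + b1 * x[:, None, None]
            return np.sum(
                a[:, None, None] * eta - np.logaddexp(0.0, eta), axis=0
            )

        # coarse pass then refinement around the best cell
        g0 = np.linspace(-3, 3, 241)
        ll = loglik(g0[:, None], g0[None, :])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        f0 = np.linspace(g0[i] - 0.05, g0[i] + 0.05, 401)
        f1 = np.linspace(g0[j] - 0.05, g0[j] + 0.05, 401)
        ll = loglik(f0[:, None], f1[None, :])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert m.alpha0 == pytest.approx(f0[i], abs=1e-3)
        assert m.alpha[0] == pytest.approx(f1[j], abs=1e-3)

    def test_saturated_fit_reproduces_stratum_fractions(self):
        rng = np.random.default_rng(5)
        s, a, _ = saturated_fixture(rng)
        d = design_from_labels(s)
        m = fit_propensity(d, a)
        for j in np.unique(s):
            assert m.fitted[s == j][0] == pytest.approx(a[s == j].mean(), abs=1e-8)

    def test_agrees_with_statsmodels_logit(self):
        rng = np.random.default_rng(17)
        s, a, _ = saturated_fixture(rng, n_range=(60, 100))
        d = design_from_labels(s)
        ours = fit_propensity(d, a)
        ref = sm.Logit(a, d.matrix).fit(disp=0)
        assert np.allclose(ours.params, ref.params, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_constant_exposure_rejected(self):
        d = design_from_labels([0, 1, 0, 1])
        with pytest.raises(EstimationError, match="constant"):
            fit_propensity(d, np.ones(4))

    def test_complete_separation_rejected_with_pattern(self):
        # confounder perfectly predicts exposure
        x = np.repeat([0, 1], 25)
        a = x.copy()
        d = design_from_labels(x)
        with pytest.raises(EstimationError, match="separation"):
            fit_propensity(d, a)

    def test_reference_level_invariance(self):
        rng = np.random.default_rng(9)
        s, a, _ = saturated_fixture(rng, k_range=(3, 4))
        levels = sorted(set(str(v) for v in s))
        d1 = design_from_labels(s, levels, reference=levels[0])
        d2 = design_from_labels(s, levels, reference=levels[-1])
        m1 = fit_propensity(d1, a)
        m2 = fit_propensity(d2, a)
        assert np.allclose(m1.fitted, m2.fitted, atol=1e-8)


class TestAttWeights:
    def _constant_propensity_model(self, frac, n=20):
        n1 = int(round(frac * n))
        a = np.array([1] * n1 + [0] * (n - n1))
        d = design_from_labels(["z"] * n, levels=("z", "w"), reference="w")
        # drop the structurally empty dummy to keep the design full rank
        from pascreen.survey import DesignMatrix

        d = DesignMatrix(matrix=d.matrix[:, :1], columns=("intercept",))
        return fit_propensity(d, a), a

    def test_constant_half_gives_unit_weights(self):
        m, a = self._constant_propensity_model(0.5)
        w = att_weights(m, a)
        assert np.allclose(w, 1.0, atol=1e-9)

    def test_constant_point_eight_gives_odds_four(self):
        m, a = self._constant_propensity_model(0.8)
        w = att_weights(m, a)
        assert np.allclose(w[a == 0], 4.0, atol=1e-8)

    def test_exposed_weights_identically_one(self):
        rng = np.random.default_rng(21)
        s, a, _ = saturated_fixture(rng)
        m = fit_propensity(design_from_labels(s), a)
        w = att_weights(m, a)
        assert np.all(w[a == 1] == 1.0)
        assert np.all(w > 0)

    def test_stratified_odds_by_hand(self):
        # strata propensities {0.25, 0.75} -> unexposed odds {1/3, 3}
        s = np.repeat([0, 1], 8)
        a = np.array([1, 0, 0, 0] * 2 + [1, 1, 1, 0] * 2)
        m = fit_propensity(design_from_labels(s), a)
        w = att_weights(m, a)
        assert np.allclose(w[(s == 0) & (a == 0)], 1 / 3, atol=1e-9)
        assert np.allclose(w[(s == 1) & (a == 0)], 3.0, atol=1e-9)

    def test_weights_balance_confounder_distribution(self):
        """Odds weighting makes the weighted unexposed match the exposed strata."""
        rng = np.random.default_rng(33)
        s, a, _ = saturated_fixture(rng, n_range=(100, 200))
        m = fit_propensity(design_from_labels(s), a)
        w = att_weights(m, a)
        w0 = w[a == 0]
        s0 = s[a == 0]
        exposed_freq = np.array(
            [(s[a == 1] == j).mean() for j in np.unique(s)]
        )
        weighted_freq = np.array(
            [w0[s0 == j].sum() / w0.sum() for j in np.unique(s)]
        )
        assert np.allclose(weighted_freq, exposed_freq, atol=1e-8)

    def test_infinite_weight_rejected(self):
        from pascreen.propensity import PropensityModel

        m = PropensityModel(
            alpha0=logit(1 - 1e-13), alpha=np.zeros(0), converged=True, n_iter=1,
            loglik=-1.0, fitted=np.array([1 - 1e-13, 1 - 1e-13]),
            columns=("intercept",),
        )
        with pytest.raises(EstimationError, match="infinite"):
            att_weights(m, np.array([1, 0]))

    def test_true_propensity_recovered_under_logistic_generator(self):
        # fitted probabilities approach the generating expit curve
        rng = np.random.default_rng(55)
        x = rng.integers(0, 2, 4000)
        e = expit(-0.5 + 1.0 * x)
        a = (rng.random(4000) < e).astype(int)
        m = fit_propensity(design_from_labels(x), a)
        assert m.alpha0 == pytest.approx(-0.5, abs=0.15)
        assert m.alpha[0] == pytest.approx(1.0, abs=0.2)
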
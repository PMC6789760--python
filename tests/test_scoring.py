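import numpy as np
import pytest

from nestlogit import (
    AbilityEstimates,
    BinaryItemParams,
    BinaryMatrix,
    QuadratureGrid,
    eap_scores,
    empirical_reliability,
    reliability_function,
    simulate,
)
from nestlogit.em import FitResult, n_free_params
from nestlogit.simulate import paper_fixture


def fixed_fit(items, model_tag, grid=None, n_persons=1):
    """FitResult wrapper around known parameters (no estimation)."""
    grid = grid or QuadratureGrid.normal()
    return FitResult(
        model_tag=model_tag, items=items, loglik=0.0,
        n_params=n_free_params(items, model_tag), n_persons=n_persons,
        converged=True, n_cycles=0, loglik_path=np.array([]), grid=grid,
    )


class TestEAP:
    def test_zero_slopes_give_prior_scores(self):
        items = [BinaryItemParams(0.0, 0.4), BinaryItemParams(0.0, -0.2)]
        est = eap_scores(fixed_fit(items, "2PL"), BinaryMatrix([[1, 0], [0, 0]]))
        np.testing.assert_allclose(est.theta, 0.0, atol=1e-12)
        np.testing.assert_allclose(est.post_sd, 1.0, atol=1e-3)

    def test_single_item_dense_grid_value(self):
        # frozen dense-grid oracle: posterior mean of theta given one
        # correct response on a 2PL item with alpha=1, beta=0
        grid = QuadratureGrid.normal(2001, 8.0)
        est = eap_scores(fixed_fit([BinaryItemParams(1.0, 0.0)], "2PL", grid),
                         BinaryMatrix([[1]]))
        assert est.theta[0] == pytest.approx(0.4132419, abs=1e-4)
        assert est.post_sd[0] == pytest.approx(0.9106213, abs=1e-4)

    def test_default_grid_close_to_dense(self):
        est = eap_scores(fixed_fit([BinaryItemParams(1.0, 0.0)], "2PL"),
                         BinaryMatrix([[1]]))
        assert est.theta[0] == pytest.approx(0.4132419, abs=1e-3)

    def test_all_missing_row_gets_prior_mean_and_unit_sd(self, small_binary_bank):
        scores = np.full((1, 6), -1)
        est = eap_scores(fixed_fit(small_binary_bank, "2PL"), BinaryMatrix(scores))
        assert est.theta[0] == 0.0 and est.post_sd[0] == 1.0

    def test_correcting_a_response_never_lowers_the_score(self, small_binary_bank):
        rng = np.random.default_rng(9)
        fit = fixed_fit(small_binary_bank, "2PL")
        data, _ = simulate(small_binary_bank, 50, seed=10)
        base = eap_scores(fit, data)
        for j in rng.choice(50, size=10, replace=False):
            i = rng.integers(0, 6)
            if data.scores[j, i] == 1:
                continue
            flipped = data.scores.copy()
            flipped[j, i] = 1
            est = eap_scores(fit, BinaryMatrix(flipped))
            assert est.theta[j] >= base.theta[j] - 1e-12

    def test_item_count_mismatch_rejected(self, small_binary_bank):
        with pytest.raises(ValueError, match="item count"):
            eap_scores(fixed_fit(small_binary_bank, "2PL"), BinaryMatrix([[1, 0]]))


class TestReliabilityFunction:
    def test_forced_values(self):
        # I=0 -> r=0 (zero-slope item); at any theta where I(theta)=1, r=0.5
        flat = fixed_fit([BinaryItemParams(0.0, 0.0)], "2PL")
        curve = reliability_function(flat).curve
        np.testing.assert_allclose(curve["reliability"], 0.0, atol=1e-12)
        report = reliability_function(fixed_fit([BinaryItemParams(2.0, 0.0)], "2PL"),
                                      theta_grid=[0.0])
        info = report.curve["information"].iloc[0]
        assert report.curve["reliability"].iloc[0] == pytest.approx(info / (info + 1))

    def test_monotone_in_information(self, small_binary_bank):
        curve = reliability_function(fixed_fit(small_binary_bank, "2PL")).curve
        order = np.argsort(curve["information"].to_numpy())
        r_sorted = curve["reliability"].to_numpy()[order]
        assert np.all(np.diff(r_sorted) >= -1e-15)
        assert ((curve["reliability"] >= 0) & (curve["reliability"] < 1)).all()

    def test_nested_model_dominates_binary_collapse_at_low_ability(self):
        bank = paper_fixture("nested_3pnl")
        level1 = [it.level1 for it in bank]
        r_nested = reliability_function(fixed_fit(bank, "3PNL"), theta_grid=[-2.0])
        r_binary = reliability_function(fixed_fit(level1, "3PL"), theta_grid=[-2.0])
        assert (
            r_nested.curve["reliability"].iloc[0] >= r_binary.curve["reliability"].iloc[0]
        )


class TestEmpiricalReliability:
    def test_error_free_limit(self):
        est = AbilityEstimates(theta=np.array([-1.0, 0.0, 1.0]), post_sd=np.zeros(3))
        assert empirical_reliability(est) == 1.0

    def test_variance_ratio_formula(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=200)
        theta = (theta - theta.mean()) / theta.std(ddof=1) * np.sqrt(0.75)
        est = AbilityEstimates(theta=theta, post_sd=np.full(200, 0.5))
        assert empirical_reliability(est) == pytest.approx(0.75, abs=1e-12)

    def test_invariant_to_person_order(self):
        rng = np.random.default_rng(4)
        est = AbilityEstimates(theta=rng.normal(size=100), post_sd=rng.uniform(0.2, 1, 100))
        perm = rng.permutation(100)
        shuffled = AbilityEstimates(theta=est.theta[perm], post_sd=est.post_sd[perm])
        assert empirical_reliability(est) == pytest.approx(
            empirical_reliability(shuffled), abs=1e-15
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            empirical_reliability(AbilityEstimates(np.array([0.0]), np.array([1.0])))

    def test_matches_squared_correlation_with_true_ability(self):
        # definitional consistency: r ~ corr(EAP, true theta)^2 at large N
        bank = paper_fixture("binary_2pl")
        data, theta = simulate(bank, 20_000, seed=123)
        est = eap_scores(fixed_fit(bank, "2PL"), data)
        r = empirical_reliability(est)
        r2 = np.corrcoef(est.theta, theta)[0, 1] ** 2
        assert r == pytest.approx(r2, abs=0.02)

    def test_uninformative_distractors_give_no_gain(self):
        # scoring the nominal data adds nothing when distractor slopes are 0
        from conftest import make_nested_bank
        from nestlogit import collapse_binary

        bank = make_nested_bank(n_items=8, m=4, distractor_slope_spread=0.0, seed=6)
        data, _ = simulate(bank, 4000, seed=61)
        est_nested = eap_scores(fixed_fit(bank, "2PNL"), data)
        est_binary = eap_scores(
            fixed_fit([it.level1 for it in bank], "2PL"), collapse_binary(data)
        )
        gap = empirical_reliability(est_nested) - empirical_reliability(est_binary)
        assert abs(gap) < 0.01
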
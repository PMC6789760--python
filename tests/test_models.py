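import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestlogit import (
    BinaryItemParams,
    NestedItemParams,
    NominalItemParams,
    QuadratureGrid,
    item_information,
    prob_binary,
    prob_nested,
    prob_nominal,
)

finite = st.floats(-5, 5, allow_nan=False)
theta_st = st.floats(-6, 6, allow_nan=False)


class TestBinaryKernel:
    def test_logistic_symmetry(self):
        assert prob_binary(BinaryItemParams(1.0, 0.0), 0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "item, expected",
        [
            (BinaryItemParams(1.527, 2.930), 0.9493096751),
            (BinaryItemParams(1.438, -0.852, gamma=0.1189930947), 0.3824260356),
        ],
    )
    def test_published_item_values_at_theta0(self, item, expected):
        assert prob_binary(item, 0.0) == pytest.approx(expected, abs=1e-9)

    @given(alpha=finite, beta=finite, theta=theta_st)
    @settings(deadline=None, max_examples=100)
    def test_4p_with_unit_asymptotes_equals_2p(self, alpha, beta, theta):
        p4 = prob_binary(BinaryItemParams(alpha, beta, gamma=0.0, delta=1.0), theta)
        p2 = prob_binary(BinaryItemParams(alpha, beta), theta)
        assert p4 == p2

    @given(
        alpha=st.floats(0, 5), beta=finite,
        gamma=st.floats(0, 0.5), delta=st.floats(0.5, 1), theta=theta_st,
    )
    @settings(deadline=None, max_examples=100)
    def test_bounded_and_monotone(self, alpha, beta, gamma, delta, theta):
        item = BinaryItemParams(alpha, beta, gamma=gamma, delta=delta)
        p = prob_binary(item, theta)
        assert gamma - 1e-12 <= p <= delta + 1e-12
        assert prob_binary(item, theta + 0.5) >= p - 1e-12


class TestNominalKernel:
    def test_equal_propensities(self):
        item = NominalItemParams(zeta=[0, 0], lam=[0, 0])
        np.testing.assert_allclose(prob_nominal(item, 3.7), [0.5, 0.5])
        item4 = NominalItemParams(zeta=np.zeros(4), lam=np.zeros(4))
        np.testing.assert_allclose(prob_nominal(item4, -1.2), np.full(4, 0.25))

    def test_softmax_oracle(self):
        item = NominalItemParams(zeta=[0, 1, -1], lam=[0, 0.5, -0.5])
        # independent softmax of (0, 1.5, -1.5)
        z = np.exp([0.0, 1.5, -1.5])
        np.testing.assert_allclose(prob_nominal(item, 1.0), z / z.sum(), atol=1e-12)

    @given(
        zeta=st.lists(finite, min_size=2, max_size=6),
        lam=st.lists(finite, min_size=2, max_size=6),
        theta=theta_st, shift=finite,
    )
    @settings(deadline=None, max_examples=100)
    def test_sum_to_one_and_shift_invariance(self, zeta, lam, theta, shift):
        m = min(len(zeta), len(lam))
        item = NominalItemParams(zeta=zeta[:m], lam=lam[:m])
        p = prob_nominal(item, theta)
        assert np.all(p > 0)
        assert abs(p.sum() - 1.0) < 1e-12
        shifted = NominalItemParams(zeta=np.array(zeta[:m]) + shift, lam=lam[:m])
        np.testing.assert_allclose(prob_nominal(shifted, theta), p, atol=1e-12)

    @given(beta=finite, alpha=finite, theta=theta_st)
    @settings(deadline=None, max_examples=100)
    def test_two_category_nrm_equals_2pl(self, beta, alpha, theta):
        nrm = NominalItemParams(zeta=[0, beta], lam=[0, alpha])
        p2pl = prob_binary(BinaryItemParams(alpha, beta), theta)
        assert prob_nominal(nrm, theta)[1] == pytest.approx(p2pl, abs=1e-12)

    def test_overflow_safe(self):
        item = NominalItemParams(zeta=[0, 500], lam=[0, 200])
        p = prob_nominal(item, 6.0)
        assert np.isfinite(p).all() and abs(p.sum() - 1.0) < 1e-12


class TestNestedKernel:
    def test_uniform_split_of_incorrect_mass(self):
        level1 = BinaryItemParams(1.0, 0.0, gamma=0.7, delta=0.7)  # forces P(correct)=0.7
        item = NestedItemParams(level1=level1, zeta=np.zeros(6), lam=np.zeros(6), key=0)
        p = prob_nested(item, 1.3)
        assert p[0] == pytest.approx(0.7)
        np.testing.assert_allclose(p[1:], np.full(5, 0.06), atol=1e-12)

    def test_published_2pnl_item1_at_theta0(self):
        zeta = np.array([0.0, -0.312, 2.878, 1.248, 1.771, 0.0])
        lam = np.array([0.0, 0.426, 1.067, 0.744, 1.327, 0.0])
        item = NestedItemParams(
            level1=BinaryItemParams(1.549, 2.954), zeta=zeta, lam=lam, key=0, ref=5
        )
        p = prob_nested(item, 0.0)
        assert p[0] == pytest.approx(0.9504521995, abs=1e-9)
        assert p[2] == pytest.approx(0.0305116512, abs=1e-9)  # distractor with zeta=2.878

    @given(theta=theta_st, seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_marginalisation_identity(self, theta, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 7))
        level1 = BinaryItemParams(
            float(rng.normal(1, 0.5)), float(rng.normal()), gamma=float(rng.uniform(0, 0.3))
        )
        item = NestedItemParams(
            level1=level1, zeta=rng.normal(0, 1, m), lam=rng.normal(0, 1, m),
            key=int(rng.integers(0, m)),
        )
        p = prob_nested(item, theta)
        p1 = prob_binary(level1, theta)
        assert p[item.key] == pytest.approx(p1, abs=1e-12)
        assert np.delete(p, item.key).sum() == pytest.approx(1 - p1, abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestInformation:
    def test_flat_curves_carry_no_information(self):
        assert item_information(BinaryItemParams(0.0, 0.3), 1.0) == 0.0
        nom = NominalItemParams(zeta=[0, 1, -1], lam=[0, 0, 0])
        assert item_information(nom, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_2pl_closed_form(self):
        assert item_information(BinaryItemParams(1.0, 0.0), 0.0) == pytest.approx(
            0.25, abs=1e-10
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, th = rng.normal(1, 0.5), rng.normal(), rng.normal()
            p = prob_binary(BinaryItemParams(a, b), th)
            assert item_information(BinaryItemParams(a, b), th) == pytest.approx(
                a**2 * p * (1 - p), abs=1e-10
            )

    def test_nested_information_matches_numeric_derivative_oracle(self):
        from nestlogit.simulate import paper_fixture

        item = paper_fixture("nested_3pnl")[8]  # steep mid-range item
        h = 1e-6
        for theta in (-2.0, 0.0, 1.5):
            p = prob_nested(item, theta)
            dp = (prob_nested(item, theta + h) - prob_nested(item, theta - h)) / (2 * h)
            oracle = (dp**2 / p).sum()
            assert item_information(item, theta) == pytest.approx(oracle, abs=1e-6)

    def test_informative_distractors_add_information(self, small_nested_bank):
        theta = np.linspace(-3, 3, 13)
        for item in small_nested_bank:
            nested_info = item_information(item, theta)
            binary_info = item_information(item.level1, theta)
            assert np.all(nested_info >= binary_info - 1e-8)
        # with zero distractor slopes the distractors add nothing
        flat = NestedItemParams(
            level1=BinaryItemParams(1.2, 0.3), zeta=np.array([0, 0.5, -0.5, 0.0]),
            lam=np.zeros(4), key=0,
        )
        np.testing.assert_allclose(
            item_information(flat, theta), item_information(flat.level1, theta), atol=1e-7
        )


class TestQuadratureGrid:
    def test_normal_grid_properties(self):
        g = QuadratureGrid.normal(61, 6.0)
        assert len(g) == 61
        assert abs(g.weights.sum() - 1.0) < 1e-12
        assert np.all(np.diff(g.nodes) > 0)
        # weights proportional to the standard normal density
        ratio = g.weights / np.exp(-g.nodes**2 / 2)
        np.testing.assert_allclose(ratio, ratio[0])

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            QuadratureGrid(nodes=[0.0, 0.0], weights=[0.5, 0.5])
        with pytest.raises(ValueError):
            QuadratureGrid(nodes=[0.0, 1.0], weights=[0.7, 0.7])
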
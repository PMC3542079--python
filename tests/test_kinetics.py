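"""Exact-kinetics layer: rate matrices, survival, position and displacement PDFs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.linalg import expm

import lifediff as ld
from lifediff.models import (InfiniteLifetimeError, InvalidModelError,
                             KineticModel, displacement_scale2)


def two_state_biexponential(model, t):
    """Hand-diagonalized 2x2 solution; independent oracle for Q_j(t)."""
    a = model.lam_apparent[0] + model.k[0, 1]
    d = model.lam_apparent[1] + model.k[1, 0]
    b = model.k[1, 0]  # K[0,1]
    c = model.k[0, 1]  # K[1,0]
    tr, det = -(a + d), a * d - b * c
    disc = np.sqrt(tr**2 - 4.0 * det)
    w1, w2 = 0.5 * (tr + disc), 0.5 * (tr - disc)
    out = []
    for w in (w1, w2):
        # eigenvector of [[-a, b], [c, -d]] for eigenvalue w
        v = np.array([b, w + a]) if abs(b) > 1e-300 else np.array([w + d, c])
        out.append(v)
    V = np.column_stack(out)
    coef = np.linalg.solve(V, model.q)
    return (coef[0] * np.exp(w1 * t)) * V[:, 0] + (coef[1] * np.exp(w2 * t)) * V[:, 1]


class TestRateMatrix:
    def test_single_state(self):
        m = KineticModel(D=[0.0], lam=[1.0], q=[1.0])
        assert np.allclose(ld.build_rate_matrix(m), [[-1.0]])

    def test_two_state_entries(self, demo_switching):
        K = ld.build_rate_matrix(demo_switching)
        assert np.allclose(np.diag(K), [-0.20, -1.50])
        assert K[1, 0] == pytest.approx(0.10)  # state 1 -> 2
        assert K[0, 1] == pytest.approx(0.50)  # state 2 -> 1

    def test_column_leakage_is_dissociation(self, pten3):
        # probability mass leaves only by dissociation/bleaching
        K = ld.build_rate_matrix(pten3)
        assert np.allclose(-K.sum(axis=0), pten3.lam_apparent)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidModelError):
            KineticModel(D=[0.1], lam=[-1.0], q=[1.0])


class TestSurvival:
    def test_single_state_closed_form(self, demo_1state):
        assert ld.residence_probability(demo_1state, 1.0) == pytest.approx(
            np.exp(-1.0), abs=1e-12)

    def test_two_state_no_transition_closed_form(self, demo_static):
        # q1 e^{-lam1 t} + q2 e^{-lam2 t}
        expected = 0.2 * np.exp(-0.1) + 0.8 * np.exp(-1.0)
        assert ld.residence_probability(demo_static, 1.0) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("t", [0.1, 1.0, 5.0])
    def test_spectral_equals_matrix_exponential(self, demo_switching, t):
        sd = ld.spectral_decomposition(demo_switching)
        q_expm = ld.subpopulation_probabilities(demo_switching, t)
        assert np.max(np.abs(sd.subpopulations(t) - q_expm)) < 1e-10

    def test_two_state_biexponential_oracle(self, demo_switching):
        for t in (0.1, 0.7, 2.0, 5.0):
            q = ld.subpopulation_probabilities(demo_switching, t)
            assert np.max(np.abs(q - two_state_biexponential(demo_switching, t))) < 1e-10

    def test_initial_condition(self, demo_switching):
        assert np.allclose(ld.subpopulation_probabilities(demo_switching, 0.0),
                           demo_switching.q, atol=1e-14)

    def test_no_transition_states_decay_independently(self, demo_static):
        t = 2.3
        q = ld.subpopulation_probabilities(demo_static, t)
        assert np.allclose(q, demo_static.q * np.exp(-demo_static.lam * t),
                           atol=1e-12)

    def test_late_log_slopes_converge_to_slowest_eigenvalue(self, demo_switching):
        K = ld.build_rate_matrix(demo_switching)
        slowest = np.max(np.linalg.eigvals(K).real)
        t = np.array([30.0, 30.5])
        Q = ld.subpopulation_probabilities(demo_switching, t)
        slopes = np.diff(np.log(Q), axis=0)[0] / 0.5
        assert np.allclose(slopes, slowest, atol=1e-6)

    def test_reduction_chain(self, demo_switching, demo_static, demo_1state):
        # switching model with k=0 reproduces the static model; the static
        # model with a single state reproduces single-exponential survival
        m = demo_switching.with_(k=np.zeros((2, 2)))
        for t in (0.3, 1.0, 3.0):
            assert ld.residence_probability(m, t) == pytest.approx(
                ld.residence_probability(demo_static, t), abs=1e-12)
        m1 = KineticModel(D=demo_static.D[:1], lam=[1.0], q=[1.0], eps=0.04)
        assert ld.residence_probability(m1, 0.8) == pytest.approx(
            ld.residence_probability(demo_1state, 0.8), abs=1e-12)


@st.composite
def kinetic_models(draw):
    n = draw(st.integers(1, 3))
    rate = st.floats(0.0, 5.0, allow_nan=False)
    D = [draw(st.floats(0.0, 1.0, allow_nan=False)) for _ in range(n)]
    lam = [draw(rate) for _ in range(n)]
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                k[i, j] = draw(rate)
    raw_q = [draw(st.floats(0.01, 1.0, allow_nan=False)) for _ in range(n)]
    q = np.array(raw_q) / np.sum(raw_q)
    return KineticModel(D=D, lam=lam, k=k, q=q)


class TestInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(kinetic_models())
    def test_subpopulations_sum_to_survival(self, model):
        t_grid = np.array([0.0, 0.2, 1.0, 4.0])
        Q = ld.subpopulation_probabilities(model, t_grid)
        R = ld.residence_probability(model, t_grid)
        assert np.max(np.abs(Q.sum(axis=1) - R)) < 1e-12
        assert R[0] == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(kinetic_models())
    def test_survival_monotone_nonincreasing(self, model):
        t_grid = np.linspace(0.0, 5.0, 21)
        R = ld.residence_probability(model, t_grid)
        assert np.all(np.diff(R) <= 1e-12)


class TestPositionPDF:
    def test_single_state_matches_gaussian(self, demo_1state):
        r = np.linspace(0.0, 0.5, 80)
        pdf = ld.position_pdf(demo_1state, 0.3, r)
        s2 = 0.01 * 0.3 + 0.04**2
        closed = np.exp(-1.0 * 0.3) / (4 * np.pi * s2) * np.exp(-r**2 / (4 * s2))
        assert np.max(np.abs(pdf.total - closed)) < 1e-6

    @pytest.mark.parametrize("t", [0.1, 0.3, 1.0, 5.0])
    def test_planar_integral_equals_survival(self, demo_switching, t):
        pdf = ld.position_pdf(demo_switching, t)
        assert pdf.planar_integral() == pytest.approx(
            ld.residence_probability(demo_switching, t), abs=1e-4)

    def test_no_transition_equals_gaussian_mixture(self, demo_static):
        t = 0.5
        r = np.linspace(0.0, 1.0, 60)
        pdf = ld.position_pdf(demo_static, t, r)
        mix = np.zeros_like(r)
        for qj, Dj, lamj in zip(demo_static.q, demo_static.D, demo_static.lam):
            s2 = Dj * t + demo_static.eps**2
            mix += qj * np.exp(-lamj * t) / (4 * np.pi * s2) * np.exp(-r**2 / (4 * s2))
        assert np.max(np.abs(pdf.total - mix)) < 1e-6

    def test_per_state_integrals_match_subpopulations(self, demo_switching):
        pdf = ld.position_pdf(demo_switching, 1.0)
        Q = ld.subpopulation_probabilities(demo_switching, 1.0)
        for j in range(2):
            integral = np.trapezoid(2 * np.pi * pdf.r * pdf.per_state[j], pdf.r)
            assert integral == pytest.approx(Q[j], abs=1e-4)


class TestDisplacementPDF:
    def test_normalization_and_second_moment(self):
        r = np.linspace(0.0, 2.0, 40001)
        f = ld.displacement_pdf([0.05], [1.0], eps=0.04, dt=1 / 30, dr=r)
        s2 = 0.05 / 30 + 0.04**2
        assert np.trapezoid(f, r) == pytest.approx(1.0, abs=1e-6)
        assert np.trapezoid(f * r**2, r) == pytest.approx(4 * s2, rel=1e-6)

    def test_three_component_mixture_normalized(self):
        # the pooled three-state displacement mixture of PTEN in
        # non-polarized cells
        r = np.linspace(0.0, 3.0, 60001)
        f = ld.displacement_pdf([0.035, 0.133, 0.693], [0.479, 0.480, 0.041],
                                eps=0.036, dt=0.033, dr=r)
        assert np.trapezoid(f, r) == pytest.approx(1.0, abs=1e-5)
        mean_s2 = np.trapezoid(f * r**2, r) / 4.0
        expected = np.dot([0.479, 0.480, 0.041],
                          displacement_scale2([0.035, 0.133, 0.693], 0.036, 0.033))
        assert mean_s2 == pytest.approx(expected, rel=1e-4)

    def test_degenerate_point_mass(self):
        f = ld.displacement_pdf([0.0], [1.0], eps=0.0, dt=1 / 30,
                                dr=np.array([0.0, 0.1]))
        assert np.isinf(f[0]) and f[1] == 0.0


class TestLifetime:
    def test_single_state(self):
        m = KineticModel(D=[0.1], lam=[2.0], q=[1.0])
        assert ld.mean_binding_lifetime(m) == pytest.approx(0.5, abs=1e-12)

    def test_equals_survival_integral(self, demo_switching):
        tau = ld.mean_binding_lifetime(demo_switching)
        integral, _ = quad(lambda t: ld.residence_probability(demo_switching, t),
                           0, np.inf, limit=200)
        assert tau == pytest.approx(integral, abs=1e-8)

    def test_no_exit_raises(self):
        m = KineticModel(D=[0.1], lam=[0.0], q=[1.0])
        with pytest.raises(InfiniteLifetimeError):
            ld.mean_binding_lifetime(m)


def test_photobleach_decay():
    assert ld.photobleach_decay(100.0, 0.1, 0.0) == pytest.approx(100.0)
    half_life = np.log(2) / 0.1
    assert ld.photobleach_decay(100.0, 0.1, half_life) == pytest.approx(50.0)
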
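"""Variational engine: value matrices, fixed-point updates, free energy."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import roots_genlaguerre

from trustinfer import (
    BeliefState,
    GenerativeModel,
    ObservationModel,
    OutcomePrior,
    PrecisionPrior,
    StateSpace,
    TransitionModel,
    compute_value_matrix,
    free_energy,
    infer,
    kl_divergence,
    sample_action,
    step_evidence,
    update_policies,
    update_precision,
    update_states,
)
from trustinfer.engine import _value_matrix


def quadrature_evidence(model, obs_label, n_nodes=64):
    """Independent oracle: enumerate (state, policy), integrate gamma by
    64-node generalized Gauss-Laguerre quadrature."""
    a, lam = model.prec.shape, model.prec.rate
    x, w = roots_genlaguerre(n_nodes, a - 1.0)
    gammas = x / lam
    weights = w / math.gamma(a)
    Q = _value_matrix(model, model.policies).Q
    prior = model.initial_belief
    ev = model.obs.A[model.space.observable_index(obs_label), :]
    num = den = 0.0
    for g, wt in zip(gammas, weights):
        boltz = np.exp(g * Q)
        den += wt * float((boltz * prior[None, :]).sum())
        num += wt * float((boltz * (ev * prior)[None, :]).sum())
    return num / den


def two_state_model(goal, pages, policies, prior=(1.0, 0.0), prec=(8.0, 1.0)):
    space = StateSpace((("o0", "t0"), ("o1", "t1")), ("o0", "o1"))
    return GenerativeModel(
        space=space,
        obs=ObservationModel(np.eye(2)),
        trans=TransitionModel(np.asarray(pages, float), control_labels=("a", "b")[: len(pages)]),
        goal=OutcomePrior(np.asarray(goal, float)),
        prec=PrecisionPrior(*prec),
        horizon=1,
        initial_belief=np.asarray(prior, float),
        policies=policies,
    )


# ----------------------------------------------------------------- value matrix
def test_value_matrix_zero_when_every_prediction_hits_the_goal():
    goal = [0.4, 0.6]
    page = np.tile(np.asarray(goal)[:, None], (1, 2))
    model = two_state_model(goal, [page], (("a",),))
    vm = compute_value_matrix(model)
    np.testing.assert_allclose(vm.Q, 0.0, atol=1e-12)


def test_value_matrix_matches_hand_computed_divergences():
    goal = [0.5, 0.5]
    page_a = np.tile(np.array([[0.5], [0.5]]), (1, 2))  # predicts the goal
    page_b = np.tile(np.array([[1.0], [0.0]]), (1, 2))  # KL = ln 2
    model = two_state_model(goal, [page_a, page_b], (("a",), ("b",)))
    vm = compute_value_matrix(model)
    np.testing.assert_allclose(vm.Q[0], 0.0, atol=1e-12)
    np.testing.assert_allclose(vm.Q[1], -math.log(2), atol=1e-12)


def test_trust_value_matrix_nonpositive_and_finite(trust_model):
    vm = compute_value_matrix(trust_model)
    assert vm.Q.shape == (2, 10)
    assert np.all(vm.Q <= 1e-12)
    assert np.all(np.isfinite(vm.Q))


# ---------------------------------------------------------------- state update
def test_uninformative_evidence_returns_prior(make_fixture):
    model = make_fixture(seed=9)
    A = np.full((3, 4), 1.0 / 3.0)
    flat = GenerativeModel(
        space=model.space,
        obs=ObservationModel(A),
        trans=model.trans,
        goal=model.goal,
        prec=model.prec,
        horizon=1,
        initial_belief=np.ones(4) / 4,
        policies=model.policies,
    )
    b = BeliefState()
    update_states(b, "o0", flat)
    np.testing.assert_allclose(b.s_hat[-1], np.ones(4) / 4, atol=1e-12)


def test_state_update_without_value_bias_is_exact_bayes(make_fixture):
    model = make_fixture(seed=13)
    b = BeliefState()
    b.s_hat = [model.initial_belief.copy(), np.zeros(4)]
    update_states(b, "o2", model, previous_action="u1")
    prior = model.trans.page("u1") @ model.initial_belief
    expected = prior * model.obs.A[2, :]
    expected /= expected.sum()
    np.testing.assert_allclose(b.s_hat[-1], expected, atol=1e-12)


def test_defection_observation_implicates_the_antisocial_trait(trust_model):
    """After mutual defection from an agnostic prior, belief settles on the
    dd states with more mass on the antisocial partner."""
    b = BeliefState()
    b.s_hat = [trust_model.initial_belief.copy(), np.zeros(10)]
    update_states(b, "dd", trust_model, previous_action="d")
    s = b.s_hat[-1]
    i_p = trust_model.space.hidden_index(("dd", "p"))
    i_n = trust_model.space.hidden_index(("dd", "n"))
    assert s[i_p] + s[i_n] == pytest.approx(1.0, abs=1e-9)
    assert s[i_n] > s[i_p]


# --------------------------------------------------------------- policy update
def test_policy_update_uniform_under_zero_values():
    b = BeliefState(gamma_posterior=(8.0, 1.0))
    b.s_hat = [np.array([0.25, 0.75])]
    update_policies(b, np.zeros((3, 2)))
    np.testing.assert_allclose(b.u_hat, np.ones(3) / 3, atol=1e-12)


def test_policy_update_closed_form_odds():
    b = BeliefState(gamma_posterior=(1.0, 1.0))  # gamma_hat = 1
    b.s_hat = [np.array([1.0, 0.0])]
    Q = np.array([[0.0, 0.0], [-math.log(2), -math.log(2)]])
    update_policies(b, Q)
    np.testing.assert_allclose(b.u_hat, [2 / 3, 1 / 3], atol=1e-12)


def test_trust_round_start_favors_cooperation(trust_model):
    b = infer(trust_model, ["start"])
    assert b.u_hat[0] > 0.5


# ------------------------------------------------------------ precision update
def test_precision_recovers_prior_mean_under_zero_values():
    b = BeliefState()
    b.s_hat = [np.array([0.5, 0.5])]
    b.u_hat = np.array([0.5, 0.5])
    update_precision(b, np.zeros((2, 2)), PrecisionPrior(8.0, 1.0))
    assert b.gamma_hat == pytest.approx(8.0)


def test_precision_closed_form_halving():
    b = BeliefState()
    b.s_hat = [np.array([1.0, 0.0])]
    b.u_hat = np.array([1.0, 0.0])
    Q = np.array([[-1.0, -1.0], [-1.0, -1.0]])
    update_precision(b, Q, PrecisionPrior(8.0, 1.0))
    assert b.gamma_hat == pytest.approx(4.0)


def test_precision_monotone_in_expected_value(rng):
    prior = PrecisionPrior(8.0, 1.0)
    Q = -rng.random((3, 4))
    b = BeliefState()
    b.s_hat = [rng.dirichlet(np.ones(4))]
    b.u_hat = rng.dirichlet(np.ones(3))
    update_precision(b, Q, prior)
    base = b.gamma_hat
    for i in range(3):
        for j in range(4):
            Q2 = Q.copy()
            Q2[i, j] += 0.3  # raise one value (still <= 0)
            Q2 = np.minimum(Q2, 0.0)
            update_precision(b, Q2, prior)
            assert b.gamma_hat >= base - 1e-12


# -------------------------------------------------------------------- inference
def test_uninformative_observation_leaves_prior_beliefs(make_fixture):
    model = make_fixture(seed=21, n_controls=1)
    A = np.full((3, 4), 1.0 / 3.0)
    flat = GenerativeModel(
        space=model.space,
        obs=ObservationModel(A),
        trans=model.trans,
        goal=model.goal,
        prec=model.prec,
        horizon=1,
        initial_belief=model.initial_belief,
        policies=model.policies,
    )
    b = infer(flat, ["o0"], fixed_gamma=0.0)
    np.testing.assert_allclose(b.s_hat[0], flat.initial_belief, atol=1e-12)


def test_free_energy_upper_bounds_exact_evidence(make_fixture):
    """F at convergence >= -ln P(o|m), the evidence computed by enumeration
    plus Gauss-Laguerre quadrature over precision."""
    for seed in range(8):
        model = make_fixture(seed=seed, n_states=5, n_observations=4, n_controls=2, horizon=2)
        obs = model.space.observable_labels[seed % 4]
        b = infer(model, [obs])
        exact = -math.log(quadrature_evidence(model, obs))
        assert b.fe_trace[-1] >= exact - 1e-10


def test_free_energy_tight_at_exact_posterior_fixed_gamma(make_fixture):
    """Single remaining policy at fixed precision: the posterior factorizes,
    and supplying it makes F equal -ln P(o|m) to 1e-8."""
    for gamma in (0.0, 1.3):
        model = make_fixture(seed=31, n_states=5, n_observations=4, n_controls=1)
        obs = "o2"
        b = infer(model, [obs], fixed_gamma=gamma)
        Q = b.value_matrix
        exact_post = (
            model.initial_belief
            * model.obs.A[model.space.observable_index(obs), :]
            * np.exp(gamma * Q[0])
        )
        exact_post /= exact_post.sum()
        b.s_hat[-1] = exact_post
        F = free_energy(b, [obs], model)
        assert F == pytest.approx(-math.log(step_evidence(model, obs, fixed_gamma=gamma)), abs=1e-8)
        # and the engine converged to the same point on its own
        np.testing.assert_allclose(b.s_hat[-1], exact_post, atol=1e-8)


def test_zero_precision_inference_is_exact_filtering(make_fixture):
    model = make_fixture(seed=11, n_states=5, n_observations=4, n_controls=2, horizon=3)
    obs_seq = ["o0", "o2", "o1", "o3"]
    acts = ["u1", "u0", "u1"]
    b = infer(model, obs_seq, actions=acts, fixed_gamma=0.0)
    s = model.initial_belief.copy()
    for t, o in enumerate(obs_seq):
        if t > 0:
            s = model.trans.page(acts[t - 1]) @ s
        s = s * model.obs.A[model.space.observable_index(o), :]
        s = s / s.sum()
        np.testing.assert_allclose(b.s_hat[t], s, atol=1e-10)


def test_free_energy_trace_is_monotone(trust_model, make_fixture):
    models_obs = [(trust_model, ["start"])]
    for seed in range(5):
        m = make_fixture(seed=seed, n_states=5, n_observations=3, horizon=2)
        models_obs.append((m, ["o1"]))
    for model, obs in models_obs:
        b = infer(model, obs)
        for seg in b.fe_segments:
            assert np.all(np.diff(seg) <= 1e-8)


def test_perturbed_beliefs_raise_free_energy(make_fixture, rng):
    model = make_fixture(seed=17, n_states=5, n_observations=4)
    obs = "o1"
    b = infer(model, [obs])
    F_star = free_energy(b, [obs], model)
    s_star, u_star = b.s_hat[-1].copy(), b.u_hat.copy()
    for _ in range(10):
        s = s_star + 0.05 * rng.dirichlet(np.ones(5))
        b.s_hat[-1] = s / s.sum()
        u = u_star + 0.05 * rng.dirichlet(np.ones(len(u_star)))
        b.u_hat = u / u.sum()
        assert free_energy(b, [obs], model) > F_star
        b.s_hat[-1], b.u_hat = s_star.copy(), u_star.copy()


def test_inference_is_deterministic(trust_model):
    b1 = infer(trust_model, ["start", "cd"], actions=["c"])
    b2 = infer(trust_model, ["start", "cd"], actions=["c"])
    for s1, s2 in zip(b1.s_hat, b2.s_hat):
        assert np.array_equal(s1, s2)
    assert b1.gamma_posterior == b2.gamma_posterior
    assert b1.fe_trace == b2.fe_trace


def test_impossible_observation_raises(trust_model):
    from trustinfer.engine import InferenceError

    zero_A = trust_model.obs.A.copy()
    zero_A[2, :] = 0.0
    zero_A[0, :] += trust_model.obs.A[2, :]
    broken = GenerativeModel(
        space=trust_model.space,
        obs=ObservationModel(zero_A),
        trans=trust_model.trans,
        goal=trust_model.goal,
        prec=trust_model.prec,
        horizon=1,
        initial_belief=trust_model.initial_belief,
        policies=trust_model.policies,
    )
    with pytest.raises(InferenceError):
        infer(broken, ["dc"])


# -------------------------------------------------------------- action sampling
def test_point_mass_always_selects_that_policy(trust_model, rng):
    b = infer(trust_model, ["start"])
    b.u_hat = np.array([1.0, 0.0])
    assert all(sample_action(b, rng) == "c" for _ in range(50))


def test_sampling_frequencies_match_binomial(trust_model, rng):
    b = infer(trust_model, ["start"])
    b.u_hat = np.array([0.5, 0.5])
    n = 10_000
    draws = sum(sample_action(b, rng) == "c" for _ in range(n))
    assert abs(draws - 0.5 * n) < 3 * math.sqrt(n * 0.25)


def test_sampling_frequencies_chi_square(trust_model, rng):
    b = infer(trust_model, ["start"])
    b.u_hat = np.array([0.7, 0.3])
    n = 10_000
    c = sum(sample_action(b, rng) == "c" for _ in range(n))
    _, p = stats.chisquare([c, n - c], [0.7 * n, 0.3 * n])
    assert p > 0.001
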
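"""Variational engine: fixed-point belief updates minimizing free energy.

Beliefs are factorized (mean field) into sufficient statistics
``mu = (s_hat_0 ... s_hat_t, u_hat, gamma_hat)``: categorical beliefs about
hidden states at each observed time, a categorical belief over the remaining
policies, and a gamma belief over precision.  One observation step couples

    state  s_hat  <- sigma( ln evidence + ln prior + gamma_hat * Q' u_hat )
    policy u_hat  <- sigma( gamma_hat * Q s_hat )
    prec   q(gamma) = Gamma(shape = alpha, rate = 1/theta - u_hat' Q s_hat)

where ``Q[i, j] = -KL[ P(s_T | s_j, policy_i) || P(s_T | m) ]`` is the value
matrix.  The three updates are cycled until the free energy stops falling.

The step generative model treats the Boltzmann policy factor
``exp(gamma * Q)`` with a single joint normalizing constant over
(state, policy, gamma), under which the three updates above are *exact*
coordinate descent on the variational free energy — the trace is therefore
monotone non-increasing by construction — and the step evidence has a closed
form through the gamma moment generating function.  Conditioned on a state
and a precision, the implied policy prior is exactly the softmax of
``-gamma * KL``.

Beliefs about states never look forward past the current time: each new
observation is assimilated against the predictive prior ``B(action) s_hat``
(filtering).  When no decisions remain (the horizon is exhausted) the state
update carries no prospective value term; precision is then re-evaluated
against the realized outcome's goal log-probability, i.e. confidence tracks
how close to the goals the episode actually landed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .generative import (
    GOAL_FLOOR,
    GenerativeModel,
    PrecisionPrior,
    ValidationError,
    kl_divergence,
    predicted_final_distribution,
    softmax,
)

__all__ = [
    "InferenceError",
    "BeliefState",
    "ValueMatrix",
    "compute_value_matrix",
    "update_states",
    "update_policies",
    "update_precision",
    "infer",
    "free_energy",
    "step_evidence",
    "sample_action",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 64


class InferenceError(RuntimeError):
    """The observations cannot be assimilated under the model."""


@dataclass(frozen=True)
class ValueMatrix:
    """Policy values: rows = policies, columns = current hidden states.

    ``Q[i, j] = -KL[predicted final distribution || goal prior] <= 0`` with
    equality iff policy i from state j predicts exactly the goal prior.
    """

    Q: np.ndarray
    policies: tuple

    def __post_init__(self):
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "policies", tuple(tuple(p) for p in self.policies))


def _floored_goal(model: GenerativeModel) -> np.ndarray:
    g = np.maximum(model.goal.p_final, GOAL_FLOOR)
    return g / g.sum()


def _value_matrix(model: GenerativeModel, policies) -> ValueMatrix:
    goal = _floored_goal(model)
    n = model.space.n_hidden
    Q = np.zeros((len(policies), n))
    for j in range(n):
        point = np.zeros(n)
        point[j] = 1.0
        for i, pol in enumerate(policies):
            if len(pol) == 0:
                # realized value of already being in state j at the horizon
                Q[i, j] = math.log(goal[j])
            else:
                pred = predicted_final_distribution(model, point, pol)
                Q[i, j] = -kl_divergence(pred, goal)
    return ValueMatrix(Q, policies)


def compute_value_matrix(model: GenerativeModel) -> ValueMatrix:
    """Value matrix for the model's declared (full-horizon) policy set."""
    return _value_matrix(model, model.policies)


@dataclass
class BeliefState:
    """Variational sufficient statistics with a free-energy trace.

    ``s_hat`` holds one distribution per assimilated observation;
    ``gamma_posterior`` is the (shape, rate) of the gamma belief and
    ``gamma_hat = shape / rate`` its mean.  ``fe_trace`` is the per-sweep
    free energy of the most recent observation step (non-increasing);
    ``fe_segments`` keeps every step's trace.  ``surprise`` accumulates the
    converged step free energies, approximating ``-ln P(observations | m)``.
    """

    s_hat: list = field(default_factory=list)
    u_hat: np.ndarray | None = None
    gamma_posterior: tuple = (8.0, 1.0)
    policies: tuple = ()
    value_matrix: np.ndarray | None = None
    fe_trace: list = field(default_factory=list)
    fe_segments: list = field(default_factory=list)
    surprise: float = 0.0
    converged: bool = True
    n_iterations: int = 0
    fixed_gamma: float | None = None
    step_prior_cache: np.ndarray | None = None

    @property
    def gamma_hat(self) -> float:
        if self.fixed_gamma is not None:
            return self.fixed_gamma
        shape, rate = self.gamma_posterior
        return shape / rate

    def trait_posterior(self, model: GenerativeModel) -> dict:
        """Current beliefs marginalized over the observable component."""
        return model.space.trait_marginal(self.s_hat[-1])


def _step_prior(b: BeliefState, model: GenerativeModel, previous_action) -> np.ndarray:
    if len(b.s_hat) <= 1:
        return np.asarray(model.initial_belief, dtype=float)
    if previous_action is None:
        if model.trans.n_controls == 1:
            previous_action = model.trans.control_labels[0]
        else:
            raise ValidationError("previous_action required when the model has several controls")
    return model.trans.page(previous_action) @ b.s_hat[-2]


def _evidence_vector(model: GenerativeModel, o_now) -> np.ndarray:
    idx = o_now if isinstance(o_now, (int, np.integer)) else model.space.observable_index(o_now)
    ev = model.obs.evidence(int(idx))
    if not np.any(ev > 0):
        raise InferenceError(f"observation {o_now!r} is impossible under every hidden state")
    return ev


def update_states(
    b: BeliefState, o_now, model: GenerativeModel, previous_action=None
) -> BeliefState:
    """Re-estimate the current state belief from evidence, prediction and value.

    Log-domain: ``s_hat <- sigma(ln evidence + ln prior + gamma_hat Q' u_hat)``
    with the transition prior replaced by the initial belief at t = 0.  With
    ``gamma_hat = 0`` (or no remaining policies) this is exact Bayes.
    """
    if not b.s_hat:
        b.s_hat.append(np.zeros(model.space.n_hidden))
    ev = _evidence_vector(model, o_now)
    prior = _step_prior(b, model, previous_action)
    with np.errstate(divide="ignore"):
        logpost = np.log(ev) + np.log(prior)
    if b.value_matrix is not None and b.u_hat is not None and len(b.u_hat):
        logpost = logpost + b.gamma_hat * (b.value_matrix.T @ b.u_hat)
    finite = logpost > -np.inf
    if not np.any(finite):
        raise InferenceError(f"observation {o_now!r} has zero posterior support")
    post = np.zeros_like(logpost)
    post[finite] = np.exp(logpost[finite] - logpost[finite].max())
    b.s_hat[-1] = post / post.sum()
    return b


def update_policies(b: BeliefState, Q: ValueMatrix | np.ndarray) -> BeliefState:
    """``u_hat <- sigma(gamma_hat * Q s_hat)`` over the remaining policies."""
    Qm = Q.Q if isinstance(Q, ValueMatrix) else np.asarray(Q, dtype=float)
    b.u_hat = softmax(Qm @ b.s_hat[-1], beta=b.gamma_hat)
    return b


def update_precision(
    b: BeliefState, Q: ValueMatrix | np.ndarray, prior: PrecisionPrior
) -> BeliefState:
    """Conjugate precision update: shape stays at alpha, the rate absorbs value.

    ``rate = 1/theta - u_hat' Q s_hat``; since Q <= 0 the rate stays positive
    and ``gamma_hat = alpha / rate`` is capped by the prior mean, increasing
    monotonically with expected value.
    """
    if b.fixed_gamma is not None:
        return b
    Qm = Q.Q if isinstance(Q, ValueMatrix) else np.asarray(Q, dtype=float)
    value = float(b.u_hat @ (Qm @ b.s_hat[-1]))
    rate = prior.rate - value
    if rate <= 0:
        raise InferenceError("precision rate became non-positive; value matrix must be <= 0")
    b.gamma_posterior = (prior.shape, rate)
    return b


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------


def _gamma_kl(shape: float, rate: float, rate0: float) -> float:
    """KL between two gamma densities sharing a shape parameter."""
    return shape * (math.log(rate / rate0) + (rate0 - rate) / rate)


def _log_joint_constant(
    prior: np.ndarray, Q: np.ndarray, prec: PrecisionPrior, fixed_gamma: float | None
) -> float:
    """ln of the joint normalizer C = sum_{s,i} prior(s) E_p(gamma)[exp(gamma Q(i,s))].

    The gamma expectation is the MGF ``(rate0 / (rate0 - q))^shape``, finite
    because Q <= 0.
    """
    if fixed_gamma is None:
        mgf = (prec.rate / (prec.rate - Q)) ** prec.shape
    else:
        mgf = np.exp(fixed_gamma * Q)
    return float(np.log((mgf * prior[None, :]).sum()))


def _step_free_energy(
    b: BeliefState, ev: np.ndarray, prior: np.ndarray, model: GenerativeModel
) -> float:
    """Free energy of the current observation step given the current beliefs."""
    s = b.s_hat[-1]
    support = s > 0
    if np.any(ev[support] <= 0) or np.any(prior[support] <= 0):
        return math.inf
    F = float(
        np.sum(s[support] * (np.log(s[support]) - np.log(ev[support]) - np.log(prior[support])))
    )
    if b.value_matrix is None:
        return F
    u = b.u_hat
    usup = u > 0
    F += float(np.sum(u[usup] * np.log(u[usup])))
    F -= b.gamma_hat * float(u @ (b.value_matrix @ s))
    if b.fixed_gamma is None:
        shape, rate = b.gamma_posterior
        F += _gamma_kl(shape, rate, model.prec.rate)
    F += _log_joint_constant(prior, b.value_matrix, model.prec, b.fixed_gamma)
    return F


def free_energy(b: BeliefState, observations, model: GenerativeModel) -> float:
    """Evaluate ``E_Q[ln Q - ln P]`` for the latest observation step.

    Upper-bounds the step surprise ``-ln P(o_t | o_<t, m)``; tight (to
    numerical precision) when the supplied beliefs are the exact posterior
    and the posterior factorizes (e.g. a single remaining policy at fixed
    precision).
    """
    obs = list(observations)
    if not obs or len(b.s_hat) < len(obs):
        raise ValidationError("belief state does not cover the observation sequence")
    ev = _evidence_vector(model, obs[-1])
    if len(obs) == 1:
        prior = np.asarray(model.initial_belief, dtype=float)
    else:
        prior = b.step_prior_cache  # set by infer for multi-step states
    return _step_free_energy(b, ev, prior, model)


def step_evidence(
    model: GenerativeModel,
    observation,
    prior=None,
    policies=None,
    fixed_gamma: float | None = None,
) -> float:
    """Exact step evidence ``P(o | m)`` of one observation, in closed form.

    Marginalizes states, policies and (via the gamma MGF) precision of the
    step joint.  Serves as the reference for the free-energy bound.
    """
    prior = np.asarray(model.initial_belief if prior is None else prior, dtype=float)
    pols = tuple(policies) if policies is not None else model.policies
    Q = _value_matrix(model, pols).Q
    ev = _evidence_vector(model, observation)
    if fixed_gamma is None:
        mgf = (model.prec.rate / (model.prec.rate - Q)) ** model.prec.shape
    else:
        mgf = np.exp(fixed_gamma * Q)
    C = (mgf * prior[None, :]).sum()
    return float((mgf * (ev * prior)[None, :]).sum() / C)


# ---------------------------------------------------------------------------
# Full inference
# ---------------------------------------------------------------------------


def infer(
    model: GenerativeModel,
    observations,
    actions=None,
    init: BeliefState | None = None,
    fixed_gamma: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> BeliefState:
    """Assimilate a sequence of observations by variational message passing.

    For each observation the engine cycles state -> policy -> precision
    updates until the step free energy changes by less than ``tol`` or
    ``max_iter`` sweeps elapse (the state is then flagged non-converged).
    ``actions[t]`` is the realized control between observations t and t+1
    (optional when the model has a single control).  Deterministic given its
    inputs; only :func:`sample_action` consumes randomness.
    """
    obs = list(observations)
    if not obs:
        raise ValidationError("need at least one observation")
    if len(obs) > model.horizon + 1:
        raise ValidationError("more observations than the model horizon admits")
    acts = list(actions) if actions is not None else [None] * (len(obs) - 1)
    if len(acts) != len(obs) - 1:
        raise ValidationError("need exactly one action between consecutive observations")

    b = init if init is not None else BeliefState(
        gamma_posterior=(model.prec.shape, model.prec.rate)
    )
    b.fixed_gamma = fixed_gamma
    b.converged = True
    b.fe_segments = []
    b.surprise = 0.0
    b.n_iterations = 0
    elapsed0 = len(b.s_hat)

    for t, o in enumerate(obs):
        remaining = model.horizon - (elapsed0 + t)
        prev = acts[t - 1] if t > 0 else None
        ev = _evidence_vector(model, o)
        prior = _step_prior_for(b, model, prev)
        b.s_hat.append(np.zeros(model.space.n_hidden))
        b.step_prior_cache = prior

        if remaining > 0:
            pols = model.policy_suffixes(t)
            vm = _value_matrix(model, pols)
            b.policies = pols
            b.value_matrix = vm.Q
            b.u_hat = np.full(len(pols), 1.0 / len(pols))
            if fixed_gamma is None:
                b.gamma_posterior = (model.prec.shape, model.prec.rate)
            trace = []
            prev_F = math.inf
            for it in range(max_iter):
                update_states(b, o, model, prev)
                update_policies(b, vm)
                update_precision(b, vm, model.prec)
                F = _step_free_energy(b, ev, prior, model)
                trace.append(F)
                b.n_iterations += 1
                if abs(prev_F - F) < tol:
                    break
                prev_F = F
            else:
                b.converged = False
            b.fe_segments.append(trace)
            b.fe_trace = trace
            b.surprise += trace[-1]
        else:
            # horizon exhausted: no prospective term in the state update
            b.policies = ((),)
            b.value_matrix = None
            b.u_hat = np.ones(1)
            update_states(b, o, model, prev)
            F = _step_free_energy(b, ev, prior, model)
            b.fe_segments.append([F])
            b.fe_trace = [F]
            b.surprise += F
            # confidence re-evaluated against the realized outcome's goal value
            if fixed_gamma is None:
                realized = _value_matrix(model, ((),)).Q
                b.gamma_posterior = (
                    model.prec.shape,
                    model.prec.rate - float(realized[0] @ b.s_hat[-1]),
                )
    return b


def _step_prior_for(b: BeliefState, model: GenerativeModel, previous_action) -> np.ndarray:
    if not b.s_hat:
        return np.asarray(model.initial_belief, dtype=float)
    if previous_action is None:
        if model.trans.n_controls == 1:
            previous_action = model.trans.control_labels[0]
        else:
            raise ValidationError("previous_action required when the model has several controls")
    return model.trans.page(previous_action) @ b.s_hat[-1]


def sample_action(b: BeliefState, rng: np.random.Generator):
    """Draw a policy from ``u_hat`` and return its first control state.

    Inverse-CDF over policies in declared order with a single uniform draw,
    so identical seeds reproduce identical choices.
    """
    u = np.asarray(b.u_hat, dtype=float)
    if u.ndim != 1 or not math.isclose(u.sum(), 1.0, abs_tol=1e-6):
        raise ValidationError("u_hat must be a normalized distribution")
    idx = int(np.searchsorted(np.cumsum(u), rng.random(), side="right"))
    idx = min(idx, len(u) - 1)
    pol = b.policies[idx]
    if not pol:
        raise ValidationError("no decisions remain to sample")
    return pol[0]
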
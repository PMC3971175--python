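"""Domain types and probability algebra for discrete active-inference models.

An agent's world model is a discrete partially observed Markov decision
process augmented with two ingredients that make it an *active-inference*
model rather than a plain POMDP:

* a **goal prior** ``P(s_T | m)`` — a probability distribution over states at
  the planning horizon, obtained by pushing per-state returns through a
  softmax.  Utility is absorbed into prior belief: preferred outcomes are a
  priori more plausible.
* a **precision prior** ``P(gamma | m)`` — a gamma distribution over the
  inverse temperature that scales the value of policies.  Confidence that
  goals are attainable is itself inferred, not a free parameter.

The value of a policy is the negative Kullback-Leibler divergence between the
final-state distribution it predicts and the goal prior; the prior belief in
a policy is a Boltzmann distribution in that value at inverse temperature
``gamma``.

Everything here is pure in-memory model algebra on dense vectors ordered by
the :class:`StateSpace` label order.  Distributions are plain numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GOAL_FLOOR",
    "StateSpace",
    "ObservationModel",
    "TransitionModel",
    "OutcomePrior",
    "PrecisionPrior",
    "GenerativeModel",
    "ValidationError",
    "DivergenceUndefinedError",
    "softmax",
    "kl_divergence",
    "predicted_final_distribution",
    "policy_prior",
    "value_decomposition",
    "validate_model",
]

#: Floor substituted for exact zeros in the goal prior before taking logs, so
#: the policy value stays defined for arbitrary user models.  States the model
#: marks as never-an-outcome keep probability zero in the prior itself; the
#: floor only guards the log.
GOAL_FLOOR = 1e-16

_ATOL = 1e-9


class ValidationError(ValueError):
    """An input violated a structural precondition of the model algebra."""


class DivergenceUndefinedError(ValueError):
    """KL divergence requested where the second argument lacks support."""


def _as_dist(x, name: str = "distribution") -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValidationError(f"{name} contains non-finite entries")
    if np.any(p < -_ATOL):
        raise ValidationError(f"{name} has negative entries")
    s = p.sum()
    if not math.isclose(s, 1.0, abs_tol=1e-6):
        raise ValidationError(f"{name} sums to {s!r}, expected 1")
    return np.clip(p, 0.0, None) / s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSpace:
    """Ordered hidden-state and observation labels with two-way index maps.

    Each hidden label is a pair ``(observable, trait)``; every hidden state
    projects deterministically onto exactly one observable label.  When
    ``conserved_traits`` is set, transitions between states with different
    trait components are structurally forbidden (traits cannot change) and
    :func:`validate_model` enforces it.
    """

    hidden_labels: tuple
    observable_labels: tuple
    conserved_traits: bool = False

    def __post_init__(self):
        hid = tuple(tuple(h) for h in self.hidden_labels)
        obs = tuple(self.observable_labels)
        object.__setattr__(self, "hidden_labels", hid)
        object.__setattr__(self, "observable_labels", obs)
        if not hid or not obs:
            raise ValidationError("label lists must be non-empty")
        if len(set(hid)) != len(hid):
            raise ValidationError("duplicate hidden labels")
        if len(set(obs)) != len(obs):
            raise ValidationError("duplicate observable labels")
        for h in hid:
            if len(h) != 2:
                raise ValidationError(f"hidden label {h!r} is not a (observable, trait) pair")
            if h[0] not in obs:
                raise ValidationError(f"hidden label {h!r} maps to unknown observable {h[0]!r}")

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_labels)

    @property
    def n_observable(self) -> int:
        return len(self.observable_labels)

    def hidden_index(self, label) -> int:
        return self.hidden_labels.index(tuple(label))

    def observable_index(self, label) -> int:
        return self.observable_labels.index(label)

    def observable_of(self, hidden_label) -> str:
        return tuple(hidden_label)[0]

    def trait_of(self, hidden_label):
        return tuple(hidden_label)[1]

    def trait_marginal(self, dist: np.ndarray) -> dict:
        """Marginalize a hidden-state distribution over the observable component."""
        out: dict = {}
        for p, lab in zip(dist, self.hidden_labels):
            out[lab[1]] = out.get(lab[1], 0.0) + float(p)
        return out


@dataclass(frozen=True)
class ObservationModel:
    """Likelihood table A with rows = observations, columns = hidden states."""

    A: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))

    def evidence(self, obs_index: int) -> np.ndarray:
        """Likelihood P(o | s) of one observation, as a vector over states."""
        return self.A[obs_index, :]


@dataclass(frozen=True)
class TransitionModel:
    """Controlled transitions B, one column-stochastic page per control state.

    ``B[u]`` has columns = state at t, rows = state at t+1.
    """

    B: np.ndarray
    control_labels: tuple = ()

    def __post_init__(self):
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 3:
            raise ValidationError(f"B must be 3-D (control, to, from); got shape {B.shape}")
        object.__setattr__(self, "B", B)
        labels = tuple(self.control_labels) or tuple(range(B.shape[0]))
        if len(labels) != B.shape[0]:
            raise ValidationError("control_labels length does not match number of B pages")
        object.__setattr__(self, "control_labels", labels)

    @property
    def n_controls(self) -> int:
        return self.B.shape[0]

    def page(self, control) -> np.ndarray:
        if isinstance(control, (int, np.integer)) and control not in self.control_labels:
            return self.B[int(control)]
        return self.B[self.control_labels.index(control)]


@dataclass(frozen=True)
class OutcomePrior:
    """Goal prior over horizon states, with the returns that generated it.

    ``p_final`` is a normalized distribution; entries listed in
    ``never_outcome`` (e.g. starting states) are exactly zero.
    """

    p_final: np.ndarray
    beta: float = 1.0
    returns: np.ndarray | None = None
    never_outcome: tuple = ()

    def __post_init__(self):
        p = np.asarray(self.p_final, dtype=float)
        object.__setattr__(self, "p_final", p)
        if self.returns is not None:
            object.__setattr__(self, "returns", np.asarray(self.returns, dtype=float))
        if self.beta < 0:
            raise ValidationError("outcome sensitivity beta must be >= 0")

    def log_floor(self) -> np.ndarray:
        """log of the goal prior with zeros floored at GOAL_FLOOR."""
        return np.log(np.maximum(self.p_final, GOAL_FLOOR))


@dataclass(frozen=True)
class PrecisionPrior:
    """Gamma prior over policy precision, parameterized by (shape, scale)."""

    shape: float = 8.0
    scale: float = 1.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValidationError("gamma prior shape and scale must be strictly positive")

    @property
    def rate(self) -> float:
        return 1.0 / self.scale

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class GenerativeModel:
    """A complete discrete active-inference world model.

    ``policies`` is an ordered tuple of control-label sequences, each of
    length ``horizon`` (the number of decisions remaining at time 0).
    """

    space: StateSpace
    obs: ObservationModel
    trans: TransitionModel
    goal: OutcomePrior
    prec: PrecisionPrior
    horizon: int
    initial_belief: np.ndarray
    policies: tuple

    def __post_init__(self):
        object.__setattr__(self, "initial_belief", np.asarray(self.initial_belief, dtype=float))
        object.__setattr__(self, "policies", tuple(tuple(p) for p in self.policies))

    def policy_suffixes(self, elapsed: int) -> tuple:
        """Distinct policy tails of length ``horizon - elapsed``, in declared order."""
        n = self.horizon - elapsed
        if n <= 0:
            return ((),)
        seen, out = set(), []
        for p in self.policies:
            tail = p[len(p) - n:]
            if tail not in seen:
                seen.add(tail)
                out.append(tail)
        return tuple(out)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def softmax(values: Sequence[float], beta: float = 1.0) -> np.ndarray:
    """Gibbs distribution ``p_i ∝ exp(beta * v_i)`` over a vector of values.

    Computed in the log domain with max subtraction, so ``|beta * v|`` up to
    ~700 cannot overflow.  Adding a constant to all values leaves the output
    unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("softmax expects a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValidationError("softmax input must be finite")
    if not np.isfinite(beta) or beta < 0:
        raise ValidationError("beta must be finite and >= 0")
    z = beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence ``D_KL[p || q]`` between two distributions.

    ``0 * log(0/q)`` is treated as 0.  Raises
    :class:`DivergenceUndefinedError` where ``p`` has support but ``q`` does not.
    """
    p = _as_dist(p, "p")
    q = _as_dist(q, "q")
    if p.shape != q.shape:
        raise ValidationError("p and q must have the same length")
    support = p > 0
    if np.any(q[support] <= 0):
        raise DivergenceUndefinedError("q assigns zero probability where p has support")
    return float(np.sum(p[support] * (np.log(p[support]) - np.log(q[support]))))


def predicted_final_distribution(
    model: GenerativeModel, s_now, policy: Sequence
) -> np.ndarray:
    """Final-state distribution ``P(s_T | s_t, u~) = B(u_T)···B(u_t) s_now``."""
    s = np.asarray(s_now, dtype=float)
    if s.shape != (model.space.n_hidden,):
        raise ValidationError(
            f"state distribution has length {s.size}, model has {model.space.n_hidden} states"
        )
    for u in policy:
        page = model.trans.page(u)
        if page.shape[1] != s.size:
            raise ValidationError("transition page incompatible with state vector")
        s = page @ s
    tot = s.sum()
    if not math.isclose(tot, 1.0, abs_tol=1e-6):
        raise ValidationError("predicted distribution failed to normalize; check B pages")
    return s / tot


def _policy_values(model: GenerativeModel, s_now, policies) -> np.ndarray:
    """-KL between each policy's prediction and the goal prior (log-floored)."""
    goal = np.maximum(model.goal.p_final, GOAL_FLOOR)
    goal = goal / goal.sum()
    vals = np.empty(len(policies))
    for i, pol in enumerate(policies):
        pred = predicted_final_distribution(model, s_now, pol)
        vals[i] = -kl_divergence(pred, goal)
    return vals


def policy_prior(model: GenerativeModel, s_now, gamma: float) -> np.ndarray:
    """Prior over policies, ``P(u~ | s_t, gamma) ∝ exp(-gamma KL[pred || goal])``."""
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    vals = _policy_values(model, s_now, model.policies)
    return softmax(vals, beta=gamma)


def value_decomposition(model: GenerativeModel, s_now, policy) -> tuple[float, float]:
    """Split a policy's value into entropy and expected utility.

    Returns ``(H[pred], E_pred[ln goal])`` whose sum equals ``-KL[pred || goal]``:
    choosing by divergence is maximizing expected utility subject to keeping
    the predicted outcome dispersion as high as possible.
    """
    pred = predicted_final_distribution(model, s_now, policy)
    goal = np.maximum(model.goal.p_final, GOAL_FLOOR)
    goal = goal / goal.sum()
    support = pred > 0
    entropy = float(-np.sum(pred[support] * np.log(pred[support])))
    expected_utility = float(np.sum(pred * np.log(goal)))
    return entropy, expected_utility


def validate_model(model: GenerativeModel) -> list[str]:
    """Collect every violated structural invariant; empty list iff well-formed."""
    issues: list[str] = []
    space, A, B = model.space, model.obs.A, model.trans.B
    n, m = space.n_hidden, space.n_observable

    if A.shape != (m, n):
        issues.append(f"A has shape {A.shape}, expected ({m}, {n})")
    else:
        if np.any(A < 0) or np.any(A > 1):
            issues.append("A entries outside [0, 1]")
        bad = np.where(np.abs(A.sum(axis=0) - 1.0) > _ATOL)[0]
        for j in bad:
            issues.append(f"A column {j} sums to {A[:, j].sum():.6g}, expected 1")

    if B.shape[1:] != (n, n):
        issues.append(f"B pages have shape {B.shape[1:]}, expected ({n}, {n})")
    else:
        if np.any(B < 0) or np.any(B > 1):
            issues.append("B entries outside [0, 1]")
        for k in range(B.shape[0]):
            bad = np.where(np.abs(B[k].sum(axis=0) - 1.0) > _ATOL)[0]
            for j in bad:
                issues.append(
                    f"B page {model.trans.control_labels[k]!r} column {j} sums to "
                    f"{B[k, :, j].sum():.6g}, expected 1"
                )
        if space.conserved_traits:
            # traits cannot change: cross-trait transition mass must be exactly 0
            traits = [space.trait_of(h) for h in space.hidden_labels]
            for k in range(B.shape[0]):
                for i in range(n):
                    for j in range(n):
                        if traits[i] != traits[j] and B[k, i, j] != 0.0:
                            issues.append(
                                f"B page {model.trans.control_labels[k]!r} mixes traits: "
                                f"{space.hidden_labels[j]} -> {space.hidden_labels[i]}"
                            )

    g = model.goal.p_final
    if g.shape != (n,):
        issues.append(f"goal prior has length {g.size}, expected {n}")
    else:
        if np.any(g < 0):
            issues.append("goal prior has negative entries")
        if abs(g.sum() - 1.0) > _ATOL:
            issues.append(f"goal prior sums to {g.sum():.6g}, expected 1")
        for lab in model.goal.never_outcome:
            idx = space.hidden_index(lab)
            if g[idx] != 0.0:
                issues.append(f"never-an-outcome state {lab!r} has goal probability {g[idx]:.3g}")

    b0 = model.initial_belief
    if b0.shape != (n,):
        issues.append(f"initial belief has length {b0.size}, expected {n}")
    elif abs(b0.sum() - 1.0) > _ATOL or np.any(b0 < 0):
        issues.append("initial belief is not a normalized distribution")

    if model.horizon < 0:
        issues.append("horizon must be >= 0")
    if not model.policies:
        issues.append("policy list is empty")
    for p in model.policies:
        if len(p) != model.horizon:
            issues.append(f"policy {p!r} has length {len(p)}, expected horizon {model.horizon}")
        for u in p:
            if u not in model.trans.control_labels:
                issues.append(f"policy {p!r} uses unknown control {u!r}")

    return issues
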
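"""Seeded random model generation for testing and demonstration.

Generated models are small, dense and always structurally valid: Dirichlet
columns for the likelihood and transition tables, a strictly positive goal
prior, and the full control-sequence policy set for the requested horizon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .generative import (
    GenerativeModel,
    ObservationModel,
    OutcomePrior,
    PrecisionPrior,
    StateSpace,
    TransitionModel,
    ValidationError,
    validate_model,
)

__all__ = ["FixtureSpec", "generate_fixture"]

_MAX_POLICIES = 256


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and seed of one random model."""

    n_states: int = 3
    n_observations: int = 3
    n_controls: int = 2
    horizon: int = 1
    seed: int = 0
    b_sparsity: float = 0.0  # fraction of transition entries zeroed out
    precision_shape: float = 8.0
    precision_scale: float = 1.0

    def __post_init__(self):
        if min(self.n_states, self.n_observations, self.n_controls, self.horizon) < 1:
            raise ValidationError("all fixture counts must be >= 1")
        if not 0.0 <= self.b_sparsity < 1.0:
            raise ValidationError("b_sparsity must lie in [0, 1)")
        if self.n_controls ** self.horizon > _MAX_POLICIES:
            raise ValidationError("fixture policy set too large; shrink controls or horizon")


def generate_fixture(spec: FixtureSpec) -> GenerativeModel:
    """Draw a random, valid generative model reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, m, c = spec.n_states, spec.n_observations, spec.n_controls

    hidden = tuple((f"o{j % m}", f"t{j // m}") for j in range(n))
    observable = tuple(f"o{k}" for k in range(m))
    space = StateSpace(hidden, observable)

    A = rng.dirichlet(np.ones(m), size=n).T  # columns over observations

    B = rng.dirichlet(np.ones(n), size=(c, n)).transpose(0, 2, 1)
    if spec.b_sparsity > 0:
        mask = rng.random(B.shape) < spec.b_sparsity
        # keep each column's largest entry so columns stay renormalizable
        keep = B.argmax(axis=1)
        for k in range(c):
            mask[k, keep[k], np.arange(n)] = False
        B = np.where(mask, 0.0, B)
        B = B / B.sum(axis=1, keepdims=True)

    goal = rng.dirichlet(np.ones(n))
    goal = np.maximum(goal, 1e-4)
    goal = goal / goal.sum()

    b0 = rng.dirichlet(np.ones(n))

    controls = tuple(f"u{k}" for k in range(c))
    policies = tuple(itertools.product(controls, repeat=spec.horizon))

    model = GenerativeModel(
        space=space,
        obs=ObservationModel(A),
        trans=TransitionModel(B, control_labels=controls),
        goal=OutcomePrior(goal),
        prec=PrecisionPrior(spec.precision_shape, spec.precision_scale),
        horizon=spec.horizon,
        initial_belief=b0,
        policies=policies,
    )
    report = validate_model(model)
    if report:  # pragma: no cover - construction guarantees validity
        raise ValidationError("generated fixture is invalid: " + "; ".join(report))
    return model
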
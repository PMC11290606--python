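"""Priors and hyperpriors of the hierarchical mixture model.

Every prior is conditioned on the latent group where the model requires it:
the learning rate is degenerate at 0 for Non-Learners and Beta otherwise;
the generalization rate is a truncated Normal below the retention boundary
for Overgeneralizers and above it for Physical/Perceptual Generalizers; the
response noise has disjoint Uniform supports for learners (below 1.5) and
Non-Learners (above 1.5). All Normal scale arguments are standard
deviations, and Gamma uses the shape/rate convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from .model import (
    LAMBDA_BOUNDARY,
    NONLEARNER,
    OVERGENERALIZER,
    PERCEPTUAL,
    PHYSICAL,
    ParticipantParams,
)

_SIGMA_SPLIT = 1.5  # response-noise split between learners and Non-Learners


@dataclass
class HyperParams:
    """Group-level parameters of the multilevel model."""

    mu_alpha: float = 0.5
    kappa_alpha: float = 5.0
    mu_lambda: float = 0.1
    sigma_lambda: float = 0.5
    mu_w0: float = 0.0
    sigma_w0: float = 2.0
    a_w1: float = 2.0
    b_w1: float = 1.0
    sigma_learner: float = 0.75
    sigma_nonlearner: float = 2.25
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    @property
    def a_alpha(self) -> float:
        return self.mu_alpha * self.kappa_alpha

    @property
    def b_alpha(self) -> float:
        return (1.0 - self.mu_alpha) * self.kappa_alpha

    def validate(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a non-negative simplex vector")
        if not 0.0 < self.mu_alpha < 1.0:
            raise ValueError("mu_alpha must lie in (0, 1)")
        if not 1.0 <= self.kappa_alpha <= 10.0:
            raise ValueError("kappa_alpha must lie in [1, 10]")
        if self.mu_lambda <= 0:
            raise ValueError("mu_lambda must be positive")
        if not 1e-9 < self.sigma_lambda <= 1.0:
            raise ValueError("sigma_lambda must lie in (1e-9, 1]")
        if self.sigma_w0 <= 0 or self.a_w1 <= 0 or self.b_w1 <= 0:
            raise ValueError("scale/shape hyperparameters must be positive")
        if not 1e-9 < self.sigma_learner < _SIGMA_SPLIT:
            raise ValueError("sigma_learner must lie in (1e-9, 1.5)")
        if not _SIGMA_SPLIT < self.sigma_nonlearner < 3.0:
            raise ValueError("sigma_nonlearner must lie in (1.5, 3)")


#: Declarative audit table of every prior and hyperprior row.
PRIOR_SPEC = [
    {"parameter": "alpha", "level": "participant",
     "family": "point-mass 0 for group 1; Beta(a_alpha, b_alpha) otherwise",
     "support": "[0, 1]", "truncation": None,
     "hyper": "a_alpha = mu_alpha*kappa_alpha; b_alpha = (1-mu_alpha)*kappa_alpha; "
              "mu_alpha ~ Beta(1, 1); kappa_alpha ~ Uniform(1, 10)"},
    {"parameter": "lambda", "level": "participant",
     "family": "point-mass 0 for group 1; Normal(mu_lambda, sigma_lambda^2) truncated",
     "support": ">= 0",
     "truncation": f"(0, {LAMBDA_BOUNDARY}] for group 2; "
                   f"({LAMBDA_BOUNDARY}, inf) for groups 3, 4",
     "hyper": "mu_lambda ~ Normal(0.1, 1) T(0, inf); "
              "sigma_lambda ~ Uniform(1e-9, 1)"},
    {"parameter": "w0", "level": "participant",
     "family": "Normal(mu_w0, sigma_w0^2)", "support": "unbounded",
     "truncation": None,
     "hyper": "mu_w0 ~ Normal(0, 10^2); sigma_w0 ~ Half-Cauchy(0, 2)"},
    {"parameter": "w1", "level": "participant",
     "family": "Gamma(a_w1, b_w1) (shape, rate)", "support": "> 0",
     "truncation": None,
     "hyper": "a_w1 ~ Half-Cauchy(0, 2); b_w1 ~ Half-Cauchy(0, 2)"},
    {"parameter": "sigma", "level": "group",
     "family": "Uniform(1e-9, 1.5) for groups 2, 3, 4; Uniform(1.5, 3) for group 1",
     "support": "(0, 3)", "truncation": None, "hyper": None},
    {"parameter": "m", "level": "participant",
     "family": "Multinomial(1; pi_1..pi_4)", "support": "{1, 2, 3, 4}",
     "truncation": None, "hyper": "pi ~ Dirichlet(1, 1, 1, 1)"},
    {"parameter": "pi", "level": "population",
     "family": "Dirichlet(1, 1, 1, 1)", "support": "4-simplex",
     "truncation": None, "hyper": None},
]


def prior_spec_yaml() -> str:
    """Serializable audit description of the prior structure."""
    return yaml.safe_dump(PRIOR_SPEC, sort_keys=False)


def _truncnorm(mu, sigma, lo, hi):
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma if np.isfinite(hi) else np.inf
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def sample_hyperpriors(seed) -> HyperParams:
    """One draw from every hyperprior, respecting supports and truncations."""
    rng = np.random.default_rng(seed)
    mu_lambda = _truncnorm(0.1, 1.0, 0.0, np.inf).rvs(random_state=rng)
    return HyperParams(
        mu_alpha=rng.beta(1.0, 1.0),
        kappa_alpha=rng.uniform(1.0, 10.0),
        mu_lambda=float(mu_lambda),
        sigma_lambda=rng.uniform(1e-9, 1.0),
        mu_w0=rng.normal(0.0, 10.0),
        sigma_w0=float(stats.halfcauchy(scale=2.0).rvs(random_state=rng)),
        a_w1=float(stats.halfcauchy(scale=2.0).rvs(random_state=rng)),
        b_w1=float(stats.halfcauchy(scale=2.0).rvs(random_state=rng)),
        sigma_learner=rng.uniform(1e-9, _SIGMA_SPLIT),
        sigma_nonlearner=rng.uniform(_SIGMA_SPLIT, 3.0),
        pi=rng.dirichlet(np.ones(4)),
    )


def sample_participant(hyper: HyperParams, m: int, seed) -> ParticipantParams:
    """Group-conditional draw of one participant's parameters."""
    rng = np.random.default_rng(seed)
    w0 = rng.normal(hyper.mu_w0, hyper.sigma_w0)
    w1 = rng.gamma(hyper.a_w1, 1.0 / hyper.b_w1)
    if m == NONLEARNER:
        return ParticipantParams(m=m, alpha=0.0, lam=0.0, w0=w0, w1=w1)
    alpha = rng.beta(hyper.a_alpha, hyper.b_alpha)
    if m == OVERGENERALIZER:
        lam = _truncnorm(
            hyper.mu_lambda, hyper.sigma_lambda, 0.0, LAMBDA_BOUNDARY
        ).rvs(random_state=rng)
    elif m in (PHYSICAL, PERCEPTUAL):
        lam = _truncnorm(
            hyper.mu_lambda, hyper.sigma_lambda, LAMBDA_BOUNDARY, np.inf
        ).rvs(random_state=rng)
    else:
        raise ValueError(f"unknown group code {m}")
    return ParticipantParams(m=m, alpha=float(alpha), lam=float(lam), w0=w0, w1=w1)


def log_prior(params: ParticipantParams, hyper: HyperParams) -> float:
    """Group-conditional log prior density of one participant's parameters.

    Truncation normalizers are included; constraint violations return -inf
    rather than raising (this is the density's honest value there).
    """
    lp = stats.norm(hyper.mu_w0, hyper.sigma_w0).logpdf(params.w0)
    m = params.m
    if m == NONLEARNER:
        if params.alpha != 0.0 or params.lam != 0.0:
            return -np.inf
        # w1 is prior-only for Non-Learners (g = 0 makes it inert)
        lp += stats.gamma(hyper.a_w1, scale=1.0 / hyper.b_w1).logpdf(params.w1)
        return float(lp)
    lp += stats.gamma(hyper.a_w1, scale=1.0 / hyper.b_w1).logpdf(params.w1)
    lp += stats.beta(hyper.a_alpha, hyper.b_alpha).logpdf(params.alpha)
    if m == OVERGENERALIZER:
        if not 0.0 < params.lam <= LAMBDA_BOUNDARY:
            return -np.inf
        lp += _truncnorm(
            hyper.mu_lambda, hyper.sigma_lambda, 0.0, LAMBDA_BOUNDARY
        ).logpdf(params.lam)
    else:
        if params.lam <= LAMBDA_BOUNDARY:
            return -np.inf
        lp += _truncnorm(
            hyper.mu_lambda, hyper.sigma_lambda, LAMBDA_BOUNDARY, np.inf
        ).logpdf(params.lam)
    return float(lp)
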
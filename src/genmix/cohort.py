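"""Synthetic cohorts with known ground truth.

The generator reproduces the recovery-study conditions: 50 participants per
latent group on the differential-conditioning trial structure, with
group-specific parameter-generating rules, and Gaussian perceived-size noise
standing in for the empirical size estimates. Its output uses the same
long-format schema the fitting code reads, so fits are agnostic to whether
data are real or simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .designs import (
    DesignSpec,
    StimulusSet,
    TrialSchedule,
    build_exp2_design,
    exp2_stimuli,
    realize_schedule,
)
from .model import (
    LAMBDA_BOUNDARY,
    NONLEARNER,
    OVERGENERALIZER,
    PERCEPTUAL,
    PHYSICAL,
    ParticipantParams,
    PerceptStream,
    forward_trajectory,
)

#: default perceived-size noise (mm); stands in for empirical size estimates
DEFAULT_PERCEPT_NOISE_SD = 5.0

#: simulation-rule truncation cap on the generalization rate of groups 3/4
SIM_LAMBDA_CAP = 0.3022


def _truncnorm_rvs(rng, mu, sd, lo, hi, size=None):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd).rvs(size=size, random_state=rng)


@dataclass
class GroupRule:
    """Parameter-generating rule for one latent group."""

    alpha: Callable  # rng -> float
    lam: Callable
    w0: Callable
    w1: Callable
    sigma: float


def default_sim_rules() -> Dict[int, GroupRule]:
    """The recovery-study generating rules.

    alpha = 0 for Non-Learners, Beta(1, 1) otherwise; lambda = 0 for
    Non-Learners, N(0.0026, 0.001) T(0, 0.0052) for Overgeneralizers and
    N(0.1537, 0.1) T(0.0052, 0.3022) for Physical/Perceptual Generalizers;
    sigma = 2.5 for Non-Learners and 0.5 for all learner groups;
    w0 ~ N(0, 5) for Non-Learners and N(-2, 1) otherwise; w1 ~ Gamma(10, 1)
    for every group. Normal scale arguments are standard deviations; Gamma
    is shape/rate.
    """
    learner_alpha = lambda rng: rng.beta(1.0, 1.0)
    overgen_lam = lambda rng: float(
        _truncnorm_rvs(rng, 0.0026, 0.001, 0.0, LAMBDA_BOUNDARY)
    )
    steep_lam = lambda rng: float(
        _truncnorm_rvs(rng, 0.1537, 0.1, LAMBDA_BOUNDARY, SIM_LAMBDA_CAP)
    )
    learner_w0 = lambda rng: rng.normal(-2.0, 1.0)
    w1 = lambda rng: rng.gamma(10.0, 1.0)
    return {
        NONLEARNER: GroupRule(
            alpha=lambda rng: 0.0,
            lam=lambda rng: 0.0,
            w0=lambda rng: rng.normal(0.0, 5.0),
            w1=w1,
            sigma=2.5,
        ),
        OVERGENERALIZER: GroupRule(
            alpha=learner_alpha, lam=overgen_lam, w0=learner_w0, w1=w1, sigma=0.5
        ),
        PHYSICAL: GroupRule(
            alpha=learner_alpha, lam=steep_lam, w0=learner_w0, w1=w1, sigma=0.5
        ),
        PERCEPTUAL: GroupRule(
            alpha=learner_alpha, lam=steep_lam, w0=learner_w0, w1=w1, sigma=0.5
        ),
    }


@dataclass
class CohortSpec:
    """Conditions under which a synthetic cohort is generated."""

    n_per_group: tuple = (50, 50, 50, 50)
    design: DesignSpec = field(default_factory=build_exp2_design)
    stimuli: StimulusSet = field(default_factory=exp2_stimuli)
    percept_noise_sd: float = DEFAULT_PERCEPT_NOISE_SD
    rules: Optional[Dict[int, GroupRule]] = None
    seed: int = 0
    shared_schedule: bool = True  # one trial order for the whole cohort

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group counts must be non-negative")
        if self.percept_noise_sd < 0:
            raise ValueError("percept_noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Generating parameters and latent states of a synthetic cohort."""

    params: pd.DataFrame  # per participant: m, alpha, lam, w0, w1, sigma
    theta: Dict[str, np.ndarray]  # per participant: per-trial response mean

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(orient="records"),
            "theta": {k: list(map(float, v)) for k, v in self.theta.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params=pd.DataFrame(payload["params"]),
            theta={k: np.asarray(v) for k, v in payload["theta"].items()},
        )


def simulate_percepts(
    schedule: TrialSchedule, noise_sd: float, seed
) -> PerceptStream:
    """Perceived sizes: N(true size, noise_sd) clipped to the 0-200 mm VAS."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    sizes = schedule.frame["size_mm"].to_numpy(dtype=float)
    percepts = np.clip(rng.normal(sizes, noise_sd), 0.0, 200.0)
    return PerceptStream(percepts, schedule.frame["role"].to_numpy())


def simulate_cohort(spec: CohortSpec):
    """Generate a full cohort: (long-format trial table, ground truth).

    For each participant: draw parameters from the group rule, simulate
    percepts, run the forward model, and draw ratings y ~ N(theta, sigma).
    Ratings are not clipped to [1, 10], matching the untruncated response
    likelihood. Deterministic given ``spec.seed``.
    """
    rules = spec.rules or default_sim_rules()
    root = np.random.default_rng(spec.seed)
    shared = (
        realize_schedule(spec.design, spec.stimuli, int(root.integers(2**31)))
        if spec.shared_schedule
        else None
    )

    frames, truth_rows, truth_theta = [], [], {}
    pid = 0
    for m, n in zip(sorted(rules), spec.n_per_group):
        rule = rules[m]
        for _ in range(n):
            pid += 1
            name = f"P{pid:03d}"
            schedule = shared or realize_schedule(
                spec.design, spec.stimuli, int(root.integers(2**31))
            )
            params = ParticipantParams(
                m=m,
                alpha=float(rule.alpha(root)),
                lam=float(rule.lam(root)),
                w0=float(rule.w0(root)),
                w1=float(rule.w1(root)),
            )
            percepts = simulate_percepts(
                schedule, spec.percept_noise_sd, int(root.integers(2**31))
            )
            traj = forward_trajectory(
                schedule, percepts, params, spec.design.paradigm
            )
            y = root.normal(traj.theta, rule.sigma)

            frame = schedule.frame.copy()
            frame.insert(0, "participant", name)
            frame.insert(
                1,
                "experiment",
                "exp2" if spec.design.paradigm == "differential" else "exp1",
            )
            frame["size_estimate_mm"] = percepts.percepts
            frame["expectancy"] = y
            frames.append(frame)

            truth_rows.append(
                {
                    "participant": name,
                    "m": m,
                    "alpha": params.alpha,
                    "lam": params.lam,
                    "w0": params.w0,
                    "w1": params.w1,
                    "sigma": rule.sigma,
                }
            )
            truth_theta[name] = traj.theta

    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["participant", "experiment", *TrialSchedule.COLUMNS,
                     "size_estimate_mm", "expectancy"]
        )
    )
    truth = GroundTruth(params=pd.DataFrame(truth_rows), theta=truth_theta)
    return table, truth
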
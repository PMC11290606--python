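"""Deterministic forward model of fear-generalization behaviour.

The observable is a trial-by-trial US-expectancy rating. Its mean is built
from three chained pieces:

* error-driven (Rescorla-Wagner) updating of the associative strength ``v``
  of each conditioned stimulus, with learning rate ``alpha``;
* exponential (Shepard) similarity ``s = exp(-lam * d)`` between the current
  stimulus and the CS, where the distance ``d`` is either physical or
  perceptual (against the running mean of the perceived CS size);
* a sigmoid mapping of the generalized strength ``g = v * s`` onto the
  1-10 expectancy scale via a baseline ``w0`` and scaling ``w1``.

Four latent groups select which pieces are active: Non-Learners (group 1,
``v`` fixed at 0), Overgeneralizers (group 2, ``lam`` at most the retention
boundary), Physical Generalizers (group 3) and Perceptual Generalizers
(group 4, perceptual distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .designs import ROLE_CS_MINUS, ROLE_CS_PLUS, TrialSchedule

NONLEARNER, OVERGENERALIZER, PHYSICAL, PERCEPTUAL = 1, 2, 3, 4
GROUP_LABELS = {
    NONLEARNER: "NonLearner",
    OVERGENERALIZER: "Overgeneralizer",
    PHYSICAL: "PhysicalGeneralizer",
    PERCEPTUAL: "PerceptualGeneralizer",
    0: "Unknown",
}

#: largest CS-to-stimulus physical distance on the canonical grid, as printed
MAX_CANONICAL_DISTANCE_MM = 68.62
#: similarity the most distant stimulus must retain for an Overgeneralizer
OVERGEN_RETENTION = 0.7


def lambda_boundary(d_max: float, retain: float) -> float:
    """Decay rate at which exp(-lam*d_max) equals ``retain``.

    The Overgeneralizer group is defined by similarity staying at or above
    ``retain`` out to the most distant stimulus; on the canonical grid
    (d_max = 68.62 mm, retain = 0.7) this rounds to 0.0052 per mm.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if not 0.0 < retain <= 1.0:
        raise ValueError("retain must lie in (0, 1]")
    return -math.log(retain) / d_max


#: truncation boundary on the generalization rate (single source of truth)
LAMBDA_BOUNDARY = round(
    lambda_boundary(MAX_CANONICAL_DISTANCE_MM, OVERGEN_RETENTION), 4
)


@dataclass(frozen=True)
class MappingConstants:
    """Floor and ceiling of the sigmoid response mapping (expectancy VAS)."""

    A: float = 1.0
    K: float = 10.0

    def __post_init__(self):
        if not self.A < self.K:
            raise ValueError("require A < K")


DEFAULT_MAPPING = MappingConstants()


@dataclass
class ParticipantParams:
    """Person-specific latent parameters.

    ``m`` is the latent group; the group-conditional constraints (alpha and
    lam degenerate at 0 for Non-Learners, lam on either side of the
    retention boundary for the other groups) are enforced on construction.
    """

    m: int
    alpha: float
    lam: float
    w0: float
    w1: float
    check: bool = True  # set False to carry constraint-violating values

    def __post_init__(self):
        if not self.check:
            return
        if self.m not in (NONLEARNER, OVERGENERALIZER, PHYSICAL, PERCEPTUAL):
            raise ValueError(f"unknown group code {self.m}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.w1 <= 0:
            raise ValueError("w1 must be positive")
        if self.m == NONLEARNER:
            if self.alpha != 0 or self.lam != 0:
                raise ValueError("Non-Learners have alpha = lam = 0")
        elif self.m == OVERGENERALIZER:
            if not 0.0 < self.lam <= LAMBDA_BOUNDARY:
                raise ValueError(
                    f"Overgeneralizer lam must lie in (0, {LAMBDA_BOUNDARY}]"
                )
        else:
            if self.lam <= LAMBDA_BOUNDARY:
                raise ValueError(
                    f"generalizer lam must exceed {LAMBDA_BOUNDARY}"
                )


def rw_update(v: float, alpha: float, r: float, k: int, m: int) -> float:
    """One Rescorla-Wagner step: ``v + alpha * (r - v) * k``.

    Non-Learners (m = 1) acquire no strength, so the result is 0 regardless
    of the inputs. ``r`` is the trial outcome (1 = US, 0 = no US on CS+
    trials; -1 codes US absence on CS- trials so inhibitory strength can
    build toward -1) and ``k`` gates updating to CS trials.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if m == NONLEARNER:
        return 0.0
    return v + alpha * (r - v) * k


def physical_distance(cs_size: float, ts_size: float) -> float:
    """Absolute physical distance |x_CS - x_TS| in mm."""
    if cs_size < 0 or ts_size < 0:
        raise ValueError("sizes must be non-negative")
    return abs(cs_size - ts_size)


class PerceptStream:
    """Per-trial perceived sizes with running CS percept means.

    The perceived CS is summarised as the cumulative mean of all CS percepts
    up to and including the current trial; on a CS trial the current percept
    therefore enters the mean before the distance is taken, which is what
    lets a misperceived CS attenuate responding even on CS trials.
    Missing percepts leave the cumulative mean unchanged.
    """

    def __init__(self, percepts, roles):
        self.percepts = np.asarray(percepts, dtype=float)
        self.roles = np.asarray(roles, dtype=object)
        if self.percepts.shape != self.roles.shape:
            raise ValueError("percepts and roles must align")
        finite = self.percepts[np.isfinite(self.percepts)]
        if finite.size and (finite.min() < 0 or finite.max() > 200):
            raise ValueError("percepts must lie in [0, 200] mm")
        self._cum_plus = self._cumulative(ROLE_CS_PLUS)
        self._cum_minus = self._cumulative(ROLE_CS_MINUS)

    def _cumulative(self, role) -> np.ndarray:
        out = np.full(len(self.percepts), np.nan)
        total, count = 0.0, 0
        for j in range(len(self.percepts)):
            x = self.percepts[j]
            if self.roles[j] == role and np.isfinite(x):
                total += x
                count += 1
            if count:
                out[j] = total / count
        return out

    def cum_mean(self, which_cs: str = "plus") -> np.ndarray:
        """Cumulative CS percept mean after each trial (nan before the
        first CS percept)."""
        if which_cs == "plus":
            return self._cum_plus
        if which_cs == "minus":
            return self._cum_minus
        raise ValueError("which_cs must be 'plus' or 'minus'")

    def distances(self, which_cs: str = "plus") -> np.ndarray:
        """|cumulative CS mean - current percept| per trial.

        nan where either side is missing; callers decide the fallback (the
        forward model never consumes such trials because strength is still
        zero before the first CS presentation).
        """
        return np.abs(self.cum_mean(which_cs) - self.percepts)

    def __len__(self):
        return len(self.percepts)


def perceptual_distance(stream: PerceptStream, j: int, which_cs: str = "plus") -> float:
    """Perceptual distance at trial ``j`` (0-based): |CS cumulative mean - percept|."""
    d = stream.distances(which_cs)[j]
    if not np.isfinite(d):
        raise ValueError(
            f"perceptual distance undefined at trial {j}: no prior CS percept"
        )
    return float(d)


def similarity(lam: float, d, m: int = PHYSICAL, v: float = 1.0):
    """Shepard similarity ``exp(-lam * d)``; 1 for Non-Learners or when no
    strength has been acquired (v = 0)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if np.any(np.asarray(d) < 0):
        raise ValueError("distance must be non-negative")
    if m == NONLEARNER or v == 0:
        return np.ones_like(np.asarray(d, dtype=float)) if np.ndim(d) else 1.0
    return np.exp(-lam * np.asarray(d, dtype=float)) if np.ndim(d) else math.exp(-lam * d)


def generalized_strength(
    v_plus,
    s_plus,
    v_minus=None,
    s_minus=None,
    paradigm: str = "simple",
):
    """Generalized associative strength ``g``.

    Simple conditioning: ``v+ * s+`` in [0, 1]. Differential conditioning
    sums the generalized excitatory and inhibitory strengths,
    ``v+ s+ + v- s-`` in [-1, 1].
    """
    if paradigm == "simple":
        return v_plus * s_plus
    if paradigm == "differential":
        if v_minus is None or s_minus is None:
            raise ValueError("differential paradigm needs v_minus and s_minus")
        return v_plus * s_plus + v_minus * s_minus
    raise ValueError("paradigm must be 'simple' or 'differential'")


def sigmoid_map(g, w0, w1, constants: MappingConstants = DEFAULT_MAPPING):
    """Map latent strength onto the response scale:
    ``A + (K - A) / (1 + exp(-(w0 + w1 * g)))``."""
    return constants.A + (constants.K - constants.A) / (
        1.0 + np.exp(-(w0 + w1 * np.asarray(g, dtype=float)))
    )


def loglik(y, theta, sigma):
    """Gaussian response log-density, untruncated.

    Ratings are modelled N(theta, sigma^2) with no censoring at the scale
    ends, so predictive draws may fall outside [1, 10] by design.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = (np.asarray(y, dtype=float) - np.asarray(theta, dtype=float)) / sigma
    return -0.5 * z**2 - np.log(sigma) - 0.5 * math.log(2 * math.pi)


@dataclass
class LatentTrajectory:
    """Per-trial deterministic states of the forward model."""

    v_plus: np.ndarray
    v_minus: Optional[np.ndarray]
    d_plus: np.ndarray
    d_minus: Optional[np.ndarray]
    s_plus: np.ndarray
    s_minus: Optional[np.ndarray]
    g: np.ndarray
    theta: np.ndarray

    def to_frame(self):
        import pandas as pd

        cols = {"v_plus": self.v_plus, "d_plus": self.d_plus,
                "s_plus": self.s_plus, "g": self.g, "theta": self.theta}
        if self.v_minus is not None:
            cols["v_minus"] = self.v_minus
            cols["d_minus"] = self.d_minus
            cols["s_minus"] = self.s_minus
        return pd.DataFrame(cols)


def forward_trajectory(
    schedule: TrialSchedule,
    percepts: Optional[PerceptStream],
    params: ParticipantParams,
    paradigm: Optional[str] = None,
    constants: MappingConstants = DEFAULT_MAPPING,
) -> LatentTrajectory:
    """Run the full deterministic model over one participant's schedule.

    The response mean on trial ``j`` uses the strength *before* that
    trial's outcome is observed (ratings precede the US). Strength starts
    at 0 on the first acquisition trial. Distances are physical for groups
    2 and 3 and perceptual for group 4; group 1 never generalizes because
    its strength stays 0.
    """
    frame = schedule.frame
    if paradigm is None:
        paradigm = schedule.design.paradigm if schedule.design else "simple"
    differential = paradigm == "differential"
    T = len(frame)
    if params.m == PERCEPTUAL:
        if percepts is None or len(percepts) != T:
            raise ValueError("perceptual pathway needs an aligned percept stream")

    roles = frame["role"].to_numpy()
    sizes = frame["size_mm"].to_numpy(dtype=float)
    us = frame["us"].to_numpy(dtype=float)
    k = frame["k"].to_numpy(dtype=int)
    is_plus = roles == ROLE_CS_PLUS
    is_minus = roles == ROLE_CS_MINUS

    cs_plus_size = sizes[is_plus][0] if is_plus.any() else np.nan
    cs_minus_size = sizes[is_minus][0] if is_minus.any() else np.nan

    # associative strengths, pre-trial values
    v_plus = np.zeros(T)
    v_minus = np.zeros(T) if differential else None
    vp = vm = 0.0
    for j in range(T):
        v_plus[j] = vp
        if differential:
            v_minus[j] = vm
        if params.m != NONLEARNER and k[j]:
            if is_plus[j]:
                vp = vp + params.alpha * (us[j] - vp)
            elif differential and is_minus[j]:
                vm = vm + params.alpha * (-1.0 - vm)

    # distances
    if params.m == PERCEPTUAL:
        d_plus = percepts.distances("plus")
        d_plus = np.where(np.isfinite(d_plus), d_plus, 0.0)
        if differential:
            d_minus = percepts.distances("minus")
            d_minus = np.where(np.isfinite(d_minus), d_minus, 0.0)
    else:
        d_plus = np.abs(cs_plus_size - sizes)
        d_minus = np.abs(cs_minus_size - sizes) if differential else None
    if not differential:
        d_minus = None

    if params.m == NONLEARNER:
        s_plus = np.ones(T)
        s_minus = np.ones(T) if differential else None
    else:
        s_plus = np.exp(-params.lam * d_plus)
        s_minus = np.exp(-params.lam * d_minus) if differential else None

    if differential:
        g = generalized_strength(v_plus, s_plus, v_minus, s_minus, "differential")
    else:
        g = generalized_strength(v_plus, s_plus, paradigm="simple")
    if params.m == NONLEARNER:
        g = np.zeros(T)
    theta = sigmoid_map(g, params.w0, params.w1, constants)

    return LatentTrajectory(
        v_plus=v_plus,
        v_minus=v_minus,
        d_plus=d_plus,
        d_minus=d_minus,
        s_plus=s_plus,
        s_minus=s_minus,
        g=g,
        theta=theta,
    )
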
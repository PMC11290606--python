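"""Stimulus sets and trial schedules for fear-generalization experiments.

Two canonical protocols are provided: a simple-conditioning task (one CS+
among seven circles, 50% reinforcement) and a differential-conditioning task
(CS+ and CS- at the extremes of a ten-circle continuum, 83% reinforcement).
Synthetic cohorts and model fits share this one design representation, so the
trial bookkeeping (cue roles, US delivery, update flags) is defined here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

#: canonical circle-diameter grid (mm)
CANONICAL_MIN_MM = 50.80
CANONICAL_STEP_MM = 7.624
CANONICAL_N = 10

ROLE_CS_PLUS = "CSplus"
ROLE_CS_MINUS = "CSminus"
ROLE_TS = "TS"

PHASE_ACQ = "acquisition"
PHASE_GEN = "generalization"


@dataclass(frozen=True)
class StimulusSet:
    """An ordered set of circle stimuli on a physical size continuum."""

    diameters_mm: tuple
    labels: tuple
    cs_plus_index: int
    cs_minus_index: Optional[int] = None

    def __post_init__(self):
        d = np.asarray(self.diameters_mm, dtype=float)
        if len(d) != len(self.labels):
            raise ValueError("labels and diameters must have equal length")
        if len(d) < 2:
            raise ValueError("need at least two stimuli")
        steps = np.diff(d)
        if np.any(steps <= 0):
            raise ValueError("diameters must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValueError("consecutive spacing must be constant")
        if np.any(d <= 0) or np.any(d >= 200):
            raise ValueError("all diameters must lie in (0, 200) mm")
        if not (0 <= self.cs_plus_index < len(d)):
            raise ValueError("cs_plus_index out of range")
        if self.cs_minus_index is not None and not (
            0 <= self.cs_minus_index < len(d)
        ):
            raise ValueError("cs_minus_index out of range")

    @property
    def step_mm(self) -> float:
        return float(self.diameters_mm[1] - self.diameters_mm[0])

    @property
    def cs_plus_label(self) -> str:
        return self.labels[self.cs_plus_index]

    @property
    def cs_minus_label(self) -> Optional[str]:
        if self.cs_minus_index is None:
            return None
        return self.labels[self.cs_minus_index]

    @property
    def cs_plus_mm(self) -> float:
        return float(self.diameters_mm[self.cs_plus_index])

    @property
    def cs_minus_mm(self) -> Optional[float]:
        if self.cs_minus_index is None:
            return None
        return float(self.diameters_mm[self.cs_minus_index])

    @property
    def ts_labels(self) -> tuple:
        cs = {self.cs_plus_index, self.cs_minus_index}
        return tuple(l for i, l in enumerate(self.labels) if i not in cs)

    @property
    def max_distance_mm(self) -> float:
        """Largest |CS - stimulus| physical distance in the set (mm)."""
        d = np.asarray(self.diameters_mm)
        dist = np.abs(d - self.cs_plus_mm)
        if self.cs_minus_index is not None:
            dist = np.maximum(dist, np.abs(d - self.cs_minus_mm))
        return float(dist.max())

    def size_of(self, label: str) -> float:
        return float(self.diameters_mm[self.labels.index(label)])


def build_stimulus_set(
    n_stimuli: int,
    min_mm: float,
    step_mm: float,
    cs_plus: str | int,
    cs_minus: str | int | None = None,
) -> StimulusSet:
    """Build an evenly spaced stimulus grid ``min_mm + i * step_mm``.

    ``cs_plus``/``cs_minus`` may be labels ("S7") or integer indices. Labels
    are always S1..Sn regardless of where the grid starts.
    """
    if n_stimuli < 2:
        raise ValueError("n_stimuli must be >= 2")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    labels = tuple(f"S{i + 1}" for i in range(n_stimuli))
    diameters = tuple(min_mm + i * step_mm for i in range(n_stimuli))

    def _index(ref) -> int:
        if isinstance(ref, str):
            if ref not in labels:
                raise ValueError(f"unknown stimulus label {ref!r}")
            return labels.index(ref)
        return int(ref)

    return StimulusSet(
        diameters_mm=diameters,
        labels=labels,
        cs_plus_index=_index(cs_plus),
        cs_minus_index=None if cs_minus is None else _index(cs_minus),
    )


def canonical_grid(cs_plus="S7", cs_minus=None) -> StimulusSet:
    """The full ten-circle grid, 50.80 to 119.42 mm in 7.624 mm steps."""
    return build_stimulus_set(
        CANONICAL_N, CANONICAL_MIN_MM, CANONICAL_STEP_MM, cs_plus, cs_minus
    )


def exp1_stimuli() -> StimulusSet:
    """Seven circles S4-S10 with the middle one (S7, 96.54 mm) as CS+.

    Labels keep their positions on the full grid, so the set starts at S4.
    """
    full = canonical_grid()
    labels = full.labels[3:]
    diameters = full.diameters_mm[3:]
    return StimulusSet(
        diameters_mm=diameters,
        labels=labels,
        cs_plus_index=labels.index("S7"),
    )


def exp2_stimuli(cs_plus: str = "S1") -> StimulusSet:
    """The full grid with CS+/CS- at the extremes (counterbalanced)."""
    if cs_plus not in ("S1", "S10"):
        raise ValueError("differential CS+ must be S1 or S10")
    cs_minus = "S10" if cs_plus == "S1" else "S1"
    return canonical_grid(cs_plus=cs_plus, cs_minus=cs_minus)


@dataclass(frozen=True)
class DesignSpec:
    """Counts-level description of a conditioning protocol.

    ``per_block`` counts include the reacquisition trials; the first
    generalization block drops its leading ``reacquisition`` CS+ trials
    because it directly follows acquisition.
    """

    paradigm: str  # "simple" | "differential"
    acquisition_cs_plus: int
    acquisition_cs_minus: int
    reinforcement_rate: float
    blocks: int
    per_block_cs_plus: int
    per_block_cs_minus: int
    per_block_ts: int
    reacquisition: int

    def __post_init__(self):
        if self.paradigm not in ("simple", "differential"):
            raise ValueError("paradigm must be 'simple' or 'differential'")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise ValueError("reinforcement_rate must lie in [0, 1]")
        if self.reacquisition > self.per_block_cs_plus:
            raise ValueError("reacquisition exceeds per-block CS+ count")
        if self.paradigm == "simple" and (
            self.acquisition_cs_minus or self.per_block_cs_minus
        ):
            raise ValueError("simple paradigm admits no CS- trials")

    @property
    def block_size(self) -> int:
        return self.per_block_cs_plus + self.per_block_cs_minus + self.per_block_ts

    @property
    def acquisition_total(self) -> int:
        return self.acquisition_cs_plus + self.acquisition_cs_minus

    @property
    def generalization_total(self) -> int:
        return self.blocks * self.block_size - self.reacquisition

    @property
    def total_trials(self) -> int:
        return self.acquisition_total + self.generalization_total

    @property
    def acquisition_us_count(self) -> int:
        return round(self.reinforcement_rate * self.acquisition_cs_plus)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "DesignSpec":
        return cls(**yaml.safe_load(text))


def build_exp1_design() -> DesignSpec:
    """Simple conditioning: 14 CS+ acquisition trials at 50% reinforcement,
    then 4 blocks of 22 CS+ / 24 TS with 10 reacquisition trials."""
    return DesignSpec(
        paradigm="simple",
        acquisition_cs_plus=14,
        acquisition_cs_minus=0,
        reinforcement_rate=0.50,
        blocks=4,
        per_block_cs_plus=22,
        per_block_cs_minus=0,
        per_block_ts=24,
        reacquisition=10,
    )


def build_exp2_design() -> DesignSpec:
    """Differential conditioning: 12 CS+ / 12 CS- acquisition trials at 83%
    reinforcement, then 3 blocks of 14 CS+ / 8 CS- / 32 TS with 6
    reacquisition trials."""
    return DesignSpec(
        paradigm="differential",
        acquisition_cs_plus=12,
        acquisition_cs_minus=12,
        reinforcement_rate=0.83,
        blocks=3,
        per_block_cs_plus=14,
        per_block_cs_minus=8,
        per_block_ts=32,
        reacquisition=6,
    )


@dataclass
class TrialSchedule:
    """Ordered trial descriptors for one participant.

    ``us`` is the US outcome as administered (never on CS-/TS trials) and
    ``k`` flags trials on which associative strength is updated (all CS
    trials, per the error-driven learning rule).
    """

    frame: pd.DataFrame = field(repr=False)
    design: DesignSpec = None
    stimuli: StimulusSet = None

    COLUMNS = ("trial", "phase", "block", "role", "stimulus", "size_mm", "us", "k")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"schedule frame missing columns: {sorted(missing)}")
        bad_us = self.frame.loc[self.frame["role"] != ROLE_CS_PLUS, "us"]
        if (bad_us != 0).any():
            raise ValueError("US delivered on a CS-/TS trial")
        k_expect = self.frame["role"].isin([ROLE_CS_PLUS, ROLE_CS_MINUS]).astype(int)
        if not (self.frame["k"] == k_expect).all():
            raise ValueError("k flag must be 1 exactly on CS trials")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path, participant_id=None) -> None:
        out = self.frame.copy()
        if participant_id is not None:
            out.insert(0, "participant", participant_id)
        out.to_csv(path, index=False)


def _balanced_ts(ts_labels, count, rng) -> list:
    """Each TS equally often; any remainder assigned at random."""
    per, rem = divmod(count, len(ts_labels))
    out = list(ts_labels) * per
    if rem:
        out += list(rng.choice(ts_labels, size=rem, replace=False))
    return out


def realize_schedule(
    design: DesignSpec, stimuli: StimulusSet, seed: int
) -> TrialSchedule:
    """Draw one concrete trial order consistent with ``design``.

    Deterministic given ``seed``: reinforced CS+ positions, acquisition
    interleaving, and within-block orders are uniform random permutations.
    Reacquisition CS+ trials lead every generalization block except the
    first.
    """
    if design.paradigm == "differential" and stimuli.cs_minus_index is None:
        raise ValueError("differential design needs a CS- in the stimulus set")
    rng = np.random.default_rng(seed)
    rows = []

    # acquisition: CS+/CS- interleaved uniformly at random
    acq_roles = [ROLE_CS_PLUS] * design.acquisition_cs_plus + [
        ROLE_CS_MINUS
    ] * design.acquisition_cs_minus
    rng.shuffle(acq_roles)
    us_flags = _assign_us(acq_roles, design.reinforcement_rate, rng)
    for role, us in zip(acq_roles, us_flags):
        rows.append((PHASE_ACQ, 0, role, us))

    # generalization blocks; TS entries are carried as their stimulus label
    for b in range(1, design.blocks + 1):
        n_lead = design.reacquisition if b > 1 else 0
        n_plus = design.per_block_cs_plus - (
            design.reacquisition if b == 1 else 0
        )
        inner = (
            [ROLE_CS_PLUS] * (n_plus - n_lead)
            + [ROLE_CS_MINUS] * design.per_block_cs_minus
            + _balanced_ts(stimuli.ts_labels, design.per_block_ts, rng)
        )
        rng.shuffle(inner)
        block_roles = [ROLE_CS_PLUS] * n_lead + inner
        us_flags = _assign_us(block_roles, design.reinforcement_rate, rng)
        for role, us in zip(block_roles, us_flags):
            rows.append((PHASE_GEN, b, role, us))

    records = []
    for j, (phase, block, role, us) in enumerate(rows, start=1):
        if role == ROLE_CS_PLUS:
            label = stimuli.cs_plus_label
        elif role == ROLE_CS_MINUS:
            label = stimuli.cs_minus_label
        else:
            label = role  # TS entries carry their stimulus label
            role = ROLE_TS
        size = stimuli.size_of(label)
        k = 1 if role in (ROLE_CS_PLUS, ROLE_CS_MINUS) else 0
        records.append((j, phase, block, role, label, size, us, k))

    frame = pd.DataFrame(records, columns=TrialSchedule.COLUMNS)
    return TrialSchedule(frame=frame, design=design, stimuli=stimuli)


def _assign_us(roles, rate, rng):
    """US on a random round(rate * n) subset of the CS+ trials in a segment."""
    idx = [i for i, r in enumerate(roles) if r == ROLE_CS_PLUS]
    n_us = round(rate * len(idx))
    chosen = set(rng.choice(idx, size=n_us, replace=False)) if n_us else set()
    return [1 if i in chosen else 0 for i in range(len(roles))]
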
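"""Latent-group allocation from posterior membership draws.

A participant is assigned their modal group only when at least a threshold
fraction (default 75%) of the membership draws agree; otherwise they land in
the Unknown category. Cohort-level composition is reported both as the
empirical share of allocated labels and as credible intervals on the
mixture-weight draws — two related but distinct quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GROUP_LABELS
from .mcmc import PosteriorSamples

UNKNOWN = 0
DEFAULT_THRESHOLD = 0.75


@dataclass
class Allocation:
    """Per-participant allocation plus cohort-level composition."""

    table: pd.DataFrame  # participant, modal_group, fraction, group, label
    proportions: pd.DataFrame  # per group: share of labels, pi median + CI
    threshold: float

    def counts(self) -> pd.Series:
        return self.table["label"].value_counts()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def allocate(
    samples: PosteriorSamples, threshold: float = DEFAULT_THRESHOLD
) -> Allocation:
    """Assign each participant their modal membership, or Unknown.

    The criterion is inclusive ("at least"): a modal fraction exactly equal
    to the threshold counts as allocated. Exact ties between modal groups go
    to Unknown.
    """
    if not 0.25 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.25, 1]")
    m = samples.m_draws().reshape(-1, len(samples.participants))
    n_draws = m.shape[0]
    comps = np.asarray(samples.components)

    counts = np.stack([(m == c).sum(axis=0) for c in comps], axis=1)
    order = np.argsort(-counts, axis=1)
    top = counts[np.arange(len(samples.participants)), order[:, 0]]
    second = (
        counts[np.arange(len(samples.participants)), order[:, 1]]
        if counts.shape[1] > 1
        else np.zeros_like(top)
    )
    modal = comps[order[:, 0]]
    frac = top / n_draws

    assigned = (frac >= threshold) & (top > second)  # ties -> Unknown
    group = np.where(assigned, modal, UNKNOWN)

    table = pd.DataFrame(
        {
            "participant": samples.participants,
            "modal_group": modal,
            "fraction": frac,
            "group": group,
            "label": [GROUP_LABELS[g] for g in group],
        }
    )

    pi = samples.draws["pi"].reshape(-1, len(comps))
    n = max(len(samples.participants), 1)
    rows = []
    for j, c in enumerate(comps):
        rows.append(
            {
                "group": int(c),
                "label": GROUP_LABELS[int(c)],
                "share_allocated": float((group == c).sum() / n),
                "pi_median": float(np.median(pi[:, j])),
                "pi_ci_low": float(np.quantile(pi[:, j], 0.025)),
                "pi_ci_high": float(np.quantile(pi[:, j], 0.975)),
            }
        )
    rows.append(
        {
            "group": UNKNOWN,
            "label": GROUP_LABELS[UNKNOWN],
            "share_allocated": float((group == UNKNOWN).sum() / n),
            "pi_median": np.nan,
            "pi_ci_low": np.nan,
            "pi_ci_high": np.nan,
        }
    )
    return Allocation(
        table=table, proportions=pd.DataFrame(rows), threshold=threshold
    )


def sensitivity(
    samples: PosteriorSamples, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Allocation under a range of thresholds (stricter and more lenient).

    Returns one row per participant per threshold; the Unknown count is
    non-decreasing in the threshold.
    """
    frames = []
    for t in thresholds:
        alloc = allocate(samples, threshold=t)
        f = alloc.table.copy()
        f.insert(0, "threshold", t)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
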
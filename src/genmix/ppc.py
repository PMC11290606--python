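"""Posterior predictive checks, recovery reports and gradient summaries.

Posterior predictive replicates pair each replicated data set with a single
joint posterior draw pushed through the forward model plus Gaussian response
noise; summaries use the mean and the 10/30/50/70/90% sample quantiles per
stimulus across the generalization phase, the same statistics used to judge
model fit against observed gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .designs import PHASE_GEN
from .mcmc import ModelData, PosteriorSamples, _FrozenState, _Sampler
from .model import NONLEARNER

PPC_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def posterior_predictive(
    samples: PosteriorSamples,
    data: pd.DataFrame,
    R: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Replicated response arrays of shape (R, n, T).

    Each replicate r uses one randomly chosen joint posterior draw: the
    deterministic trajectory for every participant under that draw's
    parameters and membership, plus N(0, sigma_m) response noise. No
    truncation is applied, so replicates may exceed the 1-10 scale.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    md = ModelData(data, paradigm=samples.paradigm)
    sampler = _Sampler(md, samples.config, samples.components)

    out = np.empty((R, md.n, md.T))
    chains = rng.integers(samples.n_chains, size=R)
    draw_ix = rng.integers(samples.n_draws, size=R)
    for r in range(R):
        st = _FrozenState(samples, int(chains[r]), int(draw_ix[r]))
        vp, vm = sampler.compute_v(st.alpha)
        theta = sampler._theta(st, vp, vm)
        sigma = np.where(
            st.m == NONLEARNER, st.hy["sigma_nonlearner"], st.hy["sigma_learner"]
        )
        out[r] = theta + rng.normal(0.0, 1.0, size=theta.shape) * sigma[:, None]
    return out


@dataclass
class PPCReport:
    """Per-stimulus observed statistics against replicate bands."""

    table: pd.DataFrame  # stimulus, stat, observed, rep_median, rep_lo, rep_hi
    n_replicates: int
    quantile_method: str = "linear"

    def coverage(self) -> float:
        """Fraction of observed statistic points inside their replicate band."""
        t = self.table
        inside = (t["observed"] >= t["rep_lo"]) & (t["observed"] <= t["rep_hi"])
        return float(inside.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def ppc_quantiles(
    data: pd.DataFrame,
    replicates: np.ndarray,
    band: float = 0.95,
) -> PPCReport:
    """Compare observed per-stimulus statistics with replicate bands.

    Statistics are the mean and the 10/30/50/70/90% quantiles of the
    generalization-phase responses pooled per stimulus; the band is the
    central ``band`` interval of each statistic across replicates.
    Quantiles use linear-interpolation sample quantiles.
    """
    md_order = list(dict.fromkeys(data["participant"]))
    gen = data["phase"] == PHASE_GEN
    if not gen.any():
        raise ValueError("no generalization-phase rows in the data")

    # map each (participant, trial) onto the replicate array coordinates
    pos = {p: i for i, p in enumerate(md_order)}
    rows_i = data.loc[gen, "participant"].map(pos).to_numpy()
    rows_j = (data.loc[gen, "trial"].to_numpy() - 1).astype(int)
    stim = data.loc[gen, "stimulus"].to_numpy()
    y_obs = pd.to_numeric(data.loc[gen, "expectancy"], errors="coerce").to_numpy()

    lo_q, hi_q = (1.0 - band) / 2.0, 1.0 - (1.0 - band) / 2.0
    records = []
    for s in sorted(set(stim)):
        sel = stim == s
        if not sel.any():
            raise ValueError(f"empty stimulus cell {s}")
        obs = y_obs[sel]
        obs = obs[np.isfinite(obs)]
        rep = replicates[:, rows_i[sel], rows_j[sel]]  # (R, cell)
        stats_obs = {"mean": float(np.mean(obs))}
        stats_rep = {"mean": rep.mean(axis=1)}
        for q in PPC_QUANTILES:
            stats_obs[f"q{int(q * 100)}"] = float(np.quantile(obs, q))
            stats_rep[f"q{int(q * 100)}"] = np.quantile(rep, q, axis=1)
        for stat, o in stats_obs.items():
            rv = stats_rep[stat]
            records.append(
                {
                    "stimulus": s,
                    "stat": stat,
                    "observed": o,
                    "rep_median": float(np.median(rv)),
                    "rep_lo": float(np.quantile(rv, lo_q)),
                    "rep_hi": float(np.quantile(rv, hi_q)),
                }
            )
    return PPCReport(
        table=pd.DataFrame(records), n_replicates=replicates.shape[0]
    )


@dataclass
class RecoveryReport:
    """True-vs-estimated comparison on a synthetic cohort."""

    params: pd.DataFrame  # participant, parameter, true, estimate, group...
    summary: pd.DataFrame  # per parameter x true group: bias, rmse, rank corr
    confusion: pd.DataFrame  # true group x allocated label counts

    def to_csv(self, prefix) -> None:
        self.params.to_csv(f"{prefix}_params.csv", index=False)
        self.summary.to_csv(f"{prefix}_summary.csv", index=False)
        self.confusion.to_csv(f"{prefix}_confusion.csv")


def recovery_report(ground_truth, samples: PosteriorSamples, allocation) -> RecoveryReport:
    """Recovery statistics for the learning and generalization rates.

    Estimates are posterior medians of the model-level parameters (zero on
    Non-Learner draws). The confusion matrix crosses true groups with
    allocated labels, Unknown included; its rows sum to the true group
    sizes.
    """
    truth = ground_truth.params.set_index("participant")
    order = samples.participants
    missing = set(order) - set(truth.index)
    if missing:
        raise ValueError(f"ground truth missing participants: {sorted(missing)}")

    est = {
        name: np.median(
            samples.draws[name].reshape(-1, len(order)), axis=0
        )
        for name in ("alpha", "lam", "w0", "w1")
    }

    rows = []
    for name in ("alpha", "lam", "w0", "w1"):
        for i, pid in enumerate(order):
            rows.append(
                {
                    "participant": pid,
                    "parameter": name,
                    "true": float(truth.loc[pid, name if name != "lam" else "lam"]),
                    "estimate": float(est[name][i]),
                    "true_group": int(truth.loc[pid, "m"]),
                }
            )
    params = pd.DataFrame(rows)

    from scipy import stats as sps

    summ = []
    for (name, grp), sub in params.groupby(["parameter", "true_group"]):
        err = sub["estimate"] - sub["true"]
        if len(sub) >= 3 and sub["true"].nunique() > 1:
            rho = float(sps.spearmanr(sub["true"], sub["estimate"]).statistic)
        else:
            rho = np.nan
        summ.append(
            {
                "parameter": name,
                "true_group": grp,
                "n": len(sub),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "rank_corr": rho,
            }
        )
    summary = pd.DataFrame(summ)

    alloc = allocation.table.set_index("participant").loc[order]
    confusion = pd.crosstab(
        truth.loc[order, "m"].to_numpy(), alloc["label"].to_numpy(),
        rownames=["true_group"], colnames=["allocated"],
    )
    return RecoveryReport(params=params, summary=summary, confusion=confusion)


def gradient_summary(
    data: pd.DataFrame, allocation=None
) -> pd.DataFrame:
    """Mean generalization-phase response per stimulus, overall and by group.

    Averages pool every generalization-phase trial of a stimulus; with an
    allocation, per-group curves are added (Unknown kept as its own curve).
    """
    gen = data[data["phase"] == PHASE_GEN].copy()
    if gen.empty:
        raise ValueError("no generalization-phase rows in the data")
    gen["expectancy"] = pd.to_numeric(gen["expectancy"], errors="coerce")

    per_part = (
        gen.groupby(["participant", "stimulus"], sort=False)["expectancy"]
        .mean()
        .reset_index()
    )
    overall = (
        per_part.groupby("stimulus")["expectancy"].mean().reset_index()
    )
    overall.insert(0, "group_label", "all")

    frames = [overall]
    if allocation is not None:
        lab = allocation.table.set_index("participant")["label"]
        per_part["group_label"] = per_part["participant"].map(lab)
        by_group = (
            per_part.groupby(["group_label", "stimulus"])["expectancy"]
            .mean()
            .reset_index()
        )
        frames.append(by_group)
    out = pd.concat(frames, ignore_index=True)
    sizes = data.drop_duplicates("stimulus").set_index("stimulus")["size_mm"]
    out["size_mm"] = out["stimulus"].map(sizes)
    return out.sort_values(["group_label", "size_mm"]).reset_index(drop=True)
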
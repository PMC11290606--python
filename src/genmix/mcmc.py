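"""Posterior sampling for the hierarchical mixture model.

The sampler is Metropolis-within-Gibbs. The discrete group membership m_i
is drawn from its exact conditional each sweep; to keep those conditionals
well defined across the disjoint truncation regions, each participant
carries per-component copies of the constrained continuous parameters (a
generalization rate on each side of the retention boundary). Copies that the
current membership does not use are refreshed from their priors, which is
the standard mixture augmentation and leaves the marginal posterior of the
active parameters untouched. Label switching is structurally absent because
the components have disjoint parameter constraints.

Two ablations are provided: ``simplified1`` removes the perceptual-distance
pathway (no Perceptual Generalizer component), and ``simplified2`` removes
learning dynamics (associative strength pinned at its asymptote from the
first trial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .designs import ROLE_CS_MINUS, ROLE_CS_PLUS
from .model import (
    DEFAULT_MAPPING,
    LAMBDA_BOUNDARY,
    NONLEARNER,
    OVERGENERALIZER,
    PERCEPTUAL,
    PHYSICAL,
)

_LOG_2PI = float(np.log(2.0 * np.pi))
_SIGMA_SPLIT = 1.5

VARIANTS = ("full", "simplified1", "simplified2")


def _rw_scan_py(alpha, k, r, out):
    n, T = out.shape
    for i in range(n):
        v, a = 0.0, alpha[i]
        for j in range(T):
            out[i, j] = v
            if k[i, j]:
                v = v + a * (r[i, j] - v)


try:  # jit the error-driven-learning scan; pure-python fallback is identical
    from numba import njit

    _rw_scan = njit(cache=True)(_rw_scan_py)
except Exception:  # pragma: no cover
    _rw_scan = _rw_scan_py


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.

    The default preset matches the reference analysis (4 chains, 100,000
    iterations, 75,000 burn-in, thinning 10, hence 10,000 retained draws);
    ``FitConfig.test()`` is the scaled-down preset used throughout the test
    suite.
    """

    variant: str = "full"
    chains: int = 4
    iterations: int = 100_000
    burn_in: int = 75_000
    thin: int = 10
    seed: int = 0
    paradigm: Optional[str] = None
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def paper(cls, **kw) -> "FitConfig":
        return cls(**kw)

    @classmethod
    def test(cls, **kw) -> "FitConfig":
        kw.setdefault("chains", 4)
        kw.setdefault("iterations", 4_000)
        kw.setdefault("burn_in", 2_000)
        kw.setdefault("thin", 2)
        return cls(**kw)


# ---------------------------------------------------------------------------
# data preparation


class ModelData:
    """Per-participant trial arrays, padded to a common length.

    Precomputes everything the likelihood needs: update flags, delivered
    outcomes, physical CS distances and perceptual distances (absolute
    difference between the running CS percept mean and the current percept).
    A missing percept falls back to the physical distance on that trial; a
    missing rating is masked out of the likelihood.
    """

    def __init__(self, table: pd.DataFrame, paradigm: Optional[str] = None):
        self.participants = list(dict.fromkeys(table["participant"]))
        n = len(self.participants)
        groups = {pid: g.sort_values("trial") for pid, g in table.groupby("participant", sort=False)}
        T = max((len(g) for g in groups.values()), default=0)
        self.n, self.T = n, T

        if paradigm is None:
            any_minus = (table["role"] == ROLE_CS_MINUS).any() if len(table) else False
            paradigm = "differential" if any_minus else "simple"
        self.paradigm = paradigm
        self.differential = paradigm == "differential"

        shape = (n, T)
        self.y = np.full(shape, np.nan)
        self.kp = np.zeros(shape, dtype=bool)
        self.km = np.zeros(shape, dtype=bool)
        self.rp = np.zeros(shape)
        self.d_phys_p = np.zeros(shape)
        self.d_phys_m = np.zeros(shape)
        self.d_perc_p = np.zeros(shape)
        self.d_perc_m = np.zeros(shape)
        self.has_percepts = (
            "size_estimate_mm" in table.columns
            and table["size_estimate_mm"].notna().any()
        )

        for i, pid in enumerate(self.participants):
            g = groups[pid]
            t = len(g)
            roles = g["role"].to_numpy()
            sizes = g["size_mm"].to_numpy(dtype=float)
            us = g["us"].to_numpy(dtype=float)
            is_p = roles == ROLE_CS_PLUS
            is_m = roles == ROLE_CS_MINUS
            self.kp[i, :t] = is_p
            self.km[i, :t] = is_m
            self.rp[i, :t] = us
            if "expectancy" in g.columns:
                self.y[i, :t] = pd.to_numeric(g["expectancy"], errors="coerce")

            cs_p = sizes[is_p][0] if is_p.any() else np.nan
            cs_m = sizes[is_m][0] if is_m.any() else np.nan
            dpp = np.abs(cs_p - sizes)
            dpm = np.abs(cs_m - sizes) if self.differential else np.zeros(t)
            self.d_phys_p[i, :t] = np.nan_to_num(dpp)
            self.d_phys_m[i, :t] = np.nan_to_num(dpm)

            if self.has_percepts:
                x = pd.to_numeric(g["size_estimate_mm"], errors="coerce").to_numpy()
                self.d_perc_p[i, :t] = self._perc_dist(x, is_p, self.d_phys_p[i, :t])
                self.d_perc_m[i, :t] = (
                    self._perc_dist(x, is_m, self.d_phys_m[i, :t])
                    if self.differential
                    else 0.0
                )

        self.rm = np.where(self.km, -1.0, 0.0)  # CS- outcome coding
        self.mask = np.isfinite(self.y)

    @staticmethod
    def _perc_dist(x, is_cs, d_phys) -> np.ndarray:
        """|running CS percept mean - percept|, physical fallback on gaps."""
        out = np.array(d_phys, dtype=float)
        total, count = 0.0, 0
        for j in range(len(x)):
            if is_cs[j] and np.isfinite(x[j]):
                total += x[j]
                count += 1
            if count and np.isfinite(x[j]):
                out[j] = abs(total / count - x[j])
        return out


# ---------------------------------------------------------------------------
# density helpers (manual, for speed in the sweep loop)


def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _beta_logpdf(x, a, b):
    return (
        (a - 1.0) * np.log(x)
        + (b - 1.0) * np.log1p(-x)
        - special.betaln(a, b)
    )


def _gamma_logpdf(x, shape, rate):
    return (
        shape * np.log(rate)
        + (shape - 1.0) * np.log(x)
        - rate * x
        - special.gammaln(shape)
    )


def _halfcauchy_logpdf(x, scale=2.0):
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def _tn_lognorm(mu, sd, lo, hi):
    """log of the truncated-normal normalizing constant P(lo < X < hi),
    computed in log space so deep-tail intervals stay finite."""
    a = (lo - mu) / sd
    if np.isinf(hi):
        return float(special.log_ndtr(-a))
    b = (hi - mu) / sd
    if a > 0:  # reflect into the lower tail where log_ndtr is accurate
        la, lb = special.log_ndtr(-b), special.log_ndtr(-a)
    else:
        la, lb = special.log_ndtr(a), special.log_ndtr(b)
    diff = la - lb
    if diff >= 0:
        return -np.inf
    return float(lb + np.log1p(-np.exp(diff)))


def _truncnorm_rvs(rng, mu, sd, lo, hi, size):
    """Inverse-CDF sampling on the truncated support."""
    a = special.ndtr((lo - mu) / sd)
    b = 1.0 if np.isinf(hi) else special.ndtr((hi - mu) / sd)
    u = rng.uniform(a, b, size=size)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return mu + sd * special.ndtri(u)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Chain-aware posterior draws.

    Participant-level arrays have shape (chains, draws, n); hyperparameters
    (chains, draws); ``pi`` (chains, draws, n_components). ``m`` holds the
    per-draw membership; ``alpha`` and ``lam`` are the model-level values
    (zeroed for Non-Learner draws, the active truncation copy otherwise).
    """

    draws: Dict[str, np.ndarray]
    participants: list
    components: Tuple[int, ...]
    paradigm: str
    config: FitConfig

    PARTICIPANT_PARAMS = ("m", "alpha", "lam", "w0", "w1")
    HYPER_PARAMS = (
        "mu_alpha", "kappa_alpha", "mu_lambda", "sigma_lambda",
        "mu_w0", "sigma_w0", "a_w1", "b_w1", "sigma_learner",
        "sigma_nonlearner",
    )

    @property
    def n_chains(self) -> int:
        return self.draws["m"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["m"].shape[1]

    def m_draws(self) -> np.ndarray:
        return self.draws["m"]

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.draws.items()})

    def rhat_table(self, threshold: Optional[float] = None) -> pd.DataFrame:
        """Split-chain Gelman-Rubin diagnostic for every continuous parameter."""
        thr = threshold if threshold is not None else self.config.rhat_threshold
        rows = []
        for name, arr in self.draws.items():
            if name == "m":
                continue
            if arr.ndim == 2:
                rows.append((name, gelman_rubin(arr)))
            else:
                for idx in range(arr.shape[2]):
                    label = (
                        f"{name}[{self.participants[idx]}]"
                        if name in self.PARTICIPANT_PARAMS
                        else f"{name}[{idx}]"
                    )
                    rows.append((label, gelman_rubin(arr[:, :, idx])))
        table = pd.DataFrame(rows, columns=["parameter", "rhat"])
        table["converged"] = table["rhat"] < thr
        return table

    def save(self, path) -> None:
        meta = {
            "participants": self.participants,
            "components": list(self.components),
            "paradigm": self.paradigm,
            "config": {
                k: getattr(self.config, k)
                for k in self.config.__dataclass_fields__
            },
        }
        np.savez_compressed(path, _meta=json.dumps(meta), **self.draws)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            draws = {k: z[k] for k in z.files if k != "_meta"}
        return cls(
            draws=draws,
            participants=meta["participants"],
            components=tuple(meta["components"]),
            paradigm=meta["paradigm"],
            config=FitConfig(**meta["config"]),
        )


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a (chains, draws)
    array. Identical constant chains return 1.0 by convention."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = half * splits.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def rhat(samples: PosteriorSamples, parameter: str) -> np.ndarray | float:
    """R-hat for one named parameter (vector-valued for participant-level)."""
    arr = samples.draws[parameter]
    if arr.ndim == 2:
        return gelman_rubin(arr)
    return np.array([gelman_rubin(arr[:, :, i]) for i in range(arr.shape[2])])


# ---------------------------------------------------------------------------
# the sampler


class _ChainState:
    """Mutable state of one chain."""

    def __init__(self, md: ModelData, components, rng, fixed_v):
        n = md.n
        self.rng = rng
        self.components = np.asarray(components)
        self.fixed_v = fixed_v
        self.m = self.components[rng.integers(len(self.components), size=n)]
        self.alpha = rng.uniform(0.05, 0.95, size=n)
        self.lam2 = rng.uniform(0.5e-3, LAMBDA_BOUNDARY * 0.9, size=n)
        self.lam34 = rng.uniform(0.02, 0.25, size=n)
        self.w0 = rng.normal(0.0, 1.0, size=n)
        self.w1 = rng.gamma(5.0, 1.0, size=n) + 0.5
        self.hy = {
            "mu_alpha": rng.uniform(0.3, 0.7),
            "kappa_alpha": rng.uniform(2.0, 8.0),
            "mu_lambda": rng.uniform(0.05, 0.2),
            "sigma_lambda": rng.uniform(0.1, 0.5),
            "mu_w0": rng.normal(0.0, 1.0),
            "sigma_w0": rng.uniform(1.0, 3.0),
            "a_w1": rng.uniform(2.0, 8.0),
            "b_w1": rng.uniform(0.5, 1.5),
            "sigma_learner": rng.uniform(0.4, 1.2),
            "sigma_nonlearner": rng.uniform(1.7, 2.8),
        }
        self.pi = np.full(len(self.components), 1.0 / len(self.components))


class _Sampler:
    def __init__(self, md: ModelData, config: FitConfig, components):
        self.md = md
        self.cfg = config
        self.components = tuple(components)
        self.fixed_v = config.variant == "simplified2"
        self.A, self.K = DEFAULT_MAPPING.A, DEFAULT_MAPPING.K

    # -- deterministic pieces -------------------------------------------------

    def compute_v(self, alpha: np.ndarray):
        """Associative-strength trajectories (pre-trial values) for every
        participant at learning rates ``alpha``."""
        md = self.md
        n, T = md.n, md.T
        if self.fixed_v:
            vp = np.ones((n, T))
            vm = -np.ones((n, T)) if md.differential else None
            return vp, vm
        vp_out = np.empty((n, T))
        _rw_scan(alpha, md.kp, md.rp, vp_out)
        vm_out = None
        if md.differential:
            vm_out = np.empty((n, T))
            _rw_scan(alpha, md.km, md.rm, vm_out)
        return vp_out, vm_out

    def _loglik(self, vp, vm, lam, d_p, d_m, w0, w1, sigma):
        """Row-wise response log likelihood; all inputs broadcast over (n, T)."""
        md = self.md
        g = vp * np.exp(-lam[:, None] * d_p)
        if md.differential:
            g = g + vm * np.exp(-lam[:, None] * d_m)
        theta = self.A + (self.K - self.A) / (
            1.0 + np.exp(-(w0[:, None] + w1[:, None] * g))
        )
        z = (md.y - theta) / sigma[:, None]
        ll = -0.5 * z * z - np.log(sigma)[:, None] - 0.5 * _LOG_2PI
        return np.where(md.mask, ll, 0.0).sum(axis=1)

    def _theta(self, st, vp, vm):
        """Response means under the current mixed membership."""
        md = self.md
        lam = self._lam_eff(st)
        d_p, d_m = self._d_eff(st)
        learner = st.m != NONLEARNER
        vpe = np.where(learner[:, None], vp, 0.0)
        g = vpe * np.exp(-lam[:, None] * d_p)
        if md.differential:
            vme = np.where(learner[:, None], vm, 0.0)
            g = g + vme * np.exp(-lam[:, None] * d_m)
        return self.A + (self.K - self.A) / (
            1.0 + np.exp(-(st.w0[:, None] + st.w1[:, None] * g))
        )

    def _lam_eff(self, st):
        return np.where(st.m == OVERGENERALIZER, st.lam2, st.lam34)

    def _d_eff(self, st):
        md = self.md
        perc = (st.m == PERCEPTUAL)[:, None]
        d_p = np.where(perc, md.d_perc_p, md.d_phys_p)
        d_m = np.where(perc, md.d_perc_m, md.d_phys_m) if md.differential else None
        return d_p, d_m

    def _sigma_eff(self, st):
        return np.where(
            st.m == NONLEARNER, st.hy["sigma_nonlearner"], st.hy["sigma_learner"]
        )

    def _mixed_loglik(self, st, vp, vm, w0=None, w1=None, lam=None):
        """Likelihood under each participant's current component, optionally
        overriding one parameter vector (for MH proposals)."""
        md = self.md
        lam_ = self._lam_eff(st) if lam is None else lam
        d_p, d_m = self._d_eff(st)
        learner = st.m != NONLEARNER
        vpe = np.where(learner[:, None], vp, 0.0)
        vme = (
            np.where(learner[:, None], vm, 0.0) if md.differential else None
        )
        return self._loglik(
            vpe,
            vme,
            lam_,
            d_p,
            d_m,
            st.w0 if w0 is None else w0,
            st.w1 if w1 is None else w1,
            self._sigma_eff(st),
        )

    def component_loglik(self, st, comp, vp, vm):
        """Likelihood of every participant's data under component ``comp``."""
        md = self.md
        n = md.n
        if comp == NONLEARNER:
            zeros = np.zeros((n, md.T))
            return self._loglik(
                zeros,
                zeros if md.differential else None,
                np.zeros(n),
                md.d_phys_p,
                md.d_phys_m,
                st.w0,
                st.w1,
                np.full(n, st.hy["sigma_nonlearner"]),
            )
        sigma = np.full(n, st.hy["sigma_learner"])
        if comp == OVERGENERALIZER:
            return self._loglik(
                vp, vm, st.lam2, md.d_phys_p, md.d_phys_m, st.w0, st.w1, sigma
            )
        if comp == PHYSICAL:
            return self._loglik(
                vp, vm, st.lam34, md.d_phys_p, md.d_phys_m, st.w0, st.w1, sigma
            )
        if comp == PERCEPTUAL:
            return self._loglik(
                vp, vm, st.lam34, md.d_perc_p, md.d_perc_m, st.w0, st.w1, sigma
            )
        raise ValueError(f"unknown component {comp}")

    # -- sweep ----------------------------------------------------------------

    def run_chain(self, seed) -> Dict[str, np.ndarray]:
        md, cfg = self.md, self.cfg
        rng = np.random.default_rng(seed)
        st = _ChainState(md, self.components, rng, self.fixed_v)
        n = md.n

        scales = {
            "alpha": np.full(n, 0.10),
            "lam2": np.full(n, 1.5e-3),
            "lam34": np.full(n, 0.03),
            "w0": np.full(n, 0.4),
            "w1": np.full(n, 0.8),
        }
        hy_scales = {
            "mu_alpha": 0.08, "kappa_alpha": 0.6, "mu_lambda": 0.04,
            "sigma_lambda": 0.08, "sigma_w0": 0.4, "a_w1": 0.8,
            "b_w1": 0.25, "sigma_learner": 0.06, "sigma_nonlearner": 0.15,
        }
        acc = {k: np.zeros(n) for k in scales}
        hy_acc = {k: 0.0 for k in hy_scales}
        window = 50

        vp, vm = self.compute_v(st.alpha)
        store = {k: [] for k in (
            "m", "alpha", "lam", "w0", "w1", "pi", *st.hy.keys()
        )}

        for it in range(1, cfg.iterations + 1):
            vp, vm = self._sweep(st, vp, vm, rng, scales, hy_scales, acc, hy_acc)

            if it <= cfg.burn_in and it % window == 0:
                for k in scales:
                    rate = acc[k] / window
                    scales[k] *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
                    acc[k][:] = 0.0
                for k in hy_scales:
                    rate = hy_acc[k] / window
                    hy_scales[k] *= float(np.exp(np.clip(rate - 0.35, -0.5, 0.5)))
                    hy_acc[k] = 0.0

            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                learner = st.m != NONLEARNER
                store["m"].append(st.m.copy())
                store["alpha"].append(np.where(learner, st.alpha, 0.0))
                store["lam"].append(
                    np.where(
                        learner,
                        np.where(st.m == OVERGENERALIZER, st.lam2, st.lam34),
                        0.0,
                    )
                )
                store["w0"].append(st.w0.copy())
                store["w1"].append(st.w1.copy())
                store["pi"].append(st.pi.copy())
                for k, v in st.hy.items():
                    store[k].append(v)

        return {k: np.asarray(v) for k, v in store.items()}

    def _mh_vec(self, rng, cur, scale, active, logpost, acc_key, acc):
        if not np.any(active):
            return cur
        prop = cur + rng.normal(0.0, scale, size=cur.shape)
        lp_cur = logpost(cur)
        lp_prop = logpost(prop)
        with np.errstate(invalid="ignore"):
            accept = (
                np.log(rng.uniform(size=cur.shape)) < (lp_prop - lp_cur)
            ) & active
        acc[acc_key] += accept
        return np.where(accept, prop, cur)

    def _sweep(self, st, vp, vm, rng, scales, hy_scales, acc, hy_acc):
        md = self.md
        n = md.n
        hy = st.hy
        a_a, b_a = (
            hy["mu_alpha"] * hy["kappa_alpha"],
            (1.0 - hy["mu_alpha"]) * hy["kappa_alpha"],
        )
        if n:
            learner = st.m != NONLEARNER

            # alpha: MH for learners (changes trajectories), prior draw others
            if not self.fixed_v:
                prop = st.alpha + rng.normal(0.0, scales["alpha"], size=n)
                ok = (prop > 1e-9) & (prop < 1.0 - 1e-9)
                prop_safe = np.clip(prop, 1e-9, 1.0 - 1e-9)
                vp_prop, vm_prop = self.compute_v(prop_safe)
                lp_cur = _beta_logpdf(st.alpha, a_a, b_a) + self._mixed_loglik(
                    st, vp, vm
                )
                lp_prop = np.where(
                    ok,
                    _beta_logpdf(prop_safe, a_a, b_a)
                    + self._mixed_loglik(st, vp_prop, vm_prop),
                    -np.inf,
                )
                accept = (
                    np.log(rng.uniform(size=n)) < (lp_prop - lp_cur)
                ) & learner
                acc["alpha"] += accept
                st.alpha = np.where(accept, prop_safe, st.alpha)
                fresh = ~learner
                if np.any(fresh):
                    st.alpha[fresh] = np.clip(
                        rng.beta(a_a, b_a, size=int(fresh.sum())), 1e-9, 1 - 1e-9
                    )
                vp, vm = self.compute_v(st.alpha)
            else:
                st.alpha = np.clip(rng.beta(a_a, b_a, size=n), 1e-9, 1 - 1e-9)

            # lam2 (overgeneralizer copy)
            act2 = st.m == OVERGENERALIZER
            lnorm2 = _tn_lognorm(hy["mu_lambda"], hy["sigma_lambda"], 0.0, LAMBDA_BOUNDARY)

            def lp_lam2(x):
                inside = (x > 0) & (x <= LAMBDA_BOUNDARY)
                xs = np.clip(x, 1e-12, LAMBDA_BOUNDARY)
                out = _norm_logpdf(xs, hy["mu_lambda"], hy["sigma_lambda"]) - lnorm2
                out = out + self._mixed_loglik(st, vp, vm, lam=xs)
                return np.where(inside, out, -np.inf)

            st.lam2 = self._mh_vec(
                rng, st.lam2, scales["lam2"], act2, lp_lam2, "lam2", acc
            )
            fresh = ~act2
            if np.any(fresh):
                st.lam2[fresh] = _truncnorm_rvs(
                    rng, hy["mu_lambda"], hy["sigma_lambda"], 0.0,
                    LAMBDA_BOUNDARY, int(fresh.sum()),
                )

            # lam34 (physical/perceptual copy)
            act34 = (st.m == PHYSICAL) | (st.m == PERCEPTUAL)
            lnorm34 = _tn_lognorm(
                hy["mu_lambda"], hy["sigma_lambda"], LAMBDA_BOUNDARY, np.inf
            )

            def lp_lam34(x):
                inside = x > LAMBDA_BOUNDARY
                xs = np.maximum(x, LAMBDA_BOUNDARY + 1e-12)
                out = _norm_logpdf(xs, hy["mu_lambda"], hy["sigma_lambda"]) - lnorm34
                out = out + self._mixed_loglik(st, vp, vm, lam=xs)
                return np.where(inside, out, -np.inf)

            st.lam34 = self._mh_vec(
                rng, st.lam34, scales["lam34"], act34, lp_lam34, "lam34", acc
            )
            fresh = ~act34
            if np.any(fresh):
                st.lam34[fresh] = _truncnorm_rvs(
                    rng, hy["mu_lambda"], hy["sigma_lambda"], LAMBDA_BOUNDARY,
                    np.inf, int(fresh.sum()),
                )

            # w0 (all groups)
            def lp_w0(x):
                return _norm_logpdf(
                    x, hy["mu_w0"], hy["sigma_w0"]
                ) + self._mixed_loglik(st, vp, vm, w0=x)

            st.w0 = self._mh_vec(
                rng, st.w0, scales["w0"], np.ones(n, bool), lp_w0, "w0", acc
            )

            # w1 (inert for Non-Learners: prior draw there)
            def lp_w1(x):
                inside = x > 0
                xs = np.maximum(x, 1e-12)
                out = _gamma_logpdf(xs, hy["a_w1"], hy["b_w1"])
                out = out + self._mixed_loglik(st, vp, vm, w1=xs)
                return np.where(inside, out, -np.inf)

            st.w1 = self._mh_vec(
                rng, st.w1, scales["w1"], learner, lp_w1, "w1", acc
            )
            fresh = ~learner
            if np.any(fresh):
                st.w1[fresh] = np.maximum(
                    rng.gamma(hy["a_w1"], 1.0 / hy["b_w1"], size=int(fresh.sum())),
                    1e-9,
                )

            # membership m: exact conditional draw
            ll = np.stack(
                [self.component_loglik(st, c, vp, vm) for c in self.components],
                axis=1,
            )
            logp = np.log(np.maximum(st.pi, 1e-300))[None, :] + ll
            logp -= logp.max(axis=1, keepdims=True)
            p = np.exp(logp)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.uniform(size=n)
            idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
            st.m = np.asarray(self.components)[np.minimum(idx, len(self.components) - 1)]

        # pi | m  (Dirichlet conjugacy)
        counts = np.array([(st.m == c).sum() for c in self.components])
        st.pi = rng.dirichlet(1.0 + counts)

        # hyperparameters
        self._update_hypers(st, vp, vm, rng, hy_scales, hy_acc)
        return vp, vm

    def _update_hypers(self, st, vp, vm, rng, hy_scales, hy_acc):
        hy = st.hy
        n = self.md.n

        def mh(name, logpost):
            cur = hy[name]
            prop = cur + rng.normal(0.0, hy_scales[name])
            lp_c, lp_p = logpost(cur), logpost(prop)
            logr = lp_p - lp_c
            if np.isfinite(logr) and np.log(rng.uniform()) < logr:
                hy[name] = prop
                hy_acc[name] += 1.0

        alpha = st.alpha

        def lp_mu_alpha(x):
            if not 1e-6 < x < 1.0 - 1e-6:
                return -np.inf
            a, b = x * hy["kappa_alpha"], (1.0 - x) * hy["kappa_alpha"]
            return float(_beta_logpdf(alpha, a, b).sum()) if n else 0.0

        def lp_kappa(x):
            if not 1.0 <= x <= 10.0:
                return -np.inf
            a, b = hy["mu_alpha"] * x, (1.0 - hy["mu_alpha"]) * x
            return float(_beta_logpdf(alpha, a, b).sum()) if n else 0.0

        mh("mu_alpha", lp_mu_alpha)
        mh("kappa_alpha", lp_kappa)

        def lam_like(mu, sd):
            if n == 0:
                return 0.0
            l2 = _norm_logpdf(st.lam2, mu, sd) - _tn_lognorm(
                mu, sd, 0.0, LAMBDA_BOUNDARY
            )
            l34 = _norm_logpdf(st.lam34, mu, sd) - _tn_lognorm(
                mu, sd, LAMBDA_BOUNDARY, np.inf
            )
            return float(l2.sum() + l34.sum())

        def lp_mu_lambda(x):
            if x <= 0:
                return -np.inf
            return _norm_logpdf(x, 0.1, 1.0) + lam_like(x, hy["sigma_lambda"])

        def lp_sigma_lambda(x):
            if not 1e-9 < x <= 1.0:
                return -np.inf
            return lam_like(hy["mu_lambda"], x)

        mh("mu_lambda", lp_mu_lambda)
        mh("sigma_lambda", lp_sigma_lambda)

        # mu_w0: conjugate normal draw
        prior_prec = 1.0 / 100.0
        prec = prior_prec + n / hy["sigma_w0"] ** 2
        mean = (st.w0.sum() / hy["sigma_w0"] ** 2) / prec if n else 0.0
        hy["mu_w0"] = rng.normal(mean, 1.0 / np.sqrt(prec))

        def lp_sigma_w0(x):
            if x <= 0:
                return -np.inf
            lp = _halfcauchy_logpdf(x)
            if n:
                lp += float(_norm_logpdf(st.w0, hy["mu_w0"], x).sum())
            return lp

        mh("sigma_w0", lp_sigma_w0)

        def lp_a_w1(x):
            if x <= 0:
                return -np.inf
            lp = _halfcauchy_logpdf(x)
            if n:
                lp += float(_gamma_logpdf(st.w1, x, hy["b_w1"]).sum())
            return lp

        def lp_b_w1(x):
            if x <= 0:
                return -np.inf
            lp = _halfcauchy_logpdf(x)
            if n:
                lp += float(_gamma_logpdf(st.w1, hy["a_w1"], x).sum())
            return lp

        mh("a_w1", lp_a_w1)
        mh("b_w1", lp_b_w1)

        # response noise: residual sums under the current membership
        if n:
            theta = self._theta(st, vp, vm)
            resid2 = np.where(self.md.mask, (self.md.y - theta) ** 2, 0.0)
            learner_rows = st.m != NONLEARNER
            ss_l = float(resid2[learner_rows].sum())
            n_l = int(self.md.mask[learner_rows].sum())
            ss_nl = float(resid2[~learner_rows].sum())
            n_nl = int(self.md.mask[~learner_rows].sum())
        else:
            ss_l = ss_nl = 0.0
            n_l = n_nl = 0

        def lp_sigma_learner(x):
            if not 1e-9 < x < _SIGMA_SPLIT:
                return -np.inf
            return -n_l * np.log(x) - ss_l / (2.0 * x * x)

        def lp_sigma_nonlearner(x):
            if not _SIGMA_SPLIT < x < 3.0:
                return -np.inf
            return -n_nl * np.log(x) - ss_nl / (2.0 * x * x)

        mh("sigma_learner", lp_sigma_learner)
        mh("sigma_nonlearner", lp_sigma_nonlearner)


# ---------------------------------------------------------------------------
# public fitting interface


def _components_for(variant: str) -> Tuple[int, ...]:
    if variant == "simplified1":
        return (NONLEARNER, OVERGENERALIZER, PHYSICAL)
    return (NONLEARNER, OVERGENERALIZER, PHYSICAL, PERCEPTUAL)


def fit(data: pd.DataFrame, config: FitConfig) -> PosteriorSamples:
    """Sample the posterior of the mixture model on a long-format table.

    ``data`` must follow the native trial schema (percepts embedded as the
    ``size_estimate_mm`` column). Reproducible given ``config.seed``; chain
    seeds are spawned from it. Non-convergence is reported through
    ``rhat_table``, never raised.
    """
    md = ModelData(data, paradigm=config.paradigm)
    components = _components_for(config.variant)
    if PERCEPTUAL in components and md.n and not md.has_percepts:
        raise ValueError(
            "perceptual pathway requires size estimates; "
            "use variant='simplified1' for percept-free data"
        )
    sampler = _Sampler(md, config, components)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [sampler.run_chain(s) for s in seeds]
    draws = {
        k: np.stack([c[k] for c in chains], axis=0) for k in chains[0]
    }
    return PosteriorSamples(
        draws=draws,
        participants=md.participants,
        components=components,
        paradigm=md.paradigm,
        config=config,
    )


def fit_simplified(
    data: pd.DataFrame, variant: str, config: FitConfig
) -> PosteriorSamples:
    """Fit one of the ablated models (``simplified1``/``simplified2``)."""
    if variant not in ("simplified1", "simplified2"):
        raise ValueError("variant must be 'simplified1' or 'simplified2'")
    return fit(data, replace(config, variant=variant))


def predict_theta(
    samples: PosteriorSamples, data: pd.DataFrame, chain: int, draw: int
) -> np.ndarray:
    """Response means (n, T) implied by one joint posterior draw."""
    md = ModelData(data, paradigm=samples.paradigm)
    sampler = _Sampler(md, samples.config, samples.components)
    st = _FrozenState(samples, chain, draw)
    vp, vm = sampler.compute_v(st.alpha)
    return sampler._theta(st, vp, vm)


class _FrozenState:
    """Adapter exposing one stored posterior draw with the chain-state API."""

    def __init__(self, samples: PosteriorSamples, chain: int, draw: int):
        d = samples.draws
        self.m = d["m"][chain, draw]
        self.alpha = d["alpha"][chain, draw]
        lam = d["lam"][chain, draw]
        # both copies collapse onto the stored active value
        self.lam2 = lam
        self.lam34 = lam
        self.w0 = d["w0"][chain, draw]
        self.w1 = d["w1"][chain, draw]
        self.hy = {
            "sigma_learner": float(d["sigma_learner"][chain, draw]),
            "sigma_nonlearner": float(d["sigma_nonlearner"][chain, draw]),
        }
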
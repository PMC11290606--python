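"""Sampler mechanics: draw accounting, determinism, diagnostics, limits."""

import numpy as np
import pandas as pd
import pytest

from genmix.cohort import CohortSpec, simulate_cohort
from genmix.mcmc import (
    FitConfig,
    PosteriorSamples,
    _tn_lognorm,
    fit,
    gelman_rubin,
    predict_theta,
    rhat,
)
from genmix.model import PHYSICAL

EMPTY = pd.DataFrame(
    columns=[
        "participant", "trial", "phase", "block", "role", "stimulus",
        "size_mm", "us", "k", "size_estimate_mm", "expectancy",
    ]
)


class TestConfig:
    def test_paper_preset_draw_accounting(self):
        cfg = FitConfig.paper()
        assert (cfg.chains, cfg.iterations, cfg.burn_in, cfg.thin) == (
            4, 100_000, 75_000, 10,
        )
        assert cfg.retained_per_chain == 2_500
        assert cfg.chains * cfg.retained_per_chain == 10_000

    @pytest.mark.parametrize(
        "iters, burn, thin", [(4000, 2000, 2), (101, 1, 10), (50, 25, 1)]
    )
    def test_retained_closed_form(self, iters, burn, thin):
        cfg = FitConfig(iterations=iters, burn_in=burn, thin=thin)
        assert cfg.retained_per_chain == (iters - burn) // thin

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            FitConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            FitConfig(thin=0)
        with pytest.raises(ValueError):
            FitConfig(variant="nope")


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        chains = np.ones((4, 200))
        assert gelman_rubin(chains) == 1.0

    def test_single_distribution_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_shifted_chains_diverge(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 500)) + np.arange(4)[:, None] * 5
        assert gelman_rubin(chains) > 2.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_matches_arviz(self):
        """Cross-check the split-chain statistic against arviz."""
        import arviz as az

        rng = np.random.default_rng(7)
        chains = np.cumsum(rng.normal(size=(4, 400)), axis=1) * 0.01 + rng.normal(
            size=(4, 400)
        )
        ours = gelman_rubin(chains)
        theirs = float(
            az.rhat(az.convert_to_dataset(chains[..., None]))["x"].values[0]
        )
        assert ours == pytest.approx(theirs, rel=0.01)


class TestTruncatedNormalNormalizer:
    def test_matches_quadrature(self):
        from scipy import integrate, stats

        for mu, sd, lo, hi in [(0.1, 0.5, 0.0, 0.0052), (0.1, 1.0, 0.0052, np.inf),
                               (0.0026, 0.001, 0.0, 0.0052)]:
            expected = stats.norm(mu, sd).cdf(min(hi, 1e6)) - stats.norm(mu, sd).cdf(lo)
            assert _tn_lognorm(mu, sd, lo, hi) == pytest.approx(
                np.log(expected), abs=1e-8
            )

    def test_deep_tail_stays_finite(self):
        val = _tn_lognorm(0.5, 0.01, 0.0, 0.0052)
        assert np.isfinite(val) and val < -100


class TestFit:
    def test_deterministic_given_seed(self, small_cohort):
        table, _ = small_cohort
        sub = table[table["participant"].isin(["P001", "P003"])]
        cfg = FitConfig.test(seed=5, iterations=300, burn_in=150, chains=2)
        a = fit(sub, cfg)
        b = fit(sub, cfg)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_empty_data_posterior_matches_prior(self):
        """With no observations the sampler must reproduce the hyperpriors."""
        cfg = FitConfig.test(seed=3, iterations=4000, burn_in=1000, thin=1, chains=2)
        ps = fit(EMPTY, cfg)
        assert ps.draws["mu_alpha"].mean() == pytest.approx(0.5, abs=0.05)
        assert ps.draws["kappa_alpha"].mean() == pytest.approx(5.5, abs=0.4)
        assert ps.draws["sigma_learner"].mean() == pytest.approx(0.75, abs=0.06)
        assert ps.draws["sigma_nonlearner"].mean() == pytest.approx(2.25, abs=0.08)
        np.testing.assert_allclose(
            ps.draws["pi"].mean(axis=(0, 1)), 0.25, atol=0.03
        )

    def test_single_learner_membership_recovery(self):
        """A clean Physical Generalizer is classified as such."""
        from genmix.cohort import GroupRule, default_sim_rules

        rules = default_sim_rules()
        rules[PHYSICAL] = GroupRule(
            alpha=lambda rng: 0.9, lam=lambda rng: 0.05,
            w0=lambda rng: -2.0, w1=lambda rng: 10.0, sigma=0.3,
        )
        spec = CohortSpec(n_per_group=(0, 0, 1, 0), rules=rules, seed=2)
        table, _ = simulate_cohort(spec)
        cfg = FitConfig.test(seed=11, iterations=1500, burn_in=800, chains=2)
        ps = fit(table, cfg)
        m = ps.m_draws().ravel()
        assert np.mean(m == PHYSICAL) > 0.5

    def test_rhat_table_and_accessor(self, small_cohort):
        table, _ = small_cohort
        sub = table[table["participant"].isin(["P005", "P007"])]
        cfg = FitConfig.test(seed=8, iterations=400, burn_in=200, chains=2)
        ps = fit(sub, cfg)
        rt = ps.rhat_table()
        assert {"parameter", "rhat", "converged"} <= set(rt.columns)
        assert len(rt[rt["parameter"] == "mu_alpha"]) == 1
        assert np.isfinite(rhat(ps, "mu_w0"))
        vec = rhat(ps, "w0")
        assert vec.shape == (2,)

    def test_save_load_roundtrip(self, small_cohort, tmp_path):
        table, _ = small_cohort
        sub = table[table["participant"] == "P002"]
        cfg = FitConfig.test(seed=4, iterations=300, burn_in=150, chains=2)
        ps = fit(sub, cfg)
        path = tmp_path / "fit.npz"
        ps.save(path)
        back = PosteriorSamples.load(path)
        assert back.participants == ps.participants
        assert back.config == ps.config
        for k in ps.draws:
            np.testing.assert_array_equal(back.draws[k], ps.draws[k])

    def test_full_variant_requires_percepts(self, small_cohort):
        table, _ = small_cohort
        stripped = table.drop(columns=["size_estimate_mm"])
        with pytest.raises(ValueError, match="perceptual"):
            fit(stripped, FitConfig.test(seed=1, iterations=100, burn_in=50))

    def test_simplified1_has_no_perceptual_component(self, small_cohort):
        table, _ = small_cohort
        sub = table[table["participant"].isin(["P001", "P005"])]
        cfg = FitConfig.test(
            seed=6, iterations=300, burn_in=150, chains=2, variant="simplified1"
        )
        ps = fit(sub, cfg)
        assert ps.components == (1, 2, 3)
        assert set(np.unique(ps.m_draws())) <= {1, 2, 3}
        assert ps.draws["pi"].shape[-1] == 3

    def test_predict_theta_matches_forward_model(self, small_cohort):
        """The sampler's internal trajectory math agrees with the reference
        forward model for a stored draw."""
        from genmix.designs import TrialSchedule, build_exp2_design, exp2_stimuli
        from genmix.model import ParticipantParams, PerceptStream, forward_trajectory

        table, _ = small_cohort
        sub = table[table["participant"] == "P007"]  # physical generalizer
        cfg = FitConfig.test(seed=9, iterations=300, burn_in=150, chains=2)
        ps = fit(sub, cfg)
        theta = predict_theta(ps, sub, chain=0, draw=10)
        d = ps.draws
        m = int(d["m"][0, 10, 0])
        params = ParticipantParams(
            m=m,
            alpha=float(d["alpha"][0, 10, 0]),
            lam=float(d["lam"][0, 10, 0]),
            w0=float(d["w0"][0, 10, 0]),
            w1=float(d["w1"][0, 10, 0]),
            check=False,
        )
        sched = TrialSchedule(
            frame=sub.drop(columns=["participant", "experiment",
                                    "size_estimate_mm", "expectancy"]),
            design=build_exp2_design(), stimuli=exp2_stimuli(),
        )
        stream = PerceptStream(sub["size_estimate_mm"].to_numpy(),
                               sub["role"].to_numpy())
        traj = forward_trajectory(sched, stream, params, "differential")
        np.testing.assert_allclose(theta[0], traj.theta, atol=1e-10)
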
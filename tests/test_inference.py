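"""Posterior machinery: sampler, HPD, inequality probabilities, DIC."""

import numpy as np
import pytest
from scipy import stats

import oracles
from conftest import small_sim
from smfm.inference import (MCMCConfig, Prior, PriorSpec,
                            adaptive_metropolis, build_param_space,
                            dic_stats, hpd_interval, posterior_prob,
                            run_mcmc, summarize)
from smfm.smfm_core import ModelVariant, SMFMParams


class TestHPD:
    def test_uniform_integer_case(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94
        assert float(lo).is_integer() and float(hi).is_integer()

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(99), 0.95)

    @pytest.mark.parametrize("dist,seed", [("normal", 0), ("expon", 1),
                                           ("lognorm", 2)])
    def test_equals_brute_force_scan(self, dist, seed):
        rng = np.random.default_rng(seed)
        draws = {"normal": rng.normal(size=500),
                 "expon": rng.exponential(size=500),
                 "lognorm": rng.lognormal(size=500)}[dist]
        assert hpd_interval(draws, 0.95) == oracles.brute_hpd(draws, 0.95)
        assert hpd_interval(draws, 0.5) == oracles.brute_hpd(draws, 0.5)

    def test_exponential_hpd_hugs_zero_and_beats_central(self):
        rng = np.random.default_rng(5)
        draws = rng.exponential(size=100_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo < 0.01
        central = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < central[1] - central[0]

    def test_symmetric_sample_close_to_central_interval(self):
        rng = np.random.default_rng(6)
        draws = rng.normal(size=100_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)


class TestPosteriorProb:
    def test_all_positive_draws(self):
        assert posterior_prob(np.ones(10), "le", 0.0) == 0.0

    def test_identically_zero_contrast(self):
        x = np.random.default_rng(0).normal(size=50)
        assert posterior_prob(x - x, "le", 0.0) == 1.0

    def test_standard_normal_half(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=40_000)
        mcse = 0.5 / np.sqrt(draws.size)
        assert posterior_prob(draws, "le", 0.0) == \
            pytest.approx(0.5, abs=3 * mcse)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            posterior_prob(np.array([]))


class TestDIC:
    def test_degenerate_chain_has_zero_pd(self):
        dev = np.full(200, 123.4)
        d, dbar, pd_ = dic_stats(dev, 123.4)
        assert pd_ == pytest.approx(0.0, abs=1e-9)
        assert d == pytest.approx(dbar) == pytest.approx(123.4)

    def test_normal_mean_toy_pd_is_one(self):
        # y ~ N(theta, 1), flat prior: theta | y ~ N(ybar, 1/n);
        # pD = E[D] - D(thetabar) = n Var(theta) ~ 1 free parameter
        rng = np.random.default_rng(8)
        n = 50
        y = rng.normal(0.3, 1.0, size=n)
        thetas = rng.normal(y.mean(), np.sqrt(1 / n), size=40_000)
        dev = np.array([np.sum((y - th) ** 2) for th in thetas])
        _, _, pd_ = dic_stats(dev, np.sum((y - thetas.mean()) ** 2))
        assert pd_ == pytest.approx(1.0, abs=0.1)


class TestSampler:
    def test_recovers_standard_normal_target(self):
        rng = np.random.default_rng(11)
        draws, _, rate = adaptive_metropolis(
            lambda x: float(-0.5 * x @ x), np.zeros(2), n_iter=12_000,
            n_burn=2000, thin=1, rng=rng)
        ess_floor = 500  # conservative for a tuned RWM at d=2
        mcse = 1.0 / np.sqrt(ess_floor)
        assert draws[:, 0].mean() == pytest.approx(0.0, abs=3 * mcse)
        assert draws[:, 0].std() == pytest.approx(1.0, abs=0.1)
        assert 0.1 < rate < 0.6

    def test_seeded_determinism_of_full_fit(self):
        log, params, _, _ = small_sim(seed=4, length=80.0, size=4,
                                      n_groups=1, n_sessions=2)
        variant = ModelVariant(condition="any")
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_burn=100, seed=12)
        a = run_mcmc(log, variant, config=cfg, template=params)
        b = run_mcmc(log, variant, config=cfg, template=params)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.loglik, b.loglik)

    def test_every_draw_is_a_valid_parameter_set(self):
        log, params, _, _ = small_sim(seed=4, length=80.0, size=4,
                                      n_groups=1, n_sessions=2)
        variant = ModelVariant(condition="any")
        cfg = MCMCConfig(n_chains=1, n_iter=250, n_burn=50, seed=1)
        chains = run_mcmc(log, variant, config=cfg, template=params)
        for z in chains.z[0][::25]:
            assert chains.space.to_params(z).validation_errors() == []

    def test_posterior_tightens_with_more_sessions(self):
        # simulation-consistency: the r posteriors shrink as data grow
        sds = {}
        for n_sessions in (2, 8):
            log, params, _, _ = small_sim(seed=6, length=100.0, size=5,
                                          n_groups=1,
                                          n_sessions=n_sessions)
            variant = ModelVariant(condition="any")
            cfg = MCMCConfig(n_chains=1, n_iter=1200, n_burn=400, seed=2)
            chains = run_mcmc(log, variant, config=cfg, template=params)
            flat = chains.flat()
            j = chains.names.index("r:flap")
            sds[n_sessions] = flat[:, j].std()
        assert sds[8] < sds[2]


class TestParamSpace:
    def test_round_trip_through_transforms(self, rich_params):
        variant = ModelVariant(condition="any", lambda_by_dominance=True,
                               g_by_age=True, sametype_kernel=True,
                               social_classes=("manipulation", "entry",
                                               "feeding"),
                               covariates=("sex=M",))
        space = build_param_space(variant, rich_params)
        x = space.natural_from_params(rich_params)
        z = space.z_from_natural(x)
        assert np.allclose(space.natural(z), x)
        p = space.to_params(z)
        assert p.rho == pytest.approx(rich_params.rho)
        assert p.lambda_a == pytest.approx(rich_params.lambda_a)
        assert p.beta["sex=M"] == pytest.approx(
            rich_params.beta["sex=M"])

    def test_tied_parameters_set_all_keys(self):
        variant = ModelVariant(condition="any")
        template = SMFMParams.build(r=0.01, lambda_a=0.05,
                                    s={"entry": 0.01}, g_general=1.0,
                                    g_box=1.0, g_specific=1.0)
        space = build_param_space(variant, template)
        z = space.z_from_natural(space.initial_natural())
        p = space.to_params(z)
        assert len(set(p.lambda_a.values())) == 1
        assert len(set(p.g_specific.values())) == 1

    def test_no_transient_variant_zeroes_strengths(self):
        variant = ModelVariant(condition="any", transient=False,
                               label="none")
        template = SMFMParams.build(r=0.01, g_general=2.0, g_box=2.0,
                                    g_specific=2.0)
        space = build_param_space(variant, template)
        assert "rho" not in space.names
        p = space.to_params(space.z_from_natural(space.initial_natural()))
        assert all(v == 0.0 for v in p.g_general.values())
        assert all(v == 0.0 for v in p.g_specific.values())

    def test_prior_override_is_used(self):
        variant = ModelVariant(condition="any")
        template = SMFMParams.build(r=0.01, lambda_a=0.05,
                                    s={"entry": 0.01}, g_general=1.0,
                                    g_box=1.0, g_specific=1.0)
        priors = PriorSpec({"gamma": Prior("halfnormal", 0.1)})
        space = build_param_space(variant, template, priors)
        j = space.names.index("gamma")
        assert space.free[j].prior.a == 0.1

    def test_log_prior_tracks_scipy(self):
        variant = ModelVariant(condition="any")
        template = SMFMParams.build(r=0.01, lambda_a=0.05,
                                    s={"entry": 0.01}, g_general=1.0,
                                    g_box=1.0, g_specific=1.0)
        space = build_param_space(variant, template)
        x = space.initial_natural()
        z = space.z_from_natural(x)
        manual = 0.0
        for j, f in enumerate(space.free):
            manual += f.prior.logpdf(x[j])
            if f.kind == "log":
                manual += z[j]
            elif f.kind == "logit":
                manual += np.log(x[j]) + np.log1p(-x[j])
        assert space.log_prior(z) == pytest.approx(manual)
        _ = stats  # keep the scipy import honest


class TestCompareVariants:
    def test_identical_variants_have_near_zero_delta_dic(self):
        from smfm.inference import compare_variants
        log, params, _, _ = small_sim(seed=25, length=120.0, size=5,
                                      n_groups=1, n_sessions=3)
        variants = [ModelVariant(label="a", condition="any"),
                    ModelVariant(label="b", condition="any")]
        cfg = MCMCConfig(n_chains=2, n_iter=900, n_burn=400, seed=4)
        table = compare_variants(log, variants, config=cfg,
                                 template=params)
        assert list(table["variant"]) == ["a", "b"]
        assert table["delta_dic"].iloc[0] == 0.0
        slack = 6 * table["dic_se"].max() + 2.0
        assert abs(table["delta_dic"].iloc[1]) < slack
        assert (table["pd"] > 0).all()


class TestSummarize:
    def test_summary_and_contrasts(self):
        log, params, _, _ = small_sim(seed=4, length=80.0, size=4,
                                      n_groups=1, n_sessions=2)
        variant = ModelVariant(condition="any")
        cfg = MCMCConfig(n_chains=2, n_iter=400, n_burn=150, seed=3)
        chains = run_mcmc(log, variant, config=cfg, template=params)
        s = summarize(chains,
                      contrasts={"spec-box": "g:specific - g:box"})
        assert set(s.table.columns) == {"median", "hpd_lo", "hpd_hi",
                                        "ess", "rhat"}
        assert (s.table["hpd_lo"] < s.table["hpd_hi"]).all()
        row = s.contrasts.loc["spec-box"]
        assert 0.0 <= row["p_le_0"] <= 1.0
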
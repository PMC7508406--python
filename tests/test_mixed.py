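"""Gibbs sampler correctness, posterior summaries, DIC and model ranking."""

import numpy as np
import pandas as pd
import pytest

from relaxsel.curves import InverseParams, WeibullParams
from relaxsel.mixed import (
    Design,
    GibbsSamples,
    MCMCConfig,
    PhyloMetaRegression,
    build_design,
    compute_dic,
    rank_models,
    run_chains,
    run_gibbs,
    summarize_posterior,
)

SHORT = MCMCConfig.scaled_down(n_iter=8000, burn_in=1000, thin=5)


def _records(n, rng, species=4, studies=5):
    return pd.DataFrame(
        {
            "generation": np.resize(np.linspace(0, 40, 5), n),
            "standardized_mean": rng.normal(size=n),
            "weight": np.ones(n),
            "species_id": [f"sp{i % species}" for i in range(n)],
            "study_id": [f"st{i % studies}" for i in range(n)],
            "trait_class": ["behavioral" if i % 2 else "physiological"
                            for i in range(n)],
        }
    )


class TestBuildDesign:
    def test_inverse_basis_column(self, rng):
        rec = _records(3, rng)
        rec["generation"] = [0.0, 1.0, 2.0]
        d = build_design(rec, InverseParams(0.0, 1.0, 0.5),
                         random_levels=("study",))
        np.testing.assert_allclose(d.X[:, 1], [1.0, 0.5, 0.25])
        assert d.colnames == ["intercept", "basis"]

    def test_interaction_gives_two_intercepts_two_slopes(self, rng):
        rec = _records(4, rng, species=2)
        lh = pd.DataFrame(
            {"species_id": ["sp0", "sp1"], "foraging_guild": ["herbivore", "omnivore"],
             "sociality": ["solitary", "gregarious"], "max_longevity": [10.0, 12.0]}
        )
        d = build_design(rec, InverseParams(0.0, 1.0, 0.5), group="foraging_guild",
                         lifehistory=lh, random_levels=("study",))
        assert d.X.shape[1] == 4
        assert sum(n.startswith("intercept[") for n in d.colnames) == 2
        assert sum(n.startswith("basis[") for n in d.colnames) == 2

    def test_weibull_basis_zero_before_onset(self, rng):
        rec = _records(3, rng)
        rec["generation"] = [1.0, 5.0, 20.0]
        p = WeibullParams(y_ini=0.5, a=3.0, k=2.0, lam=10.0, t_min=4.0)
        d = build_design(rec, p, random_levels=("study",))
        assert d.X[0, 1] == 0.0
        assert d.X[1, 1] > 0.0

    def test_missing_lifehistory_species_listed(self, rng):
        rec = _records(4, rng, species=2)
        lh = pd.DataFrame(
            {"species_id": ["sp0"], "foraging_guild": ["herbivore"],
             "sociality": ["solitary"], "max_longevity": [10.0]}
        )
        with pytest.raises(ValueError, match="sp1"):
            build_design(rec, InverseParams(0.0, 1.0, 0.5), group="sociality",
                         lifehistory=lh, random_levels=("study",))

    def test_collinear_fixed_effects_rejected(self, rng):
        rec = _records(6, rng)
        rec["generation"] = 0.0  # basis column == intercept column
        with pytest.raises(ValueError, match="singular|collinear"):
            build_design(rec, InverseParams(0.0, 1.0, 0.5),
                         random_levels=("study",))


class TestGibbsCorrectness:
    def test_known_variance_conjugate_posterior(self, rng):
        """With sigma2 fixed, beta's posterior is the closed-form Gaussian."""
        n, sigma2 = 120, 0.49
        x = rng.normal(size=n)
        beta_true = 1.3
        y = beta_true * x + rng.normal(0, np.sqrt(sigma2), n)
        d = Design(y=y, X=x[:, None], colnames=["b"], weights=np.ones(n), levels={})
        s = run_gibbs(d, MCMCConfig.scaled_down(n_iter=30000, burn_in=2000, thin=2,
                                                seed=3),
                      fix_residual=sigma2)
        # analytic conjugate posterior under a flat prior
        post_mean = float(x @ y / (x @ x))
        post_var = sigma2 / float(x @ x)
        draws = s.beta[:, 0]
        ess = draws.size  # thin=2 on an independence-like chain; conservative SEs below
        mc_se_mean = np.sqrt(post_var / 1000)
        assert draws.mean() == pytest.approx(post_mean, abs=3 * mc_se_mean)
        mc_se_var = post_var * np.sqrt(2.0 / 1000)
        assert draws.var(ddof=1) == pytest.approx(post_var, abs=3 * mc_se_var)

    def test_variance_components_recovered_within_factor_two(self, rng):
        ns, per = 40, 10
        study = np.repeat(np.arange(ns), per)
        y = 1.0 + rng.normal(0, 1, ns)[study] + rng.normal(0, 1, ns * per)
        d = Design(y=y, X=np.ones((ns * per, 1)), colnames=["intercept"],
                   weights=np.ones(ns * per), levels={"study": (study, ns)})
        s = run_gibbs(d, MCMCConfig.scaled_down(seed=4))
        assert 0.5 <= np.median(s.sigma2["study"]) <= 2.0
        assert 0.5 <= np.median(s.sigma2["residual"]) <= 2.0

    def test_config_guards(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_reproducible_given_seed(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        d = Design(y=y, X=x[:, None], colnames=["b"], weights=np.ones(n),
                   levels={"study": (np.arange(n) % 5, 5)})
        cfg = MCMCConfig.scaled_down(n_iter=2000, burn_in=200, thin=2, seed=9)
        s1, s2 = run_gibbs(d, cfg), run_gibbs(d, cfg)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.sigma2["residual"], s2.sigma2["residual"])

    def test_doubling_weights_leaves_beta_posterior_unchanged(self, rng):
        n = 200
        x = np.linspace(0, 1, n)
        y = 2.0 * x + rng.normal(0, 0.5, n)
        w = rng.uniform(1, 10, n)
        X = np.column_stack([np.ones(n), x])
        d1 = Design(y=y, X=X, colnames=["i", "s"], weights=w, levels={})
        d2 = Design(y=y, X=X, colnames=["i", "s"], weights=2 * w, levels={})
        cfg = MCMCConfig.scaled_down(n_iter=30000, burn_in=2000, thin=5, seed=5)
        s1, s2 = run_gibbs(d1, cfg), run_gibbs(d2, cfg)
        se = s1.beta.std(axis=0) / np.sqrt(500)
        np.testing.assert_allclose(
            s1.beta.mean(axis=0), s2.beta.mean(axis=0), atol=3 * np.max(se)
        )
        # residual variance rescales by the weight factor
        assert np.median(s2.sigma2["residual"]) == pytest.approx(
            2 * np.median(s1.sigma2["residual"]), rel=0.2
        )

    def test_identity_phylo_exchangeable_with_species(self, rng):
        """With A = I the species/phylogeny split is unidentified but their
        sum is recovered."""
        n_sp, per = 25, 12
        sp = np.repeat(np.arange(n_sp), per)
        u = rng.normal(0, np.sqrt(0.8), n_sp)  # combined species-linked var 0.8
        y = u[sp] + rng.normal(0, 0.5, n_sp * per)
        d = Design(
            y=y, X=np.ones((n_sp * per, 1)), colnames=["intercept"],
            weights=np.ones(n_sp * per),
            levels={"species": (sp, n_sp), "phylogeny": (sp, n_sp)},
            phylo_A=np.eye(n_sp),
        )
        s = run_gibbs(d, MCMCConfig.scaled_down(seed=6))
        total = np.median(s.sigma2["species"] + s.sigma2["phylogeny"])
        assert 0.4 <= total <= 1.6

    def test_five_chains_agree(self, rng):
        n = 150
        x = np.linspace(0, 1, n)
        y = 1.5 * x + rng.normal(0, 0.3, n)
        d = Design(y=y, X=np.column_stack([np.ones(n), x]), colnames=["i", "s"],
                   weights=np.ones(n), levels={})
        cfg = MCMCConfig(n_iter=4000, burn_in=500, thin=5, seed=7, n_chains=5)
        s = run_chains(d, cfg)
        means, ses = [], []
        for c in range(5):
            draws = s.beta[s.chain_id == c, 1]
            means.append(draws.mean())
            ses.append(draws.std(ddof=1) / np.sqrt(draws.size))
        spread = max(means) - min(means)
        combined_se = np.sqrt(np.mean(np.square(ses)))
        assert spread <= 2 * 3 * combined_se


class TestSummaries:
    def _samples(self, beta_draws):
        beta = np.asarray(beta_draws, float)[:, None]
        return GibbsSamples(
            beta=beta, colnames=["b"],
            sigma2={"residual": np.ones(beta.shape[0])},
            config=MCMCConfig.scaled_down(),
        )

    def test_one_sided_degenerate_pmcmc_floored(self):
        s = self._samples(np.ones(400))
        out = summarize_posterior(s)
        row = out[out["term"] == "b"].iloc[0]
        assert row["pMCMC"] == pytest.approx(1 / 400)
        assert row["significant"]

    def test_perfectly_balanced_draws_not_significant(self):
        s = self._samples([1.0, -1.0] * 200)
        row = summarize_posterior(s).iloc[0]
        assert row["pMCMC"] == 1.0
        assert not row["significant"]

    def test_normal_draws_credible_interval(self, rng):
        s = self._samples(rng.standard_normal(1000))
        row = summarize_posterior(s).iloc[0]
        assert row["lower"] == pytest.approx(-1.96, abs=0.15)
        assert row["upper"] == pytest.approx(1.96, abs=0.15)

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValueError):
            summarize_posterior(self._samples(np.ones(50)))


class TestDIC:
    def _design(self, rng, n=80):
        x = np.linspace(0, 1, n)
        y = 1.0 + 2 * x + rng.normal(0, 0.4, n)
        return Design(y=y, X=np.column_stack([np.ones(n), x]),
                      colnames=["i", "s"], weights=np.ones(n), levels={})

    def test_degenerate_posterior_has_zero_pd(self, rng):
        d = self._design(rng)
        beta = np.tile([1.0, 2.0], (200, 1))
        s = GibbsSamples(beta=beta, colnames=d.colnames,
                         sigma2={"residual": np.full(200, 0.16)},
                         config=MCMCConfig.scaled_down())
        out = compute_dic(s, d)
        assert out["pD"] == pytest.approx(0.0, abs=1e-9)
        assert out["DIC"] == pytest.approx(out["mean_deviance"], abs=1e-9)

    def test_dic_recomputation_is_deterministic(self, rng):
        d = self._design(rng)
        s = run_gibbs(d, MCMCConfig.scaled_down(n_iter=3000, burn_in=500,
                                                thin=5, seed=2))
        assert compute_dic(s, d) == compute_dic(s, d)

    def test_pure_noise_covariate_costs_about_one_parameter(self, rng):
        """Adding an uninformative fixed effect raises pD by ~1."""
        diffs = []
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            n = 80
            x = np.linspace(0, 1, n)
            noise_col = r.normal(size=n)
            y = 1.0 + 2 * x + r.normal(0, 0.4, n)
            base = Design(y=y, X=np.column_stack([np.ones(n), x]),
                          colnames=["i", "s"], weights=np.ones(n), levels={})
            aug = Design(y=y, X=np.column_stack([np.ones(n), x, noise_col]),
                         colnames=["i", "s", "z"], weights=np.ones(n), levels={})
            cfg = MCMCConfig.scaled_down(n_iter=4000, burn_in=1000, thin=3,
                                         seed=200 + rep)
            pd_base = compute_dic(run_gibbs(base, cfg), base)["pD"]
            pd_aug = compute_dic(run_gibbs(aug, cfg), aug)["pD"]
            diffs.append(pd_aug - pd_base)
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.5)


class TestRankModels:
    def test_equal_dics_equal_weights(self):
        out = rank_models([10.0, 10.0, 10.0, 10.0])
        np.testing.assert_allclose(out["weight"], 0.25)

    def test_delta_two_gives_731_269(self):
        out = rank_models([100.0, 102.0], labels=["a", "b"])
        assert out.loc[0, "weight"] == pytest.approx(0.731, abs=5e-4)
        assert out.loc[1, "weight"] == pytest.approx(0.269, abs=5e-4)

    def test_weights_sum_to_one_and_delta_nonnegative(self, rng):
        out = rank_models(list(rng.uniform(50, 80, 6)))
        assert out["weight"].sum() == pytest.approx(1.0)
        assert (out["delta_DIC"] >= 0).all()
        assert out["delta_DIC"].min() == 0.0


class TestEstimator:
    def test_fit_attributes_and_predict(self, sim_dataset):
        rec = sim_dataset.records
        sub = rec[rec["context"] == "domestication"].copy()
        sub["standardized_mean"] = sub.pop("latent_response")
        sub["weight"] = sub["sample_size"].astype(float)
        truth = sim_dataset.truth["contexts"]["domestication"]["mean_params"]
        est = PhyloMetaRegression(
            InverseParams(**truth),
            random_levels=("study", "species", "trait_type"),
            mcmc=MCMCConfig.scaled_down(n_iter=3000, burn_in=500, thin=5, seed=8),
        ).fit(sub)
        assert hasattr(est, "samples_") and hasattr(est, "dic_")
        slope = est.summary_.set_index("term").loc["basis"]
        assert slope["significant"]
        # slope recovers the generating k
        assert slope["post_mean"] == pytest.approx(truth["k"], abs=0.4)
        pred = est.predict(sub)
        assert pred.shape == (len(sub),)

    def test_get_set_params(self):
        est = PhyloMetaRegression(InverseParams(0, 1, 0.5))
        p = est.get_params()
        assert p["response"] == "standardized_mean"
        est.set_params(longevity=True)
        assert est.longevity
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
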
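"""Sampler correctness, joint-density consistency, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from fire_extremes import priors
from fire_extremes.inference import compute_rhat, fit, holdout_loglik, posterior_predict
from fire_extremes.inference.api import PosteriorDraws, rhat_flags
from fire_extremes.inference.nuts import nuts_chain
from fire_extremes.inference.posteriors import CountPosterior, SizePosterior


@pytest.fixture(scope="module")
def train_design(toy_panel, toy_hierarchy, toy_specs):
    from fire_extremes.design import build_design_matrix

    train = toy_panel[toy_panel["split"] == "train"].reset_index(drop=True)
    return train, build_design_matrix(train, toy_hierarchy, toy_specs)


@pytest.fixture(scope="module")
def event_design(toy_catalog, toy_panel, toy_hierarchy, toy_specs):
    from fire_extremes.design import build_design_matrix
    from fire_extremes.experiments import events_with_covariates

    ev = events_with_covariates(toy_catalog, toy_panel)
    ev_train = ev[ev["split"] == "train"].reset_index(drop=True)
    return ev_train, build_design_matrix(ev_train, toy_hierarchy, toy_specs)


class TestNutsOnTractableTargets:
    def test_conjugate_normal_posterior(self):
        """Normal likelihood + normal prior: closed-form posterior."""
        rng_data = np.random.default_rng(1)
        y = rng_data.normal(1.5, 1.0, size=10)
        prior_var = 4.0
        post_var = 1.0 / (len(y) + 1.0 / prior_var)
        post_mean = post_var * y.sum()

        def logp_grad(x):
            th = x[0]
            return (
                -0.5 * np.sum((y - th) ** 2) - th**2 / (2 * prior_var),
                np.array([np.sum(y - th) - th / prior_var]),
            )

        rng = np.random.default_rng(5)
        draws, _ = nuts_chain(logp_grad, np.zeros(1), 4000, 500, rng)
        mc_se = draws.std() / np.sqrt(200.0)  # conservative ESS guess
        assert abs(draws.mean() - post_mean) < 3 * mc_se
        assert abs(draws.std() - np.sqrt(post_var)) < 0.1 * np.sqrt(post_var)

    def test_correlated_gaussian_covariance(self):
        rng0 = np.random.default_rng(0)
        A = rng0.normal(size=(4, 4))
        cov = A @ A.T + np.eye(4)
        prec = np.linalg.inv(cov)

        def lg(x):
            return -0.5 * x @ prec @ x, -prec @ x

        draws = []
        for c in range(2):
            r = np.random.default_rng(10 + c)
            d, _ = nuts_chain(lg, r.normal(size=4), 1500, 500, r)
            draws.append(d)
        D = np.concatenate(draws)
        assert np.abs(D.mean(axis=0)).max() < 0.2
        assert np.abs(np.cov(D.T) - cov).max() < 0.15 * np.abs(cov).max()


class TestGradients:
    """Analytic gradients of every joint posterior vs finite differences."""

    @pytest.mark.parametrize("family", ["poisson", "nb", "zip", "zinb"])
    def test_count_families(self, family, train_design):
        train, dm = train_design
        post = CountPosterior(
            family, dm, train["count"].to_numpy(), np.log(train["area_km2"].to_numpy())
        )
        self._check(post, seed=3)

    @pytest.mark.parametrize(
        "family", ["lognormal", "gamma", "weibull", "gpd_lomax", "tapered_pareto"]
    )
    def test_size_families(self, family, event_design):
        ev, dm = event_design
        post = SizePosterior(family, dm, ev["exceedance_ha"].to_numpy())
        self._check(post, seed=4)

    def test_count_with_spacetime(self, train_design, toy_hierarchy):
        train, dm = train_design
        months = np.array(sorted(train["t"].unique()))
        post = CountPosterior(
            "zinb",
            dm,
            train["count"].to_numpy(),
            np.log(train["area_km2"].to_numpy()),
            hierarchy=toy_hierarchy,
            include_spacetime=True,
            cell_region_index=np.array([toy_hierarchy.index_of(int(r)) for r in train["region"]]),
            cell_time_index=np.searchsorted(months, train["t"].to_numpy()),
        )
        self._check(post, seed=5, n_dims=30)

    @staticmethod
    def _check(post, seed, n_dims=25, h=1e-5, tol=1e-4):
        rng = np.random.default_rng(seed)
        x = post.initial(rng)
        lp, g = post.logp_grad(x)
        assert np.isfinite(lp)
        idx = rng.choice(post.dim, size=min(n_dims, post.dim), replace=False)
        for i in idx:
            e = np.zeros(post.dim)
            e[i] = h
            lp1, _ = post.logp_grad(x + e)
            lp0, _ = post.logp_grad(x - e)
            fd = (lp1 - lp0) / (2 * h)
            assert abs(fd - g[i]) <= tol * max(1.0, abs(fd)), (i, fd, g[i])


class TestJointDensityConsistency:
    """The sampler's joint log density equals likelihood + priors computed
    independently by the count/size/priors modules (cross-module check)."""

    def test_zinb_joint_decomposition(self, train_design):
        from fire_extremes import count_models

        train, dm = train_design
        post = CountPosterior(
            "zinb", dm, train["count"].to_numpy(), np.log(train["area_km2"].to_numpy())
        )
        rng = np.random.default_rng(6)
        x = post.initial(rng)
        lp, _ = post.logp_grad(x)
        u = post.unpack(x)
        lay = post.layout

        params = count_models.CountParams(
            "zinb",
            alpha_mu=u["alpha_mu"],
            beta_mu=u["beta_mu"],
            dispersion=u["delta"],
            alpha_pi=u["alpha_pi"],
            beta_pi=u["beta_pi"],
        )
        mu, pi = count_models.count_linear_predictors(
            dm.X, params, np.log(train["area_km2"].to_numpy())
        )
        ll = float(
            np.sum(
                count_models.count_logpmf("zinb", train["count"].to_numpy(), mu, u["delta"], pi)
            )
        )

        # paired horseshoe over the basis columns, centered + Jacobian
        sd = u["tau"] * priors.HorseshoeState(lam=u["lam"], tau=u["tau"], c=u["c"]).lam_tilde()
        hs_centered = priors.paired_horseshoe_logdensity(
            u["beta_mu"][post.hs_cols],
            u["beta_pi"][post.hs_cols],
            u["lam"],
            u["tau"],
            u["c"],
            u["rho"],
        )
        # change of variables (z_mu, z_pi_raw) -> (beta_mu, beta_pi) per pair:
        # |J| = sd_j^2 * sqrt(1 - rho^2)
        q = post.hs_cols.size
        jac = 2 * float(np.sum(np.log(sd))) + q * 0.5 * np.log(1 - u["rho"] ** 2)

        from scipy import stats

        expected = ll + hs_centered + jac
        # hyperpriors: local/global scales, slab, rho, intercepts, delta,
        # adjustment blocks (non-centered normal + half-normal scales)
        lam = u["lam"]
        expected += float(np.sum(np.log(2 / np.pi) - np.log1p(lam**2) + np.log(lam)))
        t = np.log(u["tau"])
        expected += np.log(2 / np.pi) - np.log(post.tau0) - np.log1p((u["tau"] / post.tau0) ** 2) + t
        w = 2 * np.log(u["c"])
        expected += float(stats.invgamma.logpdf(u["c"] ** 2, priors.SLAB_DF, scale=priors.SLAB_SCALE)) + w
        rho = u["rho"]
        expected += -np.log(2.0) + np.log1p(-rho**2)
        expected += float(stats.norm.logpdf(u["alpha_mu"], scale=5.0))
        expected += float(stats.norm.logpdf(u["alpha_pi"], scale=5.0))
        d = u["delta"]
        expected += np.log(2 / np.pi) - np.log(5.0) - np.log1p((d / 5.0) ** 2) + np.log(d)
        for blk in (post.adj_mu, post.adj_pi):
            za = lay.get(x, f"za_{blk.suffix}")
            expected += float(np.sum(stats.norm.logpdf(za)))
            log_sd = lay.get(x, f"log_sd_adj_{blk.suffix}")
            for v in log_sd:
                s = np.exp(v)
                expected += 0.5 * np.log(2 / np.pi) - s**2 / 2 + v
        assert lp == pytest.approx(expected, abs=1e-8)

    def test_spacetime_prior_matches_priors_module(self, train_design, toy_hierarchy):
        train, dm = train_design
        months = np.array(sorted(train["t"].unique()))
        post = CountPosterior(
            "poisson",
            dm,
            train["count"].to_numpy(),
            np.log(train["area_km2"].to_numpy()),
            hierarchy=toy_hierarchy,
            include_spacetime=True,
            cell_region_index=np.array([toy_hierarchy.index_of(int(r)) for r in train["region"]]),
            cell_time_index=np.searchsorted(months, train["t"].to_numpy()),
        )
        rng = np.random.default_rng(7)
        x = post.initial(rng)
        lp_with, _ = post.logp_grad(x)
        # zero out the field: the difference must equal the AR x ICAR kernel
        # (plus its tau normalization) and the field's likelihood effect
        vals = post.st_mu.values(post.layout, x)
        phi, ar, tau = vals["phi"], vals["ar"], vals["tau"]
        S, T = phi.shape
        kernel = priors.ar1_icar_logdensity(phi, toy_hierarchy, ar, tau)
        kernel += -(S - 1) * T * np.log(tau)
        x0 = x.copy()
        x0[post.layout.slices["phi_st_mu"]] = 0.0
        lp_zero, _ = post.logp_grad(x0)
        kernel_zero = priors.ar1_icar_logdensity(np.zeros_like(phi), toy_hierarchy, ar, tau)
        kernel_zero += -(S - 1) * T * np.log(tau)

        # isolate likelihood difference directly
        from fire_extremes.inference.posteriors import count_loglik_grads

        lay = post.layout
        vals_hs = post.hs.values(lay, x)
        adj = post.adj_mu.values(lay, x)
        eta_base = (
            float(lay.get(x, "alpha_mu")[0])
            + post.X_hs @ vals_hs["beta_mu"]
            + post.X_adj @ adj["beta_adj"]
            + post.log_offset
        )
        cells = phi[post.cell_s, post.cell_t]
        ll_with = count_loglik_grads("poisson", post.n, eta_base + cells)[0]
        ll_zero = count_loglik_grads("poisson", post.n, eta_base)[0]
        assert (lp_with - lp_zero) == pytest.approx(
            (ll_with - ll_zero) + (kernel - kernel_zero), abs=1e-7
        )


class TestFitApi:
    def test_same_seed_identical_draws(self, train_design):
        train, dm = train_design
        kw = dict(chains=2, iterations=12, warmup=6, seed=42)
        a = fit({"kind": "count", "family": "poisson"}, train, dm, **kw)
        b = fit({"kind": "count", "family": "poisson"}, train, dm, **kw)
        for name in a.params:
            assert np.array_equal(a.get(name), b.get(name))

    def test_variational_runs_and_unpacks(self, train_design):
        train, dm = train_design
        d = fit(
            {"kind": "count", "family": "poisson"},
            train,
            dm,
            method="variational",
            chains=2,
            iterations=30,
            warmup=10,
            seed=0,
        )
        assert d.get("beta_mu").shape == (2, 20, dm.shape[1])

    def test_warmup_must_be_smaller(self, train_design):
        train, dm = train_design
        with pytest.raises(ValueError):
            fit({"kind": "count", "family": "poisson"}, train, dm, iterations=10, warmup=10)


class TestRhat:
    def _draws(self, arr):
        return PosteriorDraws({"theta": arr}, {"kind": "count", "family": "poisson"})

    def test_identical_constant_chains_flagged(self):
        d = self._draws(np.ones((4, 100)))
        flags = rhat_flags(compute_rhat(d))
        assert flags["theta"]

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(0)
        d = self._draws(rng.normal(size=(4, 500)))
        r = compute_rhat(d)["theta"]
        assert r < 1.01

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, 500))
        arr[0] += 10.0
        r = compute_rhat(self._draws(arr))["theta"]
        assert r >= 1.1

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            compute_rhat(self._draws(np.zeros((1, 100))))

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(4, 400)) + np.linspace(0, 0.5, 4)[:, None]
        ours = compute_rhat(self._draws(arr))["theta"]
        ref = float(az.rhat(az.convert_to_dataset(arr[:, :, None]))["x"].values[0])
        # arviz rank-normalizes; agreement is approximate by construction
        assert ours == pytest.approx(ref, abs=0.02)


class TestHoldoutAndPrediction:
    @pytest.fixture(scope="class")
    def short_fit(self, train_design):
        train, dm = train_design
        return fit(
            {"kind": "count", "family": "poisson"},
            train,
            dm,
            chains=2,
            iterations=40,
            warmup=20,
            seed=3,
        )

    def test_single_draw_sd_zero(self, short_fit, train_design):
        train, dm = train_design
        one = PosteriorDraws(
            {k: v[:1, :1] for k, v in short_fit.params.items()}, short_fit.meta
        )
        mean, sd = holdout_loglik(one, train, dm)
        assert sd == 0.0
        assert np.isfinite(mean)

    def test_duplicated_draws_same_mean_sd(self, short_fit, train_design):
        train, dm = train_design
        m1, s1 = holdout_loglik(short_fit, train, dm)
        doubled = PosteriorDraws(
            {k: np.concatenate([v, v], axis=1) for k, v in short_fit.params.items()},
            short_fit.meta,
        )
        m2, s2 = holdout_loglik(doubled, train, dm)
        assert m1 == pytest.approx(m2)
        assert s2 == pytest.approx(s1, rel=0.01)

    def test_posterior_predict_shape_and_determinism(self, short_fit, train_design):
        train, dm = train_design
        a = posterior_predict(short_fit, dm, train, seed=1)
        b = posterior_predict(short_fit, dm, train, seed=1)
        assert a.shape == (40, len(train))
        assert np.array_equal(a, b)

    def test_replicate_cell_means_match_mu(self, train_design):
        """Replicate means across draws track the posterior mean of mu."""
        train, dm = train_design
        d = fit(
            {"kind": "count", "family": "poisson"},
            train,
            dm,
            chains=2,
            iterations=120,
            warmup=60,
            seed=9,
        )
        reps = posterior_predict(d, dm, train, seed=2)
        log_offset = np.log(train["area_km2"].to_numpy())
        mus = np.stack(
            [
                np.exp(d.stacked("alpha_mu")[i] + dm.X @ d.stacked("beta_mu")[i] + log_offset)
                for i in range(reps.shape[0])
            ]
        )
        post_mu = mus.mean(axis=0)
        se = np.sqrt(post_mu.sum()) / len(post_mu)  # Poisson MC error of grand mean
        assert abs(reps.mean() - post_mu.mean()) < 3 * se + 1e-3

    def test_save_load_round_trip(self, short_fit, tmp_path):
        short_fit.save(tmp_path / "draws")
        back = PosteriorDraws.load(tmp_path / "draws")
        for name in short_fit.params:
            assert np.allclose(back.get(name), short_fit.get(name))
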
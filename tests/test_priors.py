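"""Horseshoe and ICAR prior kernels against dense oracles."""

import numpy as np
import pytest
from scipy import stats

from fire_extremes.hierarchy import generate_hierarchy
from fire_extremes.priors import (
    HorseshoeState,
    ar1_icar_logdensity,
    icar_logdensity,
    paired_horseshoe_logdensity,
    regularized_horseshoe_logdensity,
)


@pytest.fixture(scope="module")
def state():
    rng = np.random.default_rng(0)
    return HorseshoeState(lam=rng.uniform(0.1, 3.0, size=8), tau=0.5, c=2.0)


class TestRegularizedHorseshoe:
    def test_slab_off_limit_is_plain_horseshoe(self):
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.1, 2.0, 6)
        beta = rng.normal(size=6)
        big_c = HorseshoeState(lam=lam, tau=0.7, c=1e8)
        ours = regularized_horseshoe_logdensity(beta, big_c, include_hyperpriors=False)
        plain = float(np.sum(stats.norm.logpdf(beta, scale=0.7 * lam)))
        assert ours == pytest.approx(plain, abs=1e-8)

    def test_large_lambda_capped_at_slab(self):
        st_ = HorseshoeState(lam=np.array([1e8]), tau=0.5, c=2.0)
        # effective sd tends to c as lambda -> infinity
        assert st_.tau * st_.lam_tilde()[0] == pytest.approx(2.0, rel=1e-8)

    def test_matches_direct_reimplementation(self, state):
        rng = np.random.default_rng(2)
        beta = rng.normal(size=8)
        ours = regularized_horseshoe_logdensity(beta, state, include_hyperpriors=False)
        lt2 = state.c**2 * state.lam**2 / (state.c**2 + state.tau**2 * state.lam**2)
        direct = float(np.sum(stats.norm.logpdf(beta, scale=state.tau * np.sqrt(lt2))))
        assert ours == pytest.approx(direct, abs=1e-12)

    def test_nonpositive_scales_raise(self):
        with pytest.raises(ValueError):
            HorseshoeState(lam=np.array([1.0, -1.0]), tau=1.0, c=1.0)


class TestPairedHorseshoe:
    def test_rho_zero_reduces_to_independent(self, state):
        rng = np.random.default_rng(3)
        bmu = rng.normal(size=8)
        bpi = rng.normal(size=8)
        paired = paired_horseshoe_logdensity(bmu, bpi, state.lam, state.tau, state.c, 0.0)
        indep = regularized_horseshoe_logdensity(
            bmu, state, include_hyperpriors=False
        ) + regularized_horseshoe_logdensity(bpi, state, include_hyperpriors=False)
        assert paired == pytest.approx(indep, abs=1e-10)

    def test_density_increases_in_rho_for_equal_blocks(self, state):
        beta = np.full(8, 0.3)
        vals = [
            paired_horseshoe_logdensity(beta, beta, state.lam, state.tau, state.c, r)
            for r in [0.0, 0.3, 0.6, 0.9, 0.99]
        ]
        assert np.all(np.diff(vals) > 0)

    def test_matches_bivariate_normal_oracle(self, state):
        rng = np.random.default_rng(4)
        bmu = rng.normal(size=8)
        bpi = rng.normal(size=8)
        rho = 0.665
        ours = paired_horseshoe_logdensity(bmu, bpi, state.lam, state.tau, state.c, rho)
        sd = state.tau * state.lam_tilde()
        direct = 0.0
        for j in range(8):
            cov = sd[j] ** 2 * np.array([[1.0, rho], [rho, 1.0]])
            direct += stats.multivariate_normal.logpdf([bmu[j], bpi[j]], cov=cov)
        assert ours == pytest.approx(float(direct), abs=1e-10)

    def test_invalid_rho_raises(self, state):
        with pytest.raises(ValueError):
            paired_horseshoe_logdensity(
                np.zeros(8), np.zeros(8), state.lam, state.tau, state.c, 1.0
            )


@pytest.fixture(scope="module")
def toy12():
    return generate_hierarchy(2, 4, 12, seed=7)


class TestIcar:
    def test_constant_field_maximal_pairwise_term(self, toy12):
        flat = icar_logdensity(np.full(12, 3.0), toy12, 1.0, include_sum_to_zero=False)
        bumpy = icar_logdensity(np.arange(12.0), toy12, 1.0, include_sum_to_zero=False)
        assert flat == pytest.approx(0.0)
        assert bumpy < flat

    def test_two_node_example(self):
        h = generate_hierarchy(1, 1, 2, seed=0)
        val = icar_logdensity(np.array([1.0, -1.0]), h, 1.0, include_sum_to_zero=False)
        assert val == pytest.approx(-2.0)  # (1 - (-1))^2 / 2

    def test_matches_dense_quadratic_form(self, toy12):
        rng = np.random.default_rng(5)
        phi = rng.normal(size=12)
        tau = 0.8
        ours = icar_logdensity(phi, toy12, tau, include_sum_to_zero=False)
        q = toy12.laplacian()
        assert ours == pytest.approx(-0.5 * phi @ q @ phi / tau**2, abs=1e-12)

    def test_shift_invariance_and_sum_to_zero(self, toy12):
        rng = np.random.default_rng(6)
        phi = rng.normal(size=12)
        a = icar_logdensity(phi, toy12, 1.0, include_sum_to_zero=False)
        b = icar_logdensity(phi + 100.0, toy12, 1.0, include_sum_to_zero=False)
        assert a == pytest.approx(b, abs=1e-6)
        # identifiability restored only by the soft constraint
        a2 = icar_logdensity(phi - phi.mean(), toy12, 1.0, include_sum_to_zero=True)
        b2 = icar_logdensity(phi - phi.mean() + 100.0, toy12, 1.0, include_sum_to_zero=True)
        assert a2 > b2


class TestAr1Icar:
    def test_zero_ar_is_sum_of_monthly_kernels(self, toy12):
        rng = np.random.default_rng(7)
        phi = rng.normal(size=(12, 6))
        total = ar1_icar_logdensity(phi, toy12, 0.0, 1.3)
        parts = sum(icar_logdensity(phi[:, t], toy12, 1.3) for t in range(6))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_single_month_is_single_kernel(self, toy12):
        rng = np.random.default_rng(8)
        phi = rng.normal(size=(12, 1))
        assert ar1_icar_logdensity(phi, toy12, 0.9, 0.7) == pytest.approx(
            icar_logdensity(phi[:, 0], toy12, 0.7), abs=1e-12
        )

    def test_matches_dense_space_time_quadratic(self, toy12):
        """Brute-force oracle: assemble the full (S*T) quadratic form."""
        rng = np.random.default_rng(9)
        S, T = 12, 6
        phi = rng.normal(size=(S, T))
        ar, tau = 0.55, 0.9
        q = toy12.laplacian()
        # dense precision of the innovations representation
        big = 0.0
        innov = phi.copy()
        innov[:, 1:] -= ar * phi[:, :-1]
        for t in range(T):
            big += -0.5 * innov[:, t] @ q @ innov[:, t] / tau**2
            big += stats.norm.logpdf(innov[:, t].sum(), scale=0.001 * S)
        ours = ar1_icar_logdensity(phi, toy12, ar, tau)
        assert ours == pytest.approx(float(big), abs=1e-9)

    def test_invalid_ar_raises(self, toy12):
        with pytest.raises(ValueError):
            ar1_icar_logdensity(np.zeros((12, 3)), toy12, 1.0, 1.0)


def test_kernels_decrease_away_from_mode(toy12, state):
    """Moving radially away from the mode lowers every kernel."""
    rng = np.random.default_rng(10)
    direction = rng.normal(size=8)
    vals = [
        regularized_horseshoe_logdensity(t * direction, state, include_hyperpriors=False)
        for t in [0.0, 0.5, 1.0, 2.0]
    ]
    assert np.all(np.diff(vals) < 0)
    phi_dir = rng.normal(size=12)
    phi_dir -= phi_dir.mean()
    vals2 = [icar_logdensity(t * phi_dir, toy12, 1.0) for t in [0.0, 1.0, 2.0, 4.0]]
    assert np.all(np.diff(vals2) < 0)
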
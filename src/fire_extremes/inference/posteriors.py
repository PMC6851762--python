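"""Joint log posteriors (value + analytic gradient) for count and size models.

Each posterior object exposes ``logp_grad(x)`` over an unconstrained
parameter vector, suitable for the NUTS engine, plus ``unpack(x)`` mapping
a point to named, constrained parameters.

Parameterization notes (all sampled on unconstrained scales):

* Spline-effect coefficients use a non-centered regularized horseshoe:
  beta_j = z_j * tau * lam_tilde_j with z_j ~ N(0,1), lam_j ~ C+(0,1),
  tau ~ C+(0, tau0), c^2 ~ inv-gamma. For zero-inflated models the mu and
  pi blocks share (lam, tau, c) and their standard scores are correlated:
  z_pi = rho * z_mu + sqrt(1-rho^2) * w, rho ~ U(-1,1) — the paired
  (multivariate) horseshoe.
* Region intercept adjustments are non-centered hierarchical normals with
  one half-normal scale per hierarchy level.
* Intercepts are N(0, 5); NB dispersion and size auxiliaries get
  half-Cauchy priors on their natural scale.
* Optional spatiotemporal fields follow the AR(1) x ICAR prior with a
  soft sum-to-zero constraint per innovation; the improper ICAR kernel is
  given its rank-(S-1) normalization in tau_phi so the scale is
  identified.

The non-centered parameterization is what makes the horseshoe funnel
tractable for the sampler. All gradients are hand-derived and covered by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse, special

from fire_extremes import priors
from fire_extremes.design import DesignMatrix
from fire_extremes.hierarchy import EcoregionHierarchy

_LOG_2_PI = np.log(2.0 * np.pi)


class Layout:
    """Named slices into a flat unconstrained parameter vector."""

    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.dim = 0

    def add(self, name: str, size: int) -> None:
        self.slices[name] = slice(self.dim, self.dim + size)
        self.dim += size

    def get(self, x: np.ndarray, name: str) -> np.ndarray:
        return x[self.slices[name]]

    def has(self, name: str) -> bool:
        return name in self.slices


# -- scalar prior terms on log-transformed positives ------------------------


def _half_cauchy_log(log_x: float, scale: float) -> tuple[float, float]:
    """log p(x) + Jacobian for x = exp(log_x), x ~ half-Cauchy(0, scale).

    Written via logaddexp/expit so extreme log_x neither overflows nor
    produces NaN gradients.
    """
    u = 2.0 * (log_x - np.log(scale))
    lp = np.log(2.0 / np.pi) - np.log(scale) - np.logaddexp(0.0, u) + log_x
    return float(lp), float(1.0 - 2.0 * special.expit(u))


def _half_normal_log(log_x: float, scale: float) -> tuple[float, float]:
    x = np.exp(log_x)
    lp = 0.5 * np.log(2.0 / np.pi) - np.log(scale) - x**2 / (2 * scale**2) + log_x
    return float(lp), float(1.0 - x**2 / scale**2)


def _inv_gamma_log(log_x: float, a: float, b: float) -> tuple[float, float]:
    """x ~ inv-gamma(a, b) with x = exp(log_x); includes the Jacobian."""
    x = np.exp(log_x)
    lp = a * np.log(b) - special.gammaln(a) - (a + 1) * log_x - b / x + log_x
    return float(lp), float(-a + b / x)


def _normal_log(v: np.ndarray, sd: float) -> tuple[float, np.ndarray]:
    lp = float(-0.5 * np.sum(v**2) / sd**2 - v.size * (0.5 * _LOG_2_PI + np.log(sd)))
    return lp, -v / sd**2


# -- count likelihoods -------------------------------------------------------


def count_loglik_grads(family, n, eta_mu, eta_pi=None, log_delta=None, lgamma_n1=None):
    """Summed log likelihood and per-cell gradients wrt linear predictors.

    Returns (ll, g_mu, g_pi | None, g_logdelta | None). Stable at large
    mu and at the zero-inflated n = 0 mixture.
    """
    n = np.asarray(n, dtype=float)
    if lgamma_n1 is None:
        lgamma_n1 = special.gammaln(n + 1.0)
    mu = np.exp(eta_mu)
    if not np.all(np.isfinite(mu)):
        return -np.inf, None, None, None
    nb = family in ("nb", "zinb")
    zi = family in ("zip", "zinb")

    if nb:
        delta = np.exp(log_delta)
        log_ratio = log_delta - np.logaddexp(log_delta, eta_mu)  # log(delta/(delta+mu))
        log_mu_ratio = eta_mu - np.logaddexp(log_delta, eta_mu)
        base = (
            special.gammaln(n + delta)
            - special.gammaln(delta)
            - lgamma_n1
            + delta * log_ratio
            + n * log_mu_ratio
        )
        g_base_mu = delta * (n - mu) / (delta + mu)
        g_base_ld = delta * (
            special.digamma(n + delta)
            - special.digamma(delta)
            + log_ratio
            + 1.0
            - (n + delta) / (delta + mu)
        )
        l0 = delta * (log_delta - np.logaddexp(log_delta, eta_mu))
        dl0_mu = -delta * mu / (delta + mu)
        dl0_ld = delta * (log_ratio + mu / (delta + mu))
    else:
        base = n * eta_mu - mu - lgamma_n1
        g_base_mu = n - mu
        g_base_ld = None
        l0 = -mu
        dl0_mu = -mu
        dl0_ld = None

    if not zi:
        ll = float(np.sum(base))
        gd = float(np.sum(g_base_ld)) if nb else None
        return ll, g_base_mu, None, gd

    log_pi = -np.logaddexp(0.0, -eta_pi)
    log_1mpi = -np.logaddexp(0.0, eta_pi)
    zero = n == 0
    logD = np.logaddexp(log_pi, log_1mpi + l0)
    ll_cells = np.where(zero, logD, log_1mpi + base)
    ll = float(np.sum(ll_cells))

    wB = np.exp(log_1mpi + l0 - logD)  # weight of the count branch at n = 0
    g_mu = np.where(zero, wB * dl0_mu, g_base_mu)
    pi = np.exp(log_pi)
    g_pi_zero = np.exp(log_pi + log_1mpi - logD) * (-np.expm1(l0))
    g_pi = np.where(zero, g_pi_zero, -pi)
    if nb:
        gd = float(np.sum(np.where(zero, wB * dl0_ld, g_base_ld)))
    else:
        gd = None
    return ll, g_mu, g_pi, gd


# -- size likelihoods --------------------------------------------------------


def size_loglik_grads(family, y, eta, log_aux, y0=1.0):
    """Summed log likelihood, per-event d/deta, and scalar d/dlog_aux."""
    y = np.asarray(y, dtype=float)
    if family == "lognormal":
        sigma = np.exp(log_aux)
        r = (np.log(y) - eta) / sigma
        ll = float(np.sum(-np.log(y) - log_aux - 0.5 * _LOG_2_PI - 0.5 * r**2))
        return ll, r / sigma, float(np.sum(r**2 - 1.0))
    if family == "gamma":
        k = np.exp(log_aux)
        ll = float(
            np.sum(
                k * np.log(k) - k * eta - special.gammaln(k) + (k - 1) * np.log(y)
                - k * y * np.exp(-eta)
            )
        )
        g_eta = k * (y * np.exp(-eta) - 1.0)
        g_k = k * np.sum(
            np.log(k) + 1.0 - eta - special.digamma(k) + np.log(y) - y * np.exp(-eta)
        )
        return ll, g_eta, float(g_k)
    if family == "weibull":
        k = np.exp(log_aux)
        logy_eta = np.log(y) - eta
        u = np.exp(k * logy_eta)
        ll = float(np.sum(np.log(k) - k * eta + (k - 1) * np.log(y) - u))
        g_eta = k * (u - 1.0)
        g_k = float(np.sum(1.0 + k * logy_eta * (1.0 - u)))
        return ll, g_eta, g_k
    if family == "gpd_lomax":
        kappa = np.exp(log_aux)
        sigma = np.exp(eta)
        log1py = np.log1p(y / sigma)
        ll = float(np.sum(log_aux - eta - (kappa + 1) * log1py))
        frac = (y / sigma) / (1.0 + y / sigma)
        g_eta = -1.0 + (kappa + 1) * frac
        g_k = float(np.sum(1.0 - kappa * log1py))
        return ll, g_eta, g_k
    if family == "tapered_pareto":
        kappa = np.exp(eta)  # covariates act on the shape
        theta = np.exp(log_aux)
        a = kappa / y + 1.0 / theta
        ll = float(np.sum(np.log(a) + kappa * (np.log(y0) - np.log(y)) + (y0 - y) / theta))
        g_eta = kappa * ((1.0 / y) / a + np.log(y0) - np.log(y))
        g_th = float(np.sum(-(1.0 / theta) / a - (y0 - y) / theta))
        return ll, g_eta, g_th
    raise ValueError(f"unknown size family {family!r}")


# -- shared building blocks --------------------------------------------------


class _HorseshoeBlock:
    """Non-centered regularized horseshoe over a set of design columns."""

    def __init__(self, layout: Layout, q: int, tau0: float, paired: bool,
                 slab_df: float, slab_scale: float):
        self.q = q
        self.tau0 = tau0
        self.paired = paired
        self.slab_df = slab_df
        self.slab_scale = slab_scale
        layout.add("z_mu", q)
        layout.add("log_lam", q)
        layout.add("log_tau", 1)
        layout.add("log_c2", 1)
        if paired:
            layout.add("z_pi_raw", q)
            layout.add("u_rho", 1)

    def values(self, lay: Layout, x):
        z_mu = lay.get(x, "z_mu")
        log_lam = lay.get(x, "log_lam")
        log_tau = float(lay.get(x, "log_tau")[0])
        log_c2 = float(lay.get(x, "log_c2")[0])
        # s = tau * lam_tilde and r = c^2/(c^2 + tau^2 lam^2), both computed
        # on the log scale so extreme local scales stay finite
        log_c = 0.5 * log_c2
        u = 2.0 * (log_tau + log_lam - log_c)
        r = special.expit(-u)
        log_s = log_tau + log_c + log_lam - 0.5 * np.logaddexp(2.0 * log_c, 2.0 * (log_tau + log_lam))
        s = np.exp(log_s)
        beta_mu = z_mu * s
        out = {"s": s, "r": r, "beta_mu": beta_mu, "tau": np.exp(log_tau),
               "lam": np.exp(log_lam), "c": np.exp(0.5 * log_c2)}
        if self.paired:
            # clip the unconstrained correlation so 1 - rho^2 never rounds
            # to zero; beyond the clip the transform is flat and the
            # uniform prior's pullback (-2 tanh u) still applies
            u = float(np.clip(lay.get(x, "u_rho")[0], -15.0, 15.0))
            rho = np.tanh(u)
            w = lay.get(x, "z_pi_raw")
            z_pi = rho * z_mu + np.sqrt(1 - rho**2) * w
            out.update({"rho": rho, "z_pi": z_pi, "beta_pi": z_pi * s, "w": w})
        return out

    def prior_logp_grads(self, lay: Layout, x, g: np.ndarray) -> float:
        """Hyperprior terms; adds gradients in place; returns log density."""
        z_mu = lay.get(x, "z_mu")
        log_lam = lay.get(x, "log_lam")
        log_tau = float(lay.get(x, "log_tau")[0])
        log_c2 = float(lay.get(x, "log_c2")[0])
        lp, gz = _normal_log(z_mu, 1.0)
        g[lay.slices["z_mu"]] += gz
        lp += float(np.sum(np.log(2.0 / np.pi) - np.logaddexp(0.0, 2.0 * log_lam) + log_lam))
        g[lay.slices["log_lam"]] += 1.0 - 2.0 * special.expit(2.0 * log_lam)
        lpt, gt = _half_cauchy_log(log_tau, self.tau0)
        lp += lpt
        g[lay.slices["log_tau"]] += gt
        lpc, gc = _inv_gamma_log(log_c2, self.slab_df, self.slab_scale)
        lp += lpc
        g[lay.slices["log_c2"]] += gc
        if self.paired:
            w = lay.get(x, "z_pi_raw")
            lpw, gw = _normal_log(w, 1.0)
            lp += lpw
            g[lay.slices["z_pi_raw"]] += gw
            u = float(np.clip(lay.get(x, "u_rho")[0], -15.0, 15.0))
            rho = np.tanh(u)
            lp += float(-np.log(2.0) + np.log1p(-rho**2))
            g[lay.slices["u_rho"]] += -2.0 * rho
        return lp

    def backprop(self, lay: Layout, x, vals, dbeta_mu, dbeta_pi, g: np.ndarray) -> None:
        """Chain likelihood gradients wrt beta back to the raw parameters."""
        s, r = vals["s"], vals["r"]
        z_mu = lay.get(x, "z_mu")
        g[lay.slices["z_mu"]] += dbeta_mu * s
        g[lay.slices["log_lam"]] += dbeta_mu * vals["beta_mu"] * r
        g[lay.slices["log_tau"]] += float(np.sum(dbeta_mu * vals["beta_mu"] * r))
        g[lay.slices["log_c2"]] += float(np.sum(dbeta_mu * vals["beta_mu"] * (1 - r) / 2.0))
        if self.paired and dbeta_pi is not None:
            rho, w = vals["rho"], vals["w"]
            beta_pi = vals["beta_pi"]
            g[lay.slices["z_mu"]] += dbeta_pi * rho * s
            g[lay.slices["z_pi_raw"]] += dbeta_pi * np.sqrt(1 - rho**2) * s
            g[lay.slices["log_lam"]] += dbeta_pi * beta_pi * r
            g[lay.slices["log_tau"]] += float(np.sum(dbeta_pi * beta_pi * r))
            g[lay.slices["log_c2"]] += float(np.sum(dbeta_pi * beta_pi * (1 - r) / 2.0))
            dz_pi = dbeta_pi * s
            drho = float(np.sum(dz_pi * (z_mu - rho / np.sqrt(1 - rho**2) * w)))
            g[lay.slices["u_rho"]] += drho * (1 - rho**2)


class _AdjustmentBlock:
    """Non-centered hierarchical normal region-intercept adjustments."""

    def __init__(self, layout: Layout, levels: np.ndarray, suffix: str, scale: float = 1.0):
        self.levels = levels  # per-column level label array (strings)
        self.level_names = sorted(set(levels))
        self.scale = scale
        self.suffix = suffix
        layout.add(f"za_{suffix}", len(levels))
        layout.add(f"log_sd_adj_{suffix}", len(self.level_names))
        self.level_idx = np.array([self.level_names.index(l) for l in levels])

    def values(self, lay: Layout, x):
        za = lay.get(x, f"za_{self.suffix}")
        log_sd = lay.get(x, f"log_sd_adj_{self.suffix}")
        sd = np.exp(log_sd)[self.level_idx]
        return {"beta_adj": za * sd, "sd": sd}

    def prior_logp_grads(self, lay: Layout, x, g) -> float:
        za = lay.get(x, f"za_{self.suffix}")
        lp, gz = _normal_log(za, 1.0)
        g[lay.slices[f"za_{self.suffix}"]] += gz
        log_sd = lay.get(x, f"log_sd_adj_{self.suffix}")
        for k, _ in enumerate(self.level_names):
            lps, gs = _half_normal_log(float(log_sd[k]), self.scale)
            lp += lps
            g[lay.slices[f"log_sd_adj_{self.suffix}"]][k] += gs
        return lp

    def backprop(self, lay: Layout, x, vals, dbeta, g) -> None:
        za = lay.get(x, f"za_{self.suffix}")
        g[lay.slices[f"za_{self.suffix}"]] += dbeta * vals["sd"]
        contrib = dbeta * vals["beta_adj"]
        for k, _ in enumerate(self.level_names):
            g[lay.slices[f"log_sd_adj_{self.suffix}"]][k] += float(
                np.sum(contrib[self.level_idx == k])
            )


class _SpacetimeBlock:
    """AR(1) x ICAR field over S regions and T months (centered)."""

    def __init__(self, layout: Layout, hierarchy: EcoregionHierarchy, n_t: int, suffix: str):
        self.S = hierarchy.n_l3
        self.T = n_t
        self.suffix = suffix
        self.Q = sparse.csr_matrix(hierarchy.laplacian())
        self.sum_sd = priors.SUM_TO_ZERO_SCALE * self.S
        layout.add(f"phi_{suffix}", self.S * n_t)
        layout.add(f"u_ar_{suffix}", 1)
        layout.add(f"log_tauphi_{suffix}", 1)

    def values(self, lay: Layout, x):
        phi = lay.get(x, f"phi_{self.suffix}").reshape(self.S, self.T, order="F")
        u = float(lay.get(x, f"u_ar_{self.suffix}")[0])
        return {"phi": phi, "ar": np.tanh(u), "tau": float(np.exp(lay.get(x, f"log_tauphi_{self.suffix}")[0]))}

    def logp_grads(self, lay: Layout, x, vals, dphi_cells, g) -> float:
        """Prior + chain rule; dphi_cells is d loglik / d phi as an S x T array."""
        phi, ar, tau = vals["phi"], vals["ar"], vals["tau"]
        S, T = self.S, self.T
        innov = phi.copy()
        innov[:, 1:] -= ar * phi[:, :-1]
        Qi = self.Q @ innov
        quad = float(np.sum(innov * Qi))
        sums = innov.sum(axis=0)
        lp = -quad / (2 * tau**2)
        lp += float(np.sum(-0.5 * _LOG_2_PI - np.log(self.sum_sd) - sums**2 / (2 * self.sum_sd**2)))
        lp += -(S - 1) * T * np.log(tau)

        dinnov = -Qi / tau**2
        dinnov -= sums[None, :] / self.sum_sd**2
        dphi = dinnov.copy()
        dphi[:, :-1] -= ar * dinnov[:, 1:]
        dphi += dphi_cells
        g[lay.slices[f"phi_{self.suffix}"]] += dphi.ravel(order="F")

        dar = -float(np.sum(phi[:, :-1] * dinnov[:, 1:]))
        g[lay.slices[f"u_ar_{self.suffix}"]] += dar * (1 - ar**2) + (-2.0 * ar)
        lp += float(-np.log(2.0) + np.log1p(-ar**2))

        lpt, gt = _half_normal_log(np.log(tau), 1.0)
        g[lay.slices[f"log_tauphi_{self.suffix}"]] += quad / tau**2 - (S - 1) * T + gt
        lp += lpt
        return lp


# -- the posteriors ----------------------------------------------------------


class CountPosterior:
    """Joint log posterior of a fire-occurrence model."""

    def __init__(
        self,
        family: str,
        design: DesignMatrix,
        counts: np.ndarray,
        log_offset: np.ndarray,
        hierarchy: EcoregionHierarchy | None = None,
        include_spacetime: bool = False,
        cell_region_index: np.ndarray | None = None,
        cell_time_index: np.ndarray | None = None,
        p0: int = 30,
        alpha_sd: float = 5.0,
        delta_scale: float = 5.0,
        slab_df: float = priors.SLAB_DF,
        slab_scale: float = priors.SLAB_SCALE,
    ):
        self.family = family
        self.zi = family in ("zip", "zinb")
        self.nb = family in ("nb", "zinb")
        self.design = design
        self.n = np.asarray(counts, dtype=float)
        self.lgamma_n1 = special.gammaln(self.n + 1.0)
        self.log_offset = np.asarray(log_offset, dtype=float)
        self.alpha_sd = alpha_sd
        self.delta_scale = delta_scale

        meta = design.meta
        self.hs_cols = np.flatnonzero((meta["kind"] == "basis").to_numpy())
        self.adj_cols = np.flatnonzero((meta["kind"] == "intercept_adjustment").to_numpy())
        self.X_hs = design.X[:, self.hs_cols].tocsr()
        self.X_adj = design.X[:, self.adj_cols].tocsr()
        self.X_hs_T = self.X_hs.T.tocsr()
        self.X_adj_T = self.X_adj.T.tocsr()
        adj_levels = meta.loc[meta["kind"] == "intercept_adjustment", "level"].to_numpy()

        q = self.hs_cols.size
        # likelihood-informed pseudo-variance for the global-scale reference:
        # for a log-link count model the unit information is ~1/mean(n)
        pseudo_sigma = float(np.sqrt(1.0 / max(self.n.mean(), 1e-3)))
        self.tau0 = priors.tau0_heuristic(q, self.n.size, p0=p0, pseudo_sigma=pseudo_sigma)
        lay = Layout()
        lay.add("alpha_mu", 1)
        if self.zi:
            lay.add("alpha_pi", 1)
        self.hs = _HorseshoeBlock(lay, q, self.tau0, paired=self.zi,
                                  slab_df=slab_df, slab_scale=slab_scale)
        self.adj_mu = _AdjustmentBlock(lay, adj_levels, "mu")
        self.adj_pi = _AdjustmentBlock(lay, adj_levels, "pi") if self.zi else None
        if self.nb:
            lay.add("log_delta", 1)
        self.st_mu = self.st_pi = None
        if include_spacetime:
            if hierarchy is None or cell_region_index is None or cell_time_index is None:
                raise ValueError("spacetime effects need hierarchy and cell indices")
            n_t = int(cell_time_index.max()) + 1
            self.cell_s = np.asarray(cell_region_index)
            self.cell_t = np.asarray(cell_time_index)
            self.st_mu = _SpacetimeBlock(lay, hierarchy, n_t, "st_mu")
            if self.zi:
                self.st_pi = _SpacetimeBlock(lay, hierarchy, n_t, "st_pi")
        self.layout = lay
        self.dim = lay.dim

    # -- helpers ---------------------------------------------------------

    def _phi_cells(self, block, vals):
        return vals["phi"][self.cell_s, self.cell_t]

    def _scatter(self, block, g_cells):
        out = np.zeros((block.S, block.T))
        np.add.at(out, (self.cell_s, self.cell_t), g_cells)
        return out

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        lay = self.layout
        g = np.zeros(self.dim)
        vals = self.hs.values(lay, x)
        adj_mu_vals = self.adj_mu.values(lay, x)
        alpha_mu = float(lay.get(x, "alpha_mu")[0])
        eta_mu = (
            alpha_mu
            + self.X_hs @ vals["beta_mu"]
            + self.X_adj @ adj_mu_vals["beta_adj"]
            + self.log_offset
        )
        st_mu_vals = st_pi_vals = None
        if self.st_mu is not None:
            st_mu_vals = self.st_mu.values(lay, x)
            eta_mu = eta_mu + self._phi_cells(self.st_mu, st_mu_vals)
        eta_pi = None
        adj_pi_vals = None
        if self.zi:
            adj_pi_vals = self.adj_pi.values(lay, x)
            eta_pi = (
                float(lay.get(x, "alpha_pi")[0])
                + self.X_hs @ vals["beta_pi"]
                + self.X_adj @ adj_pi_vals["beta_adj"]
            )
            if self.st_pi is not None:
                st_pi_vals = self.st_pi.values(lay, x)
                eta_pi = eta_pi + self._phi_cells(self.st_pi, st_pi_vals)

        log_delta = float(lay.get(x, "log_delta")[0]) if self.nb else None
        with np.errstate(over="ignore", invalid="ignore"):
            ll, g_mu, g_pi, g_ld = count_loglik_grads(
                self.family, self.n, eta_mu, eta_pi, log_delta, self.lgamma_n1
            )
        if not np.isfinite(ll):
            return -np.inf, g

        # likelihood chain rule
        g[lay.slices["alpha_mu"]] += float(np.sum(g_mu))
        dbeta_hs_mu = self.X_hs_T @ g_mu
        dbeta_adj_mu = self.X_adj_T @ g_mu
        dbeta_hs_pi = None
        if self.zi:
            g[lay.slices["alpha_pi"]] += float(np.sum(g_pi))
            dbeta_hs_pi = self.X_hs_T @ g_pi
            dbeta_adj_pi = self.X_adj_T @ g_pi
        if self.nb:
            g[lay.slices["log_delta"]] += g_ld

        self.hs.backprop(lay, x, vals, dbeta_hs_mu, dbeta_hs_pi, g)
        self.adj_mu.backprop(lay, x, adj_mu_vals, dbeta_adj_mu, g)
        if self.zi:
            self.adj_pi.backprop(lay, x, adj_pi_vals, dbeta_adj_pi, g)

        # priors
        lp = ll
        lp += self.hs.prior_logp_grads(lay, x, g)
        lp += self.adj_mu.prior_logp_grads(lay, x, g)
        if self.zi:
            lp += self.adj_pi.prior_logp_grads(lay, x, g)
        lpa, ga = _normal_log(lay.get(x, "alpha_mu"), self.alpha_sd)
        lp += lpa
        g[lay.slices["alpha_mu"]] += ga
        if self.zi:
            lpa, ga = _normal_log(lay.get(x, "alpha_pi"), self.alpha_sd)
            lp += lpa
            g[lay.slices["alpha_pi"]] += ga
        if self.nb:
            lpd, gd = _half_cauchy_log(log_delta, self.delta_scale)
            lp += lpd
            g[lay.slices["log_delta"]] += gd
        if self.st_mu is not None:
            lp += self.st_mu.logp_grads(lay, x, st_mu_vals, self._scatter(self.st_mu, g_mu), g)
        if self.st_pi is not None:
            lp += self.st_pi.logp_grads(lay, x, st_pi_vals, self._scatter(self.st_pi, g_pi), g)
        if not np.all(np.isfinite(g)):
            return -np.inf, np.zeros(self.dim)
        return float(lp), g

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        """Random start on the unconstrained scale.

        Scales are drawn near weakly-informative values and the intercept
        near the empirical rate, which keeps the first gradient steps well
        conditioned; everything else is uniform in [-1, 1].
        """
        x = rng.uniform(-1.0, 1.0, size=self.dim)
        lay = self.layout
        alpha0 = np.log(max(self.n.mean(), 0.02)) - self.log_offset.mean()
        x[lay.slices["alpha_mu"]] = alpha0 + rng.uniform(-0.5, 0.5)
        if self.zi:
            x[lay.slices["alpha_pi"]] = rng.uniform(-1.0, 1.0)
        x[lay.slices["log_lam"]] = rng.uniform(-1.0, 0.0, size=self.hs.q)
        x[lay.slices["log_tau"]] = np.log(self.tau0) + rng.uniform(-1.0, 1.0)
        x[lay.slices["log_c2"]] = np.log(4.0) + rng.uniform(-0.5, 0.5)
        x[lay.slices["z_mu"]] = rng.uniform(-0.5, 0.5, size=self.hs.q)
        if self.zi:
            x[lay.slices["z_pi_raw"]] = rng.uniform(-0.5, 0.5, size=self.hs.q)
        for blk in (self.adj_mu, self.adj_pi):
            if blk is not None:
                x[lay.slices[f"log_sd_adj_{blk.suffix}"]] = rng.uniform(-2.0, -1.0, size=len(blk.level_names))
        if self.nb:
            x[lay.slices["log_delta"]] = rng.uniform(-0.5, 1.0)
        for st in (self.st_mu, self.st_pi):
            if st is not None:
                x[lay.slices[f"phi_{st.suffix}"]] = rng.uniform(-0.1, 0.1, size=st.S * st.T)
                x[lay.slices[f"log_tauphi_{st.suffix}"]] = rng.uniform(-2.0, -1.0)
        return x

    def unpack(self, x: np.ndarray) -> dict:
        """Named constrained parameters at a point (full-length betas)."""
        lay = self.layout
        vals = self.hs.values(lay, x)
        p = self.design.shape[1]
        beta_mu = np.zeros(p)
        beta_mu[self.hs_cols] = vals["beta_mu"]
        adj = self.adj_mu.values(lay, x)
        beta_mu[self.adj_cols] = adj["beta_adj"]
        out = {
            "alpha_mu": float(lay.get(x, "alpha_mu")[0]),
            "beta_mu": beta_mu,
            "tau": float(vals["tau"]),
            "c": float(vals["c"]),
            "lam": vals["lam"],
        }
        if self.nb:
            out["delta"] = float(np.exp(lay.get(x, "log_delta")[0]))
        if self.zi:
            beta_pi = np.zeros(p)
            beta_pi[self.hs_cols] = vals["beta_pi"]
            beta_pi[self.adj_cols] = self.adj_pi.values(lay, x)["beta_adj"]
            out["alpha_pi"] = float(lay.get(x, "alpha_pi")[0])
            out["beta_pi"] = beta_pi
            out["rho"] = float(vals["rho"])
        for st in (self.st_mu, self.st_pi):
            if st is not None:
                v = st.values(lay, x)
                out[f"phi_{st.suffix}"] = v["phi"]
                out[f"ar_{st.suffix}"] = float(v["ar"])
                out[f"tauphi_{st.suffix}"] = float(v["tau"])
        return out


class SizePosterior:
    """Joint log posterior of a burned-area exceedance model."""

    def __init__(
        self,
        family: str,
        design: DesignMatrix,
        exceedances: np.ndarray,
        p0: int = 30,
        alpha_sd: float = 5.0,
        aux_scale: float = 5.0,
        y0: float = 1.0,
        slab_df: float = priors.SLAB_DF,
        slab_scale: float = priors.SLAB_SCALE,
    ):
        self.family = family
        self.design = design
        self.y = np.asarray(exceedances, dtype=float)
        if np.any(self.y <= 0):
            raise ValueError("exceedances must be positive")
        if family == "tapered_pareto":
            self.y = np.maximum(self.y, y0 * (1 + 1e-12))
        self.y0 = y0
        self.alpha_sd = alpha_sd
        self.aux_scale = aux_scale

        meta = design.meta
        self.hs_cols = np.flatnonzero((meta["kind"] == "basis").to_numpy())
        self.adj_cols = np.flatnonzero((meta["kind"] == "intercept_adjustment").to_numpy())
        self.X_hs = design.X[:, self.hs_cols].tocsr()
        self.X_adj = design.X[:, self.adj_cols].tocsr()
        self.X_hs_T = self.X_hs.T.tocsr()
        self.X_adj_T = self.X_adj.T.tocsr()
        adj_levels = meta.loc[meta["kind"] == "intercept_adjustment", "level"].to_numpy()

        q = self.hs_cols.size
        # pseudo-variance from the spread of the (log) responses
        pseudo_sigma = float(np.std(np.log(self.y))) if self.y.size > 1 else 1.0
        self.tau0 = priors.tau0_heuristic(q, self.y.size, p0=p0, pseudo_sigma=max(pseudo_sigma, 0.5))
        lay = Layout()
        lay.add("alpha", 1)
        self.hs = _HorseshoeBlock(lay, q, self.tau0, paired=False,
                                  slab_df=slab_df, slab_scale=slab_scale)
        self.adj = _AdjustmentBlock(lay, adj_levels, "size")
        lay.add("log_aux", 1)
        self.layout = lay
        self.dim = lay.dim

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        lay = self.layout
        g = np.zeros(self.dim)
        vals = self.hs.values(lay, x)
        adj_vals = self.adj.values(lay, x)
        eta = (
            float(lay.get(x, "alpha")[0])
            + self.X_hs @ vals["beta_mu"]
            + self.X_adj @ adj_vals["beta_adj"]
        )
        log_aux = float(lay.get(x, "log_aux")[0])
        with np.errstate(over="ignore", invalid="ignore"):
            ll, g_eta, g_aux = size_loglik_grads(self.family, self.y, eta, log_aux, self.y0)
        if not np.isfinite(ll):
            return -np.inf, g
        g[lay.slices["alpha"]] += float(np.sum(g_eta))
        self.hs.backprop(lay, x, vals, self.X_hs_T @ g_eta, None, g)
        self.adj.backprop(lay, x, adj_vals, self.X_adj_T @ g_eta, g)
        g[lay.slices["log_aux"]] += g_aux

        lp = ll
        lp += self.hs.prior_logp_grads(lay, x, g)
        lp += self.adj.prior_logp_grads(lay, x, g)
        lpa, ga = _normal_log(lay.get(x, "alpha"), self.alpha_sd)
        lp += lpa
        g[lay.slices["alpha"]] += ga
        lpx, gx = _half_cauchy_log(log_aux, self.aux_scale)
        lp += lpx
        g[lay.slices["log_aux"]] += gx
        if not np.all(np.isfinite(g)):
            return -np.inf, np.zeros(self.dim)
        return float(lp), g

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        x = rng.uniform(-1.0, 1.0, size=self.dim)
        lay = self.layout
        if self.family == "lognormal":
            alpha0 = float(np.mean(np.log(self.y)))
        elif self.family == "tapered_pareto":
            alpha0 = 0.0
        else:
            alpha0 = float(np.log(np.mean(self.y)))
        x[lay.slices["alpha"]] = alpha0 + rng.uniform(-0.5, 0.5)
        x[lay.slices["log_lam"]] = rng.uniform(-1.0, 0.0, size=self.hs.q)
        x[lay.slices["log_tau"]] = np.log(self.tau0) + rng.uniform(-1.0, 1.0)
        x[lay.slices["log_c2"]] = np.log(4.0) + rng.uniform(-0.5, 0.5)
        x[lay.slices["z_mu"]] = rng.uniform(-0.5, 0.5, size=self.hs.q)
        x[lay.slices["log_sd_adj_size"]] = rng.uniform(-2.0, -1.0, size=len(self.adj.level_names))
        x[lay.slices["log_aux"]] = rng.uniform(-0.3, 0.3)
        return x

    def unpack(self, x: np.ndarray) -> dict:
        lay = self.layout
        vals = self.hs.values(lay, x)
        p = self.design.shape[1]
        beta = np.zeros(p)
        beta[self.hs_cols] = vals["beta_mu"]
        beta[self.adj_cols] = self.adj.values(lay, x)["beta_adj"]
        return {
            "alpha": float(lay.get(x, "alpha")[0]),
            "beta": beta,
            "aux": float(np.exp(lay.get(x, "log_aux")[0])),
            "tau": float(vals["tau"]),
            "c": float(vals["c"]),
            "lam": vals["lam"],
        }
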
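"""No-U-Turn sampler with dual-averaging step-size adaptation.

A self-contained gradient-based MCMC engine over an arbitrary
differentiable log density: the classic recursive NUTS tree construction
with slice sampling, a diagonal mass matrix adapted during warmup from
the sample variance, and step size tuned by dual averaging toward a
target acceptance statistic. Satisfies detailed balance over the supplied
log density; everything is driven by an explicit numpy Generator so runs
are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsConfig", "nuts_chain"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclass
class NutsConfig:
    target_accept: float = 0.9
    max_treedepth: int = 10
    init_jitter: float = 2.0  # initial positions uniform in [-jitter, jitter]
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75


@dataclass
class ChainStats:
    divergences: int = 0  # post-warmup only
    treedepths: list[int] = field(default_factory=list)
    step_size: float = float("nan")
    tracking: bool = False


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r * inv_mass, r))


def _leapfrog(logp_grad, x, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    x1 = x + eps * (inv_mass * r1)
    lp1, g1 = logp_grad(x1)
    r1 = r1 + 0.5 * eps * g1
    return x1, r1, lp1, g1


def _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng) -> float:
    eps = 1.0
    r = rng.normal(size=x.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(r, inv_mass)
    _, r1, lp1, _ = _leapfrog(logp_grad, x, r, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, lp1, _ = _leapfrog(logp_grad, x, r, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, x, r, grad, logu, v, j, eps, h0, inv_mass, rng, stats):
    """Recursively double the trajectory; returns the standard NUTS tuple."""
    if j == 0:
        x1, r1, lp1, g1 = _leapfrog(logp_grad, x, r, grad, v * eps, inv_mass)
        h1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        n1 = int(logu <= h1)
        s1 = int(logu < _DELTA_MAX + h1)
        if not s1 and stats.tracking:
            stats.divergences += 1
        alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        return x1, r1, g1, x1, r1, g1, x1, lp1, g1, n1, s1, alpha, 1
    (xm, rm, gm, xp, rp, gp, xc, lpc, gc, n1, s1, a1, na1) = _build_tree(
        logp_grad, x, r, grad, logu, v, j - 1, eps, h0, inv_mass, rng, stats
    )
    if s1:
        if v == -1:
            (xm, rm, gm, _, _, _, xc2, lpc2, gc2, n2, s2, a2, na2) = _build_tree(
                logp_grad, xm, rm, gm, logu, v, j - 1, eps, h0, inv_mass, rng, stats
            )
        else:
            (_, _, _, xp, rp, gp, xc2, lpc2, gc2, n2, s2, a2, na2) = _build_tree(
                logp_grad, xp, rp, gp, logu, v, j - 1, eps, h0, inv_mass, rng, stats
            )
        if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
            xc, lpc, gc = xc2, lpc2, gc2
        dx = xp - xm
        s1 = s2 * int(np.dot(dx, inv_mass * rm) >= 0) * int(np.dot(dx, inv_mass * rp) >= 0)
        n1 += n2
        a1 += a2
        na1 += na2
    return xm, rm, gm, xp, rp, gp, xc, lpc, gc, n1, s1, a1, na1


def nuts_chain(
    logp_grad,
    x0: np.ndarray,
    n_draws: int,
    warmup: int,
    rng: np.random.Generator,
    config: NutsConfig | None = None,
) -> tuple[np.ndarray, ChainStats]:
    """Run one NUTS chain; returns (draws after warmup, stats)."""
    cfg = config or NutsConfig()
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise RuntimeError("failed to initialize: non-finite log density at start point")
    stats = ChainStats()

    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0

    # mass-matrix adaptation windows (fractions of warmup); the final
    # stretch of warmup is left to step-size adaptation alone
    checkpoints = {int(0.35 * warmup), int(0.7 * warmup)} if warmup >= 20 else set()
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    kept = 0
    for it in range(warmup + n_draws):
        r0 = rng.normal(size=dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(r0, inv_mass)
        logu = h0 - rng.exponential()
        xm = xp = x
        rm = rp = r0
        gm = gp = grad
        xc, lpc, gc = x, lp, grad
        j, n, s = 0, 1, 1
        alpha_sum, n_alpha = 0.0, 0
        while s and j < cfg.max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                (xm, rm, gm, _, _, _, xc1, lpc1, gc1, n1, s1, a, na) = _build_tree(
                    logp_grad, xm, rm, gm, logu, v, j, eps, h0, inv_mass, rng, stats
                )
            else:
                (_, _, _, xp, rp, gp, xc1, lpc1, gc1, n1, s1, a, na) = _build_tree(
                    logp_grad, xp, rp, gp, logu, v, j, eps, h0, inv_mass, rng, stats
                )
            if s1 and rng.uniform() < min(1.0, n1 / n):
                xc, lpc, gc = xc1, lpc1, gc1
            n += n1
            dx = xp - xm
            s = s1 * int(np.dot(dx, inv_mass * rm) >= 0) * int(np.dot(dx, inv_mass * rp) >= 0)
            alpha_sum += a
            n_alpha += na
            j += 1
        x, lp, grad = xc, lpc, gc

        if it < warmup:
            h_bar = (1 - 1 / (it + 1 + cfg.t0)) * h_bar + (
                cfg.target_accept - alpha_sum / max(n_alpha, 1)
            ) / (it + 1 + cfg.t0)
            log_eps = mu - np.sqrt(it + 1) / cfg.gamma * h_bar
            w = (it + 1) ** (-cfg.kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            window.append(x.copy())
            if it in checkpoints and len(window) > 10:
                var = np.var(np.asarray(window), axis=0)
                inv_mass = var + 1e-6 * (1.0 + var)
                window = []
                eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            stats.tracking = True
            draws[kept] = x
            kept += 1
            stats.treedepths.append(j)
    stats.step_size = eps
    return draws, stats
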
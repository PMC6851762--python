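"""Burned-area exceedance distributions.

Each fire event's response y_i is the number of hectares burned beyond the
size threshold (405 ha by default). Five candidate families are supported:
lognormal, gamma, Weibull, the generalized Pareto with positive shape
(equivalently a Lomax distribution for exceedances), and the tapered
Pareto. Covariates act on exactly one "location" parameter per family,

    lognormal:      mu_i      = eta_i               (identity link)
    gamma:          E(y_i)    = exp(eta_i)          (log link on the mean)
    weibull:        scale_i   = exp(eta_i)
    gpd_lomax:      sigma_L,i = exp(eta_i)          (Lomax scale)
    tapered_pareto: kappa_i   = exp(eta_i)          (Pareto shape)

with eta_i = alpha + X_(s_i,t_i) beta + phi_(s_i,t_i). The remaining
family-specific scalars (lognormal sd, gamma/Weibull shapes, Lomax shape,
taper scale theta and lower bound y0) are global.

The tapered Pareto has survival S(y) = (y0/y)^kappa * exp((y0-y)/theta)
and density f(y) = (kappa/y + 1/theta) * S(y) for y >= y0; it is the only
family without a scipy implementation and is coded directly, with sampling
by bracketed numeric inversion of the CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

SIZE_FAMILIES = ("lognormal", "gamma", "weibull", "gpd_lomax", "tapered_pareto")

#: default tapered-Pareto lower bound, in ha of exceedance
DEFAULT_Y0 = 1.0


def _check_family(family: str) -> None:
    if family not in SIZE_FAMILIES:
        raise ValueError(f"unknown size family {family!r}; choose from {SIZE_FAMILIES}")


@dataclass
class SizeParams:
    """Parameters of a burned-area model on the linear-predictor scale.

    ``aux`` carries the family's global scalar(s): ``sigma`` (lognormal),
    ``shape`` (gamma, weibull, gpd_lomax), ``theta`` and optionally ``y0``
    (tapered_pareto).
    """

    family: str
    alpha: float
    beta: np.ndarray
    phi: np.ndarray | float = 0.0
    aux: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_family(self.family)
        self.beta = np.asarray(self.beta, dtype=float)
        for k, v in self.aux.items():
            if not v > 0:
                raise ValueError(f"auxiliary scalar {k!r} must be positive, got {v}")


def size_location(family: str, eta: np.ndarray) -> np.ndarray:
    """Map the linear predictor to the family's covariate-linked parameter."""
    _check_family(family)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(eta)))[0])
        raise FloatingPointError(f"non-finite size linear predictor at event {bad}")
    if family == "lognormal":
        return eta
    return np.exp(eta)


def size_linear_predictor(X_rows, params: SizeParams) -> np.ndarray:
    eta = params.alpha + X_rows @ params.beta + params.phi
    return np.asarray(eta, dtype=float)


def lomax_to_gpd(sigma_l: float, kappa_l: float) -> tuple[float, float]:
    """Map Lomax (scale, shape) to generalized-Pareto (scale, shape).

    kappa_GPD = 1/kappa_L and sigma_GPD = sigma_L / kappa_L; the Lomax is
    exactly a GPD with positive shape under this reparameterization.
    """
    if not (sigma_l > 0 and kappa_l > 0):
        raise ValueError("Lomax scale and shape must be positive")
    return sigma_l / kappa_l, 1.0 / kappa_l


# ---------------------------------------------------------------------------
# family implementations
# ---------------------------------------------------------------------------


def _frozen(family: str, loc: np.ndarray, aux: dict[str, float]):
    """scipy frozen distribution for the four standard families."""
    if family == "lognormal":
        return stats.lognorm(s=aux["sigma"], scale=np.exp(loc))
    if family == "gamma":
        shape = aux["shape"]
        return stats.gamma(a=shape, scale=loc / shape)  # loc is the mean
    if family == "weibull":
        return stats.weibull_min(c=aux["shape"], scale=loc)
    if family == "gpd_lomax":
        return stats.lomax(c=aux["shape"], scale=loc)  # loc is the Lomax scale
    raise AssertionError(family)


def _tp_logsurvival(y, kappa, theta, y0):
    return kappa * (np.log(y0) - np.log(y)) + (y0 - y) / theta


def _tp_logpdf(y, kappa, theta, y0):
    return np.log(kappa / y + 1.0 / theta) + _tp_logsurvival(y, kappa, theta, y0)


def _tp_aux(aux: dict[str, float]) -> tuple[float, float]:
    return aux["theta"], aux.get("y0", DEFAULT_Y0)


def _tp_ppf_scalar(p: float, kappa: float, theta: float, y0: float) -> float:
    if p == 0.0:
        return y0
    target = np.log1p(-p)  # solve log S(y) = log(1 - p)

    def f(logy):
        return _tp_logsurvival(np.exp(logy), kappa, theta, y0) - target

    lo = np.log(y0)
    hi = lo + 1.0
    while f(hi) > 0:
        hi += 1.0
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)))


def size_logpdf(family: str, y, loc, aux: dict[str, float]) -> np.ndarray:
    """Log density of the exceedance y under the given family."""
    _check_family(family)
    y = np.asarray(y, dtype=float)
    loc = np.asarray(loc, dtype=float)
    if family == "tapered_pareto":
        theta, y0 = _tp_aux(aux)
        if np.any(y < y0):
            raise ValueError(f"tapered-Pareto responses must be >= y0 = {y0}")
        return _tp_logpdf(y, loc, theta, y0)
    if np.any(y <= 0):
        raise ValueError("exceedances must be strictly positive")
    return _frozen(family, loc, aux).logpdf(y)


def size_cdf(family: str, y, loc, aux: dict[str, float]) -> np.ndarray:
    _check_family(family)
    y = np.asarray(y, dtype=float)
    loc = np.asarray(loc, dtype=float)
    if family == "tapered_pareto":
        theta, y0 = _tp_aux(aux)
        out = -np.expm1(_tp_logsurvival(np.maximum(y, y0), loc, theta, y0))
        return np.where(y <= y0, 0.0, out)
    return _frozen(family, loc, aux).cdf(y)


def size_ppf(family: str, p, loc, aux: dict[str, float]) -> np.ndarray:
    """Quantile function; inverse of :func:`size_cdf` in its last argument."""
    _check_family(family)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if family == "tapered_pareto":
        theta, y0 = _tp_aux(aux)
        loc_b, p_b = np.broadcast_arrays(np.asarray(loc, dtype=float), p)
        flat = [
            _tp_ppf_scalar(float(pp), float(k), theta, y0)
            for pp, k in zip(p_b.ravel(), loc_b.ravel())
        ]
        return np.asarray(flat).reshape(p_b.shape)
    return _frozen(family, np.asarray(loc, dtype=float), aux).ppf(p)


def size_rng(
    family: str,
    loc,
    aux: dict[str, float],
    seed: int | np.random.Generator = 0,
    size: int | tuple | None = None,
) -> np.ndarray:
    """Draw exceedances; one per element of ``loc`` unless ``size`` given."""
    _check_family(family)
    rng = np.random.default_rng(seed)
    loc = np.asarray(loc, dtype=float)
    if size is None:
        size = loc.shape if loc.shape else None
    if family == "tapered_pareto":
        u = rng.uniform(size=size)
        return size_ppf(family, u, loc, aux)
    return _frozen(family, loc, aux).rvs(size=size, random_state=rng)


class SizeDistribution:
    """Family-agnostic handle used by the extremes module.

    Wraps (family, aux) so downstream code can evaluate CDFs and quantiles
    given only per-event/per-cell location parameters.
    """

    def __init__(self, family: str, aux: dict[str, float]):
        _check_family(family)
        self.family = family
        self.aux = dict(aux)

    def logpdf(self, y, loc):
        return size_logpdf(self.family, y, loc, self.aux)

    def cdf(self, y, loc):
        return size_cdf(self.family, y, loc, self.aux)

    def ppf(self, p, loc):
        return size_ppf(self.family, p, loc, self.aux)

    def rvs(self, loc, seed=0, size=None):
        return size_rng(self.family, loc, self.aux, seed=seed, size=size)
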
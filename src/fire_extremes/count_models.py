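"""Fire-occurrence count distributions: Poisson, NB, ZIP, ZINB.

The number of large fires n_{s,t} in region s and month t is modelled with
one of four families. The mean follows a log link with a known area offset,

    log(mu) = alpha_mu + X beta_mu + phi_mu + log(a),

and, for the zero-inflated families, the structural-zero probability
follows a logit link,

    logit(pi) = alpha_pi + X beta_pi + phi_pi.

The negative binomial uses the mean-dispersion (NB2) parameterization with
dispersion delta > 0 and variance mu + mu^2/delta, so NB -> Poisson as
delta -> infinity. Zero inflation mixes on the probability scale:
P(0) = pi + (1-pi) g(0) and P(k>0) = (1-pi) g(k) for base pmf g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, special, stats

COUNT_FAMILIES = ("poisson", "nb", "zip", "zinb")

_ZI = {"zip", "zinb"}
_NB = {"nb", "zinb"}


def is_zero_inflated(family: str) -> bool:
    _check_family(family)
    return family in _ZI


def has_dispersion(family: str) -> bool:
    _check_family(family)
    return family in _NB


def _check_family(family: str) -> None:
    if family not in COUNT_FAMILIES:
        raise ValueError(f"unknown count family {family!r}; choose from {COUNT_FAMILIES}")


@dataclass
class CountParams:
    """Parameters of a fire-occurrence model on the linear-predictor scale."""

    family: str
    alpha_mu: float
    beta_mu: np.ndarray
    phi_mu: np.ndarray | float = 0.0
    dispersion: float | None = None
    alpha_pi: float | None = None
    beta_pi: np.ndarray | None = None
    phi_pi: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        _check_family(self.family)
        self.beta_mu = np.asarray(self.beta_mu, dtype=float)
        if has_dispersion(self.family):
            if self.dispersion is None or not self.dispersion > 0:
                raise ValueError("NB families need dispersion > 0")
        if is_zero_inflated(self.family):
            if self.alpha_pi is None or self.beta_pi is None:
                raise ValueError("zero-inflated families need alpha_pi and beta_pi")
            self.beta_pi = np.asarray(self.beta_pi, dtype=float)
            if self.beta_pi.shape != self.beta_mu.shape:
                raise ValueError("beta_pi and beta_mu must have the same length")


def count_linear_predictors(
    X: sparse.spmatrix | np.ndarray,
    params: CountParams,
    log_offset: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Evaluate (mu, pi) over all cells from the design matrix and offset.

    Returns mu > 0 always and pi in (0,1) for zero-inflated families
    (None otherwise).
    """
    log_offset = np.asarray(log_offset, dtype=float)
    if X.shape[1] != params.beta_mu.size:
        raise ValueError(
            f"design has {X.shape[1]} columns but beta_mu has {params.beta_mu.size}"
        )
    eta_mu = params.alpha_mu + X @ params.beta_mu + params.phi_mu + log_offset
    eta_mu = np.asarray(eta_mu, dtype=float)
    if not np.all(np.isfinite(eta_mu)):
        bad = int(np.flatnonzero(~np.isfinite(eta_mu))[0])
        raise FloatingPointError(f"non-finite count linear predictor at cell {bad}")
    mu = np.exp(eta_mu)
    if not is_zero_inflated(params.family):
        return mu, None
    eta_pi = params.alpha_pi + X @ params.beta_pi + params.phi_pi
    eta_pi = np.asarray(eta_pi, dtype=float)
    if not np.all(np.isfinite(eta_pi)):
        bad = int(np.flatnonzero(~np.isfinite(eta_pi))[0])
        raise FloatingPointError(f"non-finite zero-inflation predictor at cell {bad}")
    pi = special.expit(eta_pi)
    return mu, pi


def _base_logpmf(family: str, n: np.ndarray, mu: np.ndarray, delta: float | None) -> np.ndarray:
    if family in _NB:
        # NB2: mean mu, size delta -> scipy's nbinom(n=delta, p=delta/(delta+mu))
        return stats.nbinom.logpmf(n, delta, delta / (delta + mu))
    return stats.poisson.logpmf(n, mu)


def count_logpmf(
    family: str,
    n: np.ndarray,
    mu: np.ndarray,
    delta: float | None = None,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Log pmf of any of the four count families, stable for large n.

    For zero-inflated families the zero cell is computed as
    logaddexp(log pi, log(1-pi) + log g(0)).
    """
    _check_family(family)
    n = np.asarray(n)
    if np.any(n < 0) or not np.issubdtype(np.asarray(n).dtype, np.integer):
        if np.any(np.asarray(n, dtype=float) < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.mod(n, 1) != 0):
            raise ValueError("counts must be integers")
        n = np.asarray(n, dtype=int)
    mu = np.asarray(mu, dtype=float)
    if family in _NB and (delta is None or not delta > 0):
        raise ValueError("NB families need dispersion delta > 0")
    base = _base_logpmf(family, n, mu, delta)
    if family not in _ZI:
        return base
    if pi is None:
        raise ValueError("zero-inflated families need pi")
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    base0 = _base_logpmf(family, np.zeros_like(n), mu, delta)
    at_zero = np.logaddexp(log_pi, log_1mpi + base0)
    return np.where(n == 0, at_zero, log_1mpi + base)


def count_rng(
    family: str,
    mu: np.ndarray,
    delta: float | None = None,
    pi: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one count per cell from the given family."""
    _check_family(family)
    rng = np.random.default_rng(seed)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if family in _NB:
        if delta is None or not delta > 0:
            raise ValueError("NB families need dispersion delta > 0")
        # Poisson-gamma mixture representation of NB2
        lam = rng.gamma(shape=delta, scale=mu / delta)
        draws = rng.poisson(lam)
    else:
        draws = rng.poisson(mu)
    if family in _ZI:
        if pi is None:
            raise ValueError("zero-inflated families need pi")
        pi = np.atleast_1d(np.asarray(pi, dtype=float))
        structural_zero = rng.uniform(size=draws.shape) < pi
        draws = np.where(structural_zero, 0, draws)
    return draws
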
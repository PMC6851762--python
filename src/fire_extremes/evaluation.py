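"""Posterior predictive checks, interval coverage, contribution decomposition.

The model-comparison and error-analysis machinery: test statistics
compared between replicated and observed data (proportion of zeros,
maxima, sums), central-interval coverage accounting with miss directions,
per-covariate contributions to the linear predictor, and holdout
log-likelihood ranking tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fire_extremes.design import DesignMatrix

PPC_STATISTICS = ("prop_zero", "max", "sum")


@dataclass
class PpcResult:
    statistic: str
    replicate_values: np.ndarray
    observed_value: float
    tail_probability: float  # two-sided


def _stat_fn(statistic: str):
    if statistic == "prop_zero":
        return lambda a: np.mean(np.asarray(a) == 0, axis=-1)
    if statistic == "max":
        return lambda a: np.max(a, axis=-1)
    if statistic == "sum":
        return lambda a: np.sum(a, axis=-1)
    raise ValueError(f"unknown statistic {statistic!r}; choose from {PPC_STATISTICS}")


def ppc_statistic(replicates: np.ndarray, observed: np.ndarray, statistic: str) -> PpcResult:
    """Compare a test statistic between replicated and observed data.

    ``replicates`` is (n_draws, n_units); the statistic is computed
    identically on each replicate row and on the observed vector. The
    two-sided tail probability is 2 * min(P(rep >= obs), P(rep <= obs)).
    """
    fn = _stat_fn(statistic)
    rep = np.asarray(fn(np.asarray(replicates)))
    obs = float(fn(np.asarray(observed)))
    p_hi = float(np.mean(rep >= obs))
    p_lo = float(np.mean(rep <= obs))
    return PpcResult(statistic, rep, obs, min(1.0, 2.0 * min(p_hi, p_lo)))


def interval_coverage(
    pred_draws: np.ndarray,
    observed: np.ndarray,
    level: float = 0.95,
) -> dict[str, float]:
    """Central predictive-interval coverage with miss directions.

    Intervals are equal-tailed empirical quantiles of ``pred_draws``
    (shape (n_draws, n_units), type-7 interpolation). Returns the covered
    fraction plus, among misses, the fractions above and below.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    pred_draws = np.asarray(pred_draws)
    observed = np.asarray(observed)
    lo = np.quantile(pred_draws, (1 - level) / 2, axis=0)
    hi = np.quantile(pred_draws, (1 + level) / 2, axis=0)
    inside = (observed >= lo) & (observed <= hi)
    above = observed > hi
    below = observed < lo
    n_miss = int(above.sum() + below.sum())
    return {
        "coverage": float(np.mean(inside)),
        "frac_misses_above": float(above.sum() / n_miss) if n_miss else np.nan,
        "frac_misses_below": float(below.sum() / n_miss) if n_miss else np.nan,
        "lower": lo,
        "upper": hi,
    }


def variable_contribution(
    design: DesignMatrix,
    beta_draws: np.ndarray,
    covariate: str,
    band: float = 0.95,
) -> dict[str, np.ndarray]:
    """Per-row contribution of one covariate to the linear predictor.

    The contribution is the dot product of the design columns belonging
    to the covariate (global + L1 + L2 + L3 blocks) with the matching
    coefficients, per posterior draw; summaries are the posterior median
    and an equal-tailed credible band.
    """
    cols = design.columns_for(kind="basis", covariate=covariate)
    if cols.size == 0:
        raise ValueError(f"unknown covariate {covariate!r}")
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    sub = design.X[:, cols]
    draws = beta_draws[:, cols] @ sub.T.toarray()  # (n_draws, n_rows)
    lo_q, hi_q = (1 - band) / 2, (1 + band) / 2
    return {
        "draws": draws,
        "median": np.median(draws, axis=0),
        "lower": np.quantile(draws, lo_q, axis=0),
        "upper": np.quantile(draws, hi_q, axis=0),
    }


def intercept_adjustment_contribution(
    design: DesignMatrix, beta_draws: np.ndarray
) -> np.ndarray:
    """Per-draw contribution of the region intercept-adjustment columns."""
    cols = design.columns_for(kind="intercept_adjustment")
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    return beta_draws[:, cols] @ design.X[:, cols].T.toarray()


def model_ranking_report(holdout_results: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Rank model families by posterior-mean holdout log likelihood.

    Descending by mean; exact ties broken alphabetically by family name.
    """
    rows = [
        {"family": fam, "holdout_loglik_mean": m, "holdout_loglik_sd": s}
        for fam, (m, s) in holdout_results.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["holdout_loglik_mean", "family"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def format_ranking(df: pd.DataFrame) -> str:
    lines = ["Model ranking by holdout log likelihood (mean (sd)):"]
    for _, r in df.iterrows():
        lines.append(
            f"  {r['family']:<16s} {r['holdout_loglik_mean']:>12.1f} "
            f"({r['holdout_loglik_sd']:.1f})"
        )
    return "\n".join(lines)
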
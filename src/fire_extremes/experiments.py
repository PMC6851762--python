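"""End-to-end synthetic-study experiments.

These drive the whole pipeline on the toy study (2 L1 / 4 L2 / 12 L3
regions, ten modelled years of monthly data) with known parameters:

* ``recovery_experiment`` — simulate fires from a sparse ZINB + lognormal
  truth, fit count and size models, and measure coefficient recovery
  (credible-interval coverage of true nonzeros, shrinkage of true zeros)
  and holdout-log-likelihood model rankings.
* ``calibration_experiment`` — with the generative parameters treated as
  known, check that posterior-predictive intervals for counts, sizes and
  finite-sample maxima attain their nominal coverage on fresh data.

Sampler settings are scaled for minutes-scale runs (two chains, a few
hundred kept draws); they are arguments, so larger studies are one call
away.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fire_extremes import count_models, extremes, size_models
from fire_extremes.design import build_design_matrix, fit_spline_specs
from fire_extremes.evaluation import interval_coverage, model_ranking_report
from fire_extremes.hierarchy import generate_hierarchy
from fire_extremes.inference import fit, holdout_loglik
from fire_extremes.preprocess import (
    COVARIATE_COLUMNS,
    assemble_panel,
    month_index,
    rolling_prior_12_sum,
)
from fire_extremes.synthetic import default_true_parameters, simulate_covariates, simulate_fires

EMPTY_CATALOG = pd.DataFrame(
    columns=["event_id", "year", "month", "region", "size_ha", "exceedance_ha"]
)


def build_toy_study(
    seed: int,
    n_l1: int = 2,
    n_l2: int = 4,
    n_l3: int = 12,
    n_months: int = 132,
    split_month: int = 108,
    count_family: str = "zinb",
    size_family: str = "lognormal",
) -> dict:
    """Hierarchy, covariates, design and truth for the toy study.

    The first simulated year only feeds the 12-month precipitation
    window, so T = n_months - 12 months are modelled; the default split
    trains on eight years and holds out two.
    """
    hierarchy = generate_hierarchy(n_l1, n_l2, n_l3, seed=seed)
    covariates = rolling_prior_12_sum(simulate_covariates(hierarchy, n_months, seed=seed + 1))
    panel0 = assemble_panel(EMPTY_CATALOG, covariates, hierarchy, split_month=split_month)
    specs = fit_spline_specs(panel0[panel0["split"] == "train"], COVARIATE_COLUMNS)
    design = build_design_matrix(panel0, hierarchy, specs)
    truth = default_true_parameters(
        design,
        mean_area=float(np.mean(hierarchy.areas())),
        count_family=count_family,
        size_family=size_family,
    )
    return {
        "hierarchy": hierarchy,
        "covariates": covariates,
        "panel0": panel0,
        "specs": specs,
        "design": design,
        "truth": truth,
        "split_month": split_month,
    }


def events_with_covariates(catalog: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Attach each event's region-month covariates (for the size design)."""
    ev = catalog.copy()
    first = panel.iloc[0]
    year0 = int(first["year"] - (first["t"] - first["month"]) // 12)
    ev["t"] = month_index(ev["year"], ev["month"], year0)
    cols = ["region", "t", *COVARIATE_COLUMNS, "area_km2", "split"]
    return ev.merge(panel[cols], on=["region", "t"], how="left", validate="m:1")


def simulate_study_data(study: dict, rep_seed: int) -> dict:
    """One realization of the catalog/panel plus train/test designs."""
    hierarchy, covariates = study["hierarchy"], study["covariates"]
    catalog = simulate_fires(study["panel0"], study["design"], study["truth"], seed=rep_seed)
    panel = assemble_panel(catalog, covariates, hierarchy, split_month=study["split_month"])
    train = panel[panel["split"] == "train"].reset_index(drop=True)
    test = panel[panel["split"] == "test"].reset_index(drop=True)
    events = events_with_covariates(catalog, panel)
    ev_train = events[events["split"] == "train"].reset_index(drop=True)
    ev_test = events[events["split"] == "test"].reset_index(drop=True)
    specs = study["specs"]
    return {
        "catalog": catalog,
        "panel": panel,
        "train": train,
        "test": test,
        "design_train": build_design_matrix(train, hierarchy, specs),
        "design_test": build_design_matrix(test, hierarchy, specs),
        "events_train": ev_train,
        "events_test": ev_test,
        "design_ev_train": build_design_matrix(ev_train, hierarchy, specs),
        "design_ev_test": build_design_matrix(ev_test, hierarchy, specs),
    }


def recovery_replicate(
    study: dict,
    rep_seed: int,
    count_families=("zinb", "poisson"),
    size_families=("lognormal", "gamma"),
    chains: int = 2,
    iterations: int = 700,
    warmup: int = 450,
    target_accept: float = 0.92,
    max_treedepth: int = 9,
    size_iterations: int = 500,
    size_warmup: int = 300,
    screen_with_variational: bool = True,
) -> dict:
    """Fit count and size families to one simulated data set.

    Returns credible-interval coverage for the true nonzero coefficients
    of the first (true-family) count model, shrinkage summaries over true
    zeros, and holdout log likelihoods for every family fitted. Following
    the screening protocol, competing count families after the first are
    fitted with the fast variational pass by default; the lead family and
    all size families use NUTS.
    """
    truth = study["truth"]
    data = simulate_study_data(study, rep_seed)
    out: dict = {"rep_seed": rep_seed, "n_events": len(data["catalog"])}

    count_ll = {}
    for k, family in enumerate(count_families):
        draws = fit(
            {"kind": "count", "family": family},
            data["train"],
            data["design_train"],
            method="variational" if (k > 0 and screen_with_variational) else "nuts",
            chains=chains,
            iterations=iterations if k == 0 else size_iterations,
            warmup=warmup if k == 0 else size_warmup,
            seed=rep_seed * 100 + k,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        count_ll[family] = holdout_loglik(draws, data["test"], data["design_test"])
        if k == 0:
            beta = draws.stacked("beta_mu")
            lo = np.quantile(beta, 0.025, axis=0)
            hi = np.quantile(beta, 0.975, axis=0)
            med = np.median(beta, axis=0)
            nz = np.flatnonzero(truth.beta_mu)
            zeros = np.flatnonzero(truth.beta_mu == 0)
            out["nonzero_covered"] = [
                bool(lo[j] <= truth.beta_mu[j] <= hi[j]) for j in nz
            ]
            out["median_abs_zero"] = float(np.median(np.abs(med[zeros])))
            out["median_abs_nonzero"] = float(np.median(np.abs(med[nz])))
            out["divergences"] = [
                s["divergences"] for s in draws.meta["sampler_stats"]
            ]

    size_ll = {}
    for k, family in enumerate(size_families):
        draws = fit(
            {"kind": "size", "family": family},
            data["events_train"],
            data["design_ev_train"],
            chains=chains,
            iterations=size_iterations,
            warmup=size_warmup,
            seed=rep_seed * 100 + 50 + k,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        size_ll[family] = holdout_loglik(draws, data["events_test"], data["design_ev_test"])

    out["count_holdout"] = count_ll
    out["size_holdout"] = size_ll
    out["count_ranking"] = model_ranking_report(count_ll)["family"].tolist()
    out["size_ranking"] = model_ranking_report(size_ll)["family"].tolist()
    return out


def recovery_experiment(seed: int, n_replicates: int = 3, **kwargs) -> dict:
    """Seeded replicates of the recovery protocol, pooled summaries."""
    study = build_toy_study(seed)
    reps = [
        recovery_replicate(study, rep_seed=seed * 1000 + r + 1, **kwargs)
        for r in range(n_replicates)
    ]
    covered = [c for r in reps for c in r["nonzero_covered"]]
    shrink_ok = [r["median_abs_zero"] < 0.5 * r["median_abs_nonzero"] for r in reps]
    count_rank_ok = [r["count_ranking"][0] == study["truth"].count_family for r in reps]
    size_rank_ok = [r["size_ranking"][0] == study["truth"].size_family for r in reps]
    return {
        "replicates": reps,
        "nonzero_coverage": float(np.mean(covered)),
        "n_nonzero_cases": len(covered),
        "shrinkage_ok_fraction": float(np.mean(shrink_ok)),
        "count_ranking_correct_fraction": float(np.mean(count_rank_ok)),
        "size_ranking_correct_fraction": float(np.mean(size_rank_ok)),
    }


def calibration_experiment(
    seed: int,
    n_pred_draws: int = 1500,
    count_level: float = 0.95,
    size_level: float = 0.95,
    maxima_level: float = 0.99,
) -> dict:
    """Coverage of predictive intervals when the parameters are known.

    Fresh observations are simulated from the generative truth over the
    full panel; predictive draws use the same truth, so the intervals'
    empirical coverage should sit at the nominal level (counts are
    discrete, which makes their equal-tailed intervals conservative).
    """
    study = build_toy_study(seed)
    truth = study["truth"]
    panel0, design = study["panel0"], study["design"]
    rng = np.random.default_rng(seed + 7)

    cp = truth.count_params()
    mu, pi = count_models.count_linear_predictors(
        design.X, cp, np.log(panel0["area_km2"].to_numpy())
    )
    n_cells = len(panel0)
    pred_counts = np.stack(
        [
            count_models.count_rng(truth.count_family, mu, cp.dispersion, pi, seed=rng)
            for _ in range(n_pred_draws)
        ]
    )
    observed_counts = count_models.count_rng(
        truth.count_family, mu, cp.dispersion, pi, seed=rng
    )
    count_cov = interval_coverage(pred_counts, observed_counts, count_level)
    # counts are discrete, so equal-tailed intervals over-cover; the exact
    # pmf-implied coverage of these same intervals is the right reference
    kmax = int(pred_counts.max()) + 1
    ks = np.arange(kmax + 1)
    pmf = np.exp(
        count_models.count_logpmf(
            truth.count_family,
            np.broadcast_to(ks[:, None], (kmax + 1, n_cells)),
            mu,
            cp.dispersion,
            pi,
        )
    )
    cdf = np.cumsum(pmf, axis=0)
    lo_idx = np.clip(np.ceil(count_cov["lower"]).astype(int), 0, kmax)
    hi_idx = np.clip(np.floor(count_cov["upper"]).astype(int), 0, kmax)
    cols = np.arange(n_cells)
    exact = cdf[hi_idx, cols] - np.where(lo_idx > 0, cdf[lo_idx - 1, cols], 0.0)
    count_exact_coverage = float(exact.mean())

    sp = truth.size_params()
    eta = size_models.size_linear_predictor(design.X, sp)
    loc = size_models.size_location(truth.size_family, eta)
    # per-event size intervals on cells with at least one observed fire
    occupied = np.flatnonzero(observed_counts >= 1)
    n_events_per_cell = observed_counts[occupied]
    ev_loc = np.repeat(loc[occupied], n_events_per_cell)
    pred_sizes = np.stack(
        [
            size_models.size_rng(truth.size_family, ev_loc, truth.aux, seed=rng)
            for _ in range(max(n_pred_draws // 3, 300))
        ]
    )
    observed_sizes = size_models.size_rng(truth.size_family, ev_loc, truth.aux, seed=rng)
    size_cov = interval_coverage(pred_sizes, observed_sizes, size_level)

    # maxima: conditional on occurrence, via the predictive mixture CDF
    observed_max = np.empty(occupied.size)
    for i, (li, ni) in enumerate(zip(loc[occupied], n_events_per_cell)):
        observed_max[i] = size_models.size_rng(
            truth.size_family, np.full(int(ni), li), truth.aux, seed=rng
        ).max()
    loc_draws = np.tile(loc[occupied], (n_pred_draws, 1))
    aux_val = truth.aux.get("sigma", next(iter(truth.aux.values())))
    aux_draws = np.full(n_pred_draws, aux_val)
    intervals = extremes.maxima_interval(
        pred_counts[:, occupied], loc_draws, aux_draws, truth.size_family, level=maxima_level
    )
    usable = ~intervals["no_fire"].to_numpy()
    inside = (
        (observed_max[usable] >= intervals["lower"].to_numpy()[usable])
        & (observed_max[usable] <= intervals["upper"].to_numpy()[usable])
    )
    return {
        "count_coverage": count_cov["coverage"],
        "count_exact_coverage": count_exact_coverage,
        "count_n_units": n_cells,
        "size_coverage": size_cov["coverage"],
        "size_n_units": int(ev_loc.size),
        "maxima_coverage": float(np.mean(inside)),
        "maxima_n_units": int(usable.sum()),
        "count_level": count_level,
        "size_level": size_level,
        "maxima_level": maxima_level,
    }
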
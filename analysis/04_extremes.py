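"""Finite-sample maxima: intervals, coverage, threshold exceedances.

Combines the fitted ZINB count posterior and lognormal size posterior
into the posterior predictive distribution of the largest fire per
region-month on the test block: 99% maxima prediction intervals and their
empirical coverage, plus the monthly probability that at least one fire
exceeds a large threshold (the synthetic analogue of the million-acre
analysis), with an 80% credible band. Writes tidy CSVs and figures.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from fire_extremes import extremes
from fire_extremes.experiments import build_toy_study, simulate_study_data
from fire_extremes.inference import posterior_predict
from fire_extremes.inference.api import PosteriorDraws, size_location_draws

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
#: threshold on the exceedance scale for the "very large fire" analysis, ha
BIG_FIRE_EXCEEDANCE = 50_000.0


def main() -> None:
    study = build_toy_study(SEED)
    data = simulate_study_data(study, rep_seed=SEED * 1000 + 1)
    count_draws = PosteriorDraws.load(Path("scratch/draws") / "count_zinb")
    size_draws = PosteriorDraws.load(Path("scratch/draws") / "size_lognormal")
    test, dm_test = data["test"], data["design_test"]

    n_rep = posterior_predict(count_draws, dm_test, test, seed=SEED + 80)
    loc, aux = size_location_draws(size_draws, dm_test)
    # align the two posteriors by iteration (they have equal retained sizes)
    d = min(n_rep.shape[0], loc.shape[0])
    n_rep, loc, aux = n_rep[:d], loc[:d], aux[:d]

    intervals = extremes.maxima_interval(n_rep, loc, aux, "lognormal", level=0.99)
    intervals["region"] = test["region"].to_numpy()
    intervals["t"] = test["t"].to_numpy()

    obs_max = (
        data["events_test"].groupby(["region", "t"])["exceedance_ha"].max().rename("observed_max")
    )
    intervals = intervals.merge(obs_max, on=["region", "t"], how="left")
    intervals.to_csv(OUT / "maxima_intervals_test.csv", index=False)

    occupied = intervals["observed_max"].notna() & ~intervals["no_fire"]
    inside = (
        (intervals.loc[occupied, "observed_max"] >= intervals.loc[occupied, "lower"])
        & (intervals.loc[occupied, "observed_max"] <= intervals.loc[occupied, "upper"])
    )
    print(f"cells with an observed monthly maximum: {occupied.sum()}")
    print(f"99% maxima interval coverage on the test block: {inside.mean():.3f}")

    exc = extremes.exceedance_probability(
        n_rep, loc, aux, "lognormal",
        threshold=BIG_FIRE_EXCEEDANCE, groups=test["t"].to_numpy(),
    )
    exc = exc.rename(columns={"group": "t"})
    exc.to_csv(OUT / "big_fire_probability_by_month.csv", index=False)
    print(f"\nP(any fire exceeding {BIG_FIRE_EXCEEDANCE:.0f} ha exceedance) per month:")
    print(f"  median across test months: {exc['prob_median'].median():.3f}, "
          f"max: {exc['prob_median'].max():.3f}")

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(exc["t"], exc["prob_median"], color="tab:red")
    ax.fill_between(exc["t"], exc["band_lo"], exc["band_hi"], color="tab:red", alpha=0.3)
    ax.set_xlabel("month index")
    ax.set_ylabel("P(very large fire)")
    fig.tight_layout()
    fig.savefig(OUT / "big_fire_probability.png", dpi=120)

    # maxima interval figure for the busiest region
    busy = intervals[occupied].groupby("region").size().idxmax()
    sub = intervals[(intervals["region"] == busy)]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(sub["t"], sub["lower"], sub["upper"], color="tab:red", alpha=0.3)
    ax.scatter(sub["t"], sub["observed_max"], s=12, color="k")
    ax.set_yscale("log")
    ax.set_xlabel("month index")
    ax.set_ylabel("max exceedance (ha)")
    ax.set_title(f"region {busy}: 99% maxima intervals vs observed monthly maxima")
    fig.tight_layout()
    fig.savefig(OUT / "maxima_intervals_region.png", dpi=120)


if __name__ == "__main__":
    main()
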
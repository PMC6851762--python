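"""Posterior predictive checks and holdout interval coverage.

Loads the fitted ZINB count model and lognormal size model from 02,
replicates data from their posteriors, and compares the proportion of
zeros, maxima and sums between replicated and observed data on the
training and test sets; also computes 95% interval coverage (with miss
directions) for test-set counts and event sizes. Writes tidy CSVs and a
four-panel figure under results/.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from fire_extremes.evaluation import interval_coverage, ppc_statistic
from fire_extremes.experiments import build_toy_study, simulate_study_data
from fire_extremes.inference import posterior_predict
from fire_extremes.inference.api import PosteriorDraws

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    study = build_toy_study(SEED)
    data = simulate_study_data(study, rep_seed=SEED * 1000 + 1)
    count_draws = PosteriorDraws.load(Path("scratch/draws") / "count_zinb")
    size_draws = PosteriorDraws.load(Path("scratch/draws") / "size_lognormal")

    rows = []
    fig, axes = plt.subplots(2, 3, figsize=(12, 6))
    for r, (label, dat, dm) in enumerate(
        [
            ("train", data["train"], data["design_train"]),
            ("test", data["test"], data["design_test"]),
        ]
    ):
        reps = posterior_predict(count_draws, dm, dat, seed=SEED + 40 + r)
        for c, stat in enumerate(("prop_zero", "max", "sum")):
            res = ppc_statistic(reps, dat["count"].to_numpy(), stat)
            rows.append(
                {
                    "component": "count",
                    "set": label,
                    "statistic": stat,
                    "observed": res.observed_value,
                    "replicate_median": float(np.median(res.replicate_values)),
                    "tail_probability": res.tail_probability,
                }
            )
            ax = axes[r][c]
            ax.hist(res.replicate_values, bins=30, color="tab:red", alpha=0.6)
            ax.axvline(res.observed_value, color="k", ls="--")
            ax.set_title(f"count {stat} ({label})", fontsize=9)
    fig.tight_layout()
    fig.savefig(OUT / "ppc_counts.png", dpi=120)

    for label, dat, dm in [
        ("train", data["events_train"], data["design_ev_train"]),
        ("test", data["events_test"], data["design_ev_test"]),
    ]:
        reps = posterior_predict(size_draws, dm, dat, seed=SEED + 60)
        for stat in ("max", "sum"):
            res = ppc_statistic(reps, dat["exceedance_ha"].to_numpy(), stat)
            rows.append(
                {
                    "component": "size",
                    "set": label,
                    "statistic": stat,
                    "observed": res.observed_value,
                    "replicate_median": float(np.median(res.replicate_values)),
                    "tail_probability": res.tail_probability,
                }
            )
    ppc = pd.DataFrame(rows)
    ppc.to_csv(OUT / "ppc_statistics.csv", index=False)

    cnt_reps = posterior_predict(count_draws, data["design_test"], data["test"], seed=SEED + 70)
    cov_counts = interval_coverage(cnt_reps, data["test"]["count"].to_numpy(), 0.95)
    size_reps = posterior_predict(size_draws, data["design_ev_test"], data["events_test"], seed=SEED + 71)
    cov_sizes = interval_coverage(size_reps, data["events_test"]["exceedance_ha"].to_numpy(), 0.95)
    pd.DataFrame(
        [
            {"component": "count", "level": 0.95, "coverage": cov_counts["coverage"],
             "frac_misses_above": cov_counts["frac_misses_above"]},
            {"component": "size", "level": 0.95, "coverage": cov_sizes["coverage"],
             "frac_misses_above": cov_sizes["frac_misses_above"]},
        ]
    ).to_csv(OUT / "holdout_coverage.csv", index=False)

    print(ppc.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(f"\ntest-set 95% interval coverage: counts {cov_counts['coverage']:.3f}, "
          f"sizes {cov_sizes['coverage']:.3f}")
    if cov_counts["frac_misses_above"] == cov_counts["frac_misses_above"]:
        print(f"count misses above interval: {cov_counts['frac_misses_above']:.0%}")


if __name__ == "__main__":
    main()
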
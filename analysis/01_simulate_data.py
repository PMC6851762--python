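"""Generate the synthetic fire study: hierarchy, covariates, truth, events.

Builds the toy study (2 L1 / 4 L2 / 12 L3 ecoregions, 132 monthly steps of
which the first 12 only feed the precipitation lag) and simulates a fire
catalog from the known zero-inflated negative binomial + lognormal truth.
Writes everything under results/data/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from fire_extremes.experiments import build_toy_study, simulate_study_data

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    study = build_toy_study(SEED)
    nest, edges = study["hierarchy"].to_frames()
    nest.to_csv(OUT / "hierarchy.csv", index=False)
    edges.to_csv(OUT / "adjacency.csv", index=False)
    study["covariates"].to_csv(OUT / "covariates.csv", index=False)
    study["truth"].to_json(OUT / "true_parameters.json")

    data = simulate_study_data(study, rep_seed=SEED * 1000 + 1)
    data["catalog"].to_csv(OUT / "fire_catalog.csv", index=False)
    data["panel"].to_csv(OUT / "panel.csv", index=False)

    with open(OUT / "study_config.json", "w") as fh:
        json.dump({"seed": SEED, "split_month": study["split_month"]}, fh, indent=1)

    panel = data["panel"]
    print(f"regions: {study['hierarchy'].n_l3}, modelled months: {panel['t'].nunique()}")
    print(f"events simulated: {len(data['catalog'])}")
    print(f"zero cells: {(panel['count'] == 0).mean():.1%}, max monthly count: {panel['count'].max()}")
    print(f"median exceedance: {data['catalog']['exceedance_ha'].median():.0f} ha, "
          f"largest: {data['catalog']['exceedance_ha'].max():.0f} ha")
    nz = np.flatnonzero(study["truth"].beta_mu)
    print(f"true nonzero count-model coefficients: {len(nz)} of {len(study['truth'].beta_mu)}")


if __name__ == "__main__":
    main()
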
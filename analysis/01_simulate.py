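"""Generate the synthetic small-area screening system used by the analysis.

A 20x20 lattice country (400 areas) with four states, remoteness rising
with distance from the central city, spatially clustered disadvantage
quintiles, and a Leroux spatial field (rho=0.8, tau2=0.25) driving true
relative participation.  Writes the area table, counts, adjacency and the
ground truth under results/data/.
"""

import sys
from pathlib import Path

import numpy as np

from screenvar.io import write_adjacency, write_areas, write_counts, write_truth
from screenvar.pipeline import stage_rng
from screenvar.standardization import ELIGIBILITY_SCHEDULE
from screenvar.synthetic import (
    SyntheticConfig,
    default_national_rates,
    make_lattice,
    sample_leroux_field,
    simulate_counts,
    true_parameters,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_rows=20, n_cols=20, seed=SEED, mean_pop=2000.0,
                          rho=0.8, tau2=0.25)
    areas, adj = make_lattice(cfg)
    rng = stage_rng(SEED, "simulate")
    psi = sample_leroux_field(adj, cfg.rho, cfg.tau2, rng=rng)
    truth = true_parameters(areas, psi, cfg)
    counts = simulate_counts(areas, ELIGIBILITY_SCHEDULE,
                             default_national_rates(), truth, rng=rng)

    write_areas(areas, OUT / "areas.csv")
    write_counts(counts, OUT / "area_counts.csv", OUT / "national_counts.csv")
    write_adjacency(adj, OUT / "adjacency.gal")
    write_truth(truth, list(adj.ids), OUT / "truth.json")

    rate = 100 * counts.area["screened"].sum() / counts.area["invitees"].sum()
    print(f"simulated {len(areas)} areas over 2019-2020 "
          f"({counts.area['invitees'].sum():,} invitees, national "
          f"participation {rate:.1f}%)")
    print(f"true theta range: {truth.theta.min():.2f} - {truth.theta.max():.2f}")
    print(f"outputs under {OUT}/")


if __name__ == "__main__":
    main()
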
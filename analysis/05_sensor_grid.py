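"""Sensor-implementation comparison over a wall-property grid.

For a 3x3 grid of bladder-wall optical properties (mu_a 0.2-0.9,
mu_s 0.5-25 mm^-1, albedo up to 0.992) on a lobulated and a spherical
bladder, computes the true area-weighted mean wall irradiance and the
readings of three virtual monitoring implementations: a single cut-end
fiber at the neck, three 25-deg angled-cut fibers, and a 12-sensor
cos^2 cage. Writes results/property_grid_study.csv.

The ratio true-mean / sensor-mean should be 1 for a perfect monitor;
its spread across the grid measures how robustly an implementation
tracks the dose when the tissue properties are unknown.
"""

import argparse
from pathlib import Path

import numpy as np

import cavidose as cv


def main(seed: int, n_packets: int, out_dir: Path):
    cfg = cv.ExperimentConfig(
        geometries=[
            {"name": "lobulated100", "kind": "lobulated", "volume_ml": 100.0, "seed": 42},
            {"name": "sphere48", "kind": "sphere", "volume_ml": 48.5},
        ],
        grid_mu_a=(0.2, 0.9, 3),
        grid_mu_s=(0.5, 25.0, 3),
        n_packets=n_packets,
        seed=seed,
        output_dir=str(out_dir),
    )
    tab = cv.run_property_grid_study(cfg)["table"]
    print(tab[["geometry", "mu_a", "mu_s", "albedo", "true_mean_mw_cm2",
               "ratio_single", "ratio_triple", "ratio_cage12"]].round(3).to_string(index=False))

    for impl in ("single", "triple", "cage12"):
        r = tab[f"ratio_{impl}"]
        print(f"{impl:>7}: ratio range [{r.min():.2f}, {r.max():.2f}], "
              f"dynamic range {r.max() / r.min():.2f}x")
    closer = (np.abs(np.log(tab["ratio_cage12"])) < np.abs(np.log(tab["ratio_single"]))).mean()
    print(f"12-sensor cage closer to the true mean than the single fiber on "
          f"{100 * closer:.0f}% of grid points.")
    print("Cut-end fibers over-read primary-light-dominated fields (small "
          "acceptance cone calibrated against diffuse light); the cos^2 cage "
          "is the most faithful monitor across unknown tissue properties.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--packets", type=int, default=80_000)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.packets, a.out_dir)
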
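"""Void-turbidity study: what scattering in the filling liquid does to
the wall dose.

Sweeps the void scattering coefficient from clear water (1.7e-5 mm^-1)
through 17 mm^-1, plus an intralipid-grade point (85 mm^-1, i.e.
mu_s' ~ 17 with g = 0.8), on a 48.5-ml sphere with a central source.
Writes results/turbidity_study.csv.

Two competing effects appear. Mild turbidity diffuses the incidence on
the wall, which *raises* the wall's effective remission and the cavity
build-up factor (a few percent increase in mean irradiance). Only at
very high turbidity does absorption in the void over metre-scale
diffusion paths dominate and pull the mean irradiance down — the regime
of visibly cloudy filling liquid, which is why the liquid should be
exchanged when the sensors report a dropping irradiance.
"""

import argparse
from pathlib import Path

import cavidose as cv


def main(seed: int, n_packets: int, out_dir: Path):
    cfg = cv.ExperimentConfig(
        geometries=[{"name": "sphere48", "kind": "sphere", "volume_ml": 48.5}],
        turbidity_mus=(0.000017, 0.17, 1.7, 17.0),
        n_packets=n_packets,
        seed=seed,
        output_dir=str(out_dir),
    )
    rep = cv.run_turbidity_study(cfg)
    tab = rep["table"]

    # intralipid-grade endpoint at reduced packet count (very long paths)
    cfg85 = cv.ExperimentConfig(
        geometries=cfg.geometries,
        turbidity_mus=(0.000017, 85.0),
        n_packets=max(1500, n_packets // 20),
        seed=seed,
        output_dir=None,
    )
    rep85 = cv.run_turbidity_study(cfg85)
    row85 = rep85["table"].iloc[1]

    print(tab[["void_mu_s", "mean_irradiance_mw_cm2", "dsh_distance_to_clear",
               "heterogeneity_ratio"]].round(4).to_string(index=False))
    clear = tab["mean_irradiance_mw_cm2"].iloc[0]
    print(f"mu_s=85 mm^-1 (1% intralipid grade): mean "
          f"{row85['mean_irradiance_mw_cm2']:.2f} mW/cm^2 "
          f"({100 * (row85['mean_irradiance_mw_cm2'] / clear - 1):+.1f}% vs clear), "
          f"DSH distance {row85['dsh_distance_to_clear']:.3f}")
    print("Mild turbidity slightly raises the mean wall irradiance via "
          "diffuse-incidence remission; intralipid-grade turbidity reduces "
          "it through void absorption. Scattering in the void does not "
          "homogenize the dose and should be avoided.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--packets", type=int, default=30_000)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.packets, a.out_dir)
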
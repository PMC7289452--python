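"""Treatment monitoring: radiant-exposure integration on a synthetic
clinical trace.

Generates an irradiance recording emulating a clinical delivery — eight
sensors around 30 mW/cm^2 with per-sensor spread, a cystoscope-light
baseline offset, a slow downward drift as the filling liquid clouds,
two delivery interruptions and one dead sensor — then integrates the
responding-sensor average to the 90 J/cm^2 target. Writes
results/monitoring_trace.csv and results/monitoring_report.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import cavidose as cv
from cavidose.sensors import TracePattern, trace_to_csv


def main(seed: int, out_dir: Path):
    pattern = TracePattern(
        duration_s=5000.0,
        n_sensors=8,
        mean_irradiance=30.0,
        sensor_spread=0.25,
        baseline_offset=1.0,
        drift_frac=-0.15,
        noise_frac=0.02,
        interruptions=[(900.0, 120.0), (2200.0, 180.0)],
        dead_sensors=[5],
    )
    trace = cv.synth_trace(pattern, seed=seed)
    out = cv.integrate_exposure(trace, target_J_cm2=90.0)

    out_dir.mkdir(parents=True, exist_ok=True)
    trace_to_csv(trace, out_dir / "monitoring_trace.csv")
    report = {
        "termination_time_s": out["termination_time_s"],
        "per_sensor_exposure_J_cm2": [round(float(x), 3) for x in out["per_sensor_exposure_J_cm2"]],
        "responding": [bool(b) for b in out["responding"]],
        "target_J_cm2": 90.0,
        "seed": seed,
    }
    with open(out_dir / "monitoring_report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    resp = out["responding"]
    print(f"Responding sensors: {int(resp.sum())}/{len(resp)} "
          f"(sensor 5 is dead and excluded)")
    print(f"Termination at {out['termination_time_s']:.0f} s "
          f"(ideal constant-30 mW/cm^2 delivery would need 3000 s; "
          f"interruptions and drift extend it)")
    exp = out["per_sensor_exposure_J_cm2"][resp]
    print(f"Responding-sensor exposures at termination: "
          f"{exp.min():.1f}-{exp.max():.1f} J/cm^2 (mean {exp.mean():.1f})")
    print("The mean hits the 90 J/cm^2 target while individual wall sites "
          "span a band set by the dose heterogeneity - the reason multi-"
          "sensor monitoring is required.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.out_dir)
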
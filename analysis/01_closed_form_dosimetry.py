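"""Closed-form dosimetry arithmetic for green-light intravesical PDT.

Computes, from the 525-nm tissue property set and the preclinical
TLD1433 threshold/uptake data, the quantities that frame the treatment:
the bladder-wall albedo (which governs the cavity's light
multiplication), the specific uptake ratio, the tumor/normal threshold
ratios, the allowable fluence ratio across the mucosa, and the
attainable depth of selective treatment. Writes
results/closed_form_dosimetry.json.
"""

import argparse
import json
from pathlib import Path

import cavidose as cv
from cavidose.selectivity import TLD1433_DEFAULTS


def main(out_dir: Path) -> dict:
    pm = cv.preset_properties("bladder_525nm")
    model = TLD1433_DEFAULTS

    sur = cv.specific_uptake_ratio(model)
    tr_uro = cv.threshold_ratio(model, "urothelium")
    tr_mus = cv.threshold_ratio(model, "muscle")
    allow = cv.allowable_fluence_ratio(sur, 1.0 / tr_uro)
    out = {
        "wall_albedo": cv.albedo(pm.wall),
        "wall_mu_s_reduced_mm": cv.reduced_scattering(pm.wall),
        "wall_mu_eff_mm": cv.effective_attenuation(pm.wall),
        "wall_mu_eff_inv_um": 1000.0 / cv.effective_attenuation(pm.wall),
        "grid_max_albedo": cv.albedo(cv.OpticalProperties(0.2, 25.0, 0.9, 1.37)),
        "specific_uptake_ratio": sur,
        "threshold_ratio_urothelium": tr_uro,
        "threshold_ratio_muscle": tr_mus,
        "allowable_fluence_ratio": allow,
        "allowable_fluence_ratio_printed_inputs": cv.allowable_fluence_ratio(192.0, 0.0757),
        "selectivity_depth_rule_of_thumb_mm": cv.selectivity_depth(allow, 0.75, "rule_of_thumb"),
        "selectivity_depth_planar_mm": cv.selectivity_depth(allow, 0.75, "planar"),
        "selectivity_depth_spherical_28mm_mm": cv.selectivity_depth(
            allow, 0.75, "spherical", sphere_radius_mm=28.8
        ),
        "sphere_equivalent_radius_100ml_cm": cv.sphere_equivalent_radius(100.0),
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "closed_form_dosimetry.json", "w") as fh:
        json.dump(out, fh, indent=2)

    print("Closed-form dosimetry (525 nm, TLD1433 preclinical parameters)")
    print(f"  bladder-wall albedo            : {out['wall_albedo']:.4f}")
    print(f"  wall mu_eff^-1                 : {out['wall_mu_eff_inv_um']:.0f} um")
    print(f"  property-grid maximum albedo   : {out['grid_max_albedo']:.3f}")
    print(f"  specific uptake ratio (SUR)    : {sur:.1f}")
    print(f"  T_tumor / T_urothelium         : {tr_uro:.2f}")
    print(f"  T_tumor / T_muscle             : {tr_mus:.2f}")
    print(f"  allowable fluence ratio        : {allow:.2f}")
    print(f"  selective depth, 2.5/mu_eff    : {out['selectivity_depth_rule_of_thumb_mm']:.3f} mm")
    print(f"  selective depth, planar        : {out['selectivity_depth_planar_mm']:.3f} mm")
    print(f"  sphere radius of a 100-ml void : {out['sphere_equivalent_radius_100ml_cm']:.3f} cm")
    print(
        "A SUR near 192 with a 13-fold threshold handicap still permits a\n"
        "~14.5-fold fluence drop across the mucosa, i.e. ~2 mm of selective\n"
        "treatment depth at green wavelengths."
    )
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    main(ap.parse_args().out_dir)
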
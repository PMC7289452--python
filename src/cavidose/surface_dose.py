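"""Dose surface histograms (DSHs) over the inner cavity wall.

A DSH sorts per-patch surface irradiance in descending order against
the cumulative surface-area fraction, the hollow-organ analogue of the
radiotherapy dose-volume histogram: reading the curve at area fraction
f gives the irradiance exceeded by the best-illuminated fraction f of
the wall. The DSH is kept as an exact step function over patches; any
resampling happens only inside comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .transport import DoseMaps

__all__ = ["DSH", "build_dsh", "dsh_summary", "dsh_distance"]


@dataclass
class DSH:
    """Descending-sorted irradiance vs cumulative area fraction."""

    sorted_irradiance: np.ndarray  # mW cm^-2, non-increasing
    cumulative_area_fraction: np.ndarray  # right edges, ends at 1
    total_area: float  # mm^2
    mean_irradiance: float  # area-weighted, mW cm^-2

    def irradiance_at(self, area_fraction) -> np.ndarray:
        """Step-function irradiance at given area fraction(s)."""
        f = np.clip(np.asarray(area_fraction, dtype=float), 0.0, 1.0)
        idx = np.searchsorted(self.cumulative_area_fraction, f, side="left")
        idx = np.minimum(idx, len(self.sorted_irradiance) - 1)
        out = self.sorted_irradiance[idx]
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "irradiance_mw_cm2": self.sorted_irradiance,
                "cumulative_area_fraction": self.cumulative_area_fraction,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_dsh(dose_maps: DoseMaps, patches=None) -> DSH:
    """Build the DSH from a transport run.

    Patch areas are taken from the dose maps themselves; ``patches`` is
    accepted for symmetry with the scoring call but only its areas would
    be used, and they must agree.
    """
    irr = np.asarray(dose_maps.surface_irradiance, dtype=float)
    areas = np.asarray(dose_maps.patch_areas, dtype=float)
    if patches is not None and not np.allclose(patches.patch_areas, areas):
        raise ValueError("patch set does not match the one used for scoring")
    return dsh_from_values(irr, areas)


def dsh_from_values(irradiance: np.ndarray, areas: np.ndarray) -> DSH:
    """DSH from raw per-patch irradiance and areas (mm^2)."""
    irr = np.asarray(irradiance, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if irr.size == 0:
        raise ValueError("empty patch set")
    if np.any(~np.isfinite(irr)) or np.any(areas <= 0):
        raise ValueError("irradiances must be finite and areas positive")
    order = np.argsort(-irr, kind="stable")  # ties stay adjacent
    irr_sorted = irr[order]
    total = areas.sum()
    cum = np.cumsum(areas[order]) / total
    cum[-1] = 1.0
    return DSH(
        sorted_irradiance=irr_sorted,
        cumulative_area_fraction=cum,
        total_area=float(total),
        mean_irradiance=float(np.average(irr, weights=areas)),
    )


def dsh_summary(dsh: DSH) -> Dict[str, float]:
    """Area-weighted summary statistics of a DSH.

    Percentiles are by area fraction (p10 = irradiance exceeded on the
    best-lit 10% of the surface). ``heterogeneity_ratio`` is the
    irradiance at area fraction 0.05 divided by that at 0.95 — a robust
    hot-spot/cold-spot contrast that is 1 for a uniform field and rises
    with dose heterogeneity.
    """
    p05, p10, p50, p90, p95 = dsh.irradiance_at([0.05, 0.10, 0.50, 0.90, 0.95])
    return {
        "mean": dsh.mean_irradiance,
        "p10": float(p10),
        "p50": float(p50),
        "p90": float(p90),
        "heterogeneity_ratio": float(p05 / p95) if p95 > 0 else float("inf"),
    }


def dsh_distance(dsh_a: DSH, dsh_b: DSH, n_grid: int = 2001) -> float:
    """Maximum vertical deviation between two DSHs, relative to the
    mean irradiance of the first.

    Both curves are linearly resampled onto a common area-fraction grid;
    the statistic is max_f |E_a(f) - E_b(f)| / mean(E_a).
    """
    if dsh_a.mean_irradiance <= 0:
        raise ValueError("reference DSH has non-positive mean irradiance")
    grid = np.linspace(0.0, 1.0, n_grid)
    ea = _resample(dsh_a, grid)
    eb = _resample(dsh_b, grid)
    return float(np.max(np.abs(ea - eb)) / dsh_a.mean_irradiance)


def _resample(dsh: DSH, grid: np.ndarray) -> np.ndarray:
    # linear interpolation through the step-curve right edges, anchored
    # at (0, max irradiance)
    x = np.concatenate([[0.0], dsh.cumulative_area_fraction])
    y = np.concatenate([[dsh.sorted_irradiance[0]], dsh.sorted_irradiance])
    return np.interp(grid, x, y)


def write_summary_json(dsh: DSH, path) -> None:
    with open(path, "w") as fh:
        json.dump(dsh_summary(dsh), fh, indent=2)
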
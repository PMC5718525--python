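"""Gel dose calibration: linear R2-dose response and the dose scaling factor.

Polymer gel (MAGAT-type) response is linear in R2 over the working range:
R2(D) = intercept + slope * D, fitted by ordinary least squares on calibration
vial data.  R2 maps of the phantom are converted to dose by inverting the
line; a relative scaling factor (ratio of calculated to measured mean dose in
a uniform high-dose region) absorbs the systematic sensitivity difference
between small calibration vials and the head-sized phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Box, DoseGrid, resample
from .r2 import R2Map

__all__ = [
    "GelCalibration",
    "read_vial_table",
    "fit_linear_calibration",
    "r2_to_dose",
    "derive_scaling_factor",
    "apply_scaling",
]

VIAL_COLUMNS = ("dose_gy", "r2_s-1", "sd", "n")


@dataclass
class GelCalibration:
    """Linear R2-dose calibration line with fit diagnostics.

    slope in s^-1 Gy^-1 (must be positive: response increases with dose),
    intercept in s^-1 (R2 of unirradiated gel), dose_range the span of the
    calibration doses in Gy.
    """

    slope: float
    intercept: float
    dose_range: tuple[float, float]
    fit_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not self.dose_range[0] < self.dose_range[1]:
            raise ValueError("dose_range must be increasing")
        self.fit_residuals = np.asarray(self.fit_residuals, dtype=float)

    def r2_of_dose(self, dose: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(dose, dtype=float)

    def dose_of_r2(self, r2: np.ndarray) -> np.ndarray:
        return (np.asarray(r2, dtype=float) - self.intercept) / self.slope

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope_s-1_gy-1": self.slope,
                    "intercept_s-1": self.intercept,
                    "dose_range_gy": list(self.dose_range),
                    "fit_residuals_s-1": self.fit_residuals.tolist(),
                    "r_squared": self.r_squared,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GelCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            d["slope_s-1_gy-1"],
            d["intercept_s-1"],
            tuple(d["dose_range_gy"]),
            np.asarray(d["fit_residuals_s-1"]),
            d["r_squared"],
        )


def read_vial_table(path: str | Path) -> pd.DataFrame:
    """Read a calibration vial table (CSV: dose_gy, r2_s-1, sd, n)."""
    df = pd.read_csv(path)
    missing = [c for c in VIAL_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"vial table missing columns {missing}")
    return df


def fit_linear_calibration(vials: pd.DataFrame) -> GelCalibration:
    """OLS fit of mean vial R2 on delivered dose.

    Requires at least 3 vials with unique non-negative doses.  A non-positive
    fitted slope is an error: gel response must increase with dose.
    """
    dose = np.asarray(vials["dose_gy"], dtype=float)
    r2 = np.asarray(vials["r2_s-1"], dtype=float)
    if dose.size < 3:
        raise ValueError(f"need >= 3 calibration vials, got {dose.size}")
    if np.unique(dose).size != dose.size or np.any(dose < 0):
        raise ValueError("vial doses must be unique and non-negative")
    res = stats.linregress(dose, r2)
    if res.slope <= 0:
        raise ValueError(f"fitted slope {res.slope:.4g} s^-1/Gy is not positive")
    residuals = r2 - (res.intercept + res.slope * dose)
    return GelCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        dose_range=(float(dose.min()), float(dose.max())),
        fit_residuals=residuals,
        r_squared=float(res.rvalue**2),
    )


def r2_to_dose(
    r2map: R2Map, cal: GelCalibration, clamp: str = "clamp"
) -> DoseGrid:
    """Convert an R2 map to dose via the calibration line.

    dose = (r2 - intercept) / slope.  Invalid voxels become no-data.  Values
    outside the calibrated dose range are handled per ``clamp``:
    ``"clamp"`` clips to the range, ``"mark-invalid"`` turns them to no-data,
    ``"extrapolate"`` keeps the linear conversion (appropriate before the
    dose scaling factor is applied, when the gel's raw over-response can
    exceed the calibrated span while the response itself is still linear).
    """
    if clamp not in ("clamp", "mark-invalid", "extrapolate"):
        raise ValueError(f"unknown clamp policy {clamp!r}")
    dose = cal.dose_of_r2(r2map.r2)
    dose = np.where(r2map.valid, dose, np.nan)
    lo, hi = cal.dose_range
    if clamp == "clamp":
        dose = np.clip(dose, lo, hi)
    elif clamp == "mark-invalid":
        dose = np.where((dose < lo) | (dose > hi), np.nan, dose)
    return DoseGrid(dose, r2map.geometry, dict(r2map.meta))


def derive_scaling_factor(
    measured: DoseGrid, calculated: DoseGrid, region: Box
) -> float:
    """Ratio of mean calculated to mean measured dose over a uniform region.

    The measured grid is resampled onto the calculated geometry, both are
    restricted to the (inclusive, mm) region box, and the factor is
    mean(calculated)/mean(measured) over voxels valid in both.  Multiplying
    the measured grid by the factor matches it to the calculation in that
    region, as done when normalising relative gel dose to the plan.
    """
    if measured.geometry != calculated.geometry:
        measured = resample(measured, calculated.geometry)
    xs, ys, zs = calculated.geometry.meshgrid_mm()
    pts = np.stack([xs, ys, zs], axis=-1)
    mask = region.contains(pts) & measured.valid & calculated.valid
    if not mask.any():
        raise ValueError("scaling region contains no valid voxels in both grids")
    m = float(measured.data[mask].mean())
    c = float(calculated.data[mask].mean())
    if m == 0.0:
        raise ValueError("measured dose averages to zero in the scaling region")
    return c / m


def apply_scaling(measured: DoseGrid, factor: float) -> DoseGrid:
    """Multiply a measured dose grid by a scaling factor."""
    return DoseGrid(measured.data * float(factor), measured.geometry, dict(measured.meta))
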
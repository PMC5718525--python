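"""Radiochromic film processing: scans -> optical density -> 2D dose maps.

EBT2-type film darkens with dose; a flatbed transmission scan is split into
red/green/blue channels and each channel's pixel value P is converted to net
optical density OD = log10(P_ref / P) against the unexposed film.  Dose is
recovered through a per-channel 4th-degree polynomial calibration fitted on
strips of known dose; the working channel is the one with the steepest OD
response per Gy (red for the 0-10 Gy range).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import DoseGrid, GridGeometry

__all__ = [
    "CHANNELS",
    "FilmScan",
    "ODImage",
    "FilmCalibration",
    "average_scans",
    "pixel_to_od",
    "fit_film_calibration",
    "od_to_dose",
    "read_film_tiff",
    "write_film_tiff",
]

CHANNELS = ("red", "green", "blue")
POLY_DEGREE = 4


@dataclass
class FilmScan:
    """An RGB transmission scan: ``pixels`` H x W x 3 counts in [1, 65535].

    Counts are held as float64 so that multi-scan averages and synthetic
    round trips keep full precision; they are quantised to uint16 only on
    TIFF export.  ``geometry`` optionally places the scan plane in the
    stereotactic frame (singleton third axis).
    """

    pixels: np.ndarray
    dpi: float = 150.0
    scan_ids: list = field(default_factory=list)
    geometry: GridGeometry | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("film scan must be H x W x 3")
        if self.pixels.min() < 1 or self.pixels.max() > 65535:
            raise ValueError("pixel counts must lie in [1, 65535]")


@dataclass
class ODImage:
    """Net optical density per channel, H x W x 3."""

    od: np.ndarray
    geometry: GridGeometry | None = None


@dataclass
class FilmCalibration:
    """Per-channel quartic OD -> dose (Gy) calibration.

    ``coeffs[channel]`` are ascending polynomial coefficients (length 5) of
    dose as a function of net OD; ``od_span[channel]`` is the fitted OD range;
    ``monotone[channel]`` flags whether the fitted curve is non-decreasing
    over that span.
    """

    coeffs: dict[str, np.ndarray]
    r_squared: dict[str, float]
    od_span: dict[str, tuple[float, float]]
    dose_range: tuple[float, float] = (0.0, 10.0)
    selected_channel: str = "red"
    monotone: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, c in self.coeffs.items():
            c = np.asarray(c, dtype=float)
            if c.size != POLY_DEGREE + 1:
                raise ValueError(f"channel {ch}: need degree-{POLY_DEGREE} coefficients")
            self.coeffs[ch] = c
        if self.selected_channel not in self.coeffs:
            raise ValueError(f"unknown selected channel {self.selected_channel!r}")

    def dose_of_od(self, od: np.ndarray, channel: str | None = None) -> np.ndarray:
        ch = channel or self.selected_channel
        return np.polynomial.polynomial.polyval(np.asarray(od, dtype=float), self.coeffs[ch])

    def od_of_dose(self, dose: np.ndarray, channel: str | None = None) -> np.ndarray:
        """Invert the monotone quartic by Newton iteration (used when
        synthesising film exposures from a dose plane)."""
        ch = channel or self.selected_channel
        c = self.coeffs[ch]
        dc = np.polynomial.polynomial.polyder(c)
        d = np.asarray(dose, dtype=float)
        lo, hi = self.od_span[ch]
        # linear initial guess from the span endpoints
        d_lo = float(np.polynomial.polynomial.polyval(lo, c))
        d_hi = float(np.polynomial.polynomial.polyval(hi, c))
        od = lo + (d - d_lo) * (hi - lo) / (d_hi - d_lo)
        for _ in range(60):
            f = np.polynomial.polynomial.polyval(od, c) - d
            fp = np.polynomial.polynomial.polyval(od, dc)
            step = f / fp
            od = np.clip(od - step, lo - 0.05, hi + 0.05)
            if np.max(np.abs(step)) < 1e-14:
                break
        return od

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "coeffs": {ch: c.tolist() for ch, c in self.coeffs.items()},
                    "r_squared": self.r_squared,
                    "od_span": {ch: list(v) for ch, v in self.od_span.items()},
                    "dose_range_gy": list(self.dose_range),
                    "selected_channel": self.selected_channel,
                    "monotone": self.monotone,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FilmCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            {ch: np.asarray(c) for ch, c in d["coeffs"].items()},
            d["r_squared"],
            {ch: tuple(v) for ch, v in d["od_span"].items()},
            tuple(d["dose_range_gy"]),
            d["selected_channel"],
            d.get("monotone", {}),
        )


def average_scans(scans: list[FilmScan]) -> FilmScan:
    """Per-pixel arithmetic mean of repeated scans (noise averaging)."""
    if not scans:
        raise ValueError("no scans to average")
    shape = scans[0].pixels.shape
    for s in scans[1:]:
        if s.pixels.shape != shape:
            raise ValueError(f"scan shape mismatch: {s.pixels.shape} vs {shape}")
    mean = np.mean([s.pixels for s in scans], axis=0)
    ids = [i for s in scans for i in s.scan_ids]
    return FilmScan(mean, scans[0].dpi, ids, scans[0].geometry)


def pixel_to_od(scan: FilmScan, reference: tuple[float, float, float]) -> ODImage:
    """OD = log10(reference / pixel) per channel; pixels clipped to >= 1."""
    ref = np.asarray(reference, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference pixel values must be positive")
    pix = np.maximum(scan.pixels, 1.0)
    return ODImage(np.log10(ref / pix), scan.geometry)


def fit_film_calibration(strips: pd.DataFrame) -> FilmCalibration:
    """Least-squares quartic dose-on-OD fit per channel from calibration strips.

    ``strips`` columns: dose_gy, od_r, od_g, od_b.  At least 6 strips are
    required (5 coefficients plus one residual degree of freedom).  The
    selected channel is the one with the largest OD change per Gy over the
    strip range; a fitted curve that is not monotone over the data span is
    flagged and warned about.
    """
    need = {"dose_gy", "od_r", "od_g", "od_b"}
    if not need.issubset(strips.columns):
        raise ValueError(f"strip table must have columns {sorted(need)}")
    dose = np.asarray(strips["dose_gy"], dtype=float)
    if dose.size < 6:
        raise ValueError(f"need >= 6 calibration strips, got {dose.size}")
    coeffs, r2s, spans, mono, gradient = {}, {}, {}, {}, {}
    for ch, col in zip(CHANNELS, ("od_r", "od_g", "od_b")):
        od = np.asarray(strips[col], dtype=float)
        c = np.polynomial.polynomial.polyfit(od, dose, POLY_DEGREE)
        pred = np.polynomial.polynomial.polyval(od, c)
        ss_res = float(np.sum((dose - pred) ** 2))
        ss_tot = float(np.sum((dose - dose.mean()) ** 2))
        span = (float(od.min()), float(od.max()))
        grid = np.linspace(*span, 512)
        deriv = np.polynomial.polynomial.polyval(
            grid, np.polynomial.polynomial.polyder(c)
        )
        is_mono = bool(np.all(deriv >= 0))
        if not is_mono:
            warnings.warn(
                f"fitted dose-OD curve not monotone for channel {ch}", stacklevel=2
            )
        coeffs[ch] = c
        r2s[ch] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        spans[ch] = span
        mono[ch] = is_mono
        gradient[ch] = (od.max() - od.min()) / (dose.max() - dose.min())
    selected = max(CHANNELS, key=lambda ch: gradient[ch])
    return FilmCalibration(
        coeffs,
        r2s,
        spans,
        (float(dose.min()), float(dose.max())),
        selected,
        mono,
    )


def od_to_dose(
    od: ODImage, cal: FilmCalibration, clamp: str = "clamp", channel: str | None = None
) -> DoseGrid:
    """Apply the selected channel's quartic to an OD image -> 2D dose map.

    OD outside the fitted span is clipped (``clamp="clamp"``) or marked
    no-data (``"mark-invalid"``).  The result is a plane DoseGrid (singleton
    third axis) when the OD image carries geometry; otherwise a unit-spacing
    plane at the origin.
    """
    if clamp not in ("clamp", "mark-invalid"):
        raise ValueError(f"unknown clamp policy {clamp!r}")
    ch = channel or cal.selected_channel
    idx = CHANNELS.index(ch)
    vals = od.od[..., idx]
    lo, hi = cal.od_span[ch]
    if clamp == "clamp":
        vals = np.clip(vals, lo, hi)
        dose = cal.dose_of_od(vals, ch)
    else:
        dose = np.where(
            (vals < lo) | (vals > hi), np.nan, cal.dose_of_od(np.clip(vals, lo, hi), ch)
        )
    geom = od.geometry
    if geom is None:
        geom = GridGeometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), dose.shape + (1,))
    return DoseGrid(dose[..., None] if dose.ndim == 2 else dose, geom)


def write_film_tiff(scan: FilmScan, path: str | Path) -> None:
    """Export a scan as 48-bit (3 x 16-bit) RGB TIFF."""
    pix = np.clip(np.rint(scan.pixels), 1, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path), pix, photometric="rgb", resolution=(scan.dpi, scan.dpi)
    )


def read_film_tiff(path: str | Path, dpi: float = 150.0) -> FilmScan:
    pix = tifffile.imread(str(path))
    if pix.ndim != 3 or pix.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB TIFF, got shape {pix.shape}")
    return FilmScan(np.maximum(pix.astype(float), 1.0), dpi, [str(path)])
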
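"""Synthetic phantom: multi-shot plug-modified dose fields and virtual
gel / film measurements of them.

The dose model is deliberately simple, smooth plumbing — not a beam model.
Each shot contributes a separable flat-top profile (an error-function
slit-times-Gaussian penumbra per axis, the standard analytic shape for a
collimated photon profile) whose FWHM equals the nominal collimator size in
X/Y and 1.3x that in Z (the long axis of a multi-source focal spot is
broader).  Tungsten plugging is emulated as an azimuthal wedge about the shot
axis whose transmission multiplies the kernel, with raised-cosine angular
edges and a radial blend to the azimuthal mean near the axis so the field
stays smooth everywhere.  The finished grid is rescaled so that
``prescription_isodose x max = prescription_dose`` (8 Gy at 50% -> 16 Gy
maximum), mirroring how a plan prescription pins the delivered scale.

Virtual measurements add, in order: optional Gaussian blur, a multiplicative
sensitivity factor (the gel's over-response that the analysis removes with
its dose scaling factor), and seeded multiplicative Gaussian noise.  The MR
reader samples S(TE) = S0 exp(-TE * R2(D)) on the CPMG echo train; the film
writer inverts the quartic OD-dose calibration and exposes 16-bit RGB pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, special

from .film import CHANNELS, FilmCalibration, FilmScan
from .gelcal import GelCalibration
from .geometry import DoseGrid, GridGeometry
from .r2 import EchoSeries

__all__ = [
    "ShotSpec",
    "PlanSpec",
    "NoiseSpec",
    "COLLIMATORS_MM",
    "generate_calculated_dose",
    "generate_delivered_dose",
    "evaluate_plan_dose",
    "simulate_measured_dose",
    "simulate_multiecho_series",
    "simulate_film_scan",
    "default_gel_calibration",
    "default_film_calibration",
    "default_calc_geometry",
    "default_gel_geometry",
    "table1_plan",
    "load_plan_yaml",
    "save_plan_yaml",
    "DEFAULT_TE_MS",
]

COLLIMATORS_MM = (4.0, 8.0, 14.0, 18.0)
DEFAULT_TE_MS = 14.0 * np.arange(1, 9)  # 14, 28, ..., 112 ms

# z-axis broadening of the focal spot relative to the in-plane FWHM
_Z_FWHM_FACTOR = 1.3
# penumbra sigma (mm) grows mildly with collimator size
_PENUMBRA_SLOPE = 0.08
_PENUMBRA_BASE = 1.0
# a plug shadow is diffuse: ~200 convergent beams cross-fire the focus, so
# the blocked-sector deficit ramps in smoothly both in azimuth and radius
_WEDGE_EDGE_DEG = 30.0
_WEDGE_BLEND_MM = 8.0


@dataclass(frozen=True)
class ShotSpec:
    """One isocentre: position (Leksell mm), collimator (4/8/14/18 mm),
    relative weight, and plug sectors (azimuth_start_deg, azimuth_end_deg,
    transmission in [0, 1]) about the shot axis."""

    isocenter: tuple[float, float, float]
    collimator: float
    weight: float = 1.0
    plug_sectors: tuple = ()

    def __post_init__(self) -> None:
        if float(self.collimator) not in COLLIMATORS_MM:
            raise ValueError(
                f"collimator must be one of {COLLIMATORS_MM} mm, got {self.collimator}"
            )
        if self.weight < 0:
            raise ValueError("shot weight must be >= 0")
        for a0, a1, t in self.plug_sectors:
            if not (0.0 <= a0 < 360.0 and 0.0 <= a1 <= 360.0):
                raise ValueError(f"sector azimuths must lie in [0, 360), got {(a0, a1)}")
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"sector transmission must be in [0, 1], got {t}")


@dataclass(frozen=True)
class PlanSpec:
    """A multi-shot plan with its prescription.

    The derived maximum dose is prescription_dose / prescription_isodose
    (8 Gy at the 50% isodose -> 16 Gy).  The phantom is a head-sized sphere;
    its bounds are used for validation only, the kernels decay smoothly.
    """

    shots: tuple
    prescription_dose: float = 8.0
    prescription_isodose: float = 0.5
    phantom_radius: float = 80.0
    phantom_center: tuple[float, float, float] = (100.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        if not self.shots:
            raise ValueError("plan must contain at least one shot")
        if not 0.0 < self.prescription_isodose <= 1.0:
            raise ValueError("prescription isodose must be in (0, 1]")
        if self.prescription_dose <= 0:
            raise ValueError("prescription dose must be positive")
        ctr = np.asarray(self.phantom_center)
        for i, s in enumerate(self.shots):
            r = float(np.linalg.norm(np.asarray(s.isocenter) - ctr))
            if r > self.phantom_radius:
                raise ValueError(
                    f"shot {i} isocenter {s.isocenter} lies outside the phantom "
                    f"(r = {r:.1f} mm > {self.phantom_radius} mm)"
                )

    @property
    def max_dose(self) -> float:
        return self.prescription_dose / self.prescription_isodose


@dataclass(frozen=True)
class NoiseSpec:
    """Virtual-measurement imperfections: multiplicative Gaussian dose noise
    (fraction of local dose), Gaussian blur FWHM (mm), and the systematic gel
    sensitivity factor (measured = truth x sensitivity_factor; the analysis
    should recover 1/sensitivity_factor as its scaling factor)."""

    dose_noise_sigma: float = 0.0
    blur_fwhm: float = 0.0
    sensitivity_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_noise_sigma < 0:
            raise ValueError("dose_noise_sigma must be >= 0")
        if self.blur_fwhm < 0:
            raise ValueError("blur_fwhm must be >= 0")
        if self.sensitivity_factor <= 0:
            raise ValueError("sensitivity_factor must be > 0")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _axis_profile(u: np.ndarray, fwhm: float) -> np.ndarray:
    """Flat-top slit convolved with a Gaussian penumbra; half maximum at
    |u| = fwhm/2, peak normalised to 1."""
    half = fwhm / 2.0
    sigma = _PENUMBRA_BASE + _PENUMBRA_SLOPE * fwhm
    s = np.sqrt(2.0) * sigma
    prof = 0.5 * (special.erf((half - u) / s) + special.erf((half + u) / s))
    return prof / special.erf(half / s)


def _wedge_transmission(dx: np.ndarray, dy: np.ndarray, sectors) -> np.ndarray:
    """Azimuthal transmission multiplier with smooth angular edges and a
    radial blend to the azimuthal mean on the shot axis."""
    if not sectors:
        return np.ones(np.broadcast(dx, dy).shape)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    factor = np.ones_like(theta)
    mean_factor = 1.0
    ew = _WEDGE_EDGE_DEG
    for a0, a1, t in sectors:
        width = (a1 - a0) % 360.0
        if width == 0.0 and a1 != a0:
            width = 360.0
        tp = (theta - a0) % 360.0
        member = np.zeros_like(tp)
        for shift in (0.0, 360.0):
            x = tp - shift
            up = _smoothstep((x + ew / 2.0) / ew)
            down = 1.0 - _smoothstep((x - width + ew / 2.0) / ew)
            member = np.maximum(member, up * down)
        factor *= 1.0 - (1.0 - t) * member
        mean_factor *= 1.0 - (1.0 - t) * width / 360.0
    blend = _smoothstep(np.hypot(dx, dy) / _WEDGE_BLEND_MM)
    return mean_factor + blend * (factor - mean_factor)


def evaluate_plan_dose(
    plan: PlanSpec, points_mm: np.ndarray, normalize_to: float | None = None
) -> np.ndarray:
    """Evaluate the (unnormalised, or rescaled to ``normalize_to`` maximum)
    analytic dose field at arbitrary mm points (..., 3)."""
    pts = np.asarray(points_mm, dtype=float)
    out_shape = pts.shape[:-1]
    pts = pts.reshape(-1, 3)
    dose = np.zeros(pts.shape[0])
    for shot in plan.shots:
        d = pts - np.asarray(shot.isocenter)
        kern = (
            _axis_profile(d[:, 0], shot.collimator)
            * _axis_profile(d[:, 1], shot.collimator)
            * _axis_profile(d[:, 2], _Z_FWHM_FACTOR * shot.collimator)
        )
        kern *= _wedge_transmission(d[:, 0], d[:, 1], shot.plug_sectors)
        dose += shot.weight * kern
    if normalize_to is not None:
        peak = dose.max()
        if peak <= 0:
            raise ValueError("plan dose is zero everywhere at the given points")
        dose *= normalize_to / peak
    return dose.reshape(out_shape)


def generate_calculated_dose(
    plan: PlanSpec, geometry: GridGeometry, normalize: bool = True
) -> DoseGrid:
    """Sample the plan's dose field on a grid, rescaled so the grid maximum
    equals prescription_dose / prescription_isodose.

    With ``normalize=False`` the raw superposition is returned; on the raw
    field adding a plug sector can only ever lower dose (the rescale step, by
    design, restores the prescription and may raise open-sector dose, as a
    planning system's prescription normalisation does).
    """
    ext = geometry.extent
    for i, s in enumerate(plan.shots):
        for ax in range(3):
            if not ext[ax][0] <= s.isocenter[ax] <= ext[ax][1]:
                raise ValueError(
                    f"shot {i} isocenter {s.isocenter} outside grid extent on axis {ax}"
                )
    xs, ys, zs = geometry.meshgrid_mm()
    pts = np.stack([xs, ys, zs], axis=-1)
    dose = evaluate_plan_dose(plan, pts)
    meta = {"plan_max_dose_gy": plan.max_dose}
    if normalize:
        peak = dose.max()
        if peak <= 0:
            raise ValueError("plan dose is zero everywhere on the grid")
        scale = plan.max_dose / peak
        dose *= scale
        meta["dose_scale"] = scale
    return DoseGrid(dose, geometry, meta)


def generate_delivered_dose(
    plan: PlanSpec, geometry: GridGeometry, reference: DoseGrid
) -> DoseGrid:
    """Sample the delivered field on a measurement lattice, on the absolute
    scale of an already-normalised reference (TPS-export) grid.

    The delivered field and the planning grid are one continuous field: the
    prescription fixes the scale once, on the planning grid.  Resampling that
    field finely may therefore exceed the reference grid's nominal maximum
    slightly (the coarse lattice misses the true peak), exactly as a physical
    measurement can.
    """
    scale = reference.meta.get("dose_scale")
    if scale is None:
        raise ValueError("reference grid carries no dose scale (not normalised?)")
    xs, ys, zs = geometry.meshgrid_mm()
    pts = np.stack([xs, ys, zs], axis=-1)
    dose = evaluate_plan_dose(plan, pts) * scale
    return DoseGrid(dose, geometry, {"plan_max_dose_gy": plan.max_dose, "dose_scale": scale})


def simulate_measured_dose(
    calc: DoseGrid,
    noise: NoiseSpec,
    target_geometry: GridGeometry | None = None,
) -> DoseGrid:
    """Virtual dosimeter reading of a calculated grid.

    Order of effects: Gaussian blur (FWHM in mm, on the source grid), trilinear
    resampling to the measurement geometry (skipped when identical), the
    multiplicative sensitivity factor, then per-voxel multiplicative Gaussian
    noise seeded from ``noise.seed``.  Doses are clipped at zero.
    """
    if not np.all(np.isfinite(calc.data)):
        raise ValueError("calculated dose must be finite for measurement simulation")
    if np.nanmin(calc.data) < 0:
        raise ValueError("calculated dose must be non-negative")
    data = calc.data
    if noise.blur_fwhm > 0:
        sigma_vox = noise.blur_fwhm / 2.354820045 / np.asarray(calc.geometry.spacing)
        data = ndimage.gaussian_filter(data, sigma_vox, mode="nearest")
    grid = DoseGrid(data, calc.geometry, dict(calc.meta))
    if target_geometry is not None and target_geometry != calc.geometry:
        from .geometry import resample

        grid = resample(grid, target_geometry)
    out = grid.data * noise.sensitivity_factor
    if noise.dose_noise_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        out = out * (1.0 + noise.dose_noise_sigma * rng.standard_normal(out.shape))
    out = np.clip(out, 0.0, None)
    meta = dict(grid.meta)
    meta.update(noise_seed=noise.seed, sensitivity_factor=noise.sensitivity_factor)
    return DoseGrid(out, grid.geometry, meta)


def simulate_multiecho_series(
    dose: DoseGrid,
    cal: GelCalibration,
    te_ms: np.ndarray | None = None,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> EchoSeries:
    """CPMG echo stack of an irradiated gel: S(TE) = S0 exp(-TE R2(D)).

    ``noise_sigma`` is Gaussian noise in units of S0 added per echo sample.
    The default echo train is the 8-echo, 14 ms-increment acquisition.
    """
    te = DEFAULT_TE_MS if te_ms is None else np.asarray(te_ms, dtype=float)
    if te.size == 0:
        raise ValueError("echo time list must not be empty")
    if np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be positive and strictly increasing")
    r2 = cal.r2_of_dose(dose.data)  # s^-1, linear response
    te_s = te / 1000.0
    signal = s0 * np.exp(-r2[..., None] * te_s)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sigma * s0 * rng.standard_normal(signal.shape)
    signal = np.clip(signal, 0.0, None)
    return EchoSeries(signal, te, dose.geometry, {"s0": s0, "seed": seed})


def simulate_film_scan(
    dose_plane: DoseGrid,
    cal: FilmCalibration,
    scan_noise_sigma: float = 0.0,
    seed: int = 0,
    reference: tuple[float, float, float] = (55000.0, 55000.0, 55000.0),
) -> FilmScan:
    """Virtual flatbed scan of an exposed film: dose -> per-channel OD via the
    inverted quartic calibration -> pixel = reference x 10^-OD, plus additive
    Gaussian scanner noise (in counts).  Doses above the calibrated range are
    an error; the film saturates there in reality."""
    data = np.squeeze(dose_plane.data)
    if data.ndim != 2:
        raise ValueError("film simulation needs a plane (one singleton axis)")
    if np.nanmax(data) > cal.dose_range[1] + 1e-9:
        raise ValueError(
            f"dose {np.nanmax(data):.2f} Gy exceeds the calibrated film range "
            f"{cal.dose_range} Gy"
        )
    rng = np.random.default_rng(seed)
    chans = []
    for ch in CHANNELS:
        od = cal.od_of_dose(np.nan_to_num(data, nan=0.0), ch)
        pix = np.asarray(reference)[CHANNELS.index(ch)] * 10.0 ** (-od)
        chans.append(pix)
    pixels = np.stack(chans, axis=-1)
    if scan_noise_sigma > 0:
        pixels = pixels + scan_noise_sigma * rng.standard_normal(pixels.shape)
    pixels = np.clip(pixels, 1.0, 65535.0)
    # dpi consistent with the in-plane sampling of the dose plane
    in_plane = [s for s, n in zip(dose_plane.geometry.spacing, dose_plane.geometry.shape) if n > 1]
    dpi = 25.4 / in_plane[0] if in_plane else 150.0
    return FilmScan(pixels, dpi, [f"seed={seed}"], dose_plane.geometry)


# ---------------------------------------------------------------------------
# Default study fixtures


def default_gel_calibration() -> GelCalibration:
    """Linear R2-dose response spanning the observed gel range: R2 = 1.65 s^-1
    unirradiated rising to 83 s^-1 at 17 Gy."""
    slope = (83.0 - 1.65) / 17.0
    return GelCalibration(slope=slope, intercept=1.65, dose_range=(0.0, 17.0))


def default_film_calibration() -> FilmCalibration:
    """Synthetic EBT2-like response over 0-10 Gy.

    Dose is an exactly quartic, monotone function of net OD per channel
    (superlinear in OD, i.e. the OD-dose curve saturates), with the red
    channel spanning twice the OD range of green and four times blue.
    """
    od_max = {"red": 0.60, "green": 0.30, "blue": 0.15}
    shape = (0.55, 0.15, 0.15, 0.15)  # sums to 1 -> dose(od_max) = 10 Gy
    coeffs, spans = {}, {}
    for ch, om in od_max.items():
        c = np.zeros(5)
        for k, s in enumerate(shape, start=1):
            c[k] = 10.0 * s / om**k
        coeffs[ch] = c
        spans[ch] = (0.0, om)
    return FilmCalibration(
        coeffs,
        {ch: 1.0 for ch in CHANNELS},
        spans,
        (0.0, 10.0),
        "red",
        {ch: True for ch in CHANNELS},
    )


def default_calc_geometry(spacing: float = 2.5) -> GridGeometry:
    """TPS-export-like grid covering the treated region of the phantom."""
    n = int(round(140.0 / spacing)) + 1
    return GridGeometry((30.0, 30.0, 30.0), (spacing,) * 3, (n, n, n))


def default_gel_geometry() -> GridGeometry:
    """MR readout lattice: 0.5 x 0.5 mm in-plane, 2 mm slices, covering the
    analysis subvolume with margin."""
    return GridGeometry((60.0, 55.0, 84.0), (0.5, 0.5, 2.0), (131, 161, 19))


_PLAN_FILE = "table1_plan.yaml"


def table1_plan() -> PlanSpec:
    """The shipped three-shot plug plan fixture (18/14/8 mm collimators,
    prescription 8 Gy to the 50% isodose)."""
    with resources.files("gammagel.data").joinpath(_PLAN_FILE).open() as fh:
        return _plan_from_dict(yaml.safe_load(fh))


def _plan_from_dict(d: dict) -> PlanSpec:
    shots = tuple(
        ShotSpec(
            tuple(s["isocenter_mm"]),
            float(s["collimator_mm"]),
            float(s.get("weight", 1.0)),
            tuple(
                (float(p["azimuth_start_deg"]), float(p["azimuth_end_deg"]), float(p["transmission"]))
                for p in s.get("plug_sectors", [])
            ),
        )
        for s in d["shots"]
    )
    return PlanSpec(
        shots,
        float(d.get("prescription_dose_gy", 8.0)),
        float(d.get("prescription_isodose", 0.5)),
        float(d.get("phantom_radius_mm", 80.0)),
        tuple(d.get("phantom_center_mm", (100.0, 100.0, 100.0))),
    )


def load_plan_yaml(path: str | Path) -> PlanSpec:
    with open(path) as fh:
        return _plan_from_dict(yaml.safe_load(fh))


def save_plan_yaml(plan: PlanSpec, path: str | Path) -> None:
    d = {
        "prescription_dose_gy": plan.prescription_dose,
        "prescription_isodose": plan.prescription_isodose,
        "phantom_radius_mm": plan.phantom_radius,
        "phantom_center_mm": list(plan.phantom_center),
        "shots": [
            {
                "isocenter_mm": list(s.isocenter),
                "collimator_mm": s.collimator,
                "weight": s.weight,
                "plug_sectors": [
                    {
                        "azimuth_start_deg": a0,
                        "azimuth_end_deg": a1,
                        "transmission": t,
                    }
                    for a0, a1, t in s.plug_sectors
                ],
            }
            for s in plan.shots
        ],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
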
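"""Readers/writers and the end-to-end verification pipeline.

Dose grids travel as DICOM RT Dose at the boundary (GridFrameOffsetVector and
DoseGridScaling honoured) and as a lossless internal pair — a compressed
``.npz`` array next to a JSON geometry sidecar — between stages.  The
``run_pipeline`` orchestrator ties the whole study together: simulate the
plug plan, virtually measure it with gel (multi-echo MR -> R2 -> dose ->
scaling) and film, resample everything to a common 1 mm grid over the
analysis subvolume, and produce the comparison report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import compare as cmp
from .film import average_scans, fit_film_calibration, od_to_dose, pixel_to_od
from .gelcal import GelCalibration, apply_scaling, derive_scaling_factor, r2_to_dose
from .geometry import Box, DoseGrid, GridGeometry, extract_plane, resample
from .phantom import (
    NoiseSpec,
    PlanSpec,
    default_film_calibration,
    default_gel_calibration,
    default_gel_geometry,
    default_calc_geometry,
    generate_calculated_dose,
    generate_delivered_dose,
    simulate_film_scan,
    simulate_measured_dose,
    simulate_multiecho_series,
    table1_plan,
)
from .r2 import fit_r2_map

__all__ = [
    "read_rtdose",
    "write_rtdose",
    "read_sidecar",
    "write_sidecar",
    "RunConfig",
    "ComparisonReport",
    "run_pipeline",
    "DEFAULT_CRITERIA",
    "ANALYSIS_SUBVOLUME",
]

log = logging.getLogger("gammagel")

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"

# the five tolerance criteria of the verification study: (dose %, DTA mm)
DEFAULT_CRITERIA = [(3.0, 2.0), (3.0, 1.0), (2.0, 2.0), (1.0, 1.0), (0.5, 0.5)]
# analysis subvolume around the three shots, inclusive mm bounds
ANALYSIS_SUBVOLUME = Box((70.0, 65.0, 90.0), (115.0, 125.0, 114.0))


# ---------------------------------------------------------------------------
# DICOM RT Dose


def write_rtdose(grid: DoseGrid, path: str | Path) -> None:
    """Write a dose grid as DICOM RT Dose (GY, 32-bit, explicit VR).

    Dose is quantised by DoseGridScaling = max/(2^32 - 1); no-data voxels are
    stored as zero (DICOM RT Dose has no mask concept).
    """
    data = np.nan_to_num(grid.data, nan=0.0)
    if data.min() < 0:
        raise ValueError("RT Dose cannot store negative dose")
    scaling = max(float(data.max()), 1e-12) / (2**32 - 1)
    pixels = np.rint(data / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    nx, ny, nz = grid.geometry.shape
    ds.Columns = nx
    ds.Rows = ny
    ds.NumberOfFrames = nz
    ds.ImagePositionPatient = list(grid.geometry.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid.geometry.spacing[1], grid.geometry.spacing[0]]  # row, col
    ds.GridFrameOffsetVector = [
        grid.geometry.spacing[2] * k for k in range(nz)
    ]
    ds.DoseGridScaling = scaling
    # DICOM frame layout: (frame=z, row=y, col=x)
    ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose file into the internal mm frame."""
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001 - structured error, no partial grid
        raise ValueError(f"cannot parse DICOM file {path}: {exc}") from exc
    for tag in ("ImagePositionPatient", "PixelSpacing", "GridFrameOffsetVector",
                "DoseGridScaling", "Rows", "Columns"):
        if getattr(ds, tag, None) is None:
            raise ValueError(f"RT Dose file {path} missing required tag {tag}")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0]):
            raise ValueError("non-uniform GridFrameOffsetVector is unsupported")
        dz = float(dz[0])
    else:
        dz = 1.0
    geom = GridGeometry(
        tuple(float(v) for v in ds.ImagePositionPatient),
        (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz),
        (int(ds.Columns), int(ds.Rows), int(offsets.size)),
    )
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return DoseGrid(arr.transpose(2, 1, 0), geom)


# ---------------------------------------------------------------------------
# Lossless sidecar format


def write_sidecar(grid: DoseGrid, basepath: str | Path) -> None:
    """Write ``<base>.npz`` (float64 array, lossless) + ``<base>.json``
    geometry/provenance sidecar."""
    base = Path(basepath)
    np.savez_compressed(base.with_suffix(".npz"), data=grid.data)
    meta = {"geometry": grid.geometry.to_dict(), "meta": _jsonable(grid.meta)}
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_sidecar(basepath: str | Path) -> DoseGrid:
    base = Path(basepath)
    d = json.loads(base.with_suffix(".json").read_text())
    data = np.load(base.with_suffix(".npz"))["data"]
    return DoseGrid(data, GridGeometry.from_dict(d["geometry"]), d.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunConfig:
    """Everything a verification run needs; defaults reproduce the three-shot
    plug-plan study conditions."""

    plan: PlanSpec | None = None
    calc_geometry: GridGeometry | None = None
    gel_geometry: GridGeometry | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    gel_cal: GelCalibration | None = None
    criteria: list = field(default_factory=lambda: list(DEFAULT_CRITERIA))
    subvolume: Box = ANALYSIS_SUBVOLUME
    common_spacing_mm: float = 1.0
    scaling: str | float = "auto"
    mr_noise_sigma: float = 0.0  # fraction of S0
    mr_s0: float = 1000.0
    film: bool = False
    film_plane_z_mm: float = 101.0
    film_prescription_dose: float = 2.0
    film_scan_noise: float = 150.0  # counts
    film_n_scans: int = 5
    seed: int = 0
    outdir: Path | None = None

    def resolved(self) -> "RunConfig":
        cfg = RunConfig(**{**self.__dict__})
        cfg.plan = cfg.plan or table1_plan()
        cfg.calc_geometry = cfg.calc_geometry or default_calc_geometry()
        cfg.gel_geometry = cfg.gel_geometry or default_gel_geometry()
        cfg.gel_cal = cfg.gel_cal or default_gel_calibration()
        return cfg

    def digest(self) -> str:
        raw = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(raw.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Bundle of measured-vs-calculated products for one verification run."""

    pass_rates: pd.DataFrame
    scaling_factor: float
    gamma_maps: dict
    dvh_measured: cmp.DVH
    dvh_calculated: cmp.DVH
    dddvh: tuple
    d4: cmp.D4Bins
    profiles: dict
    contours: dict
    normalization_dose: float
    film_pass_rates: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def _common_grid(box: Box, spacing: float) -> GridGeometry:
    shape = tuple(
        int(np.floor((box.hi[i] - box.lo[i]) / spacing + 1e-9)) + 1 for i in range(3)
    )
    return GridGeometry(box.lo, (spacing,) * 3, shape)


def _uniform_region(plan: PlanSpec, half_width_mm: float = 5.0) -> Box:
    """Flattest dose plateau available: a small box centred on the largest
    shot (the interior of its high-isodose core)."""
    big = max(plan.shots, key=lambda s: s.collimator)
    c = np.asarray(big.isocenter)
    return Box(tuple(c - half_width_mm), tuple(c + half_width_mm))


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Simulate, measure, analyse and compare; deterministic given the seed.

    Stages: plan -> calculated grid; analytic truth at gel resolution ->
    virtual gel measurement (blur/sensitivity/noise) -> CPMG echoes -> R2 map
    -> calibration -> dose -> scaling factor -> common 1 mm grid -> gamma /
    DVH / DDDVH / D4 / profiles / contours.  Optionally the film branch on an
    axial plane.  Writes a report bundle when ``config.outdir`` is set.
    """
    cfg = config.resolved()
    rng_seed = int(cfg.seed)

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        calc = generate_calculated_dose(cfg.plan, cfg.calc_geometry)
        truth_gel = generate_delivered_dose(cfg.plan, cfg.gel_geometry, calc)
        noise = NoiseSpec(
            cfg.noise.dose_noise_sigma,
            cfg.noise.blur_fwhm,
            cfg.noise.sensitivity_factor,
            seed=rng_seed,
        )
        measured_true = simulate_measured_dose(truth_gel, noise)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        stage("r2map")
        series = simulate_multiecho_series(
            measured_true,
            cfg.gel_cal,
            s0=cfg.mr_s0,
            noise_sigma=cfg.mr_noise_sigma,
            seed=rng_seed + 1,
        )
        r2map = fit_r2_map(series)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'r2map' failed: {exc}") from exc

    try:
        stage("convert")
        measured_gel = r2_to_dose(r2map, cfg.gel_cal, clamp="extrapolate")
        if cfg.scaling == "auto":
            factor = derive_scaling_factor(measured_gel, calc, _uniform_region(cfg.plan))
        else:
            factor = float(cfg.scaling)
        measured_gel = apply_scaling(measured_gel, factor)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'convert' failed: {exc}") from exc

    try:
        stage("resample")
        common = _common_grid(cfg.subvolume, cfg.common_spacing_mm)
        m_common = resample(measured_gel, common)
        c_common = resample(calc, common)
        n_nodata = int((~(m_common.valid & c_common.valid)).sum())
        log.info("common grid %s voxels, %d no-data", common.shape, n_nodata)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'resample' failed: {exc}") from exc

    try:
        stage("compare")
        norm = cfg.plan.max_dose
        rates = cmp.pass_rate_table(c_common, m_common, cfg.criteria, norm)
        gamma_maps = {}
        for (tol, dta), row in zip(cfg.criteria, rates.itertuples()):
            if (tol, dta) == (2.0, 2.0):
                gamma_maps["2%/2 mm"] = cmp.gamma_index(
                    c_common, m_common, cmp.GammaParams(tol, dta, norm)
                )
        dvh_m = cmp.dvh(m_common, norm)
        dvh_c = cmp.dvh(c_common, norm)
        ddd = cmp.dddvh(m_common, c_common, norm)
        d4 = cmp.d4_diagram(m_common, c_common, norm)
        z0 = cfg.film_plane_z_mm
        profiles = {
            "horizontal": cmp.line_profile(c_common, (70.0, 95.0, z0), (115.0, 95.0, z0)),
            "horizontal_measured": cmp.line_profile(
                m_common, (70.0, 95.0, z0), (115.0, 95.0, z0)
            ),
            "vertical": cmp.line_profile(c_common, (92.0, 65.0, z0), (92.0, 125.0, z0)),
            "vertical_measured": cmp.line_profile(
                m_common, (92.0, 65.0, z0), (92.0, 125.0, z0)
            ),
        }
        plane_c = extract_plane(c_common, "Z", z0)
        plane_m = extract_plane(m_common, "Z", z0)
        levels = [cmp.relative_to_absolute(p, norm) for p in (5, 26, 50, 70, 90)]
        contours = {
            "calculated": cmp.isodose_contours(plane_c, levels),
            "measured": cmp.isodose_contours(plane_m, levels),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'compare' failed: {exc}") from exc

    film_rates = None
    if cfg.film:
        try:
            stage("film")
            film_rates = _film_branch(cfg, rng_seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'film' failed: {exc}") from exc

    summary = {
        "seed": rng_seed,
        "config_digest": cfg.digest(),
        "scaling_factor": factor,
        "normalization_dose_gy": norm,
        "max_calculated_dose_gy": calc.max(),
        "common_grid_shape": list(common.shape),
        "evaluated_voxels": int(rates["evaluated_voxels"].iloc[0]),
        "pass_rates_pct": {
            row.criterion: row.pass_rate_pct for row in rates.itertuples()
        },
    }
    if film_rates is not None:
        summary["film_pass_rates_pct"] = {
            row.criterion: row.pass_rate_pct for row in film_rates.itertuples()
        }

    report = ComparisonReport(
        rates, factor, gamma_maps, dvh_m, dvh_c, ddd, d4, profiles, contours,
        norm, film_rates, summary,
    )
    if cfg.outdir is not None:
        _write_bundle(report, cfg)
    return report


def _film_branch(cfg: RunConfig, seed: int) -> pd.DataFrame:
    """2D film verification on the axial plane: same plan, film prescription
    (2 Gy at 50% -> 4 Gy max), five averaged scans, red-channel dose map."""
    film_plan = PlanSpec(
        cfg.plan.shots,
        cfg.film_prescription_dose,
        cfg.plan.prescription_isodose,
        cfg.plan.phantom_radius,
        cfg.plan.phantom_center,
    )
    z0 = cfg.film_plane_z_mm
    lo, hi = cfg.subvolume.lo, cfg.subvolume.hi
    plane_geom = GridGeometry(
        (lo[0] - 5.0, lo[1] - 5.0, z0),
        (0.5, 0.5, 1.0),
        (int((hi[0] - lo[0] + 10) / 0.5) + 1, int((hi[1] - lo[1] + 10) / 0.5) + 1, 1),
    )
    calc_plane_src = generate_calculated_dose(film_plan, cfg.calc_geometry)
    truth_plane = generate_delivered_dose(film_plan, plane_geom, calc_plane_src)
    film_cal_model = default_film_calibration()
    scans = [
        simulate_film_scan(truth_plane, film_cal_model, cfg.film_scan_noise, seed + 10 + k)
        for k in range(cfg.film_n_scans)
    ]
    avg = average_scans(scans)
    od = pixel_to_od(avg, (55000.0, 55000.0, 55000.0))
    # analysis-side calibration fitted from synthetic strips of the same model
    doses = np.linspace(0.0, 10.0, 11)
    strips = pd.DataFrame(
        {
            "dose_gy": doses,
            "od_r": film_cal_model.od_of_dose(doses, "red"),
            "od_g": film_cal_model.od_of_dose(doses, "green"),
            "od_b": film_cal_model.od_of_dose(doses, "blue"),
        }
    )
    film_cal = fit_film_calibration(strips)
    measured_plane = od_to_dose(od, film_cal)

    box = Box((lo[0], lo[1], z0), (hi[0], hi[1], z0))
    common = _common_grid(box, cfg.common_spacing_mm)
    m1 = resample(measured_plane, common)
    c1 = resample(calc_plane_src, common)
    return cmp.pass_rate_table(c1, m1, cfg.criteria, film_plan.max_dose)


def _write_bundle(report: ComparisonReport, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.pass_rates.to_csv(out / "pass_rates.csv", index=False)
    if report.film_pass_rates is not None:
        report.film_pass_rates.to_csv(out / "film_pass_rates.csv", index=False)
    # the two DVHs may span different top levels; pad the shorter with zeros
    lev_m, lev_c = report.dvh_measured.dose_pct, report.dvh_calculated.dose_pct
    levels = lev_m if lev_m.size >= lev_c.size else lev_c

    def _pad(v):
        return np.pad(v, (0, levels.size - v.size))

    pd.DataFrame(
        {
            "dose_pct": levels,
            "volume_measured_pct": _pad(report.dvh_measured.volume_pct),
            "volume_calculated_pct": _pad(report.dvh_calculated.volume_pct),
        }
    ).to_csv(out / "dvh.csv", index=False)
    edges, vals = report.dddvh
    pd.DataFrame({"bin_lo_pct": edges[:-1], "bin_hi_pct": edges[1:], "value": vals}).to_csv(
        out / "dddvh.csv", index=False
    )
    pd.DataFrame(
        {
            "bin_center_pct": report.d4.bin_centers_pct,
            "mean_diff_pct": report.d4.mean_diff_pct,
            "sd_diff_pct": report.d4.sd_diff_pct,
            "n": report.d4.n,
        }
    ).to_csv(out / "d4.csv", index=False)
    contours_json = {
        side: {f"{lev:g}": [p.tolist() for p in polys] for lev, polys in levels.items()}
        for side, levels in report.contours.items()
    }
    (out / "contours.json").write_text(json.dumps(contours_json))
    (out / "summary.json").write_text(json.dumps(_jsonable(report.summary), indent=2))
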
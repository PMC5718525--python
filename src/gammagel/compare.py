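"""Measured-vs-calculated dose comparison statistics.

The central tool is the gamma index (Low's dose-difference / distance-to-
agreement composite): for an evaluated point r_m with dose D_m, against a
reference distribution D_c,

    gamma(r_m) = min over r_c of sqrt( |r_c - r_m|^2 / dta^2
                                     + (D_c(r_c) - D_m(r_m))^2 / dD^2 )

with dD = dose_tol% of the (global) normalisation dose.  A voxel passes when
gamma <= 1.  The minimisation samples the reference on a lattice of step
``interp_step`` (trilinear interpolation) out to ``search_radius``; offsets
are visited in order of increasing distance and a voxel leaves the search as
soon as the pure distance term exceeds its current best gamma^2, which is
exact (the dose term is non-negative) and makes the search fast without
changing any value relative to an exhaustive scan of the same lattice.

The module also provides dose difference maps, cumulative DVHs, the
difference of differential DVHs (DDDVH), the dose-dependent-dose-difference
(D4) diagram, arbitrary line profiles and marching-squares isodose contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .geometry import DoseGrid, sample_at

__all__ = [
    "GammaParams",
    "GammaMap",
    "DVH",
    "D4Bins",
    "Profile",
    "dose_difference",
    "gamma_index",
    "pass_rate_table",
    "dvh",
    "dddvh",
    "d4_diagram",
    "line_profile",
    "isodose_contours",
    "relative_to_absolute",
]


@dataclass(frozen=True)
class GammaParams:
    """Gamma criterion: dose_tol in % of normalization_dose (global), dta in
    mm, search radius and reference sampling step in mm."""

    dose_tol: float
    dta: float
    normalization_dose: float
    search_radius: float | None = None
    interp_step: float | None = None
    low_dose_cutoff: float | None = None  # % of normalization; None = keep all

    def __post_init__(self) -> None:
        if self.dose_tol <= 0 or self.dta <= 0:
            raise ValueError("dose_tol and dta must be positive")
        if self.normalization_dose <= 0:
            raise ValueError("normalization_dose must be positive")
        if self.search_radius is None:
            object.__setattr__(self, "search_radius", 3.0 * self.dta)
        if self.interp_step is None:
            object.__setattr__(self, "interp_step", self.dta / 10.0)
        if self.search_radius < self.dta:
            raise ValueError("search_radius must be >= dta")
        if self.interp_step > self.dta / 5.0 + 1e-12:
            raise ValueError("interp_step must be <= dta/5")


@dataclass
class GammaMap:
    """Per-voxel gamma values (NaN where not evaluated), the criterion, the
    pass rate (% of evaluated voxels with gamma <= 1) and a saturation mask
    for voxels whose minimum lay on the search-sphere boundary."""

    gamma: np.ndarray
    params: GammaParams
    pass_rate: float
    evaluated_count: int
    saturated: np.ndarray
    geometry: object = None


@dataclass
class DVH:
    """Cumulative dose-volume histogram: volume(%) with dose >= level, levels
    in % of the normalisation dose."""

    dose_pct: np.ndarray
    volume_pct: np.ndarray
    normalization_dose: float


@dataclass
class D4Bins:
    """Dose-dependent dose-difference summary: per calculated-dose bin
    (centres in % of normalisation), mean and SD of the percent difference
    100 (measured - calculated) / calculated, and the voxel count."""

    bin_centers_pct: np.ndarray
    mean_diff_pct: np.ndarray
    sd_diff_pct: np.ndarray
    n: np.ndarray
    excluded_zero_dose: int = 0


@dataclass
class Profile:
    distance_mm: np.ndarray
    points_mm: np.ndarray
    dose: np.ndarray


def dose_difference(measured: DoseGrid, calculated: DoseGrid) -> DoseGrid:
    """measured - calculated on a common geometry; no-data propagates."""
    if measured.geometry != calculated.geometry:
        raise ValueError("dose difference requires a common geometry")
    return DoseGrid(measured.data - calculated.data, measured.geometry)


def _offset_lattice(params: GammaParams) -> np.ndarray:
    """Sampling offsets (mm) inside the search sphere, sorted by distance,
    the zero offset first.  Membership is decided on integer step counts
    (i^2 + j^2 + k^2 <= (radius/step)^2) so it is reproducible exactly."""
    step = params.interp_step
    rho2 = (params.search_radius / step) ** 2 + 1e-9
    nmax = int(np.floor(np.sqrt(rho2)))
    ax = np.arange(-nmax, nmax + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    ints = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    n2 = np.einsum("ij,ij->i", ints, ints)
    keep = n2 <= rho2
    ints, n2 = ints[keep], n2[keep]
    order = np.argsort(n2, kind="stable")
    return ints[order] * step


def gamma_index(
    calculated: DoseGrid,
    measured: DoseGrid,
    params: GammaParams,
    chunk: int = 32,
) -> GammaMap:
    """Gamma map of the evaluated (measured) grid against the reference
    (calculated) grid on a common geometry.

    Voxels where either grid is no-data are not evaluated; an optional low
    dose cutoff (on the calculated dose) further restricts the evaluated set.
    Reference samples falling outside the grid support are skipped.  Voxels
    whose best gamma would only improve beyond the search sphere are capped
    at the boundary value and flagged saturated.
    """
    if measured.geometry != calculated.geometry:
        raise ValueError("gamma evaluation requires a common geometry")
    geom = measured.geometry
    tol_gy = params.dose_tol / 100.0 * params.normalization_dose
    dta2 = params.dta**2

    evalmask = measured.valid & calculated.valid
    if params.low_dose_cutoff is not None:
        evalmask &= calculated.data >= params.low_dose_cutoff / 100.0 * params.normalization_dose
    n_eval = int(evalmask.sum())
    if n_eval == 0:
        raise ValueError("no voxels to evaluate")

    idx = np.argwhere(evalmask).astype(float)  # voxel indices of evaluated pts
    d_m = measured.data[evalmask]
    spacing = np.asarray(geom.spacing)
    shape_f = np.asarray(geom.shape, dtype=float) - 1.0

    offsets = _offset_lattice(params)
    r2 = np.einsum("ij,ij->i", offsets, offsets)

    # zero offset: pure dose difference
    best = ((calculated.data[evalmask] - d_m) / tol_gy) ** 2
    active = np.arange(n_eval)

    ref = np.ascontiguousarray(calculated.data)
    pos = 1  # offsets[0] is the zero offset
    while pos < len(offsets) and active.size:
        hi = min(pos + chunk, len(offsets))
        # exact pruning: the distance term alone already exceeds best
        dist_floor = r2[pos] / dta2
        keep = best[active] > dist_floor
        active = active[keep]
        if active.size == 0:
            break
        block = offsets[pos:hi]
        coords = idx[active][None, :, :] + (block / spacing)[:, None, :]
        flat = coords.reshape(-1, 3)
        inside = np.all((flat >= 0.0) & (flat <= shape_f), axis=1)
        vals = np.full(flat.shape[0], np.nan)
        if inside.any():
            vals[inside] = ndimage.map_coordinates(
                ref, flat[inside].T, order=1, mode="nearest", prefilter=False
            )
        vals = vals.reshape(len(block), active.size)
        g2 = (r2[pos:hi, None] / dta2) + ((vals - d_m[active][None, :]) / tol_gy) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        g2min = g2.min(axis=0)
        improved = g2min < best[active]
        best[active[improved]] = g2min[improved]
        pos = hi

    gamma_vals = np.sqrt(best)
    boundary = params.search_radius / params.dta
    sat_flat = gamma_vals >= boundary - 1e-12
    gamma_vals = np.minimum(gamma_vals, boundary)

    gamma = np.full(geom.shape, np.nan)
    gamma[evalmask] = gamma_vals
    saturated = np.zeros(geom.shape, dtype=bool)
    saturated[evalmask] = sat_flat
    pass_rate = 100.0 * float(np.count_nonzero(gamma_vals <= 1.0)) / n_eval
    return GammaMap(gamma, params, pass_rate, n_eval, saturated, geom)


def pass_rate_table(
    calculated: DoseGrid,
    measured: DoseGrid,
    criteria: list[tuple[float, float]],
    normalization_dose: float | None = None,
    low_dose_cutoff: float | None = None,
) -> pd.DataFrame:
    """Gamma pass rates for a list of (dose_tol %, dta mm) criteria on the
    same voxel set.  Normalisation defaults to the calculated grid maximum."""
    norm = normalization_dose or calculated.max()
    rows = []
    for dose_tol, dta in criteria:
        gm = gamma_index(
            calculated,
            measured,
            GammaParams(dose_tol, dta, norm, low_dose_cutoff=low_dose_cutoff),
        )
        rows.append(
            {
                "dose_tol_pct": dose_tol,
                "dta_mm": dta,
                "criterion": f"{dose_tol:g}%/{dta:g} mm",
                "pass_rate_pct": gm.pass_rate,
                "evaluated_voxels": gm.evaluated_count,
            }
        )
    return pd.DataFrame(rows)


def dvh(
    dose: DoseGrid, normalization: float, bin_width_pct: float = 1.0
) -> DVH:
    """Cumulative DVH over the valid voxels: % volume receiving at least each
    dose level, levels in % of ``normalization``."""
    vals = dose.data[dose.valid]
    if vals.size == 0:
        raise ValueError("no valid voxels for DVH")
    pct = 100.0 * vals / normalization
    top = max(100.0, float(pct.max()))
    levels = np.arange(0.0, top + bin_width_pct, bin_width_pct)
    sorted_pct = np.sort(pct)
    n_below = np.searchsorted(sorted_pct, levels, side="left")
    volume = 100.0 * (vals.size - n_below) / vals.size
    return DVH(levels, volume, normalization)


def dddvh(
    measured: DoseGrid,
    calculated: DoseGrid,
    normalization: float,
    bin_width_pct: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference of differential DVHs, normalised by the total voxel count.

    Per dose bin: (n_measured - n_calculated) / N_total over the common valid
    voxel set; a bin value of 0.01 means the measured histogram holds 1% of
    all voxels more than the calculated one in that bin.  Bins span both
    distributions, so the values sum to zero exactly.  Returns (bin_edges_pct,
    values).
    """
    if measured.geometry != calculated.geometry:
        raise ValueError("DDDVH requires a common geometry")
    mask = measured.valid & calculated.valid
    m = 100.0 * measured.data[mask] / normalization
    c = 100.0 * calculated.data[mask] / normalization
    if m.size != c.size or m.size == 0:
        raise ValueError("DDDVH requires a non-empty common voxel set")
    top = max(m.max(), c.max(), 100.0)
    edges = np.arange(0.0, top + 2 * bin_width_pct, bin_width_pct)
    hm, _ = np.histogram(m, bins=edges)
    hc, _ = np.histogram(c, bins=edges)
    return edges, (hm - hc) / m.size


def d4_diagram(
    measured: DoseGrid,
    calculated: DoseGrid,
    normalization: float,
    bin_width_pct: float = 5.0,
    denominator: str = "local",
) -> D4Bins:
    """Mean +/- SD of the percent dose difference, binned by calculated dose.

    The percent difference uses the local calculated dose as denominator by
    default (``denominator="global"`` divides by the normalisation dose
    instead); voxels with zero calculated dose are excluded and counted.
    """
    if measured.geometry != calculated.geometry:
        raise ValueError("D4 diagram requires a common geometry")
    mask = measured.valid & calculated.valid
    m, c = measured.data[mask], calculated.data[mask]
    zero = c == 0.0
    excluded = int(zero.sum())
    m, c = m[~zero], c[~zero]
    if denominator == "local":
        diff_pct = 100.0 * (m - c) / c
    elif denominator == "global":
        diff_pct = 100.0 * (m - c) / normalization
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    level = 100.0 * c / normalization
    bins = np.floor(level / bin_width_pct).astype(int)
    uniq = np.unique(bins)
    centers, means, sds, ns = [], [], [], []
    for b in uniq:
        sel = bins == b
        centers.append((b + 0.5) * bin_width_pct)
        means.append(float(diff_pct[sel].mean()))
        sds.append(float(diff_pct[sel].std()))
        ns.append(int(sel.sum()))
    return D4Bins(
        np.asarray(centers), np.asarray(means), np.asarray(sds), np.asarray(ns), excluded
    )


def line_profile(
    grid: DoseGrid, start_mm, end_mm, step_mm: float = 0.5
) -> Profile:
    """Trilinear dose samples along a segment, at ``step_mm`` spacing."""
    p0 = np.asarray(start_mm, dtype=float)
    p1 = np.asarray(end_mm, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.floor(length / step_mm)) + 1, 2)
    t = np.linspace(0.0, length, n)
    pts = p0 + (p1 - p0) * (t / length)[:, None] if length > 0 else np.tile(p0, (n, 1))
    return Profile(t, pts, sample_at(grid, pts))


def isodose_contours(
    plane: DoseGrid, levels: list[float]
) -> dict[float, list[np.ndarray]]:
    """Marching-squares contours of a plane grid at the given dose levels
    (Gy), returned as (N, 2) polylines in mm of the two in-plane axes."""
    shape = plane.geometry.shape
    flat_axes = [i for i, n in enumerate(shape) if n == 1]
    if len(flat_axes) != 1:
        raise ValueError("isodose contours need a plane (exactly one singleton axis)")
    axis = flat_axes[0]
    in_plane = [i for i in range(3) if i != axis]
    data2d = np.squeeze(plane.data, axis=axis)
    out: dict[float, list[np.ndarray]] = {}
    for lev in levels:
        polys = []
        if np.nanmin(data2d) <= lev <= np.nanmax(data2d):
            for contour in skmeasure.find_contours(data2d, lev):
                mm = np.empty_like(contour)
                for k, ax in enumerate(in_plane):
                    mm[:, k] = (
                        plane.geometry.origin[ax]
                        + contour[:, k] * plane.geometry.spacing[ax]
                    )
                polys.append(mm)
        out[float(lev)] = polys
    return out


def relative_to_absolute(percent: float, normalization: float) -> float:
    """Convert a relative isodose level (%) to absolute dose (Gy)."""
    if normalization <= 0:
        raise ValueError("normalization dose must be positive")
    return percent / 100.0 * normalization
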
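"""Per-voxel spin-spin relaxation rate (R2 = 1/T2) mapping from multi-echo MRI.

A CPMG acquisition samples the transverse magnetisation at echo times TE_i;
for a mono-exponentially relaxing voxel the magnitude signal is

    S(TE) = S0 * exp(-TE * R2)

Fitting S0 and R2 per voxel turns an echo stack into an R2 map, which the gel
calibration converts to absorbed dose.  The primary fit is the
variance-stabilised log-linear least squares (weights S^2), which is exact on
noiseless data and close to maximum likelihood at high SNR; an optional
Gauss-Newton refinement iterates the weights on the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GridGeometry

__all__ = ["EchoSeries", "R2Map", "fit_r2_map"]


@dataclass
class EchoSeries:
    """Multi-echo magnitude images: ``signal[ix, iy, iz, echo]`` with the echo
    time vector ``te_ms`` (strictly increasing, in milliseconds)."""

    signal: np.ndarray
    te_ms: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.te_ms.ndim != 1 or self.te_ms.size < 2:
            raise ValueError("need at least 2 echoes")
        if np.any(np.diff(self.te_ms) <= 0) or np.any(self.te_ms <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.signal.shape != self.geometry.shape + (self.te_ms.size,):
            raise ValueError(
                f"signal shape {self.signal.shape} incompatible with geometry "
                f"{self.geometry.shape} and {self.te_ms.size} echoes"
            )


@dataclass
class R2Map:
    """Fitted relaxation-rate map: ``r2`` in s^-1, ``s0`` in signal units,
    ``valid`` marking voxels with a trustworthy fit."""

    r2: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)


def _weighted_loglinear(signal: np.ndarray, te_s: np.ndarray, w: np.ndarray):
    """Closed-form weighted LS of ln S = ln S0 - TE*R2, vectorised over voxels.

    ``signal``/``w`` are (n_vox, n_echo); w already zeroes excluded echoes.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(signal)
    y = np.where(w > 0, y, 0.0)
    sw = w.sum(axis=1)
    swx = w @ te_s
    swy = (w * y).sum(axis=1)
    swxx = w @ (te_s**2)
    swxy = (w * y) @ te_s
    denom = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swxy - swx * swy) / denom
        inter = (swy - slope * swx) / sw
    return -slope, np.exp(inter)  # R2 (s^-1), S0


def fit_r2_map(
    series: EchoSeries,
    signal_floor: float | None = None,
    refine_iters: int = 2,
) -> R2Map:
    """Fit a mono-exponential decay per voxel.

    Parameters
    ----------
    series
        The echo stack.
    signal_floor
        Echo samples at or below this level are excluded from the fit (log of
        noise-dominated magnitudes biases R2).  Default: 3x a noise estimate
        from the last echo (median absolute deviation of its spatial
        high-pass residual), or 0 if that estimate is degenerate.
    refine_iters
        Gauss-Newton reweighting iterations: weights are recomputed from the
        current model prediction instead of the measured signal, moving the
        estimate onto the nonlinear least-squares solution.  0 keeps the
        single-pass measured-signal weighting; the default 2 agrees with a
        per-voxel nonlinear fit to well under 0.5% at typical noise and is
        identical to it on noiseless data.

    Voxels with fewer than 2 usable echoes are marked invalid (no exception).
    R2 is returned in s^-1 (echo times are converted from ms).
    """
    if signal_floor is None:
        signal_floor = 3.0 * _estimate_noise(series.signal[..., -1])
    if signal_floor < 0:
        raise ValueError("signal_floor must be >= 0")

    te_s = series.te_ms / 1000.0
    shape = series.geometry.shape
    sig = series.signal.reshape(-1, te_s.size)
    usable = sig > signal_floor
    enough = usable.sum(axis=1) >= 2

    w = np.where(usable, sig, 0.0) ** 2
    r2, s0 = _weighted_loglinear(sig, te_s, w)
    for _ in range(refine_iters):
        pred = s0[:, None] * np.exp(-np.outer(r2, te_s))
        w = np.where(usable, pred, 0.0) ** 2
        r2, s0 = _weighted_loglinear(sig, te_s, w)

    valid = enough & np.isfinite(r2) & np.isfinite(s0)
    r2 = np.where(valid, r2, np.nan).reshape(shape)
    s0 = np.where(valid, s0, np.nan).reshape(shape)
    if not valid.any():
        warnings.warn("all voxels invalid in R2 fit", stacklevel=2)
    return R2Map(
        r2,
        s0,
        valid.reshape(shape),
        series.geometry,
        {"signal_floor": float(signal_floor), **series.meta},
    )


def _estimate_noise(last_echo: np.ndarray) -> float:
    """Robust noise scale of the last echo via the MAD of its Laplacian-like
    nearest-neighbour residual (signal structure is smooth at voxel scale)."""
    x = np.asarray(last_echo, dtype=float)
    if x.size < 8:
        return 0.0
    diffs = []
    for ax in range(x.ndim):
        if x.shape[ax] >= 2:
            diffs.append(np.diff(x, axis=ax).ravel())
    if not diffs:
        return 0.0
    d = np.concatenate(diffs)
    # sd of a difference of two iid samples is sigma*sqrt(2)
    return float(np.median(np.abs(d - np.median(d))) / 0.6744898 / np.sqrt(2.0))
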
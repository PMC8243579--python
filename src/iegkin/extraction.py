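"""ROI re-centering and Gaussian z-profile trace extraction.

Converts a 4D stack (a 3D image per imaging time point) plus a table of
manually-placed nuclear ROIs into per-cell fluorescence traces.  For each
time point the ROI is re-centred on the intensity centre of mass (the ROI
coordinates are shifted; images are never resampled), the mean intensity of
the circular ROI footprint is computed per z slice, a Gaussian is fitted to
that z profile, and its peak (offset + height) is taken as the cell's
activity.  A local background (median of an annulus 1-2 radii outside the
ROI) is subtracted to give background-referenced values in D.U.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import SamplingProtocol
from .traces import FluorescenceTrace

__all__ = [
    "RoiSpec",
    "ZProfile",
    "GaussianZFit",
    "recenter_roi",
    "z_mean_profile",
    "fit_gaussian_z",
    "extract_trace",
    "extract_all",
]


@dataclass(frozen=True)
class RoiSpec:
    """A circular nuclear ROI: centre (x, y in px; z in slices) and radius px."""

    roi_id: str
    x: float
    y: float
    z: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be > 0")


@dataclass(frozen=True)
class ZProfile:
    """Mean ROI intensity per z slice."""

    z_positions: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_positions, dtype=float)
        v = np.asarray(self.mean_intensity, dtype=float)
        if z.shape != v.shape:
            raise ValueError("z_positions and mean_intensity must have equal length")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile intensities must be finite")
        object.__setattr__(self, "z_positions", z)
        object.__setattr__(self, "mean_intensity", v)


@dataclass(frozen=True)
class GaussianZFit:
    """Result of fitting offset + height * exp(-(z - z0)^2 / 2 sigma^2)."""

    peak_value: float
    z_center: float
    sigma: float
    offset: float
    fitted: bool  # False when the max-of-profile fallback was used


def _disc_mask(shape_yx, cx, cy, radius):
    ny, nx = shape_yx
    yy, xx = np.ogrid[:ny, :nx]
    return (xx - cx) ** 2 + (yy - cy) ** 2 < radius**2


def recenter_roi(
    stack: np.ndarray,
    roi: RoiSpec,
    search_radius: float | None = None,
    z_halfwidth: int = 3,
) -> tuple[RoiSpec, bool]:
    """Shift the ROI centre to the local intensity centre of mass.

    Works on the maximum-intensity projection over the slices within
    ``z_halfwidth`` of the ROI's z; the centroid is computed on
    background-removed intensities (window median subtracted, clipped at 0)
    within ``search_radius`` (default: the ROI radius) of the old centre.
    The displacement is capped at the search radius.  Returns a new RoiSpec
    and a flag that is True when the neighbourhood carried no signal (the
    centre is then left unchanged).
    """
    search_radius = search_radius if search_radius is not None else roi.radius
    nz, ny, nx = stack.shape
    z0 = int(np.clip(round(roi.z) - z_halfwidth, 0, nz - 1))
    z1 = int(np.clip(round(roi.z) + z_halfwidth + 1, 1, nz))
    mip = stack[z0:z1].max(axis=0)

    mask = _disc_mask((ny, nx), roi.x, roi.y, search_radius)
    if not mask.any():
        return roi, True
    vals = mip[mask]
    weights = np.clip(mip - np.median(vals), 0.0, None) * mask
    total = weights.sum()
    if total <= 0:
        return roi, True
    yy, xx = np.mgrid[:ny, :nx]
    cx = float((weights * xx).sum() / total)
    cy = float((weights * yy).sum() / total)
    dx, dy = cx - roi.x, cy - roi.y
    norm = np.hypot(dx, dy)
    if norm > search_radius:
        dx, dy = dx * search_radius / norm, dy * search_radius / norm
    return replace(roi, x=roi.x + dx, y=roi.y + dy), False


def z_mean_profile(stack: np.ndarray, roi: RoiSpec) -> ZProfile:
    """Mean intensity over the circular ROI footprint, per z slice.

    The footprint contains the voxels whose centre lies strictly within
    ``roi.radius`` of the lateral centre (0-based indices).
    """
    nz, ny, nx = stack.shape
    mask = _disc_mask((ny, nx), roi.x, roi.y, roi.radius)
    if not mask.any():
        raise ValueError(f"ROI {roi.roi_id} footprint is empty")
    prof = stack[:, mask].mean(axis=1)
    return ZProfile(np.arange(nz, dtype=float), prof)


def _gauss(z, offset, height, z0, sigma):
    return offset + height * np.exp(-((z - z0) ** 2) / (2.0 * sigma**2))


def fit_gaussian_z(profile: ZProfile) -> GaussianZFit:
    """Least-squares Gaussian fit of the z profile; peak = offset + height.

    With fewer than 5 points, or when the optimiser fails, falls back to the
    profile maximum (``fitted`` is False, offset 0).
    """
    z, v = profile.z_positions, profile.mean_intensity
    if z.size == 0:
        raise ValueError("empty z profile")
    fallback = GaussianZFit(float(v.max()), float(z[int(np.argmax(v))]), np.nan, 0.0, False)
    if z.size < 5:
        return fallback
    vmin, vmax = float(v.min()), float(v.max())
    p0 = [vmin, max(vmax - vmin, 1e-12), float(z[int(np.argmax(v))]), max(z.size / 6.0, 1.0)]
    try:
        popt, _ = curve_fit(_gauss, z, v, p0=p0, maxfev=5000)
    except RuntimeError:
        return fallback
    offset, height, z0, sigma = popt
    if not np.all(np.isfinite(popt)):
        return fallback
    return GaussianZFit(float(offset + height), float(z0), float(abs(sigma)), float(offset), True)


def _annulus_background(stack: np.ndarray, roi: RoiSpec) -> float:
    """Median intensity of the annulus 1-2 radii out, on the ROI's z slice."""
    nz, ny, nx = stack.shape
    zc = int(np.clip(round(roi.z), 0, nz - 1))
    yy, xx = np.ogrid[:ny, :nx]
    d2 = (xx - roi.x) ** 2 + (yy - roi.y) ** 2
    ann = (d2 >= roi.radius**2) & (d2 < (2.0 * roi.radius) ** 2)
    if not ann.any():
        return float(np.median(stack[zc]))
    return float(np.median(stack[zc][ann]))


def extract_trace(
    stacks,
    roi: RoiSpec,
    protocol: SamplingProtocol,
    background_method: str = "annulus",
    search_radius: float | None = None,
) -> FluorescenceTrace:
    """Extract one ROI's background-referenced trace from a stack series.

    ``stacks`` is either a sequence of 3D (z, y, x) arrays aligned with
    ``protocol.time_points`` or a mapping {time_min: stack}.  Per time point:
    re-centre, z-profile, Gaussian z fit, background subtraction
    (``annulus`` median or ``global`` stack median).
    """
    times = protocol.time_points
    if isinstance(stacks, dict):
        missing = [t for t in times if t not in stacks]
        if missing:
            raise ValueError(f"missing stacks for time points (min): {missing}")
        series = [stacks[t] for t in times]
    else:
        if len(stacks) != times.size:
            raise ValueError(
                f"expected {times.size} stacks for protocol {protocol.name}, got {len(stacks)}"
            )
        series = list(stacks)

    values, bgs, dxs, dys = [], [], [], []
    flags: set = set()
    for stack, _t in zip(series, times):
        centered, flat = recenter_roi(stack, roi, search_radius)
        if flat:
            flags.add("recenter_no_signal")
        fit = fit_gaussian_z(z_mean_profile(stack, centered))
        if not fit.fitted:
            flags.add("zfit_fallback")
        if background_method == "annulus":
            bg = _annulus_background(stack, centered)
        elif background_method == "global":
            bg = float(np.median(stack))
        else:
            raise ValueError(f"unknown background_method {background_method!r}")
        values.append(fit.peak_value - bg)
        bgs.append(bg)
        dxs.append(centered.x - roi.x)
        dys.append(centered.y - roi.y)

    return FluorescenceTrace(
        roi_id=roi.roi_id,
        time_points=times,
        values=np.asarray(values),
        background=np.asarray(bgs),
        recenter_dx=np.asarray(dxs),
        recenter_dy=np.asarray(dys),
        flags=sorted(flags),
    )


def extract_all(stacks, roi_table, protocol, **kwargs) -> list:
    """Extract every ROI in a table (columns roi_id, x, y, z, radius)."""
    rois = [
        RoiSpec(str(r.roi_id), float(r.x), float(r.y), float(r.z), float(r.radius))
        for r in roi_table.itertuples()
    ]
    return [extract_trace(stacks, roi, protocol, **kwargs) for roi in rois]
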
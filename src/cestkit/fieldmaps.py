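"""Field mapping: WASSR B0, double-angle B1 (kappa), and variable-TR T1.

WASSR locates the water frequency per pixel from a low-power, narrow-band
Z-spectrum: the spectrum is cubic-spline interpolated onto 1000 uniform
points and a single Lorentzian dip (with a free baseline) is fitted; the
fitted center is the B0 shift in ppm.

The double-angle method recovers the true flip angle from two images at
nominal angles theta and 2*theta: theta_true = arccos(M_2theta / 2 M_theta),
and kappa = theta_true / theta_nominal is the relative B1 scaling factor.

T1 maps come from a variable-TR saturation-recovery fit
S(TR) = M0 * (1 - exp(-TR / T1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, RectBivariateSpline
from scipy.optimize import curve_fit, least_squares

from .core import OffsetImageStack, PixelMap
from .segmentation import SegmentSet

WASSR_GRID_POINTS = 1000


@dataclass
class FieldMaps:
    """Per-pixel B0 shift (ppm), B1 scaling kappa, and optional T1 (s)."""

    b0_ppm: Optional[PixelMap] = None
    kappa: Optional[PixelMap] = None
    t1_s: Optional[PixelMap] = None


def _fit_wassr_dip(offsets: np.ndarray, z: np.ndarray,
                   baseline_bounds=(0.8, 1.2)):
    """Spline-upsample one WASSR spectrum and fit b - L(A, g, w)."""
    spline = CubicSpline(offsets, z)
    grid = np.linspace(offsets[0], offsets[-1], WASSR_GRID_POINTS)
    zg = spline(grid)

    span = offsets[-1] - offsets[0]
    w0 = grid[np.argmin(zg)]
    depth0 = float(np.clip(np.max(zg) - np.min(zg), 1e-3, 1.0))

    def model(x):
        b, a, g, w = x
        q = g * g / 4.0
        return b - a * q / (q + (grid - w) ** 2)

    x0 = np.array([1.0, depth0, span / 3.0, w0])
    lo = np.array([baseline_bounds[0], 1e-4, span / 50.0, offsets[0]])
    hi = np.array([baseline_bounds[1], 1.5, 2.0 * span, offsets[-1]])
    sol = least_squares(lambda x: model(x) - zg, x0, bounds=(lo, hi),
                        xtol=1e-10, ftol=1e-10, max_nfev=400)
    if not sol.success:
        raise RuntimeError("WASSR fit failed")
    return float(sol.x[3])


def wassr_b0(stack: OffsetImageStack,
             mask: Optional[np.ndarray] = None) -> PixelMap:
    """Pixelwise B0 shift map (ppm) from a normalized WASSR stack."""
    if not stack.normalized:
        raise ValueError("WASSR stack must be normalized")
    order = np.argsort(stack.offsets_ppm)
    offsets = stack.offsets_ppm[order]
    rows, cols = stack.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    values = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    for r, c in zip(*np.nonzero(mask)):
        try:
            values[r, c] = _fit_wassr_dip(offsets, stack.data[order, r, c])
            valid[r, c] = True
        except (RuntimeError, ValueError):
            continue
    return PixelMap(values, name="B0 shift", units="ppm", valid_mask=valid)


def dam_b1(
    m_theta: np.ndarray,
    m_2theta: np.ndarray,
    theta_nominal_deg: float,
    noise_floor: Optional[float] = None,
) -> PixelMap:
    """Relative flip-angle scaling factor kappa by the double-angle method.

    Pixels where |M_2theta / 2 M_theta| > 1 (arccos domain violation) or
    where M_theta falls below the noise floor are marked invalid.  The map
    is scale-invariant: multiplying both inputs by c > 0 leaves it fixed.
    """
    m_theta = np.asarray(m_theta, dtype=float)
    m_2theta = np.asarray(m_2theta, dtype=float)
    if m_theta.shape != m_2theta.shape:
        raise ValueError("double-angle images must share a shape")
    if not 0.0 < theta_nominal_deg < 90.0:
        raise ValueError("theta_nominal must lie in (0, 90) degrees")

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_2theta / (2.0 * m_theta)
    valid = np.isfinite(ratio) & (np.abs(ratio) <= 1.0)
    if noise_floor is not None:
        valid &= m_theta > noise_floor
    theta = np.full(m_theta.shape, np.nan)
    theta[valid] = np.degrees(np.arccos(ratio[valid]))
    kappa = theta / theta_nominal_deg
    return PixelMap(kappa, name="kappa", units="", valid_mask=valid)


def upsample_map(pmap: PixelMap, target_shape) -> PixelMap:
    """Bicubic-spline interpolation of a map onto a larger grid.

    Used to match a low-resolution B1 map to the reference image size.
    Invalid pixels are filled with the valid-pixel mean before
    interpolation; the validity mask is upsampled by nearest neighbor.
    """
    rows, cols = pmap.values.shape
    tr, tc = target_shape
    if tr < rows or tc < cols:
        raise ValueError("target size must be >= source size")
    if (tr, tc) == (rows, cols):
        return PixelMap(pmap.values.copy(), pmap.name, pmap.units,
                        pmap.valid_mask.copy())

    vals = pmap.values.copy()
    if not pmap.valid_mask.all():
        fill = np.nanmean(vals[pmap.valid_mask]) if pmap.valid_mask.any() else 0.0
        vals[~pmap.valid_mask] = fill

    # map target pixel centers onto the source grid
    r_src = np.linspace(0, rows - 1, tr)
    c_src = np.linspace(0, cols - 1, tc)
    kx = min(3, rows - 1)
    ky = min(3, cols - 1)
    sp = RectBivariateSpline(np.arange(rows), np.arange(cols), vals,
                             kx=kx, ky=ky)
    out = sp(r_src, c_src)

    rr = np.clip(np.round(r_src).astype(int), 0, rows - 1)
    cc = np.clip(np.round(c_src).astype(int), 0, cols - 1)
    valid = pmap.valid_mask[np.ix_(rr, cc)]
    out[~valid] = np.nan
    return PixelMap(out, pmap.name, pmap.units, valid_mask=valid)


def t1_map(
    images: np.ndarray,
    tr_list_s: Sequence[float],
    mask: Optional[np.ndarray] = None,
) -> PixelMap:
    """Pixelwise saturation-recovery T1 fit over a variable-TR series.

    ``images`` is (n_TR, rows, cols).  Requires >= 4 TRs with real spread
    (shortest below, longest well above the expected T1).  Non-convergent
    pixels are marked invalid.
    """
    images = np.asarray(images, dtype=float)
    tr = np.asarray(tr_list_s, dtype=float)
    if images.shape[0] != tr.size:
        raise ValueError("one image per TR required")
    if tr.size < 4:
        raise ValueError("T1 fit needs >= 4 TR values")
    if np.ptp(tr) <= 0 or (tr.max() / max(tr.min(), 1e-9)) < 3:
        raise ValueError("TR list must span a real recovery range")

    rows, cols = images.shape[1:]
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    def model(t, m0, t1):
        return m0 * (1.0 - np.exp(-t / t1))

    values = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    t1_hi = 10.0 * tr.max()
    for r, c in zip(*np.nonzero(mask)):
        s = images[:, r, c]
        if not np.all(np.isfinite(s)) or s.max() <= 0:
            continue
        try:
            popt, _ = curve_fit(
                model, tr, s,
                p0=[s.max(), tr.mean()],
                bounds=([0.0, 1e-3], [10.0 * s.max(), t1_hi]),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        values[r, c] = popt[1]
        valid[r, c] = True
    return PixelMap(values, name="T1", units="s", valid_mask=valid)


def segment_field_stats(
    fieldmaps: FieldMaps,
    segments: SegmentSet,
) -> pd.DataFrame:
    """Per-segment distribution summaries (median, quartiles, n) of the
    valid B0 / kappa / T1 values; empty segments are omitted with a
    warning."""
    import warnings

    rows = []
    for label, m in segments:
        if not m.any():
            warnings.warn(f"segment {label!r} is empty; omitted")
            continue
        row: Dict[str, object] = {"segment": label}
        for key, pmap in (("b0_ppm", fieldmaps.b0_ppm),
                          ("kappa", fieldmaps.kappa),
                          ("t1_s", fieldmaps.t1_s)):
            if pmap is None:
                continue
            vals = pmap.values[m & pmap.valid_mask]
            if vals.size == 0:
                continue
            row[f"{key}_median"] = float(np.median(vals))
            row[f"{key}_q1"] = float(np.percentile(vals, 25))
            row[f"{key}_q3"] = float(np.percentile(vals, 75))
            row[f"{key}_n"] = int(vals.size)
        rows.append(row)
    return pd.DataFrame(rows)
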
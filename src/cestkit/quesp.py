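"""QUESP: quantitative exchange-rate and proton-fraction mapping from
multi-B1 CEST acquisitions.

Saturation efficiency alpha = w1^2 / (w1^2 + kb^2) with w1 = gamma*B1
rises with saturation power, so acquiring MTRasym at several B1 values
makes the pair (fb, kb) identifiable.  Three analytical routes are
provided:

- ``mtr_asym``: bounded nonlinear least squares of the closed-form
  CW-saturation MTRasym(alpha, tp) expression (valid at any tp);
- ``mtr_rex``: least squares of the steady-state inverse-difference metric
  MTRRex = 1/Z_lab - 1/Z_ref = fb*kb*alpha / R1a;
- ``omega_plot``: ordinary least squares of 1/MTRRex against 1/w1^2
  (linear rearrangement of the same expression), with
  kb = sqrt(slope/intercept), fb = R1a/(intercept*kb).

The steady-state routes assume tp >> T1a and full inter-readout
relaxation; :func:`steady_state_warning` checks both from the acquisition
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import GAMMA_MHZ_PER_T, AcquisitionParams, OffsetImageStack, PixelMap

#: gamma in rad s^-1 uT^-1
GAMMA_RAD_PER_S_UT = 2.0 * np.pi * GAMMA_MHZ_PER_T


def omega1(b1_uT) -> np.ndarray:
    """Saturation amplitude in angular frequency units, rad/s."""
    return GAMMA_RAD_PER_S_UT * np.asarray(b1_uT, dtype=float)


def alpha(b1_uT, kb: float) -> np.ndarray:
    """Saturation efficiency alpha = w1^2 / (w1^2 + kb^2)."""
    if np.any(np.asarray(kb) < 0):
        raise ValueError("kb must be non-negative")
    w1 = omega1(b1_uT)
    w1sq = w1 * w1
    denom = w1sq + kb * kb
    with np.errstate(invalid="ignore"):
        out = np.where(denom > 0, w1sq / np.maximum(denom, 1e-300), 0.0)
    return out


def mtrasym_model(fb: float, kb: float, b1_uT, r1a: float, tp_s: float,
                  zi: float = 1.0) -> np.ndarray:
    """Closed-form CW MTRasym versus saturation amplitude and time.

    Evaluates
    S + (Zi - 1) e^{-R1a tp} - (Zi - R1a/(R1a + fb kb a)) e^{-(R1a + fb kb a) tp}
    with S = fb kb a / (R1a + fb kb a); identically 0 at tp = 0 and
    approaching S as tp -> infinity.
    """
    a = alpha(b1_uT, kb)
    fka = fb * kb * a
    denom = r1a + fka
    s = np.where(denom > 0, fka / np.maximum(denom, 1e-300), 0.0)
    return (
        s
        + (zi - 1.0) * np.exp(-r1a * tp_s)
        - (zi - r1a / np.maximum(denom, 1e-300)) * np.exp(-denom * tp_s)
    )


def mtrrex_model(fb: float, kb: float, b1_uT, r1a: float) -> np.ndarray:
    """Steady-state inverse-difference metric fb*kb*alpha / R1a."""
    return fb * kb * alpha(b1_uT, kb) / r1a


@dataclass
class QuespSeries:
    """Per-pixel multi-B1 series feeding the QUESP fits.

    ``mtr_asym`` is (n_b1, rows, cols); ``z_lab``/``z_ref`` likewise when
    the inverse-metric routes are used.  ``r1a`` may be a scalar or a
    pixelwise map (a T1 map takes precedence over a scalar when both are
    supplied upstream).
    """

    b1_uT: np.ndarray
    tp_s: float
    mtr_asym: Optional[np.ndarray] = None
    z_lab: Optional[np.ndarray] = None
    z_ref: Optional[np.ndarray] = None
    zi: float = 1.0
    r1a: float | np.ndarray = 1.0 / 1.8
    dw_ppm: float = 2.0

    def __post_init__(self):
        self.b1_uT = np.asarray(self.b1_uT, dtype=float)
        nz = np.unique(self.b1_uT[self.b1_uT > 0])
        if nz.size < 3:
            raise ValueError("QUESP needs >= 3 distinct nonzero B1 values")
        if self.tp_s <= 0:
            raise ValueError("tp_s must be positive")
        for name in ("mtr_asym", "z_lab", "z_ref"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def r1a_at(self, r: int, c: int) -> float:
        if np.ndim(self.r1a) == 0:
            return float(self.r1a)
        return float(np.asarray(self.r1a)[r, c])

    def mtrrex(self) -> np.ndarray:
        if self.z_lab is None or self.z_ref is None:
            raise ValueError("MTRRex routes need z_lab and z_ref")
        with np.errstate(divide="ignore", invalid="ignore"):
            return 1.0 / self.z_lab - 1.0 / self.z_ref


@dataclass
class QuespFit:
    fb: PixelMap
    kb: PixelMap
    r2: PixelMap
    method: str
    bounds: dict = field(default_factory=dict)


DEFAULT_BOUNDS = dict(fb=(1e-6, 0.05), kb=(10.0, 2e4))
DEFAULT_INIT = dict(fb=1e-3, kb=1000.0)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _fit_pixel_nls(y, b1, r1a, tp, zi, model, bounds, init):
    lo = np.array([bounds["fb"][0], bounds["kb"][0]])
    hi = np.array([bounds["fb"][1], bounds["kb"][1]])
    x0 = np.array([init["fb"], init["kb"]])

    def resid(x):
        return model(x[0], x[1], b1, r1a, tp, zi) - y

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                        max_nfev=800)
    if not sol.success:
        raise RuntimeError("QUESP fit failed")
    yhat = model(sol.x[0], sol.x[1], b1, r1a, tp, zi)
    return float(sol.x[0]), float(sol.x[1]), _r_squared(y, yhat)


def fit_quesp(
    series: QuespSeries,
    method: str = "mtr_asym",
    mask: Optional[np.ndarray] = None,
    bounds: Optional[dict] = None,
    init: Optional[dict] = None,
) -> QuespFit:
    """Pixelwise (fb, kb) maps by one of the three QUESP routes.

    Non-convergent pixels (or, for the omega plot, pixels with a
    non-positive slope or intercept) are marked invalid, never aborting
    the batch.
    """
    if method not in ("mtr_asym", "mtr_rex", "omega_plot"):
        raise ValueError(f"unknown QUESP method {method!r}")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    init = {**DEFAULT_INIT, **(init or {})}

    if method == "mtr_asym":
        if series.mtr_asym is None:
            raise ValueError("mtr_asym route needs the MTRasym series")
        data = series.mtr_asym
    else:
        data = series.mtrrex()

    n_b1, rows, cols = data.shape
    if n_b1 != series.b1_uT.size:
        raise ValueError("one image per B1 value required")
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    fb_v = np.full((rows, cols), np.nan)
    kb_v = np.full((rows, cols), np.nan)
    r2_v = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    w1sq = omega1(series.b1_uT) ** 2

    for r, c in zip(*np.nonzero(mask)):
        y = data[:, r, c]
        if not np.all(np.isfinite(y)):
            continue
        r1a = series.r1a_at(r, c)
        try:
            if method == "mtr_asym":
                fb, kb, r2 = _fit_pixel_nls(
                    y, series.b1_uT, r1a, series.tp_s, series.zi,
                    mtrasym_model, bounds, init,
                )
            elif method == "mtr_rex":
                fb, kb, r2 = _fit_pixel_nls(
                    y, series.b1_uT, r1a, series.tp_s, series.zi,
                    lambda f, k, b1, r1, tp, zi: mtrrex_model(f, k, b1, r1),
                    bounds, init,
                )
            else:  # omega_plot
                if np.any(y <= 0):
                    continue
                x = 1.0 / w1sq
                yy = 1.0 / y
                slope, intercept = np.polyfit(x, yy, 1)
                if slope <= 0 or intercept <= 0:
                    continue
                kb = float(np.sqrt(slope / intercept))
                fb = float(r1a / (intercept * kb))
                r2 = _r_squared(yy, slope * x + intercept)
        except RuntimeError:
            continue
        fb_v[r, c], kb_v[r, c], r2_v[r, c] = fb, kb, r2
        valid[r, c] = True

    return QuespFit(
        fb=PixelMap(fb_v, name="fb", units="", valid_mask=valid),
        kb=PixelMap(kb_v, name="kb", units="1/s", valid_mask=valid),
        r2=PixelMap(r2_v, name="R2 of fit", units="", valid_mask=valid),
        method=method,
        bounds=bounds,
    )


def steady_state_warning(
    params: AcquisitionParams,
    t1a_s: float,
    ss_factor: float = 5.0,
) -> List[str]:
    """Warnings when acquisition parameters violate steady-state or
    full-relaxation assumptions of the MTRRex/omega-plot routes."""
    msgs = []
    if params.sat_time_s < ss_factor * t1a_s:
        msgs.append(
            f"saturation time {params.sat_time_s:g} s < {ss_factor:g} x T1a "
            f"({t1a_s:g} s): steady-state assumption of the MTRRex/omega-plot "
            "routes is not met"
        )
    if params.recovery_time_s < ss_factor * t1a_s:
        msgs.append(
            f"recovery time {params.recovery_time_s:g} s < {ss_factor:g} x "
            f"T1a ({t1a_s:g} s): longitudinal magnetization does not fully "
            "relax between readouts"
        )
    for m in msgs:
        warnings.warn(m)
    return msgs


def mtrasym_from_stack(
    stack: OffsetImageStack,
    dw_ppm: float,
) -> Dict[float, np.ndarray]:
    """Per-B1 MTRasym images Z(-dw) - Z(+dw) from a normalized multi-B1
    stack, interpolating along the offset axis when +/-dw are not sampled
    exactly.  The B1 of each frame comes from ``params.b1_list_uT``.
    """
    if not stack.normalized:
        raise ValueError("stack must be normalized")
    b1s = stack.params.b1_list_uT
    if b1s is None:
        raise ValueError("stack params must carry b1_list_uT per frame")
    b1s = np.asarray(b1s, dtype=float)
    if b1s.size != stack.n_offsets:
        raise ValueError("need one B1 value per frame")

    out: Dict[float, np.ndarray] = {}
    for b1 in np.unique(b1s):
        sel = b1s == b1
        offs = stack.offsets_ppm[sel]
        frames = stack.data[sel]
        if offs.min() > -abs(dw_ppm) or offs.max() < abs(dw_ppm):
            raise ValueError(
                f"one-sided acquisition at B1={b1}: offsets do not cover "
                f"+/-{abs(dw_ppm)} ppm"
            )
        order = np.argsort(offs)
        offs, frames = offs[order], frames[order]
        flat = frames.reshape(frames.shape[0], -1)
        z_neg = np.empty(flat.shape[1])
        z_pos = np.empty(flat.shape[1])
        for j in range(flat.shape[1]):
            z_neg[j] = np.interp(-abs(dw_ppm), offs, flat[:, j])
            z_pos[j] = np.interp(abs(dw_ppm), offs, flat[:, j])
        out[float(b1)] = (z_neg - z_pos).reshape(frames.shape[1:])
    return out
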
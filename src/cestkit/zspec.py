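"""Two-step Lorentzian fitting of CEST Z-spectra with internal B0 correction.

The Z-spectrum is modeled as Z(dw) = 1 - sum_i L_i(dw) with per-pool
Lorentzians L(dw) = A * (g^2/4) / (g^2/4 + (dw - w)^2), where A is peak
amplitude (fraction of M0), g the FWHM in ppm, and w the center offset
relative to water.

Fitting proceeds in two steps:

1. Water + semisolid MT are fitted over the whole spectrum; the fitted
   water center is taken as the per-pixel B0 shift and subtracted from the
   frequency axis.  Water + MT are then refitted on the corrected axis with
   offsets in the 1.4 <= |dw| <= 4 ppm bands excluded, so the reference fit
   is not biased by solute peaks.
2. The Lorentzian difference (reference water+MT fit minus measured Z, so
   CEST peaks are positive) is computed on the corrected axis and the
   requested solute pools (amide, creatine, rNOE, ...) are fitted to it.

The default pool table holds common 7T literature starting values and
bounds; every entry can be overridden from a YAML/JSON config since
Lorentzian fitting is notoriously sensitive to initial conditions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import OffsetImageStack, PixelMap

# name -> dict(omega, gamma_init, gamma_bounds, amp_init, amp_bounds,
#              omega_halfwidth): center is searched within +/- halfwidth.
DEFAULT_POOL_TABLE: Dict[str, dict] = {
    "water": dict(
        omega=0.0, omega_halfwidth=1.0,
        gamma_init=1.4, gamma_bounds=(0.3, 10.0),
        amp_init=0.9, amp_bounds=(0.02, 1.0),
    ),
    "mt": dict(
        omega=-2.5, omega_halfwidth=0.5,
        gamma_init=25.0, gamma_bounds=(15.0, 100.0),
        amp_init=0.1, amp_bounds=(0.0, 0.4),
    ),
    "amide": dict(
        omega=3.5, omega_halfwidth=0.3,
        gamma_init=1.0, gamma_bounds=(0.4, 3.0),
        amp_init=0.025, amp_bounds=(0.0, 0.3),
    ),
    "creatine": dict(
        omega=2.0, omega_halfwidth=0.3,
        gamma_init=1.0, gamma_bounds=(0.4, 3.0),
        amp_init=0.02, amp_bounds=(0.0, 0.3),
    ),
    "amine": dict(
        omega=2.0, omega_halfwidth=0.3,
        gamma_init=1.0, gamma_bounds=(0.4, 3.0),
        amp_init=0.02, amp_bounds=(0.0, 0.3),
    ),
    "hydroxyl": dict(
        omega=1.0, omega_halfwidth=0.3,
        gamma_init=1.0, gamma_bounds=(0.4, 3.0),
        amp_init=0.02, amp_bounds=(0.0, 0.3),
    ),
    "rnoe": dict(
        omega=-3.5, omega_halfwidth=0.5,
        gamma_init=3.0, gamma_bounds=(0.5, 8.0),
        amp_init=0.02, amp_bounds=(0.0, 0.3),
    ),
}


@dataclass
class LorentzianPool:
    """One fitted Lorentzian component of the Z-spectrum."""

    name: str
    A: float
    gamma_ppm: float
    omega_ppm: float

    def __post_init__(self):
        if self.gamma_ppm <= 0:
            raise ValueError("gamma_ppm (FWHM) must be positive")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")

    def __call__(self, offsets: np.ndarray) -> np.ndarray:
        return lorentzian(self.A, self.gamma_ppm, self.omega_ppm, offsets)


def lorentzian(A: float, gamma_ppm: float, omega_ppm: float,
               offsets: np.ndarray) -> np.ndarray:
    """Amplitude-parameterized Lorentzian line: value A at its center,
    A/2 at omega +/- gamma/2."""
    if gamma_ppm <= 0:
        raise ValueError("gamma_ppm must be positive")
    offsets = np.asarray(offsets, dtype=float)
    q = gamma_ppm**2 / 4.0
    return A * q / (q + (offsets - omega_ppm) ** 2)


@dataclass
class FitConfig:
    """Numerical settings of the two-step fit."""

    exclusion_band_ppm: tuple = (1.4, 4.0)
    pool_table: Dict[str, dict] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_POOL_TABLE)
    )
    tol: float = 1e-8
    max_nfev: int = 400

    def pool_entry(self, name: str) -> dict:
        try:
            return self.pool_table[name.lower()]
        except KeyError:
            raise KeyError(
                f"pool {name!r} not in pool table; known pools: "
                f"{sorted(self.pool_table)}"
            ) from None


@dataclass
class ZSpectrumFit:
    """Result of one two-step Z-spectrum fit."""

    pools: Dict[str, LorentzianPool]
    b0_shift_ppm: float
    rmse_step1: float
    rmse_step2: float
    offsets_corrected_ppm: np.ndarray
    lorentzian_difference: np.ndarray
    z: np.ndarray

    def reference_fit(self, offsets: Optional[np.ndarray] = None) -> np.ndarray:
        """Water+MT reference Z on the corrected axis."""
        if offsets is None:
            offsets = self.offsets_corrected_ppm
        ref = np.ones_like(np.asarray(offsets, dtype=float))
        for name in ("water", "mt"):
            if name in self.pools:
                ref = ref - self.pools[name](offsets)
        return ref

    def contrasts(self) -> Dict[str, float]:
        """Solute-pool peak amplitudes (fraction of M0)."""
        return {
            n: p.A for n, p in self.pools.items() if n not in ("water", "mt")
        }


def _pack(entries: Sequence[dict]):
    x0, lo, hi = [], [], []
    for e in entries:
        x0 += [e["amp_init"], e["gamma_init"], e["omega"]]
        lo += [e["amp_bounds"][0], e["gamma_bounds"][0],
               e["omega"] - e["omega_halfwidth"]]
        hi += [e["amp_bounds"][1], e["gamma_bounds"][1],
               e["omega"] + e["omega_halfwidth"]]
    return np.array(x0), (np.array(lo), np.array(hi))


def _sum_lorentzians(x: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    total = np.zeros_like(offsets)
    for i in range(0, len(x), 3):
        total += lorentzian(x[i], x[i + 1], x[i + 2], offsets)
    return total


def _fit_water_mt(offsets, z, config: FitConfig):
    entries = [config.pool_entry("water"), config.pool_entry("mt")]
    x0, bounds = _pack(entries)

    def resid(x):
        return (1.0 - _sum_lorentzians(x, offsets)) - z

    sol = least_squares(
        resid, x0, bounds=bounds,
        xtol=config.tol, ftol=config.tol, gtol=config.tol,
        max_nfev=config.max_nfev,
    )
    return sol


def fit_two_step(
    offsets_ppm: np.ndarray,
    z: np.ndarray,
    pools_requested: Sequence[str] = ("amide",),
    config: Optional[FitConfig] = None,
) -> ZSpectrumFit:
    """Fit one normalized Z-spectrum by the two-step Lorentzian method.

    Parameters
    ----------
    offsets_ppm : uncorrected saturation offsets (ppm from nominal water).
    z : normalized Z values, one per offset.
    pools_requested : solute pools to fit to the Lorentzian difference.

    Raises
    ------
    ValueError on too few offsets, and RuntimeError on non-convergence
    (pixelwise drivers catch the latter and mark the pixel invalid).
    """
    config = config or FitConfig()
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    z = np.asarray(z, dtype=float)
    if offsets_ppm.size < 10 or np.max(np.abs(offsets_ppm)) <= 4.0:
        raise ValueError(
            "two-step fit needs >= 10 offsets spanning beyond +/-4 ppm"
        )

    # step 0: water+MT over the full spectrum -> B0 from the water center
    sol0 = _fit_water_mt(offsets_ppm, z, config)
    b0 = float(sol0.x[2])
    corrected = offsets_ppm - b0

    # step 1: refit on the corrected axis, solute bands excluded
    lo_b, hi_b = config.exclusion_band_ppm
    include = ~((np.abs(corrected) >= lo_b) & (np.abs(corrected) <= hi_b))
    n_params = 6
    if np.count_nonzero(include) < n_params:
        raise ValueError(
            "fewer offsets than water+MT parameters after band exclusion"
        )
    sol1 = _fit_water_mt(corrected[include], z[include], config)
    if not (sol0.success and sol1.success):
        raise RuntimeError("water+MT fit did not converge")
    ref = 1.0 - _sum_lorentzians(sol1.x, corrected)
    rmse1 = float(np.sqrt(np.mean((ref[include] - z[include]) ** 2)))

    # step 2: solute pools fitted to the Lorentzian difference
    diff = ref - z  # CEST/rNOE peaks positive
    pools: Dict[str, LorentzianPool] = {
        "water": LorentzianPool("water", *map(float, sol1.x[0:3])),
        "mt": LorentzianPool("mt", *map(float, sol1.x[3:6])),
    }
    rmse2 = 0.0
    if pools_requested:
        entries = [config.pool_entry(p) for p in pools_requested]
        x0, bounds = _pack(entries)

        def resid(x):
            return _sum_lorentzians(x, corrected) - diff

        sol2 = least_squares(
            resid, x0, bounds=bounds,
            xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_nfev,
        )
        if not sol2.success:
            raise RuntimeError("solute-pool fit did not converge")
        for j, name in enumerate(pools_requested):
            a, g, w = sol2.x[3 * j: 3 * j + 3]
            pools[name.lower()] = LorentzianPool(
                name.lower(), float(a), float(g), float(w)
            )
        rmse2 = float(np.sqrt(np.mean(sol2.fun**2)))

    return ZSpectrumFit(
        pools=pools,
        b0_shift_ppm=b0,
        rmse_step1=rmse1,
        rmse_step2=rmse2,
        offsets_corrected_ppm=corrected,
        lorentzian_difference=diff,
        z=z,
    )


def fit_pixelwise(
    stack: OffsetImageStack,
    mask: Optional[np.ndarray] = None,
    pools_requested: Sequence[str] = ("amide",),
    config: Optional[FitConfig] = None,
) -> Dict[str, PixelMap]:
    """Two-step fit per masked pixel.

    Returns maps named after each solute pool (peak amplitude), plus
    ``"b0_shift"`` (ppm), ``"mt"`` (MT amplitude), ``"rmse_step1"`` and
    ``"rmse_step2"``.  Pixels whose fit fails are marked invalid; failures
    never abort the batch.
    """
    if not stack.normalized:
        raise ValueError("stack must be normalized before fitting")
    rows, cols = stack.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    names = [p.lower() for p in pools_requested] + [
        "mt", "b0_shift", "rmse_step1", "rmse_step2"
    ]
    out = {n: np.full((rows, cols), np.nan) for n in names}
    valid = np.zeros((rows, cols), dtype=bool)

    for r, c in zip(*np.nonzero(mask)):
        try:
            fit = fit_two_step(
                stack.offsets_ppm, stack.data[:, r, c], pools_requested, config
            )
        except (ValueError, RuntimeError):
            continue
        for p in pools_requested:
            out[p.lower()][r, c] = fit.pools[p.lower()].A
        out["mt"][r, c] = fit.pools["mt"].A
        out["b0_shift"][r, c] = fit.b0_shift_ppm
        out["rmse_step1"][r, c] = fit.rmse_step1
        out["rmse_step2"][r, c] = fit.rmse_step2
        valid[r, c] = True

    units = {"b0_shift": "ppm"}
    return {
        n: PixelMap(out[n], name=n, units=units.get(n, ""), valid_mask=valid)
        for n in names
    }


def fit_segmentwise(
    stack: OffsetImageStack,
    segments,
    pools_requested: Sequence[str] = ("amide",),
    config: Optional[FitConfig] = None,
) -> Dict[str, ZSpectrumFit]:
    """Fit the mean Z-spectrum of each labeled segment.

    Empty segments are skipped with a warning rather than raising.
    """
    import warnings

    if not stack.normalized:
        raise ValueError("stack must be normalized before fitting")
    fits: Dict[str, ZSpectrumFit] = {}
    for label, m in segments.masks.items():
        m = np.asarray(m, dtype=bool)
        if not m.any():
            warnings.warn(f"segment {label!r} is empty; skipped")
            continue
        zbar = stack.data[:, m].mean(axis=1)
        fits[label] = fit_two_step(
            stack.offsets_ppm, zbar, pools_requested, config
        )
    return fits
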
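"""Multi-pool Bloch-McConnell simulator for CW saturation transfer.

Each proton pool i carries magnetization (Mx_i, My_i, Mz_i) relaxing with
rates (R1_i, R2_i) and exchanging longitudinal/transverse magnetization
with the free water pool by first-order two-site kinetics: solute->water at
rate kb and water->solute at kb*fb (detailed balance with equilibrium pool
sizes M0_water = 1, M0_solute = fb).  Solute-solute exchange is not modeled.

During a continuous-wave saturation block the coupled ODE system is linear
with constant coefficients, so each block is propagated exactly by the
matrix exponential of the augmented homogeneous (3N+1)x(3N+1) system; no
time discretization is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .core import GAMMA_MHZ_PER_T

MAX_POOLS = 4


@dataclass
class PoolParameters:
    """Relaxation and exchange parameters of one proton pool.

    fb is the proton volume fraction (water pool: fb = 1), kb the
    solute-to-water exchange rate in 1/s, dw_ppm the chemical shift from
    water, and r1/r2 the longitudinal/transverse relaxation rates in 1/s.
    """

    name: str
    fb: float
    kb: float
    dw_ppm: float
    r1: float
    r2: float

    def __post_init__(self):
        vals = (self.fb, self.kb, self.dw_ppm, self.r1, self.r2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in pool {self.name!r}")
        if not 0.0 <= self.fb <= 1.0:
            raise ValueError("fb must lie in [0, 1]")
        if self.kb < 0:
            raise ValueError("kb must be non-negative")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("relaxation rates must be positive")


def water_pool(r1: float = 1.0 / 1.8, r2: float = 1.0 / 0.04) -> PoolParameters:
    """Convenience water pool with rodent-myocardium-like 7T defaults."""
    return PoolParameters("water", fb=1.0, kb=0.0, dw_ppm=0.0, r1=r1, r2=r2)


@dataclass
class SaturationEvent:
    """One CW saturation block: amplitude (uT), duration (s), offset (ppm)."""

    b1_uT: float
    duration_s: float
    offset_ppm: float
    shape: str = "cw"

    def __post_init__(self):
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")
        if self.shape != "cw":
            raise ValueError("only continuous-wave saturation is supported")


@dataclass
class ScheduleEntry:
    saturation: SaturationEvent
    recovery_s: float = 0.0
    flip_deg: float = 90.0


@dataclass
class Schedule:
    """Ordered list of image acquisitions for trajectory simulation."""

    entries: Sequence[ScheduleEntry] = field(default_factory=list)

    def __post_init__(self):
        if len(self.entries) == 0:
            raise ValueError("schedule must be nonempty")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _check_pools(pools: Sequence[PoolParameters]) -> None:
    if not pools:
        raise ValueError("at least one pool (water) required")
    if pools[0].fb != 1.0:
        raise ValueError("first pool must be water with fb = 1")
    if len(pools) > MAX_POOLS:
        raise ValueError(f"at most {MAX_POOLS} pools supported")


def _bm_matrix(
    pools: Sequence[PoolParameters],
    b1_uT: float,
    offset_ppm: float,
    field_MHz: float,
) -> np.ndarray:
    """Augmented (3N+1)x(3N+1) Bloch-McConnell generator for one CW block.

    State ordering: [Mx_1, My_1, Mz_1, ..., Mx_N, My_N, Mz_N, 1].
    """
    n = len(pools)
    dim = 3 * n + 1
    A = np.zeros((dim, dim))
    w1 = 2.0 * np.pi * GAMMA_MHZ_PER_T * b1_uT  # rad/s, B1 in uT
    # water->solute pseudo-first-order rates; water loss is their sum
    k_ws = [p.kb * p.fb for p in pools[1:]]
    for i, p in enumerate(pools):
        ix, iy, iz = 3 * i, 3 * i + 1, 3 * i + 2
        # off-resonance of this pool in the RF rotating frame, rad/s
        dwi = 2.0 * np.pi * field_MHz * (p.dw_ppm - offset_ppm)
        k_out = sum(k_ws) if i == 0 else p.kb
        A[ix, ix] = -(p.r2 + k_out)
        A[ix, iy] = -dwi
        A[iy, ix] = dwi
        A[iy, iy] = -(p.r2 + k_out)
        A[iy, iz] = w1
        A[iz, iy] = -w1
        A[iz, iz] = -(p.r1 + k_out)
        m0_i = 1.0 if i == 0 else p.fb
        A[iz, -1] = p.r1 * m0_i
        # exchange coupling with water (pool 0), componentwise
        if i > 0:
            for c in range(3):
                A[c, 3 * i + c] += p.kb          # solute -> water
                A[3 * i + c, c] += p.kb * p.fb   # water -> solute
    return A


def _equilibrium_state(pools: Sequence[PoolParameters], z_init: float) -> np.ndarray:
    """Transverse-free state with every pool's Mz at z_init of its M0."""
    n = len(pools)
    v = np.zeros(3 * n + 1)
    for i, p in enumerate(pools):
        m0_i = 1.0 if i == 0 else p.fb
        v[3 * i + 2] = z_init * m0_i
    v[-1] = 1.0
    return v


def _propagate(state: np.ndarray, A: np.ndarray, t: float) -> np.ndarray:
    if t == 0:
        return state
    return expm(A * t) @ state


def simulate_z(
    pools: Sequence[PoolParameters],
    event: SaturationEvent,
    field_MHz: float,
    z_init: float = 1.0,
) -> float:
    """Water longitudinal magnetization fraction after one CW block.

    Starts from a transverse-free state with all pools at ``z_init`` of
    their equilibrium Mz and returns Mz_water / M0_water.
    """
    _check_pools(pools)
    A = _bm_matrix(pools, event.b1_uT, event.offset_ppm, field_MHz)
    state = _equilibrium_state(pools, z_init)
    state = _propagate(state, A, event.duration_s)
    return float(state[2])


def simulate_zspectrum(
    pools: Sequence[PoolParameters],
    offsets_ppm: np.ndarray,
    b1_uT: float,
    sat_time_s: float,
    field_MHz: float,
    z_init: float = 1.0,
) -> np.ndarray:
    """Z(offset) for a list of saturation offsets (fresh z_init each time)."""
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    return np.array(
        [
            simulate_z(
                pools,
                SaturationEvent(b1_uT, sat_time_s, float(dw)),
                field_MHz,
                z_init,
            )
            for dw in offsets_ppm
        ]
    )


def simulate_trajectory(
    pools: Sequence[PoolParameters],
    schedule: Schedule,
    field_MHz: float,
    z_init: float = 1.0,
    spoil: bool = True,
) -> np.ndarray:
    """Signal trajectory over an acquisition schedule.

    Per entry: CW saturation, then an instantaneous readout recording
    sin(flip)*Mz_water and scaling every pool's Mz by cos(flip) (single-shot
    EPI approximation; transverse magnetization is spoiled), then free
    relaxation for the recovery delay.  Magnetization is carried across
    entries — no full-relaxation assumption.
    """
    _check_pools(pools)
    state = _equilibrium_state(pools, z_init)
    n = len(pools)
    signal = np.empty(len(schedule))
    free = _bm_matrix(pools, 0.0, 0.0, field_MHz)
    for j, entry in enumerate(schedule):
        ev = entry.saturation
        A = _bm_matrix(pools, ev.b1_uT, ev.offset_ppm, field_MHz)
        state = _propagate(state, A, ev.duration_s)
        theta = np.deg2rad(entry.flip_deg)
        signal[j] = np.sin(theta) * state[2]
        for i in range(n):
            if spoil:
                state[3 * i] = 0.0
                state[3 * i + 1] = 0.0
            state[3 * i + 2] *= np.cos(theta)
        if entry.recovery_s > 0:
            state = _propagate(state, free, entry.recovery_s)
    return signal
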
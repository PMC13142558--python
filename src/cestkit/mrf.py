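"""CEST fingerprinting: dictionary generation and dot-product matching.

A saturation schedule with varied (B1, tp, recovery) produces a per-pixel
signal trajectory.  A dictionary of synthetic trajectories is simulated
with the Bloch-McConnell propagator for every combination of water
relaxation (R1a, R2a) and solute (fb, kb) grid values; measured
trajectories are matched to the dictionary row maximizing the normalized
inner product (cosine similarity), which bounds the reported dot product
in [0, 1] for non-negative signals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .bloch import PoolParameters, Schedule, simulate_trajectory
from .core import PixelMap

GRID_CAP = int(2e6)

#: water proton concentration used for fb -> concentration conversion:
#: 55.5 M water x 2 protons = 111 M proton equivalents.
WATER_PROTON_CONC_M = 111.0


@dataclass
class MRFScenario:
    """Dictionary definition: field strength, water relaxation grids,
    one varying solute pool, and the acquisition schedule.

    ``solute`` carries the fixed solute properties (dw_ppm, r1, r2);
    ``fb_grid``/``kb_grid`` are the varied dimensions.  Grid order is
    lexicographic over (fb, kb, r1a, r2a), which fixes row indexing.
    """

    field_MHz: float
    r1a_grid: Sequence[float]
    r2a_grid: Sequence[float]
    fb_grid: Sequence[float]
    kb_grid: Sequence[float]
    solute_dw_ppm: float
    solute_r1: float = 1.0
    solute_r2: float = 50.0
    schedule: Optional[Schedule] = None

    def __post_init__(self):
        for name in ("r1a_grid", "r2a_grid", "fb_grid", "kb_grid"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size < 1:
                raise ValueError(f"{name} must be nonempty")
            setattr(self, name, vals)

    @property
    def grid_size(self) -> int:
        return (len(self.fb_grid) * len(self.kb_grid)
                * len(self.r1a_grid) * len(self.r2a_grid))

    def grid_tuples(self):
        """(fb, kb, r1a, r2a) tuples in dictionary row order."""
        return list(itertools.product(
            self.fb_grid, self.kb_grid, self.r1a_grid, self.r2a_grid
        ))


@dataclass
class MRFDictionary:
    """L2-normalized synthetic trajectories, one row per grid point."""

    entries: np.ndarray           # (n_rows, schedule length), unit L2 norm
    grid: np.ndarray              # (n_rows, 4): fb, kb, r1a, r2a
    param_names: tuple = ("fb", "kb", "r1a", "r2a")
    raw_norms: Optional[np.ndarray] = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.entries.shape[0] != self.grid.shape[0]:
            raise ValueError("one grid tuple per dictionary row required")


@dataclass
class MRFMatch:
    maps: Dict[str, PixelMap]     # fb, kb, r1a, r2a
    dp: PixelMap
    concentration_mM: Optional[PixelMap] = None


def build_dictionary(scenario: MRFScenario, cap: int = GRID_CAP) -> MRFDictionary:
    """Simulate one trajectory per grid tuple and L2-normalize the rows."""
    if scenario.schedule is None:
        raise ValueError("scenario needs a schedule")
    if scenario.grid_size > cap:
        raise ValueError(
            f"grid size {scenario.grid_size} exceeds cap {cap}; reduce the "
            "parameter grids"
        )
    tuples = scenario.grid_tuples()
    n = len(tuples)
    rows = np.empty((n, len(scenario.schedule)))
    for i, (fb, kb, r1a, r2a) in enumerate(tuples):
        pools = [PoolParameters("water", 1.0, 0.0, 0.0, r1a, r2a)]
        if fb > 0:
            pools.append(PoolParameters(
                "solute", fb, kb, scenario.solute_dw_ppm,
                scenario.solute_r1, scenario.solute_r2,
            ))
        rows[i] = simulate_trajectory(pools, scenario.schedule,
                                      scenario.field_MHz)
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return MRFDictionary(
        entries=rows / safe[:, None],
        grid=np.asarray(tuples, dtype=float),
        raw_norms=norms,
    )


def match(
    dictionary: MRFDictionary,
    measured: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> MRFMatch:
    """Dot-product matching of measured trajectories to the dictionary.

    ``measured`` is (schedule length, rows, cols).  Each pixel trajectory
    is L2-normalized (matching is therefore invariant to positive scaling)
    and assigned the grid row with the largest inner product; ties break
    to the lowest row index.  Zero-norm trajectories are invalid.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape[0] != dictionary.entries.shape[1]:
        raise ValueError("trajectory length must equal schedule length")
    rows, cols = measured.shape[1:]
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    out = {name: np.full((rows, cols), np.nan)
           for name in dictionary.param_names}
    dp_v = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)

    flat = measured.reshape(measured.shape[0], -1)
    idx = np.nonzero(mask.ravel())[0]
    if idx.size:
        traj = flat[:, idx]
        norms = np.linalg.norm(traj, axis=0)
        ok = norms > 0
        scores = dictionary.entries @ (traj[:, ok] / norms[ok])
        best = np.argmax(scores, axis=0)  # argmax takes the first maximum
        dp_best = scores[best, np.arange(best.size)]
        flat_r = idx[ok] // cols
        flat_c = idx[ok] % cols
        for j, name in enumerate(dictionary.param_names):
            out[name][flat_r, flat_c] = dictionary.grid[best, j]
        dp_v[flat_r, flat_c] = dp_best
        valid[flat_r, flat_c] = True

    units = {"kb": "1/s", "r1a": "1/s", "r2a": "1/s"}
    return MRFMatch(
        maps={
            n: PixelMap(out[n], name=n, units=units.get(n, ""),
                        valid_mask=valid)
            for n in dictionary.param_names
        },
        dp=PixelMap(dp_v, name="dot product", units="", valid_mask=valid),
    )


def schedule_from_config(entries: Sequence[dict]) -> Schedule:
    """Build a Schedule from per-image dicts of (b1_uT, tp_s, offset_ppm,
    recovery_s, flip_deg) — the schedule-file format."""
    from .bloch import SaturationEvent, ScheduleEntry

    out = []
    for e in entries:
        out.append(ScheduleEntry(
            saturation=SaturationEvent(
                b1_uT=float(e["b1_uT"]),
                duration_s=float(e["tp_s"]),
                offset_ppm=float(e.get("offset_ppm", 0.0)),
            ),
            recovery_s=float(e.get("recovery_s", 0.0)),
            flip_deg=float(e.get("flip_deg", 90.0)),
        ))
    return Schedule(out)


def scenario_from_config(cfg: dict) -> MRFScenario:
    """Build an MRFScenario from a parsed YAML/JSON scenario config."""
    return MRFScenario(
        field_MHz=float(cfg["field_MHz"]),
        r1a_grid=cfg["r1a_grid"],
        r2a_grid=cfg["r2a_grid"],
        fb_grid=cfg["fb_grid"],
        kb_grid=cfg["kb_grid"],
        solute_dw_ppm=float(cfg["solute_dw_ppm"]),
        solute_r1=float(cfg.get("solute_r1", 1.0)),
        solute_r2=float(cfg.get("solute_r2", 50.0)),
        schedule=schedule_from_config(cfg["schedule"]),
    )


def to_concentration(
    fb_map: PixelMap,
    n_protons: int,
    water_conc_M: float = 55.5,
) -> PixelMap:
    """Convert proton volume fraction to solute concentration in mM.

    concentration = fb * (2 * water_conc_M * 1000) / n_protons — the water
    proton pool is 2 protons per molecule, 111 M proton equivalents at
    55.5 M water.
    """
    if n_protons < 1:
        raise ValueError("n_protons must be >= 1")
    conc = fb_map.values * (2.0 * water_conc_M * 1000.0) / n_protons
    return PixelMap(conc, name="concentration", units="mM",
                    valid_mask=fb_map.valid_mask.copy())
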
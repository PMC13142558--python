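"""Core domain containers shared by every pipeline stage.

The central object is the :class:`OffsetImageStack` — a stack of 2D images
indexed by saturation frequency offset (the sampled Z-spectrum), together
with the far-off-resonance reference image(s) (M0) and the acquisition
parameters extracted from the scanner method file.

Sign convention: positive ppm is downfield of water (amide at +3.5 ppm);
offsets are stored relative to the nominal water frequency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Proton gyromagnetic ratio over 2*pi, in MHz/T (equivalently Hz/uT * 1e-2).
GAMMA_MHZ_PER_T = 42.577

#: Default |offset| above which a frame is treated as an M0 reference (ppm).
DEFAULT_M0_THRESHOLD_PPM = 20.0


@dataclass
class AcquisitionParams:
    """Acquisition parameters needed by the post-processing stages.

    Parameters
    ----------
    offsets_ppm : array of saturation frequency offsets, ppm from water.
    sat_b1_uT : peak CW saturation amplitude B1, microtesla.
    sat_time_s : saturation pulse time t_p, seconds.
    recovery_time_s : post-readout recovery delay, seconds.
    field_MHz : scanner proton frequency (Hz per ppm).
    readout : ``"rectilinear"`` or ``"radial"``.
    flip_angles_deg : nominal readout flip angle(s), degrees.
    tr_list_s : repetition times for a variable-TR T1 series (optional).
    b1_list_uT : per-image saturation amplitudes for QUESP/MRF schedules
        (optional).
    """

    offsets_ppm: np.ndarray = field(default_factory=lambda: np.array([]))
    sat_b1_uT: float = 0.0
    sat_time_s: float = 0.0
    recovery_time_s: float = 0.0
    field_MHz: float = 300.0
    readout: str = "rectilinear"
    flip_angles_deg: Sequence[float] = field(default_factory=lambda: (90.0,))
    tr_list_s: Optional[np.ndarray] = None
    b1_list_uT: Optional[np.ndarray] = None

    def __post_init__(self):
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.offsets_ppm.size and not np.all(np.isfinite(self.offsets_ppm)):
            raise ValueError("offsets_ppm must be finite")
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")
        if self.sat_time_s < 0:
            raise ValueError("sat_time_s must be non-negative")
        if self.sat_b1_uT < 0:
            raise ValueError("sat_b1_uT must be non-negative")
        if self.readout not in ("rectilinear", "radial"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.tr_list_s is not None:
            self.tr_list_s = np.asarray(self.tr_list_s, dtype=float)
        if self.b1_list_uT is not None:
            self.b1_list_uT = np.asarray(self.b1_list_uT, dtype=float)
            if np.any(self.b1_list_uT < 0):
                raise ValueError("b1_list_uT must be non-negative")

    def validate_quesp(self) -> None:
        """QUESP series need >= 3 distinct nonzero B1 values."""
        if self.b1_list_uT is None:
            raise ValueError("QUESP series requires b1_list_uT")
        nz = np.unique(self.b1_list_uT[self.b1_list_uT > 0])
        if nz.size < 3:
            raise ValueError(
                "QUESP series requires >= 3 distinct nonzero B1 values, "
                f"got {nz.size}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["flip_angles_deg"] = list(self.flip_angles_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        for k in ("tr_list_s", "b1_list_uT"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        if d.get("offsets_ppm") is not None:
            d["offsets_ppm"] = np.asarray(d["offsets_ppm"], dtype=float)
        return cls(**d)


@dataclass
class OffsetImageStack:
    """Stack of 2D images indexed by saturation frequency offset.

    ``data`` is (n_offsets, rows, cols) in raw signal units until
    :func:`normalize_zspectrum` divides by M0.  ``m0`` holds the reference
    image (pixelwise mean if several M0 frames were acquired).
    """

    data: np.ndarray
    offsets_ppm: np.ndarray
    params: AcquisitionParams
    m0: Optional[np.ndarray] = None
    orientation_ops: list = field(default_factory=list)
    normalized: bool = False
    frame_times_s: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (offsets, rows, cols)")
        if self.data.shape[0] != self.offsets_ppm.size:
            raise ValueError(
                f"frame count {self.data.shape[0]} does not match offset "
                f"count {self.offsets_ppm.size}"
            )

    @property
    def shape(self):
        return self.data.shape[1:]

    @property
    def n_offsets(self) -> int:
        return self.offsets_ppm.size

    def copy(self) -> "OffsetImageStack":
        return OffsetImageStack(
            data=self.data.copy(),
            offsets_ppm=self.offsets_ppm.copy(),
            params=self.params,
            m0=None if self.m0 is None else self.m0.copy(),
            orientation_ops=list(self.orientation_ops),
            normalized=self.normalized,
            frame_times_s=(
                None if self.frame_times_s is None else self.frame_times_s.copy()
            ),
        )


def normalize_zspectrum(
    stack: OffsetImageStack,
    m0_threshold_ppm: float = DEFAULT_M0_THRESHOLD_PPM,
    m0: Optional[np.ndarray] = None,
) -> OffsetImageStack:
    """Divide each frame pixelwise by M0 and drop M0 frames from the axis.

    Frames at |offset| >= ``m0_threshold_ppm`` count as M0 references;
    several are averaged pixelwise.  An explicit ``m0`` image overrides the
    threshold rule.  Offsets are returned sorted ascending.
    """
    if m0 is not None:
        m0_img = np.asarray(m0, dtype=float)
        keep = np.ones(stack.n_offsets, dtype=bool)
    else:
        is_m0 = np.abs(stack.offsets_ppm) >= m0_threshold_ppm
        if not np.any(is_m0):
            raise ValueError(
                "no M0 frame found: no offset with |offset| >= "
                f"{m0_threshold_ppm} ppm; supply an explicit m0 image or "
                "lower m0_threshold_ppm"
            )
        m0_img = stack.data[is_m0].mean(axis=0)
        keep = ~is_m0

    with np.errstate(divide="ignore", invalid="ignore"):
        z = stack.data[keep] / m0_img[None, :, :]
    z[~np.isfinite(z)] = 0.0
    offs = stack.offsets_ppm[keep]
    order = np.argsort(offs, kind="stable")
    times = None
    if stack.frame_times_s is not None:
        times = stack.frame_times_s[keep][order]
    return OffsetImageStack(
        data=z[order],
        offsets_ppm=offs[order],
        params=stack.params,
        m0=m0_img,
        orientation_ops=list(stack.orientation_ops),
        normalized=True,
        frame_times_s=times,
    )


@dataclass
class PixelMap:
    """2D parameter map with a named quantity, units, and validity mask."""

    values: np.ndarray
    name: str = ""
    units: str = ""
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid_mask is true")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class ExperimentBundle:
    """Role-tagged collection of image stacks forming one study.

    Recognised roles: ``cest``, ``wassr``, ``dam_theta``, ``dam_2theta``,
    ``t1_series``, ``quesp``, ``mrf``.
    """

    members: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    ROLES = ("cest", "wassr", "dam_theta", "dam_2theta", "t1_series", "quesp", "mrf")

    def __setitem__(self, role: str, member) -> None:
        if role not in self.ROLES:
            raise KeyError(f"unknown role {role!r}; expected one of {self.ROLES}")
        self.members[role] = member

    def __getitem__(self, role: str):
        return self.members[role]

    def __contains__(self, role: str) -> bool:
        return role in self.members

    def roles(self):
        return list(self.members)
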
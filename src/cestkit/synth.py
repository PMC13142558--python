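"""Synthetic phantom generator: every input class with known ground truth.

Fixtures emulate the study conditions the pipeline targets — a 7T
preclinical scanner (300.33 MHz proton frequency), 64x64 single-slice
matrices, creatine-vial phantoms for QUESP/fingerprinting, and a cardiac
short-axis annulus (outer radius 20 px, inner 12 px, insertion points at
180/270 degrees) for the LV workflow.  Z-spectra come either from
Lorentzian sums (fast path) or from the Bloch-McConnell propagator
(physics path).  Every fixture carries its truth table; noise is Gaussian
on the normalized signal and every draw is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import bloch
from .core import AcquisitionParams, ExperimentBundle, OffsetImageStack
from .preprocess import ProjectionSeries
from .segmentation import LVGeometry
from .zspec import lorentzian

FIELD_7T_MHZ = 300.33
DEFAULT_MATRIX = 64
M0_OFFSET_PPM = -300.0
M0_SIGNAL = 1000.0

#: default water + semisolid MT background of the Lorentzian fast path
BACKGROUND_POOLS = (
    ("water", 0.9, 1.4, 0.0),
    ("mt", 0.1, 25.0, -2.5),
)


def disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def annulus_mask(shape, center, r_outer, r_inner) -> np.ndarray:
    return disk_mask(shape, center, r_outer) & ~disk_mask(shape, center, r_inner)


@dataclass
class RegionTruth:
    """Ground truth of one phantom region."""

    solutes: List[Tuple[str, float, float, float]] = field(default_factory=list)
    # (name, amplitude, fwhm_ppm, center_ppm) for the Lorentzian fast path
    b0_ppm: float = 0.0
    kappa: float = 1.0
    t1_s: float = 1.8
    fb: float = 0.0
    kb: float = 0.0


@dataclass
class PhantomSpec:
    """Labeled layout plus per-region truth, noise level, and seed."""

    shape: Tuple[int, int] = (DEFAULT_MATRIX, DEFAULT_MATRIX)
    regions: Dict[str, np.ndarray] = field(default_factory=dict)
    truth: Dict[str, RegionTruth] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        labels = list(self.regions)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if np.any(self.regions[a] & self.regions[b]):
                    raise ValueError(f"regions {a!r} and {b!r} overlap")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def cardiac_phantom_spec(
    amide_by_segment: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[PhantomSpec, LVGeometry]:
    """Cardiac short-axis fixture: 64x64, annulus r=20/12 centered at
    (32, 32), insertion points at polar angles 180 and 270 degrees.

    With ``amide_by_segment`` the annulus is split into six angular
    sectors carrying distinct amide amplitudes, for label bookkeeping
    tests; otherwise the myocardium is homogeneous (amide A = 0.05).
    """
    shape = (DEFAULT_MATRIX, DEFAULT_MATRIX)
    center = (32.0, 32.0)
    n_poly = 72
    t = np.linspace(0, 2 * np.pi, n_poly, endpoint=False)
    epi = np.column_stack([center[1] + 20.5 * np.cos(t),
                           center[0] + 20.5 * np.sin(t)])
    endo = np.column_stack([center[1] + 11.5 * np.cos(t),
                            center[0] + 11.5 * np.sin(t)])
    # polar angle convention: x right, y up (row decreasing)
    r_mid = 16.0
    anterior = (center[1] + r_mid * np.cos(np.deg2rad(180.0)),
                center[0] - r_mid * np.sin(np.deg2rad(180.0)))
    inferior = (center[1] + r_mid * np.cos(np.deg2rad(270.0)),
                center[0] - r_mid * np.sin(np.deg2rad(270.0)))
    geom = LVGeometry(epicardium=epi, endocardium=endo,
                      anterior_insertion=anterior,
                      inferior_insertion=inferior)
    # myocardium region aligned exactly with the contour-derived LV mask
    from .segmentation import polygon_mask
    ann = polygon_mask(epi, shape) & ~polygon_mask(endo, shape)

    regions: Dict[str, np.ndarray] = {}
    truth: Dict[str, RegionTruth] = {}
    if amide_by_segment:
        rr, cc = np.nonzero(ann)
        ang = np.degrees(np.arctan2(32.0 - rr, cc - 32.0)) % 360.0
        for i in range(6):
            m = np.zeros(shape, dtype=bool)
            sel = (ang >= 60.0 * i) & (ang < 60.0 * (i + 1))
            m[rr[sel], cc[sel]] = True
            label = f"sector{i}"
            regions[label] = m
            truth[label] = RegionTruth(
                solutes=[("amide", 0.02 + 0.01 * i, 1.0, 3.5)]
            )
    else:
        regions["myocardium"] = ann
        truth["myocardium"] = RegionTruth(solutes=[("amide", 0.05, 1.0, 3.5)])
    spec = PhantomSpec(shape=shape, regions=regions, truth=truth,
                       noise_sd=noise_sd, seed=seed)
    return spec, geom


def default_offsets(n: int = 61, span_ppm: float = 6.0) -> np.ndarray:
    """Symmetric Z-spectrum offsets plus one far-off-resonance M0 frame."""
    return np.concatenate([[M0_OFFSET_PPM], np.linspace(-span_ppm, span_ppm, n)])


def _region_zspectrum_fast(truth: RegionTruth, offsets: np.ndarray) -> np.ndarray:
    dw = offsets - truth.b0_ppm
    z = np.ones_like(dw)
    for _, a, g, w in BACKGROUND_POOLS:
        z -= lorentzian(a, g, w, dw)
    for _, a, g, w in truth.solutes:
        z -= lorentzian(a, g, w, dw)
    return z


def _region_zspectrum_physics(
    truth: RegionTruth,
    offsets: np.ndarray,
    b1_uT: float,
    sat_time_s: float,
    field_MHz: float,
) -> np.ndarray:
    pools = [bloch.water_pool(r1=1.0 / truth.t1_s)]
    for name, _a, _g, w in truth.solutes or [("solute", 0, 1, 2.0)]:
        if truth.fb > 0:
            pools.append(bloch.PoolParameters(
                name, truth.fb, truth.kb, w, r1=1.0, r2=50.0,
            ))
    z = bloch.simulate_zspectrum(
        pools, offsets - truth.b0_ppm, b1_uT, sat_time_s, field_MHz
    )
    return z


def make_zspec_phantom(
    spec: PhantomSpec,
    offsets_ppm: Optional[np.ndarray] = None,
    b1_uT: float = 1.1,
    sat_time_s: float = 2.0,
    field_MHz: float = FIELD_7T_MHZ,
    physics: bool = False,
) -> Tuple[ExperimentBundle, Dict[str, RegionTruth]]:
    """Raw-unit CEST stack (M0 frames at -300 ppm) with per-region truth.

    ``physics=True`` generates spectra with the Bloch-McConnell propagator
    from (fb, kb) region truth; the default fast path sums Lorentzians.
    """
    offsets = default_offsets() if offsets_ppm is None else np.asarray(
        offsets_ppm, dtype=float)
    rng = spec.rng()
    data = np.zeros((offsets.size, *spec.shape))
    is_m0 = np.abs(offsets) >= 20.0

    for label, mask in spec.regions.items():
        truth = spec.truth[label]
        if physics:
            z = _region_zspectrum_physics(truth, offsets[~is_m0], b1_uT,
                                          sat_time_s, field_MHz)
        else:
            z = _region_zspectrum_fast(truth, offsets[~is_m0])
        full = np.ones(offsets.size)
        full[~is_m0] = z
        data[:, mask] = full[:, None]

    body = np.zeros(spec.shape, dtype=bool)
    for m in spec.regions.values():
        body |= m
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=data.shape)
        data += noise * body[None, :, :]
    data *= M0_SIGNAL

    params = AcquisitionParams(
        offsets_ppm=offsets, sat_b1_uT=b1_uT, sat_time_s=sat_time_s,
        recovery_time_s=6.0, field_MHz=field_MHz,
    )
    stack = OffsetImageStack(data=data, offsets_ppm=offsets, params=params,
                             frame_times_s=np.arange(offsets.size) * 8.0)
    bundle = ExperimentBundle(provenance={"generator": "make_zspec_phantom",
                                          "seed": spec.seed})
    bundle["cest"] = stack
    return bundle, spec.truth


def make_field_fixtures(
    spec: PhantomSpec,
    wassr_offsets: Optional[np.ndarray] = None,
    theta_nominal_deg: float = 30.0,
    tr_list_s: Optional[np.ndarray] = None,
    field_MHz: float = FIELD_7T_MHZ,
) -> ExperimentBundle:
    """WASSR stack, double-angle image pair, and variable-TR T1 series.

    WASSR dips are narrow Lorentzians centered at each region's truth B0;
    the double-angle pair follows S(theta) = sin(kappa*theta)*M0; the TR
    series follows saturation recovery with each region's truth T1.
    """
    rng = spec.rng()
    if wassr_offsets is None:
        wassr_offsets = np.concatenate([[M0_OFFSET_PPM],
                                        np.linspace(-1.0, 1.0, 33)])
    if tr_list_s is None:
        tr_list_s = np.array([0.3, 0.6, 1.0, 1.6, 2.5, 4.0, 6.5, 10.0])

    body = np.zeros(spec.shape, dtype=bool)
    for m in spec.regions.values():
        body |= m

    # WASSR
    is_m0 = np.abs(wassr_offsets) >= 20.0
    wassr = np.zeros((wassr_offsets.size, *spec.shape))
    for label, mask in spec.regions.items():
        t = spec.truth[label]
        z = 1.0 - lorentzian(0.85, 0.35, t.b0_ppm, wassr_offsets[~is_m0])
        full = np.ones(wassr_offsets.size)
        full[~is_m0] = z
        wassr[:, mask] = full[:, None]
    if spec.noise_sd > 0:
        wassr += rng.normal(0, spec.noise_sd, wassr.shape) * body[None]
    wassr *= M0_SIGNAL
    wassr_stack = OffsetImageStack(
        data=wassr, offsets_ppm=wassr_offsets,
        params=AcquisitionParams(offsets_ppm=wassr_offsets, sat_b1_uT=0.3,
                                 sat_time_s=0.5, field_MHz=field_MHz),
        frame_times_s=np.arange(wassr_offsets.size) * 8.0,
    )

    # double-angle pair
    kappa_img = np.zeros(spec.shape)
    t1_img = np.zeros(spec.shape)
    for label, mask in spec.regions.items():
        kappa_img[mask] = spec.truth[label].kappa
        t1_img[mask] = spec.truth[label].t1_s
    th = np.deg2rad(theta_nominal_deg)
    m_theta = np.sin(kappa_img * th) * M0_SIGNAL * body
    m_2theta = np.sin(kappa_img * 2 * th) * M0_SIGNAL * body
    if spec.noise_sd > 0:
        m_theta = m_theta + rng.normal(0, spec.noise_sd * M0_SIGNAL,
                                       spec.shape) * body
        m_2theta = m_2theta + rng.normal(0, spec.noise_sd * M0_SIGNAL,
                                         spec.shape) * body

    def one_frame(img, flips):
        return OffsetImageStack(
            data=img[None], offsets_ppm=np.array([0.0]),
            params=AcquisitionParams(offsets_ppm=np.array([0.0]),
                                     field_MHz=field_MHz,
                                     flip_angles_deg=flips),
        )

    # variable-TR series
    with np.errstate(divide="ignore", invalid="ignore"):
        rec = 1.0 - np.exp(-tr_list_s[:, None, None]
                           / np.where(t1_img > 0, t1_img, np.inf))
    t1_series = rec * M0_SIGNAL * body[None]
    if spec.noise_sd > 0:
        t1_series = t1_series + rng.normal(
            0, spec.noise_sd * M0_SIGNAL, t1_series.shape) * body[None]
    t1_stack = OffsetImageStack(
        data=t1_series, offsets_ppm=np.zeros(tr_list_s.size),
        params=AcquisitionParams(offsets_ppm=np.zeros(tr_list_s.size),
                                 field_MHz=field_MHz, tr_list_s=tr_list_s),
    )

    bundle = ExperimentBundle(provenance={"generator": "make_field_fixtures",
                                          "seed": spec.seed})
    bundle["wassr"] = wassr_stack
    bundle["dam_theta"] = one_frame(m_theta, (theta_nominal_deg,))
    bundle["dam_2theta"] = one_frame(m_2theta, (2 * theta_nominal_deg,))
    bundle["t1_series"] = t1_stack
    return bundle


def annulus_projection(n_samples: int, r_outer: float, r_inner: float,
                       shift: float = 0.0) -> np.ndarray:
    """Analytic parallel projection of an annulus (chord-length profile);
    identical at every view angle by circular symmetry."""
    s = np.linspace(-r_outer * 1.5, r_outer * 1.5, n_samples) - shift

    def chord(r):
        c = np.zeros_like(s)
        inside = np.abs(s) < r
        c[inside] = 2.0 * np.sqrt(r**2 - s[inside] ** 2)
        return c

    return chord(r_outer) - chord(r_inner)


def make_radial_series(
    n_offsets: int = 4,
    n_segments: int = 10,
    segment_size: int = 8,
    n_samples: int = 96,
    corrupt_segments: Sequence[Tuple[int, int]] = (),
    attenuation: float = 0.4,
    shift_px: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[ProjectionSeries, List[Tuple[int, int]]]:
    """Radial projection series with simulated respiratory corruption.

    Projections are analytic annulus chord profiles; corrupted segments
    (listed as (offset, segment) pairs) are attenuated by ``attenuation``
    and shifted by ``shift_px`` samples, mimicking diaphragm motion.
    """
    rng = np.random.default_rng(seed)
    base = annulus_projection(n_samples, 20.0, 12.0)
    corrupted = annulus_projection(n_samples, 20.0, 12.0,
                                   shift=shift_px) * (1.0 - attenuation)

    n_per_offset = n_segments * segment_size
    projections = np.empty((n_offsets * n_per_offset, n_samples))
    offsets_index = np.repeat(np.arange(n_offsets), n_per_offset)
    bad = set((int(o), int(s)) for o, s in corrupt_segments)
    row = 0
    for off in range(n_offsets):
        for seg in range(n_segments):
            profile = corrupted if (off, seg) in bad else base
            for _ in range(segment_size):
                p = profile.copy()
                if noise_sd > 0:
                    p = p + rng.normal(0, noise_sd * base.max(), n_samples)
                projections[row] = np.abs(p)
                row += 1
    series = ProjectionSeries(projections=projections,
                              segment_size=segment_size,
                              offsets_index=offsets_index)
    return series, sorted(bad)


def make_mrf_fixture(
    scenario,
    vial_truths: Sequence[Tuple[float, float, float, float]],
    shape: Tuple[int, int] = (DEFAULT_MATRIX, DEFAULT_MATRIX),
    vial_radius: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Trajectory image series from circular vials at known (fb, kb, r1a,
    r2a) truths, simulated with the Bloch-McConnell propagator.

    Returns (images, vial_masks, truth_table).
    """
    rng = np.random.default_rng(seed)
    n = len(vial_truths)
    centers = []
    cols = int(np.ceil(np.sqrt(n)))
    pitch = shape[0] / (cols + 1)
    for i in range(n):
        r = (i // cols + 1) * pitch + pitch / 2
        c = (i % cols + 1) * pitch
        centers.append((r, c))

    images = np.zeros((len(scenario.schedule), *shape))
    masks = {}
    truth_table = []
    for i, ((fb, kb, r1a, r2a), center) in enumerate(zip(vial_truths, centers)):
        pools = [bloch.PoolParameters("water", 1.0, 0.0, 0.0, r1a, r2a)]
        if fb > 0:
            pools.append(bloch.PoolParameters(
                "solute", fb, kb, scenario.solute_dw_ppm,
                scenario.solute_r1, scenario.solute_r2,
            ))
        traj = bloch.simulate_trajectory(pools, scenario.schedule,
                                         scenario.field_MHz)
        m = disk_mask(shape, center, vial_radius)
        for prev in masks.values():  # keep vials pairwise disjoint
            m &= ~prev
        images[:, m] = traj[:, None]
        masks[f"vial{i}"] = m
        truth_table.append(dict(vial=f"vial{i}", fb=fb, kb=kb,
                                r1a=r1a, r2a=r2a))
    if noise_sd > 0:
        body = np.zeros(shape, dtype=bool)
        for m in masks.values():
            body |= m
        images += rng.normal(0, noise_sd, images.shape) * body[None]
    return images, masks, truth_table
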
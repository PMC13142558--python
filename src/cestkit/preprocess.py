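"""Pre-processing: respiratory motion binning for radial acquisitions,
global PCA Z-spectral denoising, thermal drift correction, and orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import OffsetImageStack


@dataclass
class ProjectionSeries:
    """Radial projection magnitudes grouped into acquisition segments.

    ``projections`` is (n_projections, n_samples); projections are acquired
    in contiguous segments of ``segment_size``; ``offsets_index`` maps each
    projection to its frequency-offset frame.
    """

    projections: np.ndarray
    segment_size: int
    offsets_index: np.ndarray

    def __post_init__(self):
        self.projections = np.asarray(self.projections, dtype=float)
        self.offsets_index = np.asarray(self.offsets_index, dtype=int)
        if self.projections.shape[0] != self.offsets_index.size:
            raise ValueError("one offset index per projection required")
        counts = np.bincount(self.offsets_index)
        counts = counts[counts > 0]
        if np.any(counts % self.segment_size):
            raise ValueError(
                "projection count per offset must divide into whole segments"
            )

    @property
    def n_offsets(self) -> int:
        return int(self.offsets_index.max()) + 1

    def segments_of(self, offset: int) -> np.ndarray:
        """Projection row indices of each segment at one offset,
        shape (n_segments, segment_size)."""
        rows = np.nonzero(self.offsets_index == offset)[0]
        return rows.reshape(-1, self.segment_size)


@dataclass
class BinningResult:
    kept_segments: dict            # offset -> sorted list of kept segment ids
    threshold: np.ndarray          # per-segment threshold series
    moving_average: np.ndarray
    segment_sums: np.ndarray
    n_discarded_per_offset: int = 0


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # centered moving average with edge shrinkage
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def motion_bin(
    series: ProjectionSeries,
    window: int = 5,
    n_sigma: float = 1.0,
) -> BinningResult:
    """Flag respiration-corrupted acquisition segments and equalize counts.

    Segment sums (total projection magnitude per segment, in acquisition
    order) are compared against a moving average of window ``window``; a
    segment whose sum falls below (moving average − n_sigma·sd) — sd taken
    globally over the moving-average series — is flagged motion-corrupted.
    To keep quantified contrasts comparable, the same number of segments is
    then discarded at every offset: with k the largest flagged count at any
    offset, the k lowest-sum segments are dropped per offset.
    """
    n_seg_per_offset = series.segments_of(0).shape[0]
    if n_seg_per_offset < 3:
        raise ValueError("need >= 3 segments per offset")

    # per-segment sums in global acquisition order
    all_rows = []
    seg_ids = []  # (offset, local segment id)
    for off in range(series.n_offsets):
        segs = series.segments_of(off)
        for s, rows in enumerate(segs):
            all_rows.append(series.projections[rows].sum())
            seg_ids.append((off, s))
    sums = np.array(all_rows)
    ma = _moving_average(sums, window)
    sd = float(np.std(ma))
    thresh = ma - n_sigma * sd
    flagged = sums < thresh

    per_offset_flags = {off: 0 for off in range(series.n_offsets)}
    for (off, _s), f in zip(seg_ids, flagged):
        if f:
            per_offset_flags[off] += 1
    k = max(per_offset_flags.values())

    kept = {}
    for off in range(series.n_offsets):
        local = [(s, sums[i]) for i, (o, s) in enumerate(seg_ids) if o == off]
        if len(local) - k < 1:
            raise ValueError(
                f"discarding {k} segments would leave no data at offset {off}"
            )
        # drop the k lowest-sum segments at this offset
        local.sort(key=lambda t: t[1])
        kept[off] = sorted(s for s, _ in local[k:])

    return BinningResult(
        kept_segments=kept,
        threshold=thresh,
        moving_average=ma,
        segment_sums=sums,
        n_discarded_per_offset=k,
    )


def apply_binning(series: ProjectionSeries, result: BinningResult) -> ProjectionSeries:
    """Drop discarded segments; retained projection values are untouched."""
    keep_rows = []
    for off in range(series.n_offsets):
        segs = series.segments_of(off)
        for s in result.kept_segments[off]:
            keep_rows.extend(segs[s])
    keep_rows = np.array(sorted(keep_rows))
    return ProjectionSeries(
        projections=series.projections[keep_rows],
        segment_size=series.segment_size,
        offsets_index=series.offsets_index[keep_rows],
    )


def malinowski_rank(eigenvalues: np.ndarray, r: int, c: int) -> int:
    """Optimal PCA rank by Malinowski's empirical indicator function.

    IND(n) = RE(n)/(c−n)^2 with RE(n) = sqrt(sum_{j>n} λ_j / (r·(c−n))),
    minimized over n = 1..c−1; λ are eigenvalues of the data cross-product,
    r the pixel count and c the offset count.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    total = lam.sum()
    best_n, best_ind = 1, np.inf
    for n in range(1, c):
        tail = lam[n:].sum()
        if tail <= 1e-12 * total:
            # residual at the numerical floor: data are exactly rank n
            return n
        re = np.sqrt(max(tail, 0.0) / (r * (c - n)))
        ind = re / (c - n) ** 2
        if ind < best_ind:
            best_ind, best_n = ind, n
    return best_n


def pca_denoise(
    stack: OffsetImageStack,
    mask: Optional[np.ndarray] = None,
) -> tuple[OffsetImageStack, int]:
    """Global PCA denoising of the Z-spectral dimension.

    All pixels (optionally restricted to ``mask``) form a pixels×offsets
    matrix; the mean spectrum is removed, the truncation rank is chosen by
    Malinowski's empirical indicator function, and the spectra are
    reconstructed from the leading components.  Returns the denoised stack
    and the selected rank (0 for degenerate, constant data, which is
    returned unchanged).
    """
    c = stack.n_offsets
    if c < 3:
        raise ValueError("PCA denoising needs >= 3 offsets")
    rows, cols = stack.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    r = int(mask.sum())
    if r < c:
        raise ValueError(
            f"need at least as many pixels ({r}) as offsets ({c})"
        )

    X = stack.data[:, mask].T  # pixels x offsets
    mean_spec = X.mean(axis=0)
    Xc = X - mean_spec
    # eigenvalues of Xc^T Xc via SVD
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2
    if lam[0] <= 1e-12 * max(1.0, np.abs(X).max()) ** 2 * r:
        return stack.copy(), 0

    n_star = malinowski_rank(lam, r, c)
    Xrec = (U[:, :n_star] * s[:n_star]) @ Vt[:n_star] + mean_spec

    out = stack.copy()
    out.data[:, mask] = Xrec.T
    return out, n_star


def thermal_drift_correct(
    stack: OffsetImageStack,
    reference_means: Sequence[float],
    reference_times_s: Sequence[float],
    frame_times_s: Optional[np.ndarray] = None,
) -> OffsetImageStack:
    """Divide out a global multiplicative drift, linear in acquisition time.

    A least-squares line d(t) = a + b·t is fitted to the mean signal of
    time-stamped reference (M0) frames, normalized to d(t0) = 1 at the
    first reference, and each frame is divided by d at its own acquisition
    time.  With a single reference frame no correction is possible — a
    warning is issued and the stack is returned unchanged.
    """
    ref_m = np.asarray(reference_means, dtype=float)
    ref_t = np.asarray(reference_times_s, dtype=float)
    if ref_m.size < 2:
        warnings.warn("thermal drift correction needs >= 2 reference frames; "
                      "no correction applied")
        return stack.copy()
    if frame_times_s is None:
        frame_times_s = stack.frame_times_s
    if frame_times_s is None:
        raise ValueError("frame acquisition times required")
    frame_times_s = np.asarray(frame_times_s, dtype=float)

    b, a = np.polyfit(ref_t, ref_m, 1)
    d0 = a + b * ref_t[0]
    factors = (a + b * frame_times_s) / d0
    out = stack.copy()
    out.data = out.data / factors[:, None, None]
    return out


def orient(
    stack: OffsetImageStack,
    rotations_90: int = 0,
    flip_h: bool = False,
    flip_v: bool = False,
) -> OffsetImageStack:
    """Rotate (CCW, 90° steps) and/or flip all frames and M0 identically."""
    out = stack.copy()
    k = rotations_90 % 4
    if k:
        out.data = np.rot90(out.data, k=k, axes=(1, 2)).copy()
        if out.m0 is not None:
            out.m0 = np.rot90(out.m0, k=k).copy()
    if flip_h:
        out.data = out.data[:, :, ::-1].copy()
        if out.m0 is not None:
            out.m0 = out.m0[:, ::-1].copy()
    if flip_v:
        out.data = out.data[:, ::-1, :].copy()
        if out.m0 is not None:
            out.m0 = out.m0[::-1, :].copy()
    out.orientation_ops.append(
        {"rotations_90": k, "flip_h": flip_h, "flip_v": flip_v}
    )
    return out
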
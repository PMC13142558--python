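"""Pixel quality filtering and display clipping.

The filter chain removes pixels whose CEST contrast is likely corrupted by
field inhomogeneity or partial-volume dilution, in a fixed order:

1. kappa filter: discard pixels whose B1 scaling deviates from the
   dataset mean by more than ``kappa_sigma`` standard deviations
   (statistics over the dataset's valid pixels — one animal per bundle);
2. B0 filter: discard pixels with |B0 shift| above ``b0_abs_ppm`` (ppm);
3. MT filter: discard pixels with MT amplitude below ``mt_min``.

Per-step survivor counts are recorded so the attrition of each filter is
auditable and re-runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import PixelMap
from .fieldmaps import FieldMaps


@dataclass
class FilterSpec:
    kappa_sigma: float = 1.0
    b0_abs_ppm: float = 0.25
    mt_min: float = 0.02
    enabled: Dict[str, bool] = field(default_factory=lambda: {
        "kappa": True, "b0": True, "mt": True,
    })

    def __post_init__(self):
        if self.kappa_sigma <= 0 or self.b0_abs_ppm <= 0 or self.mt_min <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class FilterResult:
    valid_mask: np.ndarray
    table: pd.DataFrame           # surviving-pixel table (row, col, values)
    attrition: Dict[str, int]     # survivors after each step


def filter_pixels(
    contrasts: Dict[str, PixelMap],
    fieldmaps: FieldMaps,
    spec: Optional[FilterSpec] = None,
) -> FilterResult:
    """Apply the kappa -> B0 -> MT filter chain to aligned maps."""
    spec = spec or FilterSpec()
    maps = dict(contrasts)
    some = next(iter(maps.values()))
    mask = some.valid_mask.copy()
    for m in maps.values():
        mask &= m.valid_mask

    attrition = {"input": int(mask.sum())}

    if spec.enabled.get("kappa", True) and fieldmaps.kappa is not None:
        k = fieldmaps.kappa
        mask &= k.valid_mask
        kv = k.values[mask]
        if kv.size > 1:
            mu, sd = float(np.mean(kv)), float(np.std(kv, ddof=1))
            if sd > 0:
                keep = np.abs(k.values - mu) <= spec.kappa_sigma * sd
                mask &= keep
    attrition["kappa"] = int(mask.sum())

    if spec.enabled.get("b0", True) and fieldmaps.b0_ppm is not None:
        b0 = fieldmaps.b0_ppm
        mask &= b0.valid_mask & (np.abs(b0.values) <= spec.b0_abs_ppm)
    attrition["b0"] = int(mask.sum())

    if spec.enabled.get("mt", True) and "mt" in maps:
        mt = maps["mt"]
        mask &= mt.values >= spec.mt_min
    attrition["mt"] = int(mask.sum())

    rr, cc = np.nonzero(mask)
    cols: Dict[str, np.ndarray] = {"row": rr, "col": cc}
    for name, m in maps.items():
        cols[name] = m.values[rr, cc]
    if fieldmaps.b0_ppm is not None:
        cols["b0_ppm"] = fieldmaps.b0_ppm.values[rr, cc]
    if fieldmaps.kappa is not None:
        cols["kappa"] = fieldmaps.kappa.values[rr, cc]
    return FilterResult(valid_mask=mask, table=pd.DataFrame(cols),
                        attrition=attrition)


def percentile_clip(pmap: PixelMap, lo_pct: float, hi_pct: float) -> PixelMap:
    """Clip valid values to the [lo, hi] percentile range for display.

    Percentiles use linear interpolation between closest ranks; values
    strictly inside the range are untouched, outliers are set to the
    percentile values (clipped, not discarded).
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("need 0 <= lo < hi <= 100")
    vals = pmap.values.copy()
    vv = vals[pmap.valid_mask]
    if vv.size:
        lo = np.percentile(vv, lo_pct)
        hi = np.percentile(vv, hi_pct)
        vals[pmap.valid_mask] = np.clip(vv, lo, hi)
    return PixelMap(vals, pmap.name, pmap.units, pmap.valid_mask.copy())
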
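"""Batch pipeline: load -> orient -> (denoise) -> (drift) -> normalize ->
segment -> fit/map -> filter -> report, driven by one YAML/JSON config.

Every stage writes its parameters into a manifest so a run is auditable
and re-running a config (with its seed) is bit-identical.  Stage failures
abort with the stage name and the offending input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .core import ExperimentBundle, normalize_zspectrum
from .fieldmaps import FieldMaps, dam_b1, segment_field_stats, t1_map, wassr_b0
from .filters import FilterSpec, filter_pixels
from .io import load_bundle, write_archive, write_map_png, write_segment_table
from .preprocess import orient, pca_denoise, thermal_drift_correct
from .segmentation import LVGeometry, lv_segments, polygon_mask, SegmentSet
from .zspec import FitConfig, fit_pixelwise, fit_segmentwise


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text)
    return dict(config)


def _segments_from_config(cfg: dict, shape) -> Optional[SegmentSet]:
    seg_cfg = cfg.get("segmentation") or {}
    kind = seg_cfg.get("kind", "none")
    if kind == "none":
        return None
    if kind == "lv":
        geom = LVGeometry.from_json(Path(seg_cfg["geometry"]).read_text())
        return lv_segments(geom, shape)
    if kind == "manual":
        rois = json.loads(Path(seg_cfg["rois"]).read_text())
        masks = {label: polygon_mask(np.asarray(v), shape)
                 for label, v in rois.items()}
        return SegmentSet(masks=masks, kind="manual")
    raise StageError("segment", f"unknown segmentation kind {kind!r}")


def run_pipeline(config, out_dir=None) -> Path:
    """Execute the configured stages over one experiment bundle.

    Returns the path of the zipped results archive.  See the package
    docs for the config schema (version 1).
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: Dict[str, object] = {
        "config_schema": 1,
        "version": __version__,
        "seed": seed,
        "stages": {},
    }

    # ---- load
    try:
        bundle: ExperimentBundle = load_bundle(cfg["bundle"])
    except Exception as e:  # noqa: BLE001 - report the stage and input
        raise StageError("load", f"{cfg.get('bundle')}: {e}") from e
    manifest["stages"]["load"] = {"bundle": str(cfg["bundle"]),
                                  "roles": bundle.roles()}

    # ---- orient
    ocfg = cfg.get("orient") or {}
    if ocfg:
        for role in bundle.roles():
            bundle.members[role] = orient(
                bundle[role],
                rotations_90=int(ocfg.get("rotations_90", 0)),
                flip_h=bool(ocfg.get("flip_h", False)),
                flip_v=bool(ocfg.get("flip_v", False)),
            )
        manifest["stages"]["orient"] = ocfg

    segments = None
    contrasts = None
    fieldmaps = FieldMaps()
    tables: Dict[str, dict] = {}

    # ---- CEST branch
    if "cest" in bundle:
        stack = bundle["cest"]
        if cfg.get("drift_correct", False):
            try:
                times = stack.frame_times_s
                is_m0 = np.abs(stack.offsets_ppm) >= 20.0
                ref_means = [stack.data[i].mean()
                             for i in np.nonzero(is_m0)[0]]
                ref_times = times[is_m0]
                stack = thermal_drift_correct(stack, ref_means, ref_times)
                manifest["stages"]["drift"] = {"n_refs": len(ref_means)}
            except Exception as e:
                raise StageError("drift", str(e)) from e
        try:
            stack = normalize_zspectrum(stack)
        except Exception as e:
            raise StageError("normalize", str(e)) from e
        if cfg.get("denoise", False):
            stack, rank = pca_denoise(stack)
            manifest["stages"]["denoise"] = {"rank": rank}

        segments = _segments_from_config(cfg, stack.shape)
        pools = tuple(cfg.get("pools", ("amide",)))
        fit_cfg = FitConfig()

        if segments is not None:
            seg_fits = fit_segmentwise(stack, segments, pools, fit_cfg)
            for label, f in seg_fits.items():
                tables.setdefault(label, {}).update(
                    {f"{k}_amplitude": v for k, v in f.contrasts().items()}
                )
                tables[label]["mt_amplitude"] = f.pools["mt"].A
                tables[label]["b0_shift_ppm"] = f.b0_shift_ppm
                tables[label]["rmse_step1"] = f.rmse_step1
                tables[label]["rmse_step2"] = f.rmse_step2
        if cfg.get("pixelwise", True):
            mask = segments.union() if segments is not None else None
            contrasts = fit_pixelwise(stack, mask, pools, fit_cfg)
        manifest["stages"]["zspec"] = {"pools": list(pools)}

    # ---- field-map branch
    if "wassr" in bundle:
        wstack = normalize_zspectrum(bundle["wassr"])
        if segments is None and "cest" not in bundle:
            segments = _segments_from_config(cfg, wstack.shape)
        wmask = segments.union() if segments is not None else None
        fieldmaps.b0_ppm = wassr_b0(wstack, mask=wmask)
        manifest["stages"]["wassr"] = {"n_offsets": wstack.n_offsets}
    if "dam_theta" in bundle and "dam_2theta" in bundle:
        th = bundle["dam_theta"]
        fieldmaps.kappa = dam_b1(
            th.data[0], bundle["dam_2theta"].data[0],
            theta_nominal_deg=float(th.params.flip_angles_deg[0]),
        )
        manifest["stages"]["b1map"] = {
            "theta_nominal_deg": float(th.params.flip_angles_deg[0])
        }
    if "t1_series" in bundle:
        ts = bundle["t1_series"]
        fieldmaps.t1_s = t1_map(ts.data, ts.params.tr_list_s)
        manifest["stages"]["t1map"] = {"n_tr": int(ts.params.tr_list_s.size)}

    # ---- filter + report
    if contrasts is not None:
        fcfg = cfg.get("filters") or {}
        spec = FilterSpec(
            kappa_sigma=float(fcfg.get("kappa_sigma", 1.0)),
            b0_abs_ppm=float(fcfg.get("b0_abs_ppm", 0.25)),
            mt_min=float(fcfg.get("mt_min", 0.02)),
        )
        # prefer the WASSR B0 map; fall back to the fitted water shift
        fm = FieldMaps(
            b0_ppm=fieldmaps.b0_ppm or contrasts.get("b0_shift"),
            kappa=fieldmaps.kappa,
            t1_s=fieldmaps.t1_s,
        )
        result = filter_pixels(
            {k: v for k, v in contrasts.items()
             if k not in ("rmse_step1", "rmse_step2", "b0_shift")},
            fm, spec,
        )
        result.table.to_csv(out / "surviving_pixels.csv", index=False,
                            float_format="%.8g")
        manifest["stages"]["filter"] = {
            "spec": {"kappa_sigma": spec.kappa_sigma,
                     "b0_abs_ppm": spec.b0_abs_ppm, "mt_min": spec.mt_min},
            "attrition": result.attrition,
        }

    if tables:
        write_segment_table(tables, out / "segment_contrasts.csv")
    if segments is not None and (fieldmaps.b0_ppm is not None
                                 or fieldmaps.kappa is not None):
        stats = segment_field_stats(fieldmaps, segments)
        stats.to_csv(out / "segment_fieldmaps.csv", index=False,
                     float_format="%.8g")

    arrays: Dict[str, np.ndarray] = {}
    if contrasts is not None:
        for name, pmap in contrasts.items():
            arrays[f"contrast__{name}"] = pmap.values
            write_map_png(pmap, out / f"map_{name}.png")
        arrays["contrast__valid"] = next(iter(contrasts.values())).valid_mask
    for attr in ("b0_ppm", "kappa", "t1_s"):
        pmap = getattr(fieldmaps, attr)
        if pmap is not None:
            arrays[f"fieldmap__{attr}"] = pmap.values
            arrays[f"fieldmap__{attr}__valid"] = pmap.valid_mask
            write_map_png(pmap, out / f"map_{attr}.png")
    if segments is not None:
        for label, m in segments:
            arrays[f"segment__{label}"] = m
    if arrays:
        np.savez(out / "maps.npz", **arrays)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    archive = Path(cfg.get("archive", out / "results.zip"))
    write_archive(out, archive)
    return archive
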
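"""Readers and writers.

Two input layouts are supported:

- ParaVision-style experiment directories: a JCAMP-DX ``method`` text file
  plus a raw reconstructed image block whose dimensions follow from the
  parameters.  Parameter-key names are resolved through a configurable key
  map whose defaults target the PV6/7 MT-module dialect; an unknown
  dialect fails loudly instead of guessing.
- Portable bundles: one ``.npz`` container of named arrays plus one JSON
  sidecar of acquisition parameters, so the full pipeline runs without the
  Bruker layout.

Outputs are CSV tables (RFC-4180 via pandas), per-map PNG/array exports,
and a zipped results archive.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import AcquisitionParams, ExperimentBundle, OffsetImageStack

#: logical name -> JCAMP-DX key, PV6/7 MT-module dialect
DEFAULT_KEY_MAP = {
    "offsets_ppm": "PVM_SatTransFreqValues",
    "sat_b1_uT": "PVM_SatTransPulseAmpl",
    "sat_time_s": "PVM_SatTransPulseTime",
    "recovery_time_s": "PVM_RecoveryTime",
    "field_MHz": "PVM_FrqRef",
    "flip_angles_deg": "PVM_ExcPulseAngle",
    "matrix": "PVM_Matrix",
    "tr_list_s": "MultiRepTime",
    "b1_list_uT": "PVM_SatTransPulseAmplList",
    "readout": "PVM_ReadoutMode",
}

METHOD_FILE = "method"
IMAGE_FILE = "2dseq"
IMAGE_DTYPE = "<f8"


def parse_jcamp(text: str) -> Dict[str, object]:
    """Minimal JCAMP-DX parameter parser.

    Handles ``##$KEY=value`` scalars, ``##$KEY=( n )`` followed by
    whitespace-separated numeric values on continuation lines, and string
    values in angle brackets.  Unknown constructs are kept as raw strings;
    unparseable-but-unused keys are simply ignored downstream.
    """
    params: Dict[str, object] = {}
    key = None
    buf: list = []
    expect = 0

    def flush():
        nonlocal key, buf, expect
        if key is not None:
            params[key] = np.array(buf, dtype=float) if expect else None
        key, buf, expect = None, [], 0

    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("##"):
            flush()
            if not line.startswith("##$"):
                continue
            name, _, val = line[3:].partition("=")
            val = val.strip()
            if val.startswith("(") and val.endswith(")"):
                key = name
                expect = 1
                buf = []
            elif val.startswith("<") and val.endswith(">"):
                params[name] = val[1:-1]
            else:
                try:
                    params[name] = float(val)
                except ValueError:
                    params[name] = val
        elif expect and key is not None:
            for tok in line.split():
                try:
                    buf.append(float(tok))
                except ValueError:
                    buf.append(np.nan)
    flush()
    return params


def format_jcamp(params: Dict[str, object]) -> str:
    lines = ["##TITLE=cestkit fixture", "##JCAMPDX=4.24"]
    for k, v in params.items():
        if isinstance(v, str):
            lines.append(f"##${k}=<{v}>")
        elif np.ndim(v) == 0:
            lines.append(f"##${k}={float(v):.10g}")
        else:
            arr = np.asarray(v, dtype=float).ravel()
            lines.append(f"##${k}=( {arr.size} )")
            lines.append(" ".join(f"{x:.10g}" for x in arr))
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def write_fixture_experiment(
    path,
    data: np.ndarray,
    params: AcquisitionParams,
    key_map: Optional[Dict[str, str]] = None,
) -> Path:
    """Write a ParaVision-style fixture directory (method + image block).

    Image data is stored as little-endian float64, frame-major, row-major
    within a frame; frame count and matrix size are recoverable from the
    method file.
    """
    key_map = key_map or DEFAULT_KEY_MAP
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data, dtype=float)
    jc: Dict[str, object] = {
        key_map["offsets_ppm"]: params.offsets_ppm,
        key_map["sat_b1_uT"]: params.sat_b1_uT,
        key_map["sat_time_s"]: params.sat_time_s,
        key_map["recovery_time_s"]: params.recovery_time_s,
        key_map["field_MHz"]: params.field_MHz,
        key_map["flip_angles_deg"]: np.asarray(params.flip_angles_deg),
        key_map["matrix"]: np.array(data.shape[1:], dtype=float),
        key_map["readout"]: params.readout,
    }
    if params.tr_list_s is not None:
        jc[key_map["tr_list_s"]] = params.tr_list_s
    if params.b1_list_uT is not None:
        jc[key_map["b1_list_uT"]] = params.b1_list_uT
    (path / METHOD_FILE).write_text(format_jcamp(jc))
    data.astype(IMAGE_DTYPE).tofile(path / IMAGE_FILE)
    return path


def read_paravision_experiment(
    path,
    role: str = "cest",
    key_map: Optional[Dict[str, str]] = None,
) -> OffsetImageStack:
    """Read one ParaVision-style experiment directory into an image stack.

    Raises FileNotFoundError when the parameter file is absent ("not a
    ParaVision experiment") and ValueError on a frame-count / offset-count
    mismatch, naming both counts.
    """
    key_map = key_map or DEFAULT_KEY_MAP
    path = Path(path)
    method = path / METHOD_FILE
    if not method.exists():
        raise FileNotFoundError(
            f"{path} is not a ParaVision experiment: no {METHOD_FILE!r} file"
        )
    jc = parse_jcamp(method.read_text())

    def get(logical, default=None, required=False):
        k = key_map[logical]
        if k not in jc:
            if required:
                raise KeyError(
                    f"parameter {k!r} (for {logical}) missing from method "
                    "file; unknown ParaVision dialect?"
                )
            return default
        return jc[k]

    matrix = np.asarray(get("matrix", required=True), dtype=int)
    rows, cols = int(matrix[0]), int(matrix[1])
    offsets = np.asarray(get("offsets_ppm", np.array([])), dtype=float)

    img_file = path / IMAGE_FILE
    if not img_file.exists():
        raise FileNotFoundError(f"no image block {IMAGE_FILE!r} in {path}")
    flat = np.fromfile(img_file, dtype=IMAGE_DTYPE)
    n_frames = flat.size // (rows * cols)
    if n_frames * rows * cols != flat.size:
        raise ValueError("image block size is not a whole number of frames")
    data = flat.reshape(n_frames, rows, cols)

    tr_list = get("tr_list_s")
    if role == "t1_series":
        axis = np.zeros(n_frames)
    else:
        axis = offsets
    if axis.size != n_frames:
        raise ValueError(
            f"offset count {axis.size} does not match frame count {n_frames}"
        )

    flips = get("flip_angles_deg", np.array([90.0]))
    params = AcquisitionParams(
        offsets_ppm=offsets,
        sat_b1_uT=float(get("sat_b1_uT", 0.0)),
        sat_time_s=float(get("sat_time_s", 0.0)),
        recovery_time_s=float(get("recovery_time_s", 0.0)),
        field_MHz=float(get("field_MHz", 300.0)),
        readout=str(get("readout", "rectilinear")),
        flip_angles_deg=tuple(np.atleast_1d(flips).tolist()),
        tr_list_s=None if tr_list is None else np.asarray(tr_list, dtype=float),
        b1_list_uT=get("b1_list_uT"),
    )
    return OffsetImageStack(data=data, offsets_ppm=axis, params=params)


# ---------------------------------------------------------------- bundles

def save_bundle(bundle: ExperimentBundle, path) -> Path:
    """Write a portable bundle: ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    arrays: Dict[str, np.ndarray] = {}
    sidecar: Dict[str, dict] = {"provenance": bundle.provenance, "members": {}}
    for role, stack in bundle.members.items():
        arrays[f"{role}__data"] = stack.data
        arrays[f"{role}__offsets"] = stack.offsets_ppm
        if stack.m0 is not None:
            arrays[f"{role}__m0"] = stack.m0
        if stack.frame_times_s is not None:
            arrays[f"{role}__times"] = stack.frame_times_s
        sidecar["members"][role] = {
            "params": stack.params.to_dict(),
            "normalized": stack.normalized,
            "orientation_ops": stack.orientation_ops,
        }
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_bundle(path) -> ExperimentBundle:
    path = Path(path)
    npz = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    bundle = ExperimentBundle(provenance=sidecar.get("provenance", {}))
    for role, meta in sidecar["members"].items():
        stack = OffsetImageStack(
            data=npz[f"{role}__data"],
            offsets_ppm=npz[f"{role}__offsets"],
            params=AcquisitionParams.from_dict(meta["params"]),
            m0=npz[f"{role}__m0"] if f"{role}__m0" in npz else None,
            orientation_ops=meta.get("orientation_ops", []),
            normalized=meta.get("normalized", False),
            frame_times_s=(npz[f"{role}__times"]
                           if f"{role}__times" in npz else None),
        )
        bundle[role] = stack
    return bundle


# ----------------------------------------------------------------- tables

def write_segment_table(fits: Dict[str, Dict[str, float]], path) -> Path:
    """Per-segment results table: one row per segment, one column per
    fitted quantity, >= 6 significant digits."""
    path = Path(path)
    rows = []
    for label, quantities in fits.items():
        rows.append({"segment": label, **quantities})
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["segment"])
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def write_map_png(pmap, path, lo_pct: float = 0.0, hi_pct: float = 100.0):
    """Advisory PNG export of a parameter map (numerics live in the npz)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = pmap.values.copy()
    vals[~pmap.valid_mask] = np.nan
    finite = vals[np.isfinite(vals)]
    vmin = np.percentile(finite, lo_pct) if finite.size else 0
    vmax = np.percentile(finite, hi_pct) if finite.size else 1
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(vals, vmin=vmin, vmax=vmax, cmap="viridis")
    ax.set_title(f"{pmap.name} {('(' + pmap.units + ')') if pmap.units else ''}")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def write_archive(results_dir, zip_path) -> Path:
    """Zip a results directory (images, plots, raw processed arrays)."""
    results_dir = Path(results_dir)
    zip_path = Path(zip_path)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in sorted(results_dir.rglob("*")):
            if f.is_file() and f.resolve() != zip_path.resolve():
                zf.write(f, f.relative_to(results_dir))
    return zip_path
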
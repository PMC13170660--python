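"""On-disk formats: trace CSV, multi-page TIFF image bundles, ROI masks, JSON.

Conventions
-----------
* Trace CSV: comma-separated, UTF-8, '.' decimal, mandatory header.  First
  column ``time_s``, one column per ROI named by its identifier.
* Image bundle: multi-page TIFF (one page per channel) plus a sidecar JSON
  manifest mapping channel role → page index (and optional pixel size).
* ROI masks: either a 2-page TIFF (page 0 soma, page 1 nucleus, non-zero =
  inside) or a polygon JSON ``{"shape": [H, W], "soma": [[r, c], ...],
  "nucleus": [[r, c], ...]}`` with 0-based row/column pixel coordinates,
  origin top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon as draw_polygon

from .binding import BindingCurve
from .exceptions import FormatError, InvalidRoiError
from .images import LabeledImage, RoiSet
from .traces import FluorescenceTraceSet

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_image_bundle",
    "read_image_bundle",
    "write_roi_masks",
    "read_roi_masks",
    "read_binding_csv",
    "write_binding_csv",
    "write_json",
    "read_json",
]


def write_trace_csv(traces: FluorescenceTraceSet, path) -> None:
    df = pd.DataFrame(traces.F.T, columns=traces.roi_ids)
    df.insert(0, "time_s", traces.times)
    df.to_csv(path, index=False)


def read_trace_csv(path, group_label: str = "", timepoint_label: str = "") -> FluorescenceTraceSet:
    """Read a trace CSV; the sampling rate is inferred from the time column."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise FormatError(f"{path.name}: need a time column, >=1 ROI column and >=2 frames")
    first = df.columns[0]
    if first not in ("time_s", "frame"):
        raise FormatError(f"{path.name}: first column must be 'time_s' or 'frame', got {first!r}")
    # pandas mangles duplicate headers ("a", "a.1"), so check the raw header line
    with open(path, encoding="utf-8") as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
    roi_ids = header[1:]
    if len(set(roi_ids)) != len(roi_ids):
        dupes = sorted({r for r in roi_ids if roi_ids.count(r) > 1})
        raise FormatError(f"{path.name}: duplicated ROI id(s) {dupes}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad_rows = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
        raise FormatError(f"{path.name}: non-finite value at data row {int(bad_rows[0])}")
    tcol = df.iloc[:, 0].to_numpy(dtype=float)
    if first == "time_s":
        dt = np.diff(tcol)
        if np.any(dt <= 0):
            raise FormatError(f"{path.name}: time column must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = 1.0  # frame-indexed: 1 Hz placeholder; caller may override
    return FluorescenceTraceSet(
        F=values.T, sampling_rate=fs, roi_ids=roi_ids,
        group_label=group_label, timepoint_label=timepoint_label,
    )


def write_image_bundle(image: LabeledImage, tiff_path, manifest_path) -> None:
    roles = list(image.channels)
    pages = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    manifest = {"channels": {role: i for i, role in enumerate(roles)}}
    if image.pixel_size is not None:
        manifest["pixel_size_um"] = image.pixel_size
    Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def read_image_bundle(tiff_path, manifest_path, required_roles=()) -> LabeledImage:
    """Load a multi-page TIFF keyed by the manifest's channel roles."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest_path.name}: invalid JSON manifest") from exc
    if "channels" not in manifest:
        raise FormatError(f"{manifest_path.name}: manifest lacks a 'channels' mapping")
    mapping = manifest["channels"]
    for role in required_roles:
        if role not in mapping:
            raise FormatError(f"manifest lacks required channel role {role!r}")
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {}
    for role, page in mapping.items():
        if not 0 <= int(page) < stack.shape[0]:
            raise FormatError(f"manifest maps {role!r} to page {page} but TIFF has {stack.shape[0]} pages")
        channels[role] = np.asarray(stack[int(page)], dtype=float)
    return LabeledImage(channels=channels, pixel_size=manifest.get("pixel_size_um"))


def write_roi_masks(rois: RoiSet, path) -> None:
    """2-page uint16 TIFF: page 0 soma, page 1 nucleus (non-zero = inside)."""
    stack = np.stack([rois.soma_mask, rois.nucleus_mask]).astype(np.uint16)
    tifffile.imwrite(path, stack)


def read_roi_masks(path, image_shape=None, provenance: str = "manual") -> RoiSet:
    """Read ROI masks from a 2-page TIFF or a polygon JSON file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            spec = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path.name}: invalid polygon JSON") from exc
        for key in ("shape", "soma", "nucleus"):
            if key not in spec:
                raise FormatError(f"{path.name}: polygon JSON lacks {key!r}")
        shape = tuple(spec["shape"])
        masks = {}
        for key in ("soma", "nucleus"):
            pts = np.asarray(spec[key], dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise FormatError(f"{path.name}: {key} polygon needs >= 3 [row, col] points")
            rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=shape)
            m = np.zeros(shape, dtype=bool)
            m[rr, cc] = True
            masks[key] = m
        rois = RoiSet(soma_mask=masks["soma"], nucleus_mask=masks["nucleus"], provenance=provenance)
    else:
        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise FormatError(f"{path.name}: mask TIFF needs 2 pages (soma, nucleus)")
        rois = RoiSet(soma_mask=stack[0] > 0, nucleus_mask=stack[1] > 0, provenance=provenance)
    if image_shape is not None and rois.soma_mask.shape != tuple(image_shape):
        raise InvalidRoiError(
            f"mask shape {rois.soma_mask.shape} does not match image shape {tuple(image_shape)}"
        )
    return rois


def write_binding_csv(curve: BindingCurve, path) -> None:
    df = pd.DataFrame({"concentration": curve.concentrations, "mfi": curve.mfi})
    if curve.replicate is not None:
        df["replicate"] = curve.replicate
    df.to_csv(path, index=False)


def read_binding_csv(path, concentration_unit: str = "ug/ml") -> BindingCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    for col in ("concentration", "mfi"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return BindingCurve(
        concentrations=df["concentration"].to_numpy(dtype=float),
        mfi=df["mfi"].to_numpy(dtype=float),
        replicate=rep,
        concentration_unit=concentration_unit,
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
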
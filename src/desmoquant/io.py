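"""Plain-text / TIFF interchange formats.

Images are written as single-channel TIFF (16-bit) or PNG with ground truth
as a JSON sidecar (same basename, ``.truth.json``).  Force curves are
3-column TSV (``z_nm``, ``force_pN``, ``sweep``); force maps are a
directory of curve TSVs plus a ``map.json`` holding grid shape, spacing and
the run-length-encoded border-stripe mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .afm import AcquisitionParams, ForceDistanceCurve, ForceMap
from .core import CellLabelMask, IntensityImage


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def write_image(path, image, truth=None) -> None:
    """Write an image as 16-bit TIFF or PNG; optional ``.truth.json`` sidecar."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if isinstance(image, IntensityImage):
        arr, meta = image.pixels, {"pixel_size_um": image.pixel_size_um}
    elif isinstance(image, CellLabelMask):
        arr, meta = image.labels, {}
    else:
        arr, meta = np.asarray(image), {}
    if arr.dtype == bool:
        out = arr.astype(np.uint16) * np.uint16(65535)
    elif np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.uint16)
    else:
        out = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out, metadata=meta or None)
    else:
        iio.imwrite(path, out)
    if truth is not None:
        sidecar = path.with_suffix("").with_suffix(".truth.json")
        sidecar.write_text(json.dumps(_jsonable(truth), indent=1))


def read_image(path, pixel_size_um: float | None = None):
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if pixel_size_um is None:
        from .core import DEFAULT_PIXEL_SIZE_UM

        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
    return IntensityImage(np.asarray(arr, dtype=float), pixel_size_um)


def read_label_mask(path) -> CellLabelMask:
    import tifffile

    return CellLabelMask(np.asarray(tifffile.imread(Path(path))).astype(np.int32))


# --------------------------------------------------------------------------
# force curves and maps
# --------------------------------------------------------------------------

def write_curve_tsv(path, curve: ForceDistanceCurve) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("z_nm\tforce_pN\tsweep\n")
        for z, f in zip(curve.z_nm, curve.force_pN):
            fh.write(f"{z:.6g}\t{f:.6g}\t{curve.sweep}\n")


def read_curve_tsv(path, meta: AcquisitionParams | None = None) -> ForceDistanceCurve:
    data = np.genfromtxt(Path(path), delimiter="\t", names=True, dtype=None,
                         encoding="utf-8")
    sweep = str(np.atleast_1d(data["sweep"])[0])
    return ForceDistanceCurve(
        z_nm=np.atleast_1d(data["z_nm"]).astype(float),
        force_pN=np.atleast_1d(data["force_pN"]).astype(float),
        sweep=sweep, meta=meta or AcquisitionParams(),
    )


def _rle_encode(mask: np.ndarray) -> list:
    flat = np.asarray(mask, dtype=bool).ravel()
    runs, start = [], 0
    while start < len(flat):
        val = flat[start]
        end = start
        while end < len(flat) and flat[end] == val:
            end += 1
        runs.append([int(val), end - start])
        start = end
    return runs


def _rle_decode(runs: list, shape) -> np.ndarray:
    flat = np.concatenate([np.full(n, bool(v)) for v, n in runs]) if runs else np.zeros(0, bool)
    return flat.reshape(shape)


def write_force_map(directory, fmap: ForceMap) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, cols = fmap.shape
    for r in range(rows):
        for c in range(cols):
            write_curve_tsv(directory / f"curve_{r:03d}_{c:03d}.tsv", fmap.curves[r][c])
    meta = {
        "grid_shape": [rows, cols],
        "spacing_um": fmap.spacing_um,
        "junction_mask_rle": _rle_encode(fmap.junction_mask),
    }
    (directory / "map.json").write_text(json.dumps(meta, indent=1))


def read_force_map(directory) -> ForceMap:
    directory = Path(directory)
    meta = json.loads((directory / "map.json").read_text())
    rows, cols = meta["grid_shape"]
    curves = [[read_curve_tsv(directory / f"curve_{r:03d}_{c:03d}.tsv")
               for c in range(cols)] for r in range(rows)]
    mask = _rle_decode(meta["junction_mask_rle"], (rows, cols))
    return ForceMap(curves=curves, spacing_um=float(meta["spacing_um"]),
                    junction_mask=mask)
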
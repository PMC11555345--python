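"""Cube container, mask and table I/O.

A hyperspectral cube is stored as a plain ``.npy`` binary array next to a
JSON sidecar (same stem, ``.json``) describing the wavenumber axis, pixel
size, axes order and mode.  Masks travel as single-channel TIFF with
integer label codes (0 background, 1 cytoplasm, 2 nucleoplasm,
3 nucleolus); tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from carsense.cube import CANONICAL_AXES, HyperspectralCube


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: HyperspectralCube, path) -> Path:
    """Write cube data (.npy) plus JSON sidecar; returns the data path."""
    path = Path(path).with_suffix(".npy")
    np.save(path, cube.data)
    sidecar = {
        "axis_cm1": cube.axis_cm1.tolist(),
        "pixel_size_um": cube.pixel_size_um,
        "axes_order": CANONICAL_AXES,
        "mode": cube.mode,
        "meta": _jsonable(cube.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`, normalising axes order."""
    path = Path(path).with_suffix(".npy")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("axis_cm1", "pixel_size_um", "axes_order", "mode"):
        if key not in sidecar:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    data = np.load(path)
    order = [s.strip() for s in sidecar["axes_order"].split(",")]
    if sorted(order) != ["nu", "x", "y"]:
        raise ValueError(f"sidecar field 'axes_order' invalid: {sidecar['axes_order']!r}")
    data = np.transpose(data, [order.index(ax) for ax in ("y", "x", "nu")])
    axis = np.asarray(sidecar["axis_cm1"], dtype=float)
    if axis.size != data.shape[2]:
        raise ValueError(
            f"sidecar field 'axis_cm1' length {axis.size} does not match spectral "
            f"dimension {data.shape[2]}"
        )
    return HyperspectralCube(
        data=data,
        axis_cm1=axis,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        mode=sidecar["mode"],
        meta=sidecar.get("meta", {}),
    )


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.int32))
    return path


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def write_image(image: np.ndarray, path) -> Path:
    """32-bit float TIFF for value images, 8-bit for RGB renderings."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        tifffile.imwrite(path, arr)
    else:
        tifffile.imwrite(path, arr.astype(np.float32))
    return path
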
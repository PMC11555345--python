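"""Senescence indicator maps: the beta-sheet ratio and subtraction images.

From the per-pixel integrated band intensities g1 (alpha-helix/lipid) and
g2 (beta-sheet), two indicators are mapped: the occupancy ratio
g2/(g1+g2) in [0, 1] and the signed difference g2-g1, which tracks the
amount of beta-sheet in amyloid-like aggregates.  Pixels whose ratio falls
at or below a tiny display threshold (default 1e-19, i.e. effectively
zero beta signal) or whose denominator vanishes are flagged invalid and
excluded from statistics; they are rendered in a reserved colour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from carsense.amide import AmideFitMaps

#: Ratio values at or below this are displayed as invalid (dark purple).
RATIO_MASK_THRESHOLD = 1e-19


@dataclass
class IndicatorMaps:
    """Ratio image in [0,1], subtraction image, masks and display scale."""

    ratio: np.ndarray
    ratio_invalid: np.ndarray
    subtraction: np.ndarray | None = None
    subtraction_scale: float | None = None
    scaling_region: str | None = None
    meta: dict = field(default_factory=dict)


def _check_g(fitmaps: AmideFitMaps) -> None:
    for name, g in (("g0", fitmaps.g0), ("g1", fitmaps.g1), ("g2", fitmaps.g2)):
        if np.any(g < 0):
            raise ValueError(f"{name} contains negative values; upstream fit contract violated")


def ratio_map(fitmaps: AmideFitMaps, mask_threshold: float = RATIO_MASK_THRESHOLD) -> IndicatorMaps:
    """Per-pixel beta-sheet occupancy ratio g2/(g1+g2) with validity mask.

    Invalid pixels are those with ratio <= ``mask_threshold``, zero
    denominator, or a non-converged fit.
    """
    _check_g(fitmaps)
    denom = fitmaps.g1 + fitmaps.g2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, fitmaps.g2 / np.where(denom > 0, denom, 1.0), 0.0)
    invalid = (denom <= 0) | (ratio <= mask_threshold) | (~fitmaps.converged)
    return IndicatorMaps(
        ratio=ratio,
        ratio_invalid=invalid,
        meta={"mask_threshold": mask_threshold},
    )


def subtraction_map(
    fitmaps: AmideFitMaps,
    scaling_region_mask: np.ndarray,
    maps: IndicatorMaps | None = None,
) -> IndicatorMaps:
    """Signed g2-g1 image scaled for display by the perinuclear variance.

    ``scaling_region_mask`` selects the pixels "around the cell nucleus"
    whose standard deviation sets the display scale (rendered with
    diverging limits at +/- 3 scale units: blue = beta-sheet-rich, red =
    alpha-helix-rich).  Stored values are the unscaled differences.
    """
    _check_g(fitmaps)
    scaling_region_mask = np.asarray(scaling_region_mask, dtype=bool)
    if scaling_region_mask.shape != fitmaps.g1.shape:
        raise ValueError("scaling region mask shape mismatch")
    if not scaling_region_mask.any():
        raise ValueError("scaling region mask is empty")
    sub = fitmaps.g2 - fitmaps.g1
    scale = float(np.std(sub[scaling_region_mask]))
    if scale == 0.0:
        scale = 1.0  # degenerate flat region: unit fallback
    if maps is None:
        maps = ratio_map(fitmaps)
    maps.subtraction = sub
    maps.subtraction_scale = scale
    maps.scaling_region = "perinuclear"
    return maps


def perinuclear_ring(nucleus_mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Morphological ring of ``width`` pixels just outside the nucleus mask."""
    from scipy.ndimage import binary_dilation

    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    dilated = binary_dilation(nucleus_mask, iterations=width)
    return dilated & ~nucleus_mask


def render_ratio(maps: IndicatorMaps) -> np.ndarray:
    """8-bit RGB rendering of the ratio map; invalid pixels in dark purple."""
    import matplotlib.cm as cm

    rgba = cm.viridis(np.clip(maps.ratio, 0.0, 1.0))
    rgb = (rgba[:, :, :3] * 255).astype(np.uint8)
    rgb[maps.ratio_invalid] = (48, 0, 48)
    return rgb


def render_subtraction(maps: IndicatorMaps, n_sigma: float = 3.0) -> np.ndarray:
    """8-bit RGB diverging rendering of g2-g1 at +/- n_sigma display scale."""
    import matplotlib.cm as cm

    if maps.subtraction is None or maps.subtraction_scale is None:
        raise ValueError("subtraction map not computed")
    lim = n_sigma * maps.subtraction_scale
    normed = np.clip((maps.subtraction + lim) / (2 * lim), 0.0, 1.0)
    # Blue = high beta-sheet (positive), red = high alpha-helix (negative).
    rgba = cm.coolwarm_r(normed)
    return (rgba[:, :, :3] * 255).astype(np.uint8)
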
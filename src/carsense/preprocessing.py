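"""Wavenumber calibration and two-stage baseline correction.

The measurement chain calibrates the Raman shift axis against reference
peaks, then corrects baselines in two stages: (1) the mean spectrum of
pixels outside the cells is subtracted from every pixel, removing the common
instrumental background; (2) residual slowly varying structure is removed
per spectrum with asymmetrically reweighted penalized least squares (arPLS),
an iterative smoother whose logistic weights down-weight samples that sit
above the running baseline so genuine bands are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import solveh_banded
from scipy.sparse import diags


@dataclass
class CalibrationMap:
    """Polynomial map from detector pixel index to wavenumber (cm^-1)."""

    coefficients: np.ndarray  # ascending powers
    reference_wavenumbers: np.ndarray
    residuals: np.ndarray

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(pixels, dtype=float), self.coefficients)


@dataclass
class BaselineResult:
    baseline: np.ndarray
    corrected: np.ndarray
    iterations: int
    converged: bool


def calibrate_axis(
    observed_peak_pixels,
    reference_wavenumbers,
    order: int = 1,
) -> CalibrationMap:
    """Least-squares polynomial calibration from reference peaks.

    Requires at least ``order + 1`` peaks, ``order`` in {1, 2}, and a
    strictly monotone fitted map over the observed detector range.
    """
    px = np.asarray(observed_peak_pixels, dtype=float)
    wn = np.asarray(reference_wavenumbers, dtype=float)
    if px.size != wn.size:
        raise ValueError("peak pixel and reference wavenumber counts differ")
    if order not in (1, 2):
        raise ValueError("calibration order must be 1 or 2")
    if px.size < order + 1:
        raise ValueError(f"need at least {order + 1} reference peaks for order {order}")
    coeffs = np.polynomial.polynomial.polyfit(px, wn, order)
    fitted = np.polynomial.polynomial.polyval(px, coeffs)
    grid = np.linspace(px.min(), px.max(), 512)
    mapped = np.polynomial.polynomial.polyval(grid, coeffs)
    d = np.diff(mapped)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("fitted calibration map is not monotone over the detector range")
    return CalibrationMap(
        coefficients=coeffs, reference_wavenumbers=wn, residuals=wn - fitted
    )


def subtract_outside_baseline(cube, outside_mask: np.ndarray):
    """Subtract the mean outside-cell spectrum from every pixel of the cube."""
    outside_mask = np.asarray(outside_mask, dtype=bool)
    if outside_mask.shape != cube.shape[:2]:
        raise ValueError("outside mask shape does not match cube spatial dimensions")
    if not outside_mask.any():
        raise ValueError("outside-cell mask is empty")
    background = cube.data[outside_mask].mean(axis=0)
    return cube.with_data(cube.data - background)


def _dtd_banded(n: int) -> np.ndarray:
    """Upper banded form (for solveh_banded) of D2' D2, D2 = 2nd difference."""
    d2 = diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    dtd = (d2.T @ d2).todia()
    ab = np.zeros((3, n))
    for off in (0, 1, 2):
        diag = dtd.diagonal(off)
        ab[2 - off, off:] = diag
    return ab


def arpls_baseline(
    spectrum: np.ndarray,
    lam: float = 1e5,
    ratio_tol: float = 1e-6,
    max_iter: int = 100,
) -> BaselineResult:
    """Asymmetrically reweighted penalized least-squares baseline.

    Iterates z = argmin sum_i w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2
    with logistic weights w_i = 1 / (1 + exp(2 (d_i - (2 s - m)) / s)) where
    d = y - z and m, s are the mean and standard deviation of the negative
    part of d.  Terminates when the relative weight change drops below
    ``ratio_tol`` or after ``max_iter`` iterations.

    The spectrum is linearly extrapolated by ~10% of its length on each side
    before smoothing: the penalized smoother is linear at its free ends, so
    without padding a curved baseline sags at the window edges and the
    positive edge residuals seed runaway down-weighting of the interior.
    """
    y = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    n = y.size
    if n < 8:
        raise ValueError("spectrum must have at least 8 samples")

    pad = max(8, n // 10)
    k = min(8, n // 4)
    slope0 = (y[k] - y[0]) / k
    slope1 = (y[-1] - y[-1 - k]) / k
    yp = np.concatenate(
        [y[0] - slope0 * np.arange(pad, 0, -1), y, y[-1] + slope1 * np.arange(1, pad + 1)]
    )
    np_tot = yp.size
    hb = lam * _dtd_banded(np_tot)
    w = np.ones(np_tot)
    z = yp.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ab = hb.copy()
        ab[2] += w
        z = solveh_banded(ab, w * yp)
        d = (yp - z)[pad : pad + n]
        dn = d[d < 0]
        if dn.size < 2:
            converged = True
            break
        m, s = dn.mean(), dn.std()
        if s <= 0:
            converged = True
            break
        with np.errstate(over="ignore"):
            w_in = 1.0 / (1.0 + np.exp(np.clip(2.0 * (d - (2 * s - m)) / s, -500, 500)))
        w_new = w.copy()
        w_new[pad : pad + n] = w_in  # pad samples keep full weight
        change = np.linalg.norm(w - w_new) / max(np.linalg.norm(w), 1e-300)
        w = w_new
        if change < ratio_tol:
            converged = True
            break
    zc = z[pad : pad + n]
    return BaselineResult(baseline=zc, corrected=y - zc, iterations=it, converged=converged)


def arpls_cube(cube, lam: float = 1e5, ratio_tol: float = 1e-6, max_iter: int = 100):
    """Per-pixel arPLS correction of a cube (stage 2 of baseline removal)."""
    ny, nx, _ = cube.shape
    out = np.empty_like(cube.data)
    for iy in range(ny):
        for ix in range(nx):
            out[iy, ix] = arpls_baseline(cube.data[iy, ix], lam, ratio_tol, max_iter).corrected
    return cube.with_data(out)


def remove_water_band(
    spectrum: np.ndarray,
    axis: np.ndarray,
    mode: str = "component_subtract",
    water_center: float = 1640.0,
    width_bounds: tuple[float, float] = (60.0, 120.0),
) -> np.ndarray:
    """Fit and remove one broad water band centred at 1640 cm^-1.

    The water band is fitted jointly with the three amide components (fixed
    shapes, non-negative amplitudes) so amide intensity is not mistaken for
    water; only the fitted water component is subtracted.  ``mode='off'``
    returns the input unchanged.
    """
    from carsense.amide import DEFAULT_BAND_MODEL, amplitude_for_area, gaussian_band

    if mode == "off":
        return np.asarray(spectrum, dtype=float)
    if mode != "component_subtract":
        raise ValueError(f"unknown water-removal mode {mode!r}")
    axis = np.asarray(axis, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if axis[0] > water_center or axis[-1] < water_center:
        raise ValueError("axis must cover 1640 cm^-1 for water removal")

    bm = DEFAULT_BAND_MODEL
    comps = [
        gaussian_band(axis, amplitude_for_area(1.0, w), c, w)
        for _, c, w in bm.components
    ]

    def model(p):
        a0, a1, a2, aw, ww = p
        out = a0 * comps[0] + a1 * comps[1] + a2 * comps[2]
        return out + gaussian_band(axis, aw, water_center, ww)

    w0 = 0.5 * (width_bounds[0] + width_bounds[1])
    X = np.stack(comps + [gaussian_band(axis, 1.0, water_center, w0)], axis=1)
    init, _ = optimize.nnls(X, y)
    p0 = np.array([*init, w0])
    lo = np.array([0.0, 0.0, 0.0, 0.0, width_bounds[0]])
    hi = np.array([np.inf, np.inf, np.inf, np.inf, width_bounds[1]])
    sol = optimize.least_squares(
        lambda p: model(p) - y, np.clip(p0, lo + 1e-12, None), bounds=(lo, hi),
        method="trf", xtol=1e-12, ftol=1e-12,
    )
    aw, ww = sol.x[3], sol.x[4]
    return y - gaussian_band(axis, aw, water_center, ww)
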
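"""Im[chi3] retrieval from raw multiplex CARS spectra.

A raw CARS spectrum is the squared modulus of the third-order susceptibility,
|chi_NR + sum_j A_j / (Omega_j - nu - i Gamma_j)|^2, so the Raman-equivalent
imaginary part is hidden in an unmeasured phase.  The maximum entropy method
(MEM) models the normalized power spectrum autoregressively: autocorrelation
coefficients are obtained by discrete Fourier transform, a Toeplitz system is
solved for the AR coefficients, and the argument of the AR denominator is the
retrieved phase up to a slowly varying "error phase" that is estimated from
resonance-free samples and subtracted.  A direct Kramers-Kronig (log-modulus
Hilbert transform) estimate serves as an independent oracle in the tests.

The retrieval is fully deterministic: no randomness enters at any step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import hilbert

from carsense.preprocessing import arpls_baseline


@dataclass(frozen=True)
class LorentzianChi3Model:
    """Nonresonant constant plus complex Lorentzian lines (Omega, A, Gamma)."""

    chi_nr: float
    lines: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.chi_nr < 0:
            raise ValueError("chi_nr must be >= 0")
        for om, a, gm in self.lines:
            if gm <= 0:
                raise ValueError(f"line at {om}: Gamma must be > 0")

    def chi(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        chi = np.full(axis.shape, self.chi_nr, dtype=complex)
        for om, a, gm in self.lines:
            chi = chi + a / (om - axis - 1j * gm)
        return chi


@dataclass
class RawCarsSpectrum:
    """Measured (or simulated) CARS intensity on a uniform wavenumber grid."""

    intensity: np.ndarray
    axis: np.ndarray
    normalization_reference: np.ndarray | None = None
    true_im: np.ndarray | None = None  # analytic Im[chi3] when simulated

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("CARS intensity must be >= 0")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")


@dataclass
class Chi3Spectrum:
    """Retrieved susceptibility: modulus and phase per wavenumber."""

    modulus: np.ndarray
    phase: np.ndarray
    axis: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def imag(self) -> np.ndarray:
        return self.modulus * np.sin(self.phase)

    @property
    def real(self) -> np.ndarray:
        return self.modulus * np.cos(self.phase)


def simulate_raw_cars(model: LorentzianChi3Model, axis: np.ndarray) -> RawCarsSpectrum:
    """Raw CARS intensity |chi(nu)|^2 of a Lorentzian model, with analytic Im."""
    axis = np.asarray(axis, dtype=float)
    for om, a, gm in model.lines:
        if axis[0] > om - 5 * gm or axis[-1] < om + 5 * gm:
            raise ValueError(f"axis must cover line at {om} cm^-1 within +/- 5 Gamma")
    chi = model.chi(axis)
    return RawCarsSpectrum(
        intensity=np.abs(chi) ** 2, axis=axis, true_im=chi.imag
    )


def _normalize(raw: RawCarsSpectrum, envelope: bool = False) -> np.ndarray:
    """Scale the raw intensity into a normalized power spectrum.

    With a supplied reference (an independently measured nonresonant
    spectrum), divide by it.  Otherwise the default is division by the
    median intensity: the AR phase is invariant under constant scaling, and
    dividing by a smooth data-derived envelope would distort the dispersive
    resonant lineshapes it rides on.  ``envelope=True`` opts into arPLS
    envelope division for data with a genuine slowly varying instrumental
    response.
    """
    if raw.normalization_reference is not None:
        ref = np.asarray(raw.normalization_reference, dtype=float)
    elif envelope:
        ref = arpls_baseline(raw.intensity, lam=1e7).baseline
        # Keep the envelope safely positive: resonant dips can drag the
        # smooth baseline near zero.
        floor = 0.05 * float(np.median(raw.intensity))
        ref = np.maximum(ref, max(floor, 1e-300))
    else:
        ref = np.median(raw.intensity)
        if ref <= 0:
            ref = max(float(raw.intensity.max()), 1e-300)
    norm = raw.intensity / ref
    if np.any(norm < 0):
        raise ValueError("negative intensities after normalization")
    return norm


def mem_retrieve(
    raw: RawCarsSpectrum, pole_fraction: float = 0.45, pad_fraction: float = 1.0
) -> Chi3Spectrum:
    """Maximum-entropy phase retrieval of chi3 from a raw CARS spectrum.

    The normalized intensity is treated as a power spectrum; its discrete
    autocorrelation (via inverse DFT) defines a Hermitian Toeplitz system
    whose solution gives the AR coefficients a_k.  With
    A(x) = 1 + sum_k a_k exp(-2 pi i k x), the retrieved phase is arg A(x)
    and the modulus is sqrt(raw intensity) -- so scaling the input by k
    scales the modulus by sqrt(k) and leaves the phase unchanged.

    The DFT assumes a periodic spectrum, so the normalized input is
    edge-padded by ``pad_fraction`` of its length on each side before the
    autocorrelation; the phase is read back at the original samples.
    ``pole_fraction`` sets the AR order M = round(pole_fraction * N_padded);
    the phase still carries the slowly varying error phase, removed by
    :func:`correct_error_phase`.
    """
    n = raw.intensity.size
    if n < 64:
        raise ValueError("need at least 64 spectral samples for MEM retrieval")
    norm = _normalize(raw)
    pad = int(round(pad_fraction * n))
    padded = np.pad(norm, pad, mode="edge")
    np_tot = padded.size
    m = int(round(pole_fraction * np_tot))
    if not 1 <= m < np_tot // 2:
        raise ValueError(f"pole count {m} must be in [1, N/2) for N={np_tot}")

    c = np.fft.ifft(padded)[: m + 1]
    try:
        a = solve_toeplitz((c[:m], np.conj(c[:m])), -c[1 : m + 1])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise ValueError(f"singular Toeplitz system at pole count {m}") from exc
    if not np.all(np.isfinite(a)):
        raise ValueError(f"ill-conditioned Toeplitz system at pole count {m}")

    # A evaluated on the padded grid is the DFT of its coefficient vector.
    denom = np.fft.fft(np.concatenate(([1.0 + 0j], a)), n=np_tot)
    phase = np.angle(denom)[pad : pad + n]
    return Chi3Spectrum(
        modulus=np.sqrt(raw.intensity),
        phase=phase,
        axis=raw.axis.copy(),
        meta={"pole_count": m, "method": "mem"},
    )


def correct_error_phase(
    chi3: Chi3Spectrum, method: str = "smooth", order: int = 4
) -> Chi3Spectrum:
    """Remove the slowly varying error phase left by MEM retrieval.

    Physical resonances contribute non-negative phase (Im[chi3] >= 0), so
    the error phase is the smooth lower envelope of the retrieved phase.
    ``smooth`` (default) estimates it with a stiff arPLS baseline;
    ``polynomial`` fits a polynomial of ``order`` to the resonance-free
    samples (the half of the spectrum closest to that envelope) and
    subtracts it.
    """
    phase = np.asarray(chi3.phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase must be finite")
    n = phase.size
    envelope = arpls_baseline(phase, lam=1e8).baseline
    if method == "smooth":
        err = envelope
    elif method == "polynomial":
        if order >= n:
            raise ValueError(f"polynomial order {order} >= number of samples {n}")
        above = phase - envelope
        mask = above <= np.quantile(above, 0.5)
        t = np.linspace(-1.0, 1.0, n)
        coeffs = np.polynomial.polynomial.polyfit(t[mask], phase[mask], order)
        err = np.polynomial.polynomial.polyval(t, coeffs)
    else:
        raise ValueError(f"unknown error-phase method {method!r}")
    corrected = phase - err
    return Chi3Spectrum(
        modulus=chi3.modulus.copy(),
        phase=corrected,
        axis=chi3.axis.copy(),
        meta=chi3.meta | {"error_phase": method, "error_phase_order": order},
    )


def retrieve_im(
    raw: RawCarsSpectrum,
    pole_fraction: float = 0.45,
    error_phase: str = "smooth",
    order: int = 4,
) -> np.ndarray:
    """Convenience: MEM retrieval + error-phase correction, returning Im[chi3]."""
    return correct_error_phase(mem_retrieve(raw, pole_fraction), error_phase, order).imag


def kk_oracle(raw: RawCarsSpectrum, pad: int | None = None) -> np.ndarray:
    """Kramers-Kronig (log-modulus Hilbert) Im estimate, independent of MEM.

    The minimum-phase relation phase = H[ln sqrt(S_norm)] is evaluated on an
    edge-padded normalized spectrum; the same polynomial error-phase
    correction is applied.  Used only as a cross-check in tests.
    """
    n = raw.intensity.size
    if n < 64:
        raise ValueError("need at least 64 spectral samples")
    if pad is None:
        pad = 2 * n
    norm = np.maximum(_normalize(raw), 1e-12)
    padded = np.pad(norm, pad, mode="edge")
    phase = np.imag(hilbert(0.5 * np.log(padded)))[pad : pad + n]
    chi = Chi3Spectrum(
        modulus=np.sqrt(raw.intensity), phase=phase, axis=raw.axis.copy(), meta={"method": "kk"}
    )
    return correct_error_phase(chi).imag


def retrieve_cube(cube, pole_fraction: float = 0.45, error_phase: str = "smooth", order: int = 4):
    """Apply MEM retrieval pixel-by-pixel to a chi3_domain cube.

    Returns an im_domain cube of corrected Im[chi3] spectra.
    """
    from carsense.cube import HyperspectralCube

    if cube.mode != "chi3_domain":
        raise ValueError("retrieve_cube expects a chi3_domain cube")
    ny, nx, nv = cube.shape
    out = np.zeros_like(cube.data)
    cache: dict[bytes, np.ndarray] = {}
    for iy in range(ny):
        for ix in range(nx):
            spec = cube.data[iy, ix]
            key = spec.tobytes()
            if key not in cache:
                raw = RawCarsSpectrum(intensity=np.clip(spec, 0, None), axis=cube.axis_cm1)
                cache[key] = retrieve_im(raw, pole_fraction, error_phase, order)
            out[iy, ix] = cache[key]
    return HyperspectralCube(
        data=out,
        axis_cm1=cube.axis_cm1.copy(),
        pixel_size_um=cube.pixel_size_um,
        mode="im_domain",
        meta=cube.meta | {"retrieval": "mem", "pole_fraction": pole_fraction},
    )
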
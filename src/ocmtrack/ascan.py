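"""Spectral-domain depth-profile (A-scan) reconstruction.

A spectral-domain OCM system records, for every beam position, one
interferometric spectrum: the source envelope modulated by cosine fringes
whose frequency in wavenumber ``k = 2*pi/lambda`` is proportional to the
optical path depth of each scatterer (``cos(2*k*z)`` for a reflector at
depth ``z``, the factor 2 accounting for the double pass).  A depth profile
is obtained by the standard processing chain

    fixed-pattern removal -> resampling to uniform k -> residual dispersion
    correction -> spectral shaping -> Fourier transform,

each step of which is a function in this module.  The module also contains
a forward model (:func:`simulate_interferogram`) that synthesises spectra
from point scatterers, so the chain can be validated against closed-form
expectations such as the Gaussian-spectrum coherence length
``FWHM = 0.4413 * lambda0**2 / dlambda`` (in air).

Conventions
-----------
* wavelengths in nm, wavenumbers in rad/um, depths in um;
* depth index 0 corresponds to zero path delay, depths increase downward,
  pixel ``i`` covers the half-open bin ``[i*dz, (i+1)*dz)``;
* the default calibration mirrors a 2048-pixel spectrometer centred at
  800 nm whose 1024 depth pixels span exactly 900 um (axial pixel
  0.8789 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

# --- system constants (recorded from the instrument description) ------------

DEFAULT_CENTER_NM = 800.0     #: source central wavelength
DEFAULT_FWHM_NM = 115.0       #: -3 dB spectral bandwidth
DEFAULT_N_PIX = 2048          #: spectrometer pixels per fringe
DEFAULT_RANGE_UM = 900.0      #: imaging range spanned by n_pix/2 depth pixels
DEFAULT_LINE_RATE_HZ = 140e3  #: camera line rate
DEFAULT_LINE_PERIOD_S = 1.0 / DEFAULT_LINE_RATE_HZ
ACQUISITION_TIME_S = 20e-6    #: exposure used for the sensitivity test
ILLUMINATION_POWER_MW = 1.2
#: focal-plane power density, W/cm^2 (recorded verbatim, not re-derived)
POWER_DENSITY_W_CM2 = 1.27e4
AXIAL_RESOLUTION_TISSUE_UM = 1.9   # recorded; air-value closed form is derived
LATERAL_RESOLUTION_UM = 1.9


def axial_pixel_um(n_pix: int = DEFAULT_N_PIX, range_um: float = DEFAULT_RANGE_UM) -> float:
    """Axial sampling: ``range_um`` divided over ``n_pix/2`` depth pixels."""
    return range_um / (n_pix // 2)


# --- domain types -----------------------------------------------------------


@dataclass
class SpectralFrame:
    """One raw interferometric spectrum with its wavelength calibration."""

    samples: np.ndarray           # real intensity per spectral pixel
    wavelength_nm: np.ndarray     # strictly monotonic calibration, nm
    line_period_s: float = DEFAULT_LINE_PERIOD_S

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        if self.samples.size == 0 or self.wavelength_nm.size == 0:
            raise ValueError("empty spectral frame")
        if self.samples.shape != self.wavelength_nm.shape:
            raise ValueError("samples and wavelength grid differ in length")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")
        d = np.diff(self.wavelength_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength grid must be strictly monotonic")

    @property
    def n_pix(self) -> int:
        return self.samples.size

    @property
    def k_rad_um(self) -> np.ndarray:
        """Wavenumber per pixel, rad/um."""
        return 2.0e3 * np.pi / self.wavelength_nm

    def is_k_uniform(self, rtol: float = 1e-6) -> bool:
        dk = np.diff(self.k_rad_um)
        return bool(np.allclose(dk, dk[0], rtol=rtol, atol=abs(dk[0]) * rtol))


@dataclass
class ReconSettings:
    """Processing-chain parameters.

    ``dispersion_coeffs`` are the residual second/third-order phase
    coefficients ``(c2, c3)`` of ``phi(k) = c2*(k-k0)**2 + c3*(k-k0)**3``
    about the central wavenumber, in rad/(rad/um)^n (i.e. um^2 and um^3).
    """

    dispersion_coeffs: tuple[float, float] = (0.0, 0.0)
    window: str = "hann"                 # hann | rect | gaussian
    window_sigma_frac: float = 0.25      # gaussian window sigma / span
    reference_spectrum: np.ndarray | None = None
    zero_pad_factor: int = 1

    def __post_init__(self) -> None:
        if self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be >= 1")
        if self.window not in ("hann", "rect", "gaussian"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclass
class AScan:
    """Depth profile: non-negative magnitude per depth pixel."""

    magnitude: np.ndarray
    depth_pixel_um: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.depth_pixel_um <= 0:
            raise ValueError("depth_pixel_um must be positive")
        if np.any(self.magnitude < 0):
            raise ValueError("A-scan magnitudes must be non-negative")

    @property
    def depth_um(self) -> np.ndarray:
        return np.arange(self.magnitude.size) * self.depth_pixel_um


@dataclass
class ScattererSet:
    """Point reflectors plus the source-spectrum model used to image them.

    ``scatterers`` is a sequence of ``(depth_um, amplitude, phase_rad)``.
    """

    scatterers: Sequence[tuple[float, float, float]] = field(default_factory=list)
    center_nm: float = DEFAULT_CENTER_NM
    fwhm_nm: float = DEFAULT_FWHM_NM
    shape: str = "gaussian"
    range_um: float = DEFAULT_RANGE_UM

    def __post_init__(self) -> None:
        for depth, amp, _ in self.scatterers:
            if not np.isfinite(amp) or amp < 0:
                raise ValueError("scatterer amplitudes must be finite and >= 0")
            if depth < 0:
                raise ValueError("scatterer depths must be >= 0")
            if depth >= self.range_um:
                raise ValueError(
                    f"scatterer depth {depth} um beyond unambiguous range "
                    f"{self.range_um} um"
                )
        if self.shape != "gaussian":
            raise ValueError("only a gaussian source shape is modelled")


# --- calibration and source model -------------------------------------------


def default_wavelength_grid(
    n_pix: int = DEFAULT_N_PIX,
    center_nm: float = DEFAULT_CENTER_NM,
    range_um: float = DEFAULT_RANGE_UM,
    kind: str = "lambda",
) -> np.ndarray:
    """Synthesize a spectrometer calibration consistent with the imaging range.

    The spectral band is chosen so that its wavenumber span ``dK`` satisfies
    ``range_um = (n_pix/2) * pi / dK``; i.e. the nominal imaging range is a
    configuration invariant.  ``kind='lambda'`` spaces pixels uniformly in
    wavelength (a grating spectrometer), ``kind='k'`` uniformly in wavenumber
    (already-resampled data, with a half-pixel offset so that ``n_pix``
    spacings tile the band exactly).
    """
    k0 = 2.0e3 * np.pi / center_nm                     # rad/um
    span_k = (n_pix // 2) * np.pi / range_um           # rad/um
    if kind == "k":
        dk = span_k / n_pix
        k = k0 - span_k / 2 + (np.arange(n_pix) + 0.5) * dk
        return 2.0e3 * np.pi / k[::-1]                 # increasing wavelength
    if kind == "lambda":
        lam_min = 2.0e3 * np.pi / (k0 + span_k / 2)
        lam_max = 2.0e3 * np.pi / (k0 - span_k / 2)
        return np.linspace(lam_min, lam_max, n_pix)
    raise ValueError(f"unknown grid kind {kind!r}")


def source_envelope(k_rad_um: np.ndarray, center_nm: float, fwhm_nm: float) -> np.ndarray:
    """Gaussian source power spectrum evaluated at wavenumbers ``k``.

    The wavelength FWHM maps onto a wavenumber FWHM of
    ``2*pi*fwhm/center**2`` (first order), keeping the closed-form coherence
    length ``0.4413*lambda0**2/dlambda`` exact for this model.
    """
    k0 = 2.0e3 * np.pi / center_nm
    dk_fwhm = 2.0e3 * np.pi * fwhm_nm / center_nm**2
    return np.exp(-4.0 * np.log(2.0) * (k_rad_um - k0) ** 2 / dk_fwhm**2)


def _dispersion_phase(k: np.ndarray, k0: float, coeffs: tuple[float, float]) -> np.ndarray:
    c2, c3 = coeffs
    dk = k - k0
    return c2 * dk**2 + c3 * dk**3


# --- forward model ----------------------------------------------------------


def simulate_interferogram(
    scatterers: ScattererSet,
    settings: ReconSettings,
    n_pix: int = DEFAULT_N_PIX,
    wavelength_nm: np.ndarray | None = None,
    line_period_s: float = DEFAULT_LINE_PERIOD_S,
) -> SpectralFrame:
    """Synthesize the spectrum of a set of point reflectors.

    ``samples = E(k) * (1 + sum_j 2*a_j*cos(2*k*z_j + phi_j + phi_disp(k)))``
    with ``E`` the source envelope and ``phi_disp`` the residual dispersion
    phase from ``settings`` (applied with a positive sign here, to be removed
    by :func:`correct_dispersion`).  Deterministic given its inputs.
    """
    if n_pix % 2 != 0:
        raise ValueError("n_pix must be even")
    if wavelength_nm is None:
        wavelength_nm = default_wavelength_grid(
            n_pix, scatterers.center_nm, scatterers.range_um
        )
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if wavelength_nm.size == 0:
        raise ValueError("empty wavelength grid")
    k = 2.0e3 * np.pi / wavelength_nm
    k0 = 2.0e3 * np.pi / scatterers.center_nm
    env = source_envelope(k, scatterers.center_nm, scatterers.fwhm_nm)
    phi_d = _dispersion_phase(k, k0, settings.dispersion_coeffs)
    fringes = np.zeros_like(k)
    for depth, amp, phase in scatterers.scatterers:
        fringes += 2.0 * amp * np.cos(2.0 * k * depth + phase + phi_d)
    return SpectralFrame(env * (1.0 + fringes), wavelength_nm, line_period_s)


# --- processing chain -------------------------------------------------------


def remove_fixed_pattern(
    frames: Sequence[SpectralFrame],
    reference_spectrum: np.ndarray | None = None,
) -> list[SpectralFrame]:
    """Subtract the static (fixed-pattern) spectral component.

    With no explicit reference the per-pixel mean across frames is used, so
    at least two frames are required; a supplied ``reference_spectrum`` is
    subtracted directly.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    n = frames[0].n_pix
    if any(f.n_pix != n for f in frames):
        raise ValueError("frames differ in length")
    if reference_spectrum is None:
        if len(frames) < 2:
            raise ValueError(
                "fixed-pattern removal needs >= 2 frames or a reference spectrum"
            )
        reference_spectrum = np.mean([f.samples for f in frames], axis=0)
    reference_spectrum = np.asarray(reference_spectrum, dtype=float)
    if reference_spectrum.shape != (n,):
        raise ValueError("reference spectrum length mismatch")
    return [
        SpectralFrame(f.samples - reference_spectrum, f.wavelength_nm, f.line_period_s)
        for f in frames
    ]


def resample_to_k(frame: SpectralFrame) -> SpectralFrame:
    """Cubic resampling onto a uniform wavenumber grid spanning the same band."""
    k = frame.k_rad_um
    order = np.argsort(k)
    k_sorted = k[order]
    spline = CubicSpline(k_sorted, frame.samples[order])
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], frame.n_pix)
    return SpectralFrame(
        spline(k_uniform), 2.0e3 * np.pi / k_uniform, frame.line_period_s
    )


def correct_dispersion(frame: SpectralFrame, settings: ReconSettings) -> SpectralFrame:
    """Remove the residual polynomial dispersion phase.

    The real fringe is converted to its analytic signal (one-sided spectrum),
    multiplied by the conjugate dispersion phase about the band centre, and
    the real part returned.  Requires a k-uniform frame.
    """
    if not frame.is_k_uniform():
        raise ValueError("correct_dispersion requires a k-uniform frame; resample first")
    c2, c3 = settings.dispersion_coeffs
    if c2 == 0.0 and c3 == 0.0:
        return frame
    k = frame.k_rad_um
    if k[0] > k[-1]:  # analytic-signal sign convention needs ascending k
        analytic = hilbert(frame.samples[::-1])
        phi = _dispersion_phase(k[::-1], 0.5 * (k[0] + k[-1]), settings.dispersion_coeffs)
        corrected = np.real(analytic * np.exp(-1j * phi))[::-1]
    else:
        analytic = hilbert(frame.samples)
        phi = _dispersion_phase(k, 0.5 * (k[0] + k[-1]), settings.dispersion_coeffs)
        corrected = np.real(analytic * np.exp(-1j * phi))
    return SpectralFrame(corrected, frame.wavelength_nm, frame.line_period_s)


def _make_window(name: str, n: int, sigma_frac: float) -> np.ndarray:
    if name == "hann":
        w = np.hanning(n)
    elif name == "rect":
        w = np.ones(n)
    elif name == "gaussian":
        x = np.arange(n) - (n - 1) / 2
        w = np.exp(-0.5 * (x / (sigma_frac * n)) ** 2)
    else:  # pragma: no cover - guarded by ReconSettings
        raise ValueError(name)
    return w / np.sqrt(np.mean(w**2))  # energy normalization


def reconstruct_ascan(frame: SpectralFrame, settings: ReconSettings) -> AScan:
    """Spectral shaping followed by Fourier transformation.

    Returns the magnitude of the positive-frequency half of the transform;
    with zero padding the output has ``n_pix/2 * zero_pad_factor`` pixels and
    correspondingly finer depth sampling.
    """
    if not frame.is_k_uniform():
        raise ValueError("reconstruct_ascan requires a k-uniform frame; resample first")
    n = frame.n_pix
    window = _make_window(settings.window, n, settings.window_sigma_frac)
    if window.size != n:
        raise ValueError("window length mismatch")
    k = frame.k_rad_um
    samples = frame.samples
    if k[0] > k[-1]:
        k = k[::-1]
        samples = samples[::-1]
    dk = (k[-1] - k[0]) / (n - 1)
    n_fft = n * settings.zero_pad_factor
    spectrum = np.fft.rfft(samples * window, n=n_fft)
    n_out = (n // 2) * settings.zero_pad_factor
    # fringe cos(2*k*z): FFT bin i maps to 2*z = 2*pi*i/(n_fft*dk)
    depth_pixel = np.pi / (n_fft * dk)
    return AScan(np.abs(spectrum[:n_out]), depth_pixel)


def reconstruct_chain(
    frame: SpectralFrame,
    settings: ReconSettings,
    background: np.ndarray | None = None,
) -> AScan:
    """Full chain on one raw frame: fixed pattern -> k -> dispersion -> A-scan."""
    if background is not None:
        frame = remove_fixed_pattern([frame], reference_spectrum=background)[0]
    frame = resample_to_k(frame)
    frame = correct_dispersion(frame, settings)
    return reconstruct_ascan(frame, settings)


# --- measurement helpers ----------------------------------------------------


def peak_fwhm_um(ascan: AScan, min_pixel: int = 0) -> float:
    """FWHM of the dominant peak, in um, by linear interpolation at half max."""
    mag = ascan.magnitude
    idx = min_pixel + int(np.argmax(mag[min_pixel:]))
    half = mag[idx] / 2.0
    lo = idx
    while lo > 0 and mag[lo] > half:
        lo -= 1
    hi = idx
    while hi < mag.size - 1 and mag[hi] > half:
        hi += 1
    if mag[lo] > half or mag[hi] > half:
        raise ValueError("peak not resolved within the A-scan")
    left = lo + (half - mag[lo]) / (mag[lo + 1] - mag[lo])
    right = hi - 1 + (mag[hi - 1] - half) / (mag[hi - 1] - mag[hi])
    return (right - left) * ascan.depth_pixel_um


def gaussian_coherence_fwhm_um(center_nm: float, fwhm_nm: float) -> float:
    """Closed-form axial PSF FWHM of a Gaussian spectrum in air, um."""
    lam0_um = center_nm * 1e-3
    dlam_um = fwhm_nm * 1e-3
    return (2.0 * np.log(2.0) / np.pi) * lam0_um**2 / dlam_um
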
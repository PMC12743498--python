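"""Noise-mask synthesis, contrast normalization, and stimulus compositing.

Luminance images are square grids of cd/m² values with a pixels-per-degree
(ppd) calibration. Noise masks come in four families — white, pink, brown
(power spectral density ∝ f⁰, f⁻¹, f⁻² respectively) and narrowband (an
isotropic log-Gaussian band around a center spatial frequency in cycles per
degree). Masks are generated by spectral filtering of a seeded white-noise
field, DC-zeroed, and renormalized to a target RMS contrast about the mean
luminance. Scenes and noise combine additively in the contrast domain:

    L(x) = L̄ · (1 + c_scene·s(x) + n(x))

with negative luminances clamped to zero and the clamped fraction reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Noise families accepted by :class:`NoiseSpec`.
NOISE_FAMILIES = ("white", "pink", "brown", "narrowband")

#: Amplitude-spectrum exponents per broadband family (power exponent is 2×).
_AMPLITUDE_EXPONENT = {"white": 0.0, "pink": -0.5, "brown": -1.0}


@dataclass
class LuminanceImage:
    """Square grid of luminance values (cd/m²) with angular calibration.

    Parameters
    ----------
    values : ndarray
        2-D square array of luminances. Stored as float64.
    ppd : float
        Pixels per degree of visual angle.
    """

    values: np.ndarray
    ppd: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"luminance grid must be square 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("luminance grid must be at least 2x2")
        if self.ppd <= 0:
            raise ValueError("ppd must be positive")

    @property
    def size_px(self) -> int:
        return self.values.shape[0]

    @property
    def mean_luminance(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of one noise mask.

    ``center_sf`` (cycles/degree) and ``bandwidth_octaves`` (full width at
    half height of the amplitude envelope) only apply to the narrowband
    family.
    """

    family: str
    rms_contrast: float = 0.1
    center_sf: float | None = None
    bandwidth_octaves: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; expected one of {NOISE_FAMILIES}")
        if self.rms_contrast <= 0:
            raise ValueError("rms_contrast must be positive")
        if self.family == "narrowband":
            if self.center_sf is None or self.center_sf <= 0:
                raise ValueError("narrowband noise requires center_sf > 0")
            if self.bandwidth_octaves <= 0:
                raise ValueError("bandwidth_octaves must be positive")

    @property
    def label(self) -> str:
        """Condition tag, e.g. ``pink`` or ``narrowband-3.0``."""
        if self.family == "narrowband":
            return f"narrowband-{self.center_sf:g}"
        return self.family


@dataclass(frozen=True)
class StimulusSpec:
    """Scene contrast, optional noise mask, and luminance anchor."""

    image_contrast: float
    noise: NoiseSpec | None = None
    mean_luminance: float = 100.0

    def __post_init__(self) -> None:
        if self.image_contrast < 0:
            raise ValueError("image_contrast must be non-negative")
        if self.mean_luminance <= 0:
            raise ValueError("mean_luminance must be positive")


@dataclass
class ComposedStimulus:
    """A composed stimulus plus the fraction of pixels clamped at zero."""

    image: LuminanceImage
    clip_fraction: float


def rms_contrast(img: LuminanceImage) -> float:
    """RMS contrast: population standard deviation divided by the mean.

    Raises
    ------
    ValueError
        If the mean luminance is not strictly positive.
    """
    mean = img.values.mean()
    if mean <= 0:
        raise ValueError(f"mean luminance must be positive, got {mean}")
    return float(img.values.std() / mean)


def normalize_to(img: LuminanceImage, target_rms: float, target_mean: float) -> LuminanceImage:
    """Affinely rescale an image to an exact RMS contrast and mean.

    ``target_rms = 0`` returns a constant image at ``target_mean``. A
    constant input with ``target_rms > 0`` is a contract violation.
    """
    if target_rms < 0:
        raise ValueError("target_rms must be non-negative")
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    v = img.values
    if target_rms == 0:
        return LuminanceImage(np.full_like(v, target_mean), img.ppd)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant image to a positive RMS contrast")
    scaled = (v - v.mean()) * (target_rms * target_mean / sd) + target_mean
    return LuminanceImage(scaled, img.ppd)


def angular_size(size_px: int, ppd: float) -> float:
    """Angular extent in degrees of visual angle: ``size_px / ppd``."""
    if ppd <= 0:
        raise ValueError("ppd must be positive")
    return size_px / ppd


def _frequency_grid(size_px: int, ppd: float) -> np.ndarray:
    """Radial spatial-frequency magnitude (cpd) on the FFT grid."""
    f = np.fft.fftfreq(size_px, d=1.0 / ppd)
    fx, fy = np.meshgrid(f, f)
    return np.hypot(fx, fy)


def _amplitude_envelope(spec: NoiseSpec, fr: np.ndarray) -> np.ndarray:
    if spec.family == "narrowband":
        # log-Gaussian amplitude envelope; FWHH (octaves) -> sigma in log2 units
        sigma = spec.bandwidth_octaves / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        with np.errstate(divide="ignore"):
            logr = np.log2(np.where(fr > 0, fr / spec.center_sf, 1.0))
        w = np.exp(-(logr ** 2) / (2.0 * sigma ** 2))
        w[fr == 0] = 0.0
        return w
    expo = _AMPLITUDE_EXPONENT[spec.family]
    if expo == 0.0:
        return np.ones_like(fr)
    with np.errstate(divide="ignore"):
        w = np.where(fr > 0, fr, 1.0) ** expo
    w[fr == 0] = 0.0
    return w


def make_noise(
    spec: NoiseSpec, size_px: int, ppd: float, mean_luminance: float = 100.0
) -> LuminanceImage:
    """Generate a noise mask by spectral filtering of a seeded Gaussian field.

    The white-noise field is filtered with the family's amplitude envelope
    (``f⁰`` white, ``f^-1/2`` pink, ``f^-1`` brown — power 1/f and 1/f²
    respectively — or the log-Gaussian band), its DC component zeroed, and
    the result renormalized to ``spec.rms_contrast`` about
    ``mean_luminance``. Deterministic given the seed.
    """
    nyquist = ppd / 2.0
    if spec.family == "narrowband" and spec.center_sf > nyquist:
        raise ValueError(
            f"center_sf {spec.center_sf} cpd exceeds the Nyquist frequency {nyquist} cpd at ppd={ppd}"
        )
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((size_px, size_px))
    fr = _frequency_grid(size_px, ppd)
    spectrum = np.fft.fft2(white) * _amplitude_envelope(spec, fr)
    spectrum[0, 0] = 0.0
    noise = np.fft.ifft2(spectrum).real
    return normalize_to(LuminanceImage(noise, ppd), spec.rms_contrast, mean_luminance)


def compose_stimulus(scene: LuminanceImage, spec: StimulusSpec) -> ComposedStimulus:
    """Compose a scene at a given contrast with an optional noise mask.

    The scene is normalized to ``(spec.image_contrast, spec.mean_luminance)``,
    the noise contrast field (zero-mean, noise RMS) is added, and the result
    is clamped to non-negative luminance. A clamped fraction above 1% is
    warned about.
    """
    if spec.image_contrast == 0:
        base = np.zeros((scene.size_px, scene.size_px))
    else:
        normed = normalize_to(scene, spec.image_contrast, spec.mean_luminance)
        base = normed.values / spec.mean_luminance - 1.0
    if spec.noise is not None:
        noise_img = make_noise(spec.noise, scene.size_px, scene.ppd, spec.mean_luminance)
        if noise_img.size_px != scene.size_px:
            raise ValueError("scene and noise size mismatch")
        base = base + (noise_img.values / spec.mean_luminance - 1.0)
    lum = spec.mean_luminance * (1.0 + base)
    clipped = lum < 0
    clip_fraction = float(clipped.mean())
    if clip_fraction > 0.01:
        warnings.warn(
            f"{clip_fraction:.1%} of pixels clamped to zero luminance", stacklevel=2
        )
    lum = np.where(clipped, 0.0, lum)
    return ComposedStimulus(LuminanceImage(lum, scene.ppd), clip_fraction)


def add_noise_field(scene: LuminanceImage, noise: LuminanceImage, mean_luminance: float = 100.0) -> ComposedStimulus:
    """Add a pre-generated noise mask's contrast field to a scene as-is.

    Unlike :func:`compose_stimulus` this does not renormalize the scene; it
    is the CLI path where both components are already calibrated files.
    """
    if scene.size_px != noise.size_px:
        raise ValueError("scene and noise size mismatch")
    lum = scene.values + (noise.values - noise.values.mean())
    clipped = lum < 0
    clip_fraction = float(clipped.mean())
    lum = np.where(clipped, 0.0, lum)
    return ComposedStimulus(LuminanceImage(lum, scene.ppd), clip_fraction)


# ---------------------------------------------------------------------------
# Spectral diagnostics (shared with the patches module)
# ---------------------------------------------------------------------------

def radial_power_spectrum(img: LuminanceImage) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum.

    Power is ``|FFT|² / N²`` of the mean-subtracted image so that the total
    equals the pixel variance (Parseval). Annuli are one frequency-pixel
    (``ppd / size_px`` cpd) wide. Returns ``(freq_cpd, power)`` excluding DC.
    """
    v = img.values - img.values.mean()
    power = np.abs(np.fft.fft2(v)) ** 2 / v.size ** 2
    fr = _frequency_grid(img.size_px, img.ppd)
    df = img.ppd / img.size_px
    k = np.rint(fr / df).astype(int)
    kmax = img.size_px // 2  # annuli fully inside the square grid
    sums = np.bincount(k.ravel(), weights=power.ravel(), minlength=kmax + 1)
    counts = np.bincount(k.ravel(), minlength=kmax + 1)
    idx = np.arange(1, kmax + 1)
    return idx * df, sums[idx] / counts[idx]


def spectral_slope(
    img: LuminanceImage, fmin_cpd: float | None = None, fmax_cpd: float | None = None
) -> float:
    """Log-log slope of the radially averaged power spectrum.

    Defaults fit the mid-band: from eight frequency pixels above DC up to
    half the Nyquist frequency, avoiding both sparse low-frequency annuli
    and corner anisotropy.
    """
    freqs, power = radial_power_spectrum(img)
    df = img.ppd / img.size_px
    if fmin_cpd is None:
        fmin_cpd = 8 * df
    if fmax_cpd is None:
        fmax_cpd = img.ppd / 4.0
    sel = (freqs >= fmin_cpd) & (freqs <= fmax_cpd) & (power > 0)
    if sel.sum() < 3:
        raise ValueError("not enough frequency bins in the requested band")
    slope, _ = np.polyfit(np.log10(freqs[sel]), np.log10(power[sel]), 1)
    return float(slope)


def narrowband_peak(img: LuminanceImage, half_power: float = 0.5) -> float:
    """Peak spatial frequency (cpd) of the radial power spectrum.

    Estimated as the power-weighted centroid of log2-frequency over bins at
    or above ``half_power`` × max, which is robust to bin-level sampling
    noise near a flat peak.
    """
    freqs, power = radial_power_spectrum(img)
    sel = power >= half_power * power.max()
    w = power[sel]
    return float(2.0 ** (np.sum(w * np.log2(freqs[sel])) / np.sum(w)))
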
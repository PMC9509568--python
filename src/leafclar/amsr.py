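"""Adaptive multi-scale retinex (AMSR) enhancement for leaf images.

Retinex theory models a camera image as the product of a smooth illumination
field and an object-intrinsic reflectance field, ``S = R * L``.  Enhancement
recovers the reflectance in the log domain, ``log R = log S - log L``, with
the illumination of each colour channel estimated by Gaussian-surround
filtering at several spatial scales.

The adaptive variant implemented here differs from classic multi-scale
retinex in two ways:

* **Per-pixel scale weighting.**  A frequency-comparison coefficient
  ``A = a1 * arccot(sigma_local) + a2`` (clamped to [0, 1]) measures whether a
  pixel sits in an edge region (small local standard deviation weight) or a
  homogeneous region.  The three surround scales are blended per pixel between
  an edge profile favouring the small scale and a homogeneous profile
  favouring the large scale; the blended weights sum to one at every pixel.

* **Brightness-compensated channel merging.**  The merged log-domain
  reflectance is mapped to display range by a per-channel percentile stretch,
  and chromaticity is restored by multiplying the enhanced luminance by the
  original channel ratios ``I_j / I`` scaled by a brightness factor
  ``lambda`` (default 1).

All operations are deterministic; constant images are fixed points of the
reflectance computation (zero reflectance everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve

from .image import RgbImage, as_pixels

# Scale-blending profiles over (small, medium, large) surround scales:
# edge regions favour the small scale, homogeneous regions the large one.
EDGE_PROFILE = np.array([0.5, 0.3, 0.2], dtype=np.float64)
HOMOGENEOUS_PROFILE = np.array([0.2, 0.3, 0.5], dtype=np.float64)

#: convolution is done in the frequency domain at or above this scale
FFT_SIGMA_THRESHOLD = 8.0


@dataclass
class EnhancementConfig:
    """All tunable AMSR parameters.

    Parameters
    ----------
    sigmas
        Three strictly increasing Gaussian-surround scales (pixels).  The
        small scale preserves edges, the large one evens global illumination.
    a1, a2
        Coefficients of the frequency-comparison coefficient
        ``A = a1 * arccot(sigma_local) + a2``.  The defaults ``2/pi`` and 0
        map ``A`` onto (0, 1].
    lambda_brightness
        Brightness compensation factor of the channel merge (default 1).
    local_window
        Odd window (pixels) of the local standard deviation map, computed on
        the 8-bit-scaled channel.
    log_epsilon
        Guard added inside both logarithms (default 1/255, one quantum).
    output_percentiles
        (low, high) percentiles of the log-domain stretch to display range.
    """

    sigmas: tuple = (15.0, 80.0, 250.0)
    a1: float = 2.0 / np.pi
    a2: float = 0.0
    lambda_brightness: float = 1.0
    local_window: int = 7
    log_epsilon: float = 1.0 / 255.0
    output_percentiles: tuple = (1.0, 99.0)

    def __post_init__(self):
        s = tuple(float(v) for v in self.sigmas)
        if len(s) != 3 or not (0 < s[0] < s[1] < s[2]):
            raise ValueError("sigmas must be three strictly increasing positive scales")
        self.sigmas = s
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be an odd integer >= 3")
        lo, hi = self.output_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("output_percentiles must satisfy 0 <= low < high <= 100")
        if self.lambda_brightness <= 0:
            raise ValueError("lambda_brightness must be positive")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")


@dataclass
class SurroundKernel:
    """Normalized Gaussian surround: unit-sum taps on [-radius, radius]^2."""

    sigma: float
    radius: int
    taps: np.ndarray


@dataclass
class WeightField:
    """Per-pixel scale weights (sum to one at every pixel) and their inputs."""

    weights: np.ndarray          # (n_scales, H, W)
    local_sigma: np.ndarray      # (H, W)
    a1: float
    a2: float


def build_surround_kernel(sigma: float, radius: int) -> SurroundKernel:
    """Evaluate the Gaussian surround on the integer grid and renormalize.

    The continuous surround is ``G(x, y) = exp(-(x^2+y^2)/(2 sigma^2)) /
    (2 pi sigma^2)``; the discrete taps are renormalized to sum exactly to
    one so that convolution preserves constants.
    """
    if sigma <= 0 or radius < 1:
        raise ValueError("sigma and radius must be positive")
    radius = int(radius)
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    taps = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)
    taps /= taps.sum()
    return SurroundKernel(sigma=float(sigma), radius=radius, taps=taps)


def estimate_incident(channel: np.ndarray, kernel: SurroundKernel) -> np.ndarray:
    """Estimate the illumination field: surround-filter one channel.

    The channel is reflect-padded by the kernel radius (avoiding the dark
    halo of zero padding) and convolved at the input resolution.  Large
    kernels go through the frequency domain, small ones through direct
    spatial convolution; the two paths agree to well below 1e-6.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("channel must be 2-D")
    r = kernel.radius
    if r > min(channel.shape) - 1:
        raise ValueError("kernel larger than padded image")
    padded = np.pad(channel, r, mode="reflect")
    method = "fft" if kernel.sigma >= FFT_SIGMA_THRESHOLD else "direct"
    out = convolve(padded, kernel.taps, mode="valid", method=method)
    # smoothing with unit-sum nonnegative taps cannot exceed the input range
    return np.clip(out, channel.min(), channel.max())


def local_std_map(channel: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel population standard deviation over a centred square window.

    Borders are reflect-padded.  Computed from running first and second
    moments; the variance is floored at zero before the square root.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    from scipy.ndimage import uniform_filter

    channel = np.asarray(channel, dtype=np.float64)
    m1 = uniform_filter(channel, size=window, mode="reflect")
    m2 = uniform_filter(channel ** 2, size=window, mode="reflect")
    var = np.maximum(m2 - m1 ** 2, 0.0)
    return np.sqrt(var)


def frequency_weight(local_sigma: np.ndarray, a1: float, a2: float,
                     n_scales: int = 3) -> WeightField:
    """Per-pixel scale weights from the frequency-comparison coefficient.

    ``A = a1 * arccot(sigma) + a2`` (clamped to [0, 1]) is 1 in perfectly
    homogeneous regions (``arccot(0) = pi/2`` with the default ``a1 = 2/pi``)
    and decreases monotonically with local contrast.  The scale weights are
    ``(1 - A) * edge_profile + A * homogeneous_profile`` and sum to one at
    every pixel.
    """
    if n_scales != 3:
        raise ValueError("the scale-blending profiles are defined for 3 scales")
    local_sigma = np.asarray(local_sigma, dtype=np.float64)
    if (local_sigma < 0).any():
        raise ValueError("local_sigma must be nonnegative")
    # arccot(s) on s >= 0: arctan2(1, s) is pi/2 at 0 and monotone decreasing
    a = a1 * np.arctan2(1.0, local_sigma) + a2
    a = np.clip(a, 0.0, 1.0)
    w = (1.0 - a)[None] * EDGE_PROFILE[:, None, None] \
        + a[None] * HOMOGENEOUS_PROFILE[:, None, None]
    return WeightField(weights=w, local_sigma=local_sigma, a1=float(a1), a2=float(a2))


def msr_reflectance(channel: np.ndarray, kernels: list, weights: WeightField,
                    log_epsilon: float) -> np.ndarray:
    """Log-domain reflectance: weighted multi-scale ``log S - log L``.

    Returns ``sum_n w_n(x, y) * (log(S + eps) - log(L_n + eps))`` where
    ``L_n`` is the surround-filtered channel at scale ``n``.  Constant
    channels map to the zero field.
    """
    channel = np.asarray(channel, dtype=np.float64)
    w = weights.weights
    if len(kernels) != w.shape[0]:
        raise ValueError("one kernel per scale weight required")
    log_s = np.log(channel + log_epsilon)
    out = np.zeros_like(channel)
    for n, kernel in enumerate(kernels):
        incident = estimate_incident(channel, kernel)
        out += w[n] * (log_s - np.log(incident + log_epsilon))
    return out


def merge_and_compensate(reflectances: np.ndarray, original,
                         lambda_brightness: float = 1.0,
                         output_percentiles: tuple = (1.0, 99.0),
                         epsilon: float = 1.0 / 255.0) -> RgbImage:
    """Map log-domain reflectance to display range and restore chromaticity.

    Each channel's reflectance is percentile-stretched to [0, 1]; the
    enhanced luminance (channel mean of the stretched fields) is multiplied
    by the original chromaticity ratios ``I_j / I`` (``I`` = per-pixel mean of
    the original channels) scaled by ``lambda``.  Pixels with ``I <= eps``
    keep the enhanced luminance unmodified.  Pixels whose compensated
    channels exceed 1 are rescaled by their maximum — preserving the restored
    ratios — before the final clip.
    """
    orig = as_pixels(original).astype(np.float64)
    refl = np.asarray(reflectances, dtype=np.float64)
    if refl.shape != (3,) + orig.shape[:2]:
        raise ValueError("reflectances must be (3, H, W) matching the original")
    lo_p, hi_p = output_percentiles

    stretched = np.empty_like(refl)
    for j in range(3):
        lo, hi = np.percentile(refl[j], [lo_p, hi_p])
        if hi - lo < 1e-12:
            stretched[j] = 0.5
        else:
            stretched[j] = np.clip((refl[j] - lo) / (hi - lo), 0.0, 1.0)
    luminance = stretched.mean(axis=0)

    intensity = orig.mean(axis=2)
    safe = intensity > epsilon
    ratios = np.ones_like(orig)
    ratios[safe] = orig[safe] / intensity[safe, None]
    out = lambda_brightness * luminance[:, :, None] * ratios

    peak = out.max(axis=2)
    over = peak > 1.0
    if over.any():
        out[over] /= peak[over, None]
    return RgbImage(np.clip(out, 0.0, 1.0).astype(np.float32))


def enhance(image, config: EnhancementConfig | None = None) -> RgbImage:
    """Run the full AMSR pipeline on an RGB image.

    Decompose into R, G, B channels; estimate the illumination of each
    channel with three Gaussian surrounds; weight the three single-scale
    log-domain reflectances per pixel by the frequency-comparison
    coefficient; merge the channels with percentile stretching and
    brightness-compensated chromaticity restoration.  Deterministic given
    the configuration; output dimensions equal input dimensions.
    """
    config = config or EnhancementConfig()
    px = as_pixels(image).astype(np.float64)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("enhance expects an H×W×3 image")
    h, w = px.shape[:2]
    max_radius = min(h, w) - 1
    kernels = [
        build_surround_kernel(s, min(int(np.ceil(3.0 * s)), max_radius))
        for s in config.sigmas
    ]
    refl = np.empty((3, h, w), dtype=np.float64)
    for j in range(3):
        channel = px[:, :, j]
        sig = local_std_map(channel * 255.0, config.local_window)
        wf = frequency_weight(sig, config.a1, config.a2)
        refl[j] = msr_reflectance(channel, kernels, wf, config.log_epsilon)
    return merge_and_compensate(
        refl, px,
        lambda_brightness=config.lambda_brightness,
        output_percentiles=config.output_percentiles,
        epsilon=config.log_epsilon,
    )
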
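"""Spectral preprocessing: wavelet denoising and band lookup.

Denoising uses an orthogonal discrete wavelet transform with universal
soft thresholding.  The transform is implemented here directly (periodic
filter-bank convolutions on a symmetrically extended signal) so the package
carries no wavelet dependency; the default filter is an 8-tap least
asymmetric wavelet with 4 vanishing moments (``sym4``).

Band lookup resolves a requested center wavelength to the nearest grid
channel (ties toward the lower wavelength); derivative lookup returns the
central-difference first derivative at that channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, OutOfRangeError
from .spectra import Spectrum

# Orthonormal decomposition low-pass filters.  Values are the standard
# Daubechies / least-asymmetric coefficients (sum = sqrt(2)).
_WAVELET_FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array([
        -0.12940952255092145, 0.22414386804185735,
        0.836516303737469, 0.48296291314469025,
    ]),
    "db4": np.array([
        -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
        -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
        0.7148465705525415, 0.23037781330885523,
    ]),
    "sym4": np.array([
        -0.07576571478927333, -0.02963552764599851, 0.49761866763201545,
        0.8037387518059161, 0.29785779560527736, -0.09921954357684722,
        -0.012603967262037833, 0.0322231006040427,
    ]),
}


@dataclass(frozen=True)
class DenoiseConfig:
    """Configuration of the wavelet denoise/smooth step."""

    wavelet_name: str = "sym4"
    level: int | None = None  # None = auto: floor(log2 n) - 4, clipped to [1, 6]
    threshold_rule: str = "universal_soft"
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.wavelet_name not in _WAVELET_FILTERS:
            raise ConfigurationError(
                f"unknown wavelet {self.wavelet_name!r}; "
                f"choose from {sorted(_WAVELET_FILTERS)}"
            )
        if self.level is not None and self.level < 1:
            raise ConfigurationError("decomposition level must be >= 1")
        if self.threshold_rule != "universal_soft":
            raise ConfigurationError(
                f"unsupported threshold rule {self.threshold_rule!r}"
            )


def _qmf(h: np.ndarray) -> np.ndarray:
    """High-pass quadrature mirror filter of an orthonormal low-pass h."""
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def _analysis_step(y: np.ndarray, h: np.ndarray, g: np.ndarray):
    """One periodic DWT level: y (even length N) -> (approx, detail), N/2 each.

    a[k] = sum_m h[m] y[(2k+m) mod N]  (and likewise with g).
    """
    n, lf = len(y), len(h)
    ext = np.concatenate([y, y[: lf - 1]])
    corr_h = np.convolve(ext, h[::-1], mode="valid")  # corr_h[i] = sum h[m] y[i+m]
    corr_g = np.convolve(ext, g[::-1], mode="valid")
    return corr_h[::2], corr_g[::2]


def _synthesis_step(a: np.ndarray, d: np.ndarray, h: np.ndarray,
                    g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_analysis_step` (periodic, orthonormal)."""
    n = 2 * len(a)
    up_a = np.zeros(n)
    up_a[::2] = a
    up_d = np.zeros(n)
    up_d[::2] = d
    lf = len(h)
    # x[i] = sum_k a[k] h[(i - 2k) mod n] + d[k] g[(i - 2k) mod n]
    ext_a = np.concatenate([up_a[-(lf - 1):], up_a])
    ext_d = np.concatenate([up_d[-(lf - 1):], up_d])
    return (np.convolve(ext_a, h, mode="valid")
            + np.convolve(ext_d, g, mode="valid"))


def _dwt(y: np.ndarray, h: np.ndarray, level: int):
    g = _qmf(h)
    details = []
    a = y
    for _ in range(level):
        a, d = _analysis_step(a, h, g)
        details.append(d)
    return a, details


def _idwt(a: np.ndarray, details, h: np.ndarray) -> np.ndarray:
    g = _qmf(h)
    for d in reversed(details):
        a = _synthesis_step(a, d, h, g)
    return a


def _auto_level(n: int) -> int:
    return int(np.clip(math.floor(math.log2(n)) - 4, 1, 6))


def wavelet_denoise(s: Spectrum, cfg: DenoiseConfig | None = None) -> Spectrum:
    """Denoise/smooth a spectrum by soft-thresholded wavelet reconstruction.

    The signal is mirror-extended to a smooth periodic sequence, transformed
    with a periodic orthonormal DWT, the detail coefficients are soft
    thresholded at the universal level ``sigma * sqrt(2 ln n)`` (sigma from
    the median absolute deviation of the finest-scale details), and the
    reconstruction is cropped back to the original grid.
    """
    cfg = cfg or DenoiseConfig()
    if not cfg.enabled:
        return s.with_values(s.values.copy(), denoise="disabled")
    n = len(s)
    level = cfg.level if cfg.level is not None else _auto_level(n)
    if n < 2 ** level:
        raise ValueError(
            f"spectrum of length {n} too short for decomposition level {level}"
        )
    h = _WAVELET_FILTERS[cfg.wavelet_name]

    # symmetric extension to a length divisible by 2**level, then mirrored to
    # a smooth periodic signal of twice that length
    block = 2 ** level
    half = max(block // 2, 1)
    n_pad = int(math.ceil(n / half) * half)
    pad = n_pad - n
    y = np.concatenate([s.values, s.values[::-1][:pad]]) if pad else s.values
    y = np.concatenate([y, y[::-1]])  # length 2*n_pad, divisible by 2**level

    approx, details = _dwt(y, h, level)
    sigma = float(np.median(np.abs(details[0])) / 0.6745)
    thr = sigma * math.sqrt(2.0 * math.log(max(n, 2)))
    details = [np.sign(d) * np.maximum(np.abs(d) - thr, 0.0) for d in details]
    rec = _idwt(approx, details, h)[:n]

    out = np.clip(rec, 0.0, None)  # all spectrum kinds are non-negative
    return s.with_values(
        out,
        denoise={
            "wavelet": cfg.wavelet_name,
            "level": level,
            "threshold_rule": cfg.threshold_rule,
            "threshold": thr,
        },
    )


def _nearest_index(s: Spectrum, center: float) -> int:
    wl = s.wavelengths
    spacing = float(np.median(np.diff(wl)))
    tol = 1.5 * spacing
    if center < wl[0] - tol or center > wl[-1] + tol:
        raise OutOfRangeError(
            f"band {center} nm outside grid [{wl[0]}, {wl[-1]}] nm (tol {tol:g})"
        )
    dist = np.abs(wl - center)
    # ties toward the lower wavelength: argmin returns the first minimum
    return int(np.argmin(dist))


def band_value(s: Spectrum, center: float) -> float:
    """Value at the grid wavelength nearest to ``center``."""
    return float(s.values[_nearest_index(s, center)])


def derivative_value(s: Spectrum, center: float) -> float:
    """First derivative dR/dλ at the grid point nearest ``center``.

    Central differences at interior points, one-sided at the grid ends;
    exact for affine spectra at interior points.
    """
    if len(s) < 3:
        raise ValueError("derivative needs a spectrum of length >= 3")
    i = _nearest_index(s, center)
    wl, v = s.wavelengths, s.values
    if i == 0:
        return float((v[1] - v[0]) / (wl[1] - wl[0]))
    if i == len(s) - 1:
        return float((v[-1] - v[-2]) / (wl[-1] - wl[-2]))
    return float((v[i + 1] - v[i - 1]) / (wl[i + 1] - wl[i - 1]))
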
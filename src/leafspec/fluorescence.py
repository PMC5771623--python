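"""Fluorescence band intensities, the 7 published parameters, peak detection.

Band intensity is the mean over a ±2.5 nm window around the requested
center (11 channels on a 0.5 nm grid); a window narrower than the grid
spacing degenerates to the single nearest channel.  The parameter set is
five intensity ratios and two normalized differences built on the blue
(460 nm), green (525 nm), red (685 nm) and far-red (735/740 nm) bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import OutOfRangeError
from .features import UNDEFINED, FeatureTable
from .preprocess import DenoiseConfig, wavelet_denoise
from .spectra import SampleRecord, Spectrum, average_replicates

logger = logging.getLogger(__name__)

#: Windows searched by :func:`detect_peaks` (blue, red, far-red).
PEAK_WINDOWS = ((440.0, 465.0), (680.0, 690.0), (730.0, 740.0))


@dataclass(frozen=True)
class FluorescenceBandSpec:
    """A fluorescence extraction band: center and half window width (nm)."""

    center: float
    half_window: float = 2.5

    def __post_init__(self) -> None:
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")


def fluorescence_band(s: Spectrum, spec: FluorescenceBandSpec) -> float:
    """Mean intensity within [center - hw, center + hw] (inclusive).

    If no channel falls inside the window, the single nearest channel is
    used, provided the window overlaps the grid coverage at all.
    """
    wl = s.wavelengths
    lo, hi = spec.center - spec.half_window, spec.center + spec.half_window
    if hi < wl[0] or lo > wl[-1]:
        raise OutOfRangeError(
            f"band window [{lo}, {hi}] nm outside grid [{wl[0]}, {wl[-1]}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        return float(s.values[int(np.argmin(np.abs(wl - spec.center)))])
    return float(np.mean(s.values[mask]))


#: The 7 published parameters as (name, numerator-form) recipes.
def _parameter_recipes(far_red_center: float):
    fr = "%g" % far_red_center
    return [
        (f"F{fr}_F685", ("ratio", far_red_center, 685.0)),
        (f"F{fr}_F460", ("ratio", far_red_center, 460.0)),
        ("F685_F460", ("ratio", 685.0, 460.0)),
        ("F685_F525", ("ratio", 685.0, 525.0)),
        (f"F{fr}_F525", ("ratio", far_red_center, 525.0)),
        ("ND_460_685", ("nd", 460.0, 685.0)),
        (f"ND_460_{fr}", ("nd", 460.0, far_red_center)),
    ]


def fluorescence_parameter_names(far_red_center: float = 740.0) -> list[str]:
    return [name for name, _ in _parameter_recipes(far_red_center)]


def compute_fluorescence_params(samples: list[SampleRecord],
                                half_window: float = 2.5,
                                far_red_center: float = 740.0,
                                denoise: DenoiseConfig | None = None
                                ) -> FeatureTable:
    """The 7 fluorescence parameters for each sample.

    Replicates are averaged (and optionally denoised) before band
    extraction.  ``far_red_center`` selects 740 (default) or 735 nm for the
    far-red band; the feature names record the center used.  Zero
    denominators yield NaN sentinels with a warning.
    """
    recipes = _parameter_recipes(far_red_center)
    names = [n for n, _ in recipes]
    rows = np.full((len(samples), len(recipes)), UNDEFINED)
    for i, rec in enumerate(samples):
        if not rec.fluorescence_reps:
            logger.warning("sample %s has no fluorescence replicates; "
                           "emitting sentinel row", rec.sample_id)
            continue
        spec = average_replicates(rec.fluorescence_reps)
        if denoise is not None and denoise.enabled:
            spec = wavelet_denoise(spec, denoise)
        bands: dict[float, float] = {}
        for c in (far_red_center, 685.0, 525.0, 460.0):
            try:
                bands[c] = fluorescence_band(
                    spec, FluorescenceBandSpec(c, half_window))
            except OutOfRangeError as exc:
                raise OutOfRangeError(
                    f"sample {rec.sample_id}: {exc}") from exc
        for j, (name, (form, a, b)) in enumerate(recipes):
            fa, fb = bands[a], bands[b]
            den = fb if form == "ratio" else fa + fb
            if den == 0.0:
                logger.warning("sample %s: parameter %s has zero denominator",
                               rec.sample_id, name)
                continue
            rows[i, j] = fa / fb if form == "ratio" else (fa - fb) / den
    return FeatureTable([r.sample_id for r in samples], names, rows)


def _smooth(values: np.ndarray, width: int = 5) -> np.ndarray:
    """Symmetric moving average with edge-reflected padding."""
    if width <= 1:
        return values
    pad = width // 2
    ext = np.concatenate([values[pad:0:-1], values, values[-2:-2 - pad:-1]])
    kernel = np.ones(width) / width
    return np.convolve(ext, kernel, mode="valid")


def detect_peaks(s: Spectrum, smooth_width: int = 5) -> list[float]:
    """Fluorescence peak wavelengths in the blue/red/far-red search windows.

    For each window the in-window maximum of the lightly smoothed curve is
    returned, provided it is a genuine local maximum: strictly greater than
    its immediate neighbors and than the channels just outside both window
    edges.  Windows without a qualifying maximum are omitted.
    """
    wl = s.wavelengths
    sm = _smooth(s.values, smooth_width)
    peaks: list[float] = []
    for lo, hi in PEAK_WINDOWS:
        mask = (wl >= lo) & (wl <= hi)
        idx_in = np.nonzero(mask)[0]
        if idx_in.size == 0:
            continue
        k = idx_in[int(np.argmax(sm[idx_in]))]
        left = idx_in[0] - 1
        right = idx_in[-1] + 1
        ok = 0 < k < len(wl) - 1 and sm[k] > sm[k - 1] and sm[k] > sm[k + 1]
        if ok and left >= 0:
            ok = sm[k] > sm[left]
        if ok and right < len(wl):
            ok = sm[k] > sm[right]
        if ok:
            peaks.append(float(wl[k]))
    return peaks
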
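"""Synthetic paired reflectance + fluorescence leaf spectra.

The generator draws a leaf-nitrogen value per sample and emits replicate
spectra of both modalities whose structure tracks nitrogen through a
pigment intermediate:

* reflectance (350-2500 nm, 1 nm): near-infrared plateau, logistic red-edge
  rise near 715 nm, pigment absorption wells at 450/670 nm whose depth
  grows with the pigment level, fixed water dips at 1450/1940 nm, additive
  Gaussian replicate noise;
* fluorescence (360-800 nm, 0.5 nm): three Gaussian peaks at 460/685/735 nm
  with the red and far-red amplitudes (relative to the blue peak)
  increasing in nitrogen, multiplicative lognormal replicate noise.

``coupling`` scales the nitrogen -> spectrum links; at 0 the spectra are
statistically independent of the label (the pipeline's null case).  All
shape constants live in :data:`GENERATOR_DEFAULTS` and are version-stamped
because downstream skill thresholds depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SampleRecord, Spectrum

GENERATOR_VERSION = "1.0"

#: Frozen shape constants of the two spectral models.
GENERATOR_DEFAULTS = {
    "refl_grid": (350.0, 2500.0, 1.0),
    "fluo_grid": (360.0, 800.0, 0.5),
    "nir_plateau": 0.47,
    "visible_base": 0.26,
    "red_edge_center": 715.0,
    "red_edge_width": 12.0,
    "well_blue": (450.0, 28.0, 0.18),   # center, sd, max depth coeff
    "well_red": (670.0, 34.0, 0.21),
    "water_dips": ((1450.0, 45.0, 0.24), (1940.0, 65.0, 0.30)),
    "pigment_base": 0.15,
    "pigment_slope": 0.28,              # per unit LNC, scaled by coupling
    "lnc_anchor": 1.5,
    "fluo_peaks": (460.0, 685.0, 735.0),
    "fluo_widths": (12.0, 9.0, 14.0),
    "blue_amplitude": 100.0,
    "red_ratio_base": 0.45,
    "red_ratio_slope": 0.62,            # per unit LNC, scaled by coupling
    "farred_ratio_base": 0.55,
    "farred_ratio_slope": 0.75,
    "fluo_floor": 0.5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset draw."""

    n_samples: int = 100
    lnc_range: tuple[float, float] = (1.5, 4.0)
    noise_sd_reflectance: float = 0.005
    noise_sd_fluorescence: float = 0.02   # relative (lognormal) sigma
    n_reflectance_reps: int = 3
    n_fluorescence_reps: int = 5
    seed: int = 0
    coupling: float = 0.8
    #: per-modality overrides of ``coupling``; None means use ``coupling``
    coupling_reflectance: float | None = None
    coupling_fluorescence: float | None = None
    #: sample-level (lognormal) biological scatter on the nitrogen->pigment
    #: and nitrogen->peak-ratio links; independent between modalities
    pigment_scatter_sd: float = 0.15
    ratio_scatter_sd: float = 0.17

    def __post_init__(self) -> None:
        lo, hi = self.lnc_range
        if not lo < hi:
            raise ValueError("lnc_range must satisfy low < high")
        if self.noise_sd_reflectance < 0 or self.noise_sd_fluorescence < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_reflectance_reps < 1 or self.n_fluorescence_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        for c in (self.coupling, self.coupling_reflectance,
                  self.coupling_fluorescence):
            if c is not None and not 0.0 <= c <= 1.0:
                raise ValueError("coupling must be in [0, 1]")

    @property
    def refl_coupling(self) -> float:
        return (self.coupling if self.coupling_reflectance is None
                else self.coupling_reflectance)

    @property
    def fluo_coupling(self) -> float:
        return (self.coupling if self.coupling_fluorescence is None
                else self.coupling_fluorescence)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _pigment_level(lnc: float, cfg: SyntheticConfig, rng: np.random.Generator
                   ) -> float:
    """Nitrogen -> pigment link: affine in LNC plus lognormal scatter."""
    g = GENERATOR_DEFAULTS
    mean = g["pigment_base"] + g["pigment_slope"] * cfg.refl_coupling * (
        lnc - g["lnc_anchor"])
    scatter = (np.exp(rng.normal(0.0, cfg.pigment_scatter_sd))
               if cfg.pigment_scatter_sd > 0 else 1.0)
    return float(np.clip(mean * scatter, 0.02, 1.2))


def reflectance_model(lnc: float, cfg: SyntheticConfig,
                      rng: np.random.Generator,
                      pigment: float | None = None) -> Spectrum:
    """One replicate reflectance spectrum for a leaf with the given LNC.

    ``pigment`` overrides the drawn pigment level; :func:`generate_dataset`
    uses it to share one sample-level pigment draw across replicates.
    """
    g = GENERATOR_DEFAULTS
    wl = _grid(*g["refl_grid"])
    pig = _pigment_level(lnc, cfg, rng) if pigment is None else pigment

    edge = 1.0 / (1.0 + np.exp(-(wl - g["red_edge_center"])
                               / g["red_edge_width"]))
    r = g["visible_base"] + (g["nir_plateau"] - g["visible_base"]) * edge

    wells = np.zeros_like(wl)
    for mu, sd, depth in (g["well_blue"], g["well_red"]):
        wells += depth * pig * _gauss(wl, mu, sd)
    r -= wells * (1.0 - edge)  # pigment wells act on the visible side only

    for mu, sd, depth in g["water_dips"]:
        r -= depth * _gauss(wl, mu, sd)

    if cfg.noise_sd_reflectance > 0:
        r = r + rng.normal(0.0, cfg.noise_sd_reflectance, size=wl.shape)
    r = np.clip(r, 0.001, 0.999)
    return Spectrum(wl, r, "reflectance",
                    {"lnc": lnc, "pigment": pig,
                     "generator_version": GENERATOR_VERSION})


def peak_ratios(lnc: float, cfg: SyntheticConfig) -> tuple[float, float]:
    """Noise-free (red/blue, far-red/blue) amplitude ratios at a given LNC."""
    g = GENERATOR_DEFAULTS
    dl = cfg.fluo_coupling * (lnc - g["lnc_anchor"])
    r_red = max(g["red_ratio_base"] + g["red_ratio_slope"] * dl, 0.02)
    r_farred = max(g["farred_ratio_base"] + g["farred_ratio_slope"] * dl, 0.02)
    return r_red, r_farred


def fluorescence_model(lnc: float, cfg: SyntheticConfig,
                       rng: np.random.Generator,
                       ratio_scale: tuple[float, float] | None = None
                       ) -> Spectrum:
    """One replicate fluorescence emission spectrum for the given LNC.

    ``ratio_scale`` multiplies the (red, far-red) peak ratios; if None it is
    drawn here (lognormal, sd ``cfg.ratio_scatter_sd``).
    :func:`generate_dataset` shares one sample-level draw across replicates.
    """
    g = GENERATOR_DEFAULTS
    wl = _grid(*g["fluo_grid"])
    if ratio_scale is None:
        ratio_scale = _ratio_scatter(cfg, rng)
    r_red, r_farred = peak_ratios(lnc, cfg)
    r_red *= ratio_scale[0]
    r_farred *= ratio_scale[1]

    a = g["blue_amplitude"]
    amps = (a, a * r_red, a * r_farred)
    f = np.full_like(wl, g["fluo_floor"])
    for amp, mu, sd in zip(amps, g["fluo_peaks"], g["fluo_widths"]):
        f += amp * _gauss(wl, mu, sd)

    if cfg.noise_sd_fluorescence > 0:
        f = f * np.exp(rng.normal(0.0, cfg.noise_sd_fluorescence,
                                  size=wl.shape))
    return Spectrum(wl, np.clip(f, 0.0, None), "fluorescence",
                    {"lnc": lnc, "generator_version": GENERATOR_VERSION})


def _ratio_scatter(cfg: SyntheticConfig, rng: np.random.Generator
                   ) -> tuple[float, float]:
    if cfg.ratio_scatter_sd <= 0:
        return (1.0, 1.0)
    s = np.exp(rng.normal(0.0, cfg.ratio_scatter_sd, size=2))
    return (float(s[0]), float(s[1]))


def generate_dataset(cfg: SyntheticConfig) -> list[SampleRecord]:
    """Draw a full synthetic dataset, reproducible from ``cfg.seed``.

    Each sample gets a uniform LNC draw, one sample-level biological
    scatter draw per modality (independent between modalities), and
    ``n_reflectance_reps`` / ``n_fluorescence_reps`` replicates with
    independent measurement noise.  Generation parameters are recorded in
    each record's metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.lnc_range
    records: list[SampleRecord] = []
    for i in range(cfg.n_samples):
        lnc = float(rng.uniform(lo, hi))
        pigment = _pigment_level(lnc, cfg, rng)
        ratio_scale = _ratio_scatter(cfg, rng)
        refl = [reflectance_model(lnc, cfg, rng, pigment=pigment)
                for _ in range(cfg.n_reflectance_reps)]
        fluo = [fluorescence_model(lnc, cfg, rng, ratio_scale=ratio_scale)
                for _ in range(cfg.n_fluorescence_reps)]
        records.append(SampleRecord(
            sample_id=f"S{i:04d}",
            year=0,
            n_rate=0.0,
            lnc=lnc,
            reflectance_reps=refl,
            fluorescence_reps=fluo,
            meta={"generator_version": GENERATOR_VERSION,
                  "coupling": cfg.coupling,
                  "seed": cfg.seed},
        ))
    return records
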
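"""Pipeline configuration file handling (YAML key-value blocks)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .modeling import KernelSpec, SvrConfig
from .preprocess import DenoiseConfig


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the analysis pipeline, in one place."""

    denoise: DenoiseConfig = DenoiseConfig()
    svr: SvrConfig = SvrConfig()
    far_red_center: float = 740.0
    fluor_half_window: float = 2.5
    msr_mode: str = "canonical"
    rep_mode: str = "canonical"

    def digest(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        payload = {
            "denoise": {
                "wavelet": self.denoise.wavelet_name,
                "level": self.denoise.level,
                "threshold_rule": self.denoise.threshold_rule,
                "enabled": self.denoise.enabled,
            },
            "svr": {
                "C": self.svr.C,
                "epsilon": self.svr.epsilon,
                "standardize": self.svr.standardize,
                "gamma": None if self.svr.kernel is None else self.svr.kernel.gamma,
                "d": None if self.svr.kernel is None else self.svr.kernel.d,
            },
            "far_red_center": self.far_red_center,
            "fluor_half_window": self.fluor_half_window,
            "msr_mode": self.msr_mode,
            "rep_mode": self.rep_mode,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config file; a None path yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a key-value mapping")

    dn = raw.get("denoise", {})
    denoise = DenoiseConfig(
        wavelet_name=dn.get("wavelet", "sym4"),
        level=dn.get("level"),
        threshold_rule=dn.get("threshold_rule", "universal_soft"),
        enabled=bool(dn.get("enabled", True)),
    )
    sv = raw.get("svr", {})
    kernel = None
    if "gamma" in sv or "d" in sv:
        kernel = KernelSpec(gamma=float(sv.get("gamma", 1.0)),
                            d=int(sv.get("d", 1)))
    svr = SvrConfig(
        kernel=kernel,
        C=float(sv.get("C", 10.0)),
        epsilon=float(sv.get("epsilon", 0.1)),
        standardize=bool(sv.get("standardize", True)),
    )
    bands = raw.get("bands", {})
    indices = raw.get("indices", {})
    return PipelineConfig(
        denoise=denoise,
        svr=svr,
        far_red_center=float(bands.get("far_red_center", 740.0)),
        fluor_half_window=float(bands.get("fluor_half_window", 2.5)),
        msr_mode=indices.get("msr_mode", "canonical"),
        rep_mode=indices.get("rep_mode", "canonical"),
    )
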
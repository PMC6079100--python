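"""Pipeline configuration: YAML in, validated defaults out.

Unknown keys are rejected with a nearest-match suggestion; thresholds are
range-checked.  The effective values are echoed so every run records the
parameters it actually used.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Defaulted, validated pipeline parameters."""

    alpha: float = 0.01               # RSA hit threshold (strict <)
    rpkm_threshold: float = 1.0       # expression filter
    trim_length: int = 20             # FASTQ prefix match length
    tss_window: int = 50_000          # peak-to-gene assignment window, bp
    fragment_cutoff: int = 146        # nucleosomal insert-size boundary, bp
    knn_k: int = 10                   # MAR imputation neighbours
    lfc_threshold: float = 1.0        # signature log2FC cut (strict >)
    fdr_threshold: float = 0.05       # signature FDR cut (strict <)
    quantile_interpolation: str = "linear"
    seed: int = 0
    outdir: str = "results"

    _RANGES = {
        "alpha": (0.0, 1.0, False),          # open interval
        "rpkm_threshold": (0.0, float("inf"), True),
        "trim_length": (1, 10_000, True),
        "tss_window": (0, None, True),
        "fragment_cutoff": (1, None, True),
        "knn_k": (1, None, True),
        "lfc_threshold": (0.0, None, True),
        "fdr_threshold": (0.0, 1.0, False),
    }

    def validate(self) -> "PipelineConfig":
        for key, (lo, hi, closed) in self._RANGES.items():
            v = getattr(self, key)
            below = v < lo if closed else v <= lo
            above = False
            if hi is not None:
                above = v > hi if closed else v >= hi
            if below or above:
                raise ConfigError(
                    f"config value out of range: {key}={v!r}"
                )
        if self.quantile_interpolation not in ("linear", "lower", "higher",
                                               "midpoint", "nearest"):
            raise ConfigError(
                f"unknown quantile_interpolation "
                f"{self.quantile_interpolation!r}"
            )
        return self

    def effective(self) -> dict:
        return {k: v for k, v in asdict(self).items()}


def validate_config(text: Optional[str] = None, **overrides) -> PipelineConfig:
    """Parse YAML config text, apply overrides, validate.

    An empty/None text yields all defaults.  Unknown keys raise a
    :class:`ConfigError` that suggests the closest known key.
    """
    values = {}
    if text:
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config must be a mapping of key: value")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})

    known = {f for f in PipelineConfig.__dataclass_fields__
             if not f.startswith("_")}
    for key in values:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
    return PipelineConfig(**values).validate()
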
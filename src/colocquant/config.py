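"""Pipeline configuration: every tunable in one serializable object.

The config round-trips through a flat ``key = value`` text file so a run
can be reproduced exactly from its recorded settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["WaveletConfig", "CostesConfig", "AssayConfig", "StatsConfig",
           "PipelineConfig"]


@dataclass
class WaveletConfig:
    n_scales: int = 4          # decomposition depth J
    drop_finest: int = 1       # finest planes discarded (speckle)
    drop_residual: bool = True  # discard smooth background
    enabled: bool = True

    def validate(self) -> None:
        if self.n_scales < 1:
            raise ValueError("wavelet.n_scales must be >= 1")
        if not 0 <= self.drop_finest <= self.n_scales:
            raise ValueError("wavelet.drop_finest out of range")
        if self.drop_finest == self.n_scales and self.drop_residual:
            raise ValueError("wavelet config drops every plane")


@dataclass
class CostesConfig:
    step: float = 1.0 / 255.0  # threshold quantum; 1/65535 for 16-bit data

    def validate(self) -> None:
        if not 0.0 < self.step <= 1.0:
            raise ValueError("costes.step must be in (0, 1]")


@dataclass
class AssayConfig:
    min_nucleus_area: int = 40      # px; smaller components are debris
    dilation_radius: int = 8        # px; nucleus -> approximate cell region
    positivity_threshold: float = 0.05  # mean marker intensity per cell

    def validate(self) -> None:
        if self.min_nucleus_area < 1:
            raise ValueError("assay.min_nucleus_area must be >= 1")
        if self.dilation_radius < 0:
            raise ValueError("assay.dilation_radius must be >= 0")
        if not 0.0 <= self.positivity_threshold <= 1.0:
            raise ValueError("assay.positivity_threshold must be in [0, 1]")


@dataclass
class StatsConfig:
    variant: str = "student"  # "student" (pooled) or "welch"
    # significance stars: p below each threshold earns one more star
    star_thresholds: tuple[float, ...] = (0.005,)

    def validate(self) -> None:
        if self.variant not in ("student", "welch"):
            raise ValueError("stats.variant must be 'student' or 'welch'")
        if any(not 0.0 < t < 1.0 for t in self.star_thresholds):
            raise ValueError("star thresholds must be in (0, 1)")


@dataclass
class PipelineConfig:
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    costes: CostesConfig = field(default_factory=CostesConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    positivity_epsilon: float = 1e-12
    seed: int = 0

    def validate(self) -> None:
        self.wavelet.validate()
        self.costes.validate()
        self.assay.validate()
        self.stats.validate()
        if self.positivity_epsilon < 0:
            raise ValueError("positivity_epsilon must be >= 0")

    # -- flat key=value serialization ------------------------------------
    def to_flat(self) -> dict[str, str]:
        flat: dict[str, str] = {}
        for section in ("wavelet", "costes", "assay", "stats"):
            for k, v in asdict(getattr(self, section)).items():
                if isinstance(v, (list, tuple)):
                    flat[f"{section}.{k}"] = ",".join(repr(x) for x in v)
                else:
                    flat[f"{section}.{k}"] = repr(v)
        flat["positivity_epsilon"] = repr(self.positivity_epsilon)
        flat["seed"] = repr(self.seed)
        return flat

    def save(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(self.to_flat().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            cfg._set(key, val)
        cfg.validate()
        return cfg

    def _set(self, key: str, val: str) -> None:
        import ast
        if key == "stats.star_thresholds":
            parsed = tuple(float(x) for x in val.split(",") if x.strip())
        else:
            parsed = ast.literal_eval(val)
        if "." in key:
            section, attr = key.split(".", 1)
            obj = getattr(self, section)
            if not hasattr(obj, attr):
                raise KeyError(f"unknown config key {key!r}")
            setattr(obj, attr, parsed)
        else:
            if not hasattr(self, key):
                raise KeyError(f"unknown config key {key!r}")
            setattr(self, key, parsed)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_flat(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
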
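"""Pipeline configuration (YAML) with validated defaults."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

__all__ = ["ConfigError", "PipelineConfig"]


class ConfigError(ValueError):
    pass


_DEFAULT_TOLERANCES = {
    "ppm": 10.0,
    "rt": 0.2,
    "z_max": 8,
    "max_labels": 8,
    "max_isotopomers": 3,
}
_DEFAULT_CAPS = {"low": 0.20, "high": 5.0}


@dataclass
class PipelineConfig:
    """Validated view over the raw YAML configuration.

    Either a ``simulate`` section (inputs are generated) or an ``inputs``
    section (paths to peak-list TSV, FASTA, identifications TSV, scheme YAML)
    must be present.
    """

    raw: Dict[str, Any]
    path: Optional[Path] = None

    def __post_init__(self) -> None:
        if "simulate" not in self.raw and "inputs" not in self.raw:
            raise ConfigError("config needs a 'simulate' or an 'inputs' section")
        caps = self.caps
        if caps["high"] is not None and not 0 < caps["low"] < caps["high"]:
            raise ConfigError("caps must satisfy 0 < low < high")
        tol = self.tolerances
        if tol["ppm"] <= 0 or tol["rt"] < 0:
            raise ConfigError("tolerances must be positive")
        if self.counting_mode not in ("per_replicate", "per_experiment"):
            raise ConfigError("counting_mode must be per_replicate or per_experiment")
        if "inputs" in self.raw:
            for key in ("runs", "fasta", "identifications", "scheme"):
                p = self.raw["inputs"].get(key)
                if p is None:
                    raise ConfigError(f"inputs section missing {key!r}")
                if not self._resolve(p).exists():
                    raise ConfigError(f"input file not found: {p}")

    def _resolve(self, p) -> Path:
        p = Path(p)
        if not p.is_absolute() and self.path is not None:
            return self.path.parent / p
        return p

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw=raw, path=path)

    # -- accessors -------------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def tolerances(self) -> Dict[str, Any]:
        return {**_DEFAULT_TOLERANCES, **self.raw.get("tolerances", {})}

    @property
    def caps(self) -> Dict[str, Optional[float]]:
        caps = {**_DEFAULT_CAPS, **self.raw.get("caps", {})}
        return {"low": float(caps["low"]), "high": None if caps["high"] is None else float(caps["high"])}

    @property
    def counting_mode(self) -> str:
        return self.raw.get("counting_mode", "per_replicate")

    @property
    def simulate(self) -> Optional[Dict[str, Any]]:
        return self.raw.get("simulate")

    @property
    def inputs(self) -> Optional[Dict[str, str]]:
        sec = self.raw.get("inputs")
        if sec is None:
            return None
        return {k: str(self._resolve(v)) for k, v in sec.items()}

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]
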
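"""Run configuration: YAML loading, presets, validation and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Named featurization operating points. ``svm11`` keeps the four coarsest
#: coefficient blocks of the full 11-concentration-plus-NC input; ``svm1``
#: keeps the complete coefficient set of the highest concentration plus NC.
FEATURE_PRESETS = {
    "svm11": {"n_concentrations": 11, "include_nc": True, "level": 5, "kept_blocks": 4},
    "svm1": {"n_concentrations": 1, "include_nc": True, "level": 5, "kept_blocks": 6},
    "raw11": {"n_concentrations": 11, "include_nc": True, "level": 5, "kept_blocks": None},
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, validated up front."""

    featurization: dict = field(
        default_factory=lambda: dict(FEATURE_PRESETS["svm11"])
    )
    classifier: str = "svm"
    classifier_params: dict = field(default_factory=dict)
    repetitions: int = 100
    train_fraction: float = 0.7
    tree_structures: list = field(default_factory=list)
    drc_variant: str = "point"
    drc_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        feat = self.featurization
        n = feat.get("n_concentrations", 11)
        if not 1 <= n <= 11:
            raise ConfigError(f"n_concentrations must be in 1..11, got {n}")
        level = feat.get("level", 5)
        if level < 1:
            raise ConfigError(f"level must be >= 1, got {level}")
        m = feat.get("kept_blocks", 4)
        if m is not None and not 1 <= m <= level + 1:
            raise ConfigError(f"kept_blocks must be in 1..{level + 1} or null, got {m}")
        if self.classifier not in ("svm", "ann"):
            raise ConfigError(f"classifier must be 'svm' or 'ann', got {self.classifier!r}")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.drc_variant not in ("point", "auc"):
            raise ConfigError(f"drc_variant must be 'point' or 'auc', got {self.drc_variant!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        preset = data.pop("preset", None)
        config = cls(**data)
        if preset is not None:
            config.apply_preset(preset)
        return config

    def apply_preset(self, name: str) -> None:
        if name not in FEATURE_PRESETS:
            raise ConfigError(
                f"unknown preset {name!r}; available: {sorted(FEATURE_PRESETS)}"
            )
        self.featurization = dict(FEATURE_PRESETS[name])

    def digest(self) -> str:
        """Stable short hash of the whole configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
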
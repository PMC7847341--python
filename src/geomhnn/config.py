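"""Run configuration: defaults, YAML loading, validation.

Every knob of the enhancement pipeline lives here so a run is fully
described by one document.  Unknown keys are rejected rather than ignored,
so a typo in a config file fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables of the enhancement pipeline.

    Q defaults to None, meaning "derive from hyperplane_dim via the class
    count branch formula" (dimension 2 gives Q = 5).
    """

    patch_rows: int = 22
    patch_cols: int = 20
    neighborhood: int = 4            # 4 or 8 connectivity
    kappa0: float = 0.1              # base coupling strength
    hyperplane_dim: int = 2
    Q: int | None = None             # explicit class count overrides hyperplane_dim
    alpha: float = 0.7               # blend of stretched vs original intensities
    max_sweeps: int = 100
    seed: int = 0
    smoothness_sign: str = "potts"   # "potts" rewards agreement, "paper" penalizes
    recompute_orientation: bool = False
    prototype_method: str = "quantile"  # or "kmeans"
    window_shape: str = "gaussian"
    window_size: int = 5
    window_sigma: float = 1.0
    gradient_operator: str = "central"  # or "sobel"
    quantize_output: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.smoothness_sign not in ("potts", "paper"):
            raise ValueError("smoothness_sign must be 'potts' or 'paper'")
        if self.prototype_method not in ("quantile", "kmeans"):
            raise ValueError("prototype_method must be 'quantile' or 'kmeans'")
        if self.Q is not None and self.Q < 2:
            raise ValueError("Q must be >= 2")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Precedence: built-in defaults < YAML file < overrides (CLI flags).
    Unknown keys in either source raise ValueError.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        doc.update(loaded)
    doc.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)
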
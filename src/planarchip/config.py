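"""Run configuration: a fully serializable description of one simulation.

Units policy (stated in every output header): wavelengths and layer
thicknesses in nm, object-space lengths in um, transverse wavenumbers as
fractions of k0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .otf import PolarizerPair
from .stacks import default_chip, load_stack
from .tmm import LayerStack


@dataclass
class RunConfig:
    stack: str = "default"                # "default" or a stack-file path
    wavelength_nm: float = 643.0
    na: float = 0.45
    k_samples: int = 129
    polarizers: str = "crossed"           # "crossed" | "parallel"
    object: dict = field(default_factory=lambda: {"type": "step", "sigma_um": 0.3,
                                                  "angle_deg": 45.0})
    offset: tuple = (0.0, 0.0)
    pitch_um: float = 0.1
    shape: tuple = (512, 512)
    wavelength_range_nm: tuple = (600.0, 700.0, 0.5)
    frequency_range_thz: tuple = (350.0, 550.0, 1.0)
    output_dir: str = "planarchip_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys in {path}: {sorted(unknown)}")
        cfg = cls(**doc)
        for tup in ("offset", "shape", "wavelength_range_nm", "frequency_range_thz"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg

    def resolve_stack(self) -> LayerStack:
        if self.stack == "default":
            return default_chip()
        return load_stack(self.stack)

    def resolve_polarizers(self) -> PolarizerPair:
        if self.polarizers == "crossed":
            return PolarizerPair.crossed()
        if self.polarizers == "parallel":
            return PolarizerPair.parallel()
        raise ConfigError(f"polarizers must be 'crossed' or 'parallel', got {self.polarizers!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def stack_hash(stack: LayerStack) -> str:
    """Provenance hash of a stack with constant indices (12 hex chars)."""
    try:
        doc = {
            "sup": repr(stack.superstrate), "sub": repr(stack.substrate),
            "layers": [(l.thickness_nm, repr(l.index)) for l in stack.layers],
        }
    except Exception:  # pragma: no cover - callables fall back to object repr
        doc = {"repr": repr(stack)}
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]
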
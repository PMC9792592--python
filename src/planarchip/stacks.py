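"""Stack description files and the bundled default chip.

File format (YAML or JSON)::

    superstrate: air            # material name or number
    substrate: glass
    materials:
      air: 1.0
      glass: 1.52
      Si3N4: 2.02
      SiO2: 1.46
      dispersive_example:       # wavelength_nm -> complex index table
        - [500.0, 2.10, 0.0]
        - [700.0, 2.00, 0.0]
    layers:
      - {material: Si3N4, d_nm: 56}
      - {material: SiO2,  d_nm: 80}
      ...

A layer may alternatively carry a literal index: ``{n: 2.02, d_nm: 56}``.
Dispersion tables are interpolated linearly in wavelength (real and
imaginary parts separately).

The bundled ``chip40.yaml`` encodes the default 40-layer design: alternating
Si3N4 (56 nm) / SiO2 (80 nm), starting with Si3N4 on the illumination side,
deposited on a glass coverslip treated as semi-infinite.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .tmm import Layer, LayerStack

__all__ = ["load_stack", "save_stack", "default_chip", "default_chip_path"]

# stand-in constants for PECVD-grown films and a standard coverslip
N_SI3N4 = 2.02
N_SIO2 = 1.46
N_GLASS = 1.52
N_AIR = 1.0


class _DispersionTable:
    """Linear interpolation of a (wavelength_nm, n_re, n_im) table."""

    def __init__(self, rows):
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] not in (2, 3):
            raise ConfigError("dispersion table rows must be [lam_nm, n_re] or [lam_nm, n_re, n_im]")
        order = np.argsort(arr[:, 0])
        self.lam = arr[order, 0]
        self.n_re = arr[order, 1]
        self.n_im = arr[order, 2] if arr.shape[1] == 3 else np.zeros_like(self.lam)

    def __call__(self, wavelength_nm: float) -> complex:
        return complex(
            np.interp(wavelength_nm, self.lam, self.n_re),
            np.interp(wavelength_nm, self.lam, self.n_im),
        )


def _parse_index(value, materials: Mapping[str, object], context: str):
    if isinstance(value, str):
        if value not in materials:
            raise ConfigError(f"unknown material {value!r} referenced by {context}")
        value = materials[value]
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, complex):
        return value
    if isinstance(value, (list, tuple)):
        return _DispersionTable(value)
    if isinstance(value, _DispersionTable) or callable(value):
        return value
    raise ConfigError(f"cannot interpret refractive index {value!r} for {context}")


def load_stack(path) -> LayerStack:
    """Read a stack description from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse stack file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"stack file {path} must contain a mapping at top level")
    materials = doc.get("materials", {}) or {}
    try:
        sup = _parse_index(doc.get("superstrate", 1.0), materials, "key 'superstrate'")
        sub = _parse_index(doc.get("substrate", 1.0), materials, "key 'substrate'")
        layers = []
        for i, spec in enumerate(doc.get("layers", []) or []):
            if "d_nm" not in spec:
                raise ConfigError(f"layer {i} is missing key 'd_nm'")
            ref = spec.get("material", spec.get("n"))
            if ref is None:
                raise ConfigError(f"layer {i} needs key 'material' or 'n'")
            layers.append(Layer(float(spec["d_nm"]), _parse_index(ref, materials, f"layer {i}")))
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"malformed stack file {path}: {exc}") from exc
    return LayerStack(layers, superstrate=sup, substrate=sub)


def save_stack(stack: LayerStack, path, materials: Mapping[str, float] | None = None) -> None:
    """Write a stack description to YAML (constant indices only)."""
    inv = {complex(v): k for k, v in (materials or {}).items()}

    def encode(n):
        if callable(n):
            raise ConfigError("cannot serialize callable dispersion models to YAML")
        n = complex(n)
        if n in inv:
            return inv[n]
        return n.real if n.imag == 0 else [n.real, n.imag]

    doc = {
        "superstrate": encode(stack.n_sup(0) if callable(stack.superstrate) else stack.superstrate),
        "substrate": encode(stack.substrate),
        "materials": dict(materials or {}),
        "layers": [{"material" if isinstance(encode(l.index), str) else "n": encode(l.index),
                    "d_nm": float(l.thickness_nm)} for l in stack.layers],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_chip(
    n_layers: int = 40,
    d_high_nm: float = 56.0,
    d_low_nm: float = 80.0,
    n_high: float = N_SI3N4,
    n_low: float = N_SIO2,
    superstrate: float = N_AIR,
    substrate: float = N_GLASS,
    start_high: bool = True,
) -> LayerStack:
    """The default multilayer differentiator chip.

    40 alternating Si3N4 (56 nm) / SiO2 (80 nm) layers, Si3N4 adjacent to the
    air superstrate, on a semi-infinite glass coverslip.  All parameters are
    overridable; ``substrate=1.0`` gives the idealized symmetric-air chip.
    """
    seq = [(n_high, d_high_nm), (n_low, d_low_nm)]
    if not start_high:
        seq.reverse()
    layers = [Layer(d, n) for i in range(n_layers) for (n, d) in [seq[i % 2]]]
    return LayerStack(layers, superstrate=superstrate, substrate=substrate)


def default_chip_path() -> Path:
    """Filesystem path of the bundled chip40.yaml description."""
    return Path(resources.files("planarchip") / "data" / "chip40.yaml")
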
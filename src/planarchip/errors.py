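"""Exception types shared across the package.

Exit-code mapping used by the CLI: :class:`ConfigError` -> 2,
:class:`PhysicsError` (and subclasses) -> 3.
"""


class ConfigError(Exception):
    """Malformed configuration or stack-description input."""


class PhysicsError(ValueError):
    """A physical precondition of an optical computation is violated."""


class EvanescentIncidenceError(PhysicsError):
    """Incident in-plane wavenumber at or beyond the propagation cutoff
    of the incidence medium (kr >= n_sup * k0)."""


class GridError(PhysicsError):
    """Sampling grid cannot support the requested computation
    (Nyquist/NA violation, cut outside the aperture, ...)."""
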
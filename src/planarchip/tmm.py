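"""Transfer-matrix solver for stratified dielectric multilayers.

Computes complex amplitude reflection/transmission of a plane wave through a
stack of homogeneous layers between two semi-infinite media, for s and p
polarization, at any propagating angle of incidence and wavelength.

Conventions
-----------
* Characteristic (Abeles) 2x2 matrix per layer with phase thickness
  ``delta_j = (2*pi/lam) * n_j * d_j * cos(theta_j)``.
* Snell continuation ``n_sup * sin(theta_sup) = n_j * sin(theta_j)`` with the
  branch ``Im(n_j cos(theta_j)) >= 0`` (decaying evanescent waves).
* Tilted admittances ``eta_s = n cos(theta)``, ``eta_p = n / cos(theta)``.
* The p-polarization sign convention is chosen such that ``r_p == r_s`` and
  ``t_p == t_s`` exactly at normal incidence (no Fresnel sign flip).  At
  ``kr = 0`` both polarizations are computed from bitwise-identical inputs, so
  the s/p degeneracy holds exactly, which the crossed-polarizer transfer
  function downstream relies on.
* ``t`` is the ratio of transmitted to incident *full* electric-field
  amplitude, so the lossless energy balance reads, per polarization,
  ``|r|^2 + |t|^2 * Re(n_sub cos(theta_sub)) / (n_sup cos(theta_sup)) = 1``.

Units: thicknesses and wavelengths in nanometres; in-plane wavenumber as the
dimensionless fraction ``kr / k0`` with ``k0 = 2*pi/lam`` the vacuum
wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .errors import EvanescentIncidenceError, PhysicsError

__all__ = [
    "Layer",
    "LayerStack",
    "SPTransmission",
    "interface_coefficients",
    "stack_coefficients",
    "sp_transmission",
    "transmission_band_diagram",
]

# refractive index: a constant, or a callable wavelength_nm -> complex
IndexLike = Union[complex, float, Callable[[float], complex]]


def _resolve_index(n: IndexLike, wavelength_nm: float) -> complex:
    value = complex(n(wavelength_nm)) if callable(n) else complex(n)
    if value.imag < -1e-12:
        raise PhysicsError(f"gain media not supported: Im(n) = {value.imag}")
    return value


@dataclass(frozen=True)
class Layer:
    """One homogeneous dielectric layer.

    Parameters
    ----------
    thickness_nm:
        Physical thickness, strictly positive.
    index:
        Refractive index: a (complex) constant or a callable mapping
        wavelength in nm to a complex index.  ``Im(n) >= 0`` (absorbing or
        lossless; gain is rejected).
    """

    thickness_nm: float
    index: IndexLike

    def __post_init__(self) -> None:
        if not np.isfinite(self.thickness_nm) or self.thickness_nm <= 0:
            raise PhysicsError(f"layer thickness must be positive and finite, got {self.thickness_nm}")

    def n(self, wavelength_nm: float) -> complex:
        return _resolve_index(self.index, wavelength_nm)


@dataclass(frozen=True)
class LayerStack:
    """Ordered dielectric layers between two semi-infinite bounding media.

    ``layers[0]`` is adjacent to the superstrate (illumination side).  An
    empty stack is a single interface (or free propagation when the bounding
    media coincide).
    """

    layers: Sequence[Layer] = field(default_factory=tuple)
    superstrate: IndexLike = 1.0
    substrate: IndexLike = 1.52

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))

    def n_sup(self, wavelength_nm: float) -> complex:
        return _resolve_index(self.superstrate, wavelength_nm)

    def n_sub(self, wavelength_nm: float) -> complex:
        return _resolve_index(self.substrate, wavelength_nm)

    def reversed(self) -> "LayerStack":
        return LayerStack(tuple(reversed(self.layers)), self.substrate, self.superstrate)


@dataclass(frozen=True)
class SPTransmission:
    """Complex amplitude coefficients for both polarizations at one
    (wavelength, in-plane wavenumber) incidence context.

    ``kr_over_k0`` may be an array, in which case all coefficient fields are
    arrays of the same shape.  At ``kr = 0``, ``tp == ts`` and ``rp == rs``
    exactly by construction.
    """

    wavelength_nm: float
    kr_over_k0: np.ndarray
    ts: np.ndarray
    tp: np.ndarray
    rs: np.ndarray
    rp: np.ndarray

    @property
    def delta_t(self) -> np.ndarray:
        """tp - ts, the nonlocal response driving cross-polarized transmission."""
        return self.tp - self.ts

    @property
    def theta(self) -> np.ndarray:
        """Polar angle of incidence in the superstrate (radians)."""
        return np.arcsin(np.real(self.kr_over_k0))


def _cos_theta(n: complex, kr_over_k0: np.ndarray) -> np.ndarray:
    """cos(theta) inside a medium of index n for in-plane wavenumber kr/k0,
    on the branch Im(n cos(theta)) >= 0."""
    c = np.sqrt(1.0 - (kr_over_k0 / n) ** 2 + 0j)
    flip = (n * c).imag < 0
    return np.where(flip, -c, c)


def _check_propagating(n_sup: complex, kr: np.ndarray) -> None:
    if np.any(np.asarray(kr) >= n_sup.real):
        raise EvanescentIncidenceError(
            f"incidence is evanescent: kr/k0 >= Re(n_sup) = {n_sup.real}"
        )


def interface_coefficients(n1: complex, n2: complex, theta1: float, pol: str):
    """Fresnel amplitude coefficients (r, t) for a single interface.

    Sign convention such that ``r_p == r_s`` and ``t_p == t_s`` at
    ``theta1 = 0`` (admittance convention, no p-wave sign flip).

    Raises :class:`EvanescentIncidenceError` when the incident wave is
    evanescent in medium 1.
    """
    if pol not in ("s", "p"):
        raise ValueError(f"pol must be 's' or 'p', got {pol!r}")
    n1 = _resolve_index(n1, 0.0)
    n2 = _resolve_index(n2, 0.0)
    kr = n1.real * np.sin(theta1)  # in units of k0
    _check_propagating(n1, np.asarray(kr))
    c1 = _cos_theta(n1, kr)
    c2 = _cos_theta(n2, kr)
    if pol == "s":
        denom = n1 * c1 + n2 * c2
        return (n1 * c1 - n2 * c2) / denom, 2 * n1 * c1 / denom
    denom = n1 * c2 + n2 * c1
    return (n1 * c2 - n2 * c1) / denom, 2 * n1 * c1 / denom


def stack_coefficients(stack: LayerStack, wavelength_nm: float, kr_over_k0, pol: str):
    """Complex (r, t) of a multilayer by the characteristic-matrix product.

    Vectorized over ``kr_over_k0``.  Transmission phase is referenced to the
    stack boundaries (an empty stack between identical media gives t = 1
    exactly, with no propagation phase).
    """
    if pol not in ("s", "p"):
        raise ValueError(f"pol must be 's' or 'p', got {pol!r}")
    if not np.isfinite(wavelength_nm) or wavelength_nm <= 0:
        raise PhysicsError(f"wavelength must be positive, got {wavelength_nm}")
    kr = np.asarray(kr_over_k0, dtype=float)
    scalar = kr.ndim == 0
    kr = np.atleast_1d(kr)

    n_sup = stack.n_sup(wavelength_nm)
    n_sub = stack.n_sub(wavelength_nm)
    _check_propagating(n_sup, kr)

    c_sup = _cos_theta(n_sup, kr)
    c_sub = _cos_theta(n_sub, kr)

    def eta(n, c):
        return n * c if pol == "s" else n / c

    e_sup = eta(n_sup, c_sup)
    e_sub = eta(n_sub, c_sub)

    # [B; C] = (prod_j M_j) [1; eta_sub], accumulated from the substrate side
    B = np.ones_like(kr, dtype=complex)
    C = e_sub * B
    for layer in reversed(stack.layers):
        n_j = layer.n(wavelength_nm)
        c_j = _cos_theta(n_j, kr)
        delta = 2 * np.pi / wavelength_nm * n_j * layer.thickness_nm * c_j
        e_j = eta(n_j, c_j)
        cosd = np.cos(delta)
        sind = np.sin(delta)
        # sign chosen for the exp(+i k z) forward convention: a zero-contrast
        # layer multiplies t by exp(+i delta)
        B, C = cosd * B - 1j * sind / e_j * C, -1j * e_j * sind * B + cosd * C

    denom = e_sup * B + C
    r = (e_sup * B - C) / denom
    t = 2 * e_sup / denom
    if pol == "p":
        # convert tangential-field ratio to full-field amplitude ratio
        t = t * c_sup / c_sub
    if scalar:
        return r[0], t[0]
    return r, t


def sp_transmission(stack: LayerStack, wavelength_nm: float, kr_over_k0) -> SPTransmission:
    """Bundle s and p coefficients at one incidence context (vectorized over kr)."""
    kr = np.atleast_1d(np.asarray(kr_over_k0, dtype=float))
    rs, ts = stack_coefficients(stack, wavelength_nm, kr, "s")
    rp, tp = stack_coefficients(stack, wavelength_nm, kr, "p")
    return SPTransmission(wavelength_nm, kr, ts=ts, tp=tp, rs=rs, rp=rp)


def transmissivity(stack: LayerStack, wavelength_nm: float, kr_over_k0, pol: str):
    """Power transmittance T including the flux factor
    Re(n_sub cos(theta_sub)) / (n_sup cos(theta_sup))."""
    kr = np.atleast_1d(np.asarray(kr_over_k0, dtype=float))
    n_sup = stack.n_sup(wavelength_nm)
    n_sub = stack.n_sub(wavelength_nm)
    _, t = stack_coefficients(stack, wavelength_nm, kr, pol)
    flux = np.real(n_sub * _cos_theta(n_sub, kr)) / np.real(n_sup * _cos_theta(n_sup, kr))
    return np.abs(t) ** 2 * flux


def transmission_band_diagram(
    stack: LayerStack,
    frequencies_thz: np.ndarray,
    kr_over_k0: np.ndarray,
    pol: str,
    amplitude: bool = True,
) -> np.ndarray:
    """Transmission map over (frequency, in-plane wavenumber).

    Returns a 2D array of shape ``(len(frequencies_thz), len(kr_over_k0))``
    holding ``|t|`` (default) or ``|t|^2`` when ``amplitude=False``.  The map
    is even in kr, so only the magnitudes of ``kr_over_k0`` matter.
    """
    f = np.asarray(frequencies_thz, dtype=float)
    kr = np.abs(np.asarray(kr_over_k0, dtype=float))
    if f.size == 0 or kr.size == 0:
        raise PhysicsError("frequency and kr grids must be non-empty")
    c_nm_per_ps = 299_792.458  # speed of light in nm/ps; f in THz = 1/ps
    out = np.empty((f.size, kr.size))
    for i, fi in enumerate(f):
        lam = c_nm_per_ps / fi
        _, t = stack_coefficients(stack, lam, kr, pol)
        out[i] = np.abs(t) ** 2 if not amplitude else np.abs(t)
    return out
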
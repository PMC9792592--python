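"""Back-focal-plane intensity maps and k-space region classification.

The back focal plane of the collection objective images the angular response
of the chip directly: its intensity is |t(kx, ky)|^2.  In the crossed
configuration the map shows the characteristic dark cross along the kx and ky
axes (the sin 2*phi factor) with four bright lobes on the diagonals, zero at
the center, and each k-space region supports the differentiation order whose
power law best describes the local cut: a central disc for the even (radial)
order and off-axis horizontal bands for the odd (line) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError
from .otf import OTFGrid, PolarizerPair, fit_line_power_law, fit_radial_power_law

__all__ = ["BFPImage", "simulate_bfp", "extract_cut", "classify_regions", "RegionMap"]


@dataclass
class BFPImage:
    """Normalized back-focal-plane intensity over (kx, ky) in units of k0."""

    wavelength_nm: float
    kx: np.ndarray
    ky: np.ndarray
    intensity: np.ndarray  # [j, i] = I(kx[i], ky[j]), max-normalized
    na_limit: float
    polarizers: PolarizerPair
    provenance: dict = field(default_factory=dict)


def simulate_bfp(otf: OTFGrid, provenance: dict | None = None) -> BFPImage:
    """Intensity |t|^2 masked to the NA disc and normalized to unit maximum."""
    intensity = np.abs(otf.values) ** 2
    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    return BFPImage(otf.wavelength_nm, otf.kx, otf.ky, intensity, otf.na_limit,
                    otf.polarizers, provenance or {})


def extract_cut(source, mode: str, value: float, k_max: float | None = None,
                n_samples: int = 128):
    """1D profile through an OTF grid or BFP image.

    mode "radial": cut along azimuth phi = value (radians, from the ky axis),
    returning (kr, |t| or intensity).  mode "line": horizontal cut at
    ky = value, returning (kx, ...).  Bilinear interpolation; raises when the
    cut misses the NA disc entirely.
    """
    if isinstance(source, BFPImage):
        grid = OTFGrid(source.wavelength_nm, source.kx, source.ky,
                       source.intensity.astype(complex), source.na_limit, source.polarizers)
        def post(v):
            return v.real
    elif isinstance(source, OTFGrid):
        grid = source
        def post(v):
            return np.abs(v)
    else:
        raise TypeError(f"cannot cut through {type(source).__name__}")

    if mode == "radial":
        k_max = min(k_max or grid.na_limit, grid.na_limit)
        k = np.linspace(0.0, k_max, n_samples)
        vals = grid.interp(k * np.sin(value), k * np.cos(value))
    elif mode == "line":
        if abs(value) >= grid.na_limit:
            raise GridError(f"line cut ky = {value} lies outside the NA disc")
        half = np.sqrt(grid.na_limit ** 2 - value ** 2)
        half = min(k_max or half, half)
        k = np.linspace(-half, half, n_samples)
        vals = grid.interp(k, np.full_like(k, value))
    else:
        raise ValueError(f"mode must be 'radial' or 'line', got {mode!r}")
    return k, post(vals)


@dataclass
class RegionMap:
    """Labeled k-space mask: per grid point, the differentiation order the
    local transfer function supports (0 = unclassified)."""

    kx: np.ndarray
    ky: np.ndarray
    labels: np.ndarray
    legend: dict
    fits: dict


def classify_regions(
    otf: OTFGrid,
    even_orders=(2, 4, 6),
    disc_radius: float = 0.12,
    band_kx_window: float = 0.25,
    residual_ratio: float = 0.5,
    line_tolerance: float = 0.12,
) -> RegionMap:
    """Assign each k-point the differentiation order its neighborhood supports.

    The central disc (kr <= disc_radius) carries the even, radial order: the
    candidate in ``even_orders`` whose pure power law best fits the diagonal
    cut.  Off-axis horizontal rows are labeled with the corresponding odd
    (line) order ``n_even - 1`` where the pure odd power law along the row,
    fitted over |kx| <= band_kx_window, describes |t| well: relative misfit
    below ``residual_ratio`` times the radial misfit or below
    ``line_tolerance`` absolutely.  The absolute tolerance accommodates the
    irreducible cross term of the quartic response (kx ky^3 next to kx^3 ky),
    which leaves ~8% misfit on a pure cubic even for an ideal band; the
    structure gives no sharper criterion, so the rule and thresholds are
    configurable.
    """
    radial_fits = {n: fit_radial_power_law(otf, np.pi / 4, n) for n in even_orders}
    def misfit(f):
        return max(1.0 - f.r_squared, 0.0)
    n_even = min(radial_fits, key=lambda n: misfit(radial_fits[n]))
    radial_resid = misfit(radial_fits[n_even])
    n_odd = n_even - 1

    KX, KY = np.meshgrid(otf.kx, otf.ky)
    KR = np.hypot(KX, KY)
    labels = np.zeros(KR.shape, dtype=int)
    labels[KR <= min(disc_radius, otf.na_limit)] = n_even

    line_fits = {}
    for j, ky0 in enumerate(otf.ky):
        if abs(ky0) <= disc_radius or abs(ky0) >= otf.na_limit:
            continue
        try:
            f = fit_line_power_law(otf, float(ky0), n_odd, kx_max=band_kx_window)
        except GridError:
            continue
        line_fits[float(ky0)] = f
        if misfit(f) < max(residual_ratio * radial_resid, line_tolerance):
            row = (np.abs(KY[j]) > 0) & (np.abs(KX[j]) <= band_kx_window) & (KR[j] <= otf.na_limit)
            labels[j, row] = n_odd

    legend = {n_even: f"order-{n_even} radial differentiation disc",
              n_odd: f"order-{n_odd} line differentiation bands",
              0: "unclassified"}
    return RegionMap(otf.kx, otf.ky, labels, legend,
                     {"radial": radial_fits, "line": line_fits})
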
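# Methods

## Physical model

The device is a stratified dielectric multilayer: by default 40 alternating
layers, Si₃N₄ (56 nm) / SiO₂ (80 nm), starting with Si₃N₄ on the
illumination side, deposited on a glass coverslip. The coverslip is treated
as a semi-infinite substrate (no back-surface etalon); the illumination side
is air. Plane-wave transmission and reflection are computed with the 2×2
characteristic-matrix (Abelès) formalism:

* phase thickness δⱼ = (2π/λ) nⱼ dⱼ cosθⱼ per layer, with Snell continuation
  n_sup sinθ = nⱼ sinθⱼ and the branch Im(nⱼ cosθⱼ) ≥ 0 (decaying
  evanescent waves inside layers; gain media rejected);
* tilted admittances η_s = n cosθ, η_p = n/cosθ; the p-wave sign convention
  is chosen so that r_p = r_s and t_p = t_s **exactly** at normal incidence
  (at k_r = 0 both polarizations run through bitwise-identical arithmetic),
  which the crossed-polarizer extinction relies on;
* t is the full-field amplitude ratio, so the lossless energy balance is
  |r|² + |t|²·Re(n_sub cosθ_sub)/(n_sup cosθ_sup) = 1 (verified to 1e−9);
* the sign of the layer matrix is fixed to the e^{+ikz} forward convention:
  a zero-contrast layer multiplies t by e^{+iδ}, consistent with the
  e^{+ik·r} plane-wave phases used in image formation.

The transfer-matrix solver is validated against closed-form oracles: the
Fresnel coefficients (zero layers), the Airy single-film formula (one
layer), Brewster's angle, stack-reversal reciprocity, and the quarter-wave
Bragg condition for the stopband position.

## Material data

The main structural parameters (layer count and thicknesses) are fixed; the
refractive indices are **stand-in constants**: n(Si₃N₄) = 2.02,
n(SiO₂) = 1.46, glass 1.52, air 1.0, with a config hook for user dispersion
tables (`materials:` in the stack YAML accepts `[[λ_nm, n_re, n_im], …]`).
PECVD film indices vary by recipe and the exact dispersion used for the
original chip design is not available to this package, so absolute operating
wavelengths shift relative to the fabricated device (see *Limitations*).

## Cross-polarized transfer function

`scalar_otf` evaluates t = e_outᵀ·M·e_in through the full Jones matrix
M = t_p p̂p̂ᵀ + t_s ŝŝᵀ, supporting arbitrary linear polarizer pairs; the
crossed default (vertical in, horizontal out) reduces to
t = ½ sin(2φ)(t_p − t_s) with φ measured from the k_y axis
(sin 2φ = 2kₓk_y/k_r², removing the arctan quadrant ambiguity). The test
suite holds the two code paths against each other to 1e−12.

Angular structure is quantified two ways:

1. **Taylor classification** (`fit_angular_taylor`, `dominant_order`,
   `find_operating_wavelengths`): t_p − t_s is least-squares fitted on the
   even basis θ², …, θ⁸ over θ ≤ arcsin(0.25) (64 samples); the variance
   share of each term uses the analytic window norms
   ‖θᵖ‖² = T^{2p+1}/(2p+1), making the shares sampling-independent. An
   order dominates when its share is ≥ 0.9 (the structure itself motivates
   no sharper threshold).
2. **Power-law fits** (`fit_radial_power_law`, `fit_line_power_law`): |t|
   along a radial or horizontal cut fitted to a single power, the way
   back-focal-plane cuts are analyzed; coefficients are reported in
   (k/k₀)ⁿ units with `coefficient_absolute()` converting by k₀ⁿ. For the
   quartic response the horizontal cut is inherently
   d·(kₓ³k_y0 + kₓ k_y0³); the pure-cubic description carries an
   irreducible ≈ 8 % misfit from the linear companion term, while a dual
   odd-basis fit {kₓ, kₓ³} recovers d exactly. Cut extraction from sampled
   OTF grids uses bilinear interpolation, staying one grid cell clear of
   the NA boundary where cells are zeroed.

### Wavelength selection

Two documented selectors serve different tasks:

* `select_operating_wavelength`: among wavelengths where an order dominates
  the Taylor classification, the one with the strongest |ΔC| — best signal
  for the *operating wavelength* of that order. Default chip, 600–700 nm
  scan: 601.5 nm for order 2 (the θ²-dominant band spans ≈ 601.5–694.5 nm
  and contains 643 nm).
* `select_imaging_wavelength`: the wavelength minimizing the **complex**
  pure-power-law misfit of the OTF cut over the full imaging aperture
  (default NA 0.45) — best fidelity for pure-order *imaging*. The complex
  fit matters: a magnitude power law with a twisting phase is not a clean
  differentiator under coherent imaging. Default chip: 671.5 nm for
  order 2.

The small-angle Taylor window does not control the response out at the
aperture edge, which is why the two selectors differ; both are deterministic
functions of the stack.

## Back focal plane and k-space regions

`simulate_bfp` maps |t|² over the NA disc, normalized to unit maximum (the
physical color scale is arbitrary). Crossed polarizers produce the
signature pattern: exact zero at the center and along both axes, four lobes
on the diagonals. `classify_regions` labels a central disc with the best
even (radial) order and off-axis horizontal bands with the corresponding odd
(line) order where the per-row odd power law describes |t| well — misfit
below 0.5× the radial misfit or below 0.12 absolutely, the latter
accommodating the quartic cross term above. The geometry thresholds (disc
radius 0.12 k₀, band window |kₓ| ≤ 0.25 k₀) are configurable; no sharper
rule is derivable from the structure itself.

## Image formation

Coherent, monochromatic, scalar model (valid at NA ≤ 0.45): the object
spectrum (FFT, centered grids, Parseval-normalized) is band-limited to the
imaging NA, the OTF is sampled at frequencies shifted by the illumination
offset (k_x0, k_y0) — one offset per simulation, modeling one region of an
out-of-focus illumination cone — and inverse-transformed.
Components evanescent in the incidence medium are zeroed. Nyquist
violations (pitch > λ/2NA) raise instead of aliasing silently.

Default study conditions for edge imaging: 512² grids, 0.1 µm pixels,
edge blur σ = 0.3 µm, NA 0.45, 20 % peak threshold, ±2.5 µm edge window.
σ = 0.3 µm keeps the edge response band-limited enough that aperture
ringing stays small while the quartic response's outer lobes survive; at
σ ≥ 0.4 µm the weakest fourth-order lobes drop below the count threshold,
at much smaller σ the hard-aperture ringing grows.

**Peak counting** (`count_edge_peaks`) uses height above background — a
local maximum counts when it rises ≥ 20 % of the peak edge response above
the background (median intensity far from the edge). Two deliberate
choices: scipy's topographic prominence is avoided because its value for
decaying aperture-ringing lobes depends on where the analysis window
truncates the tail; and the 20 % level separates coherent hard-aperture
Gibbs ringing (≤ 17 % of the peak under the stated conditions) from the
weakest genuine side lobe of a fourth-order response (≥ 34 %). A 5 %
threshold — natural for low-noise experimental profiles smoothed by partial
coherence — cannot make that separation in a fully coherent model.

**Resolution** (`resolution_check`, `smallest_resolved_width`): a bar is
resolved when the minimum over its central third sits ≥ 20 % (Rayleigh-like
dip, configurable) below the mean of the two edge-ridge maxima found within
a third of the bar width of each edge. With the default chip at its
second-order operating wavelength (601.5 nm) all of 4/3/2 µm resolve; at a
*purer* quadratic wavelength the 2 µm center dip fills in coherently — the
pure second-order response's inner lobes overlap constructively — so the
2 µm figure is sensitive to the higher-order admixture and to the coherence
model, not only to the aperture.

## Synthetic objects

* `make_step_target` / `make_bar_target`: binary amplitude patterns (USAF
  three-bar style) at any edge-normal angle, optionally Gaussian-blurred
  (σ = 0 gives exact {0,1}); bar edge positions are recorded for metrics.
* `make_vortex_plate`: unit-amplitude spiral phase, integer charge, seam
  half-line at a chosen angle. An ideal 2π step is invisible to coherent
  differentiation (e^{iφ} is continuous across it); passing
  `design_wavelength_nm` models a physical plate whose thickness step gives
  2π only at its design wavelength, leaving a genuine residual discontinuity
  at other wavelengths — that is what a first-order image renders as a
  bright line.
* `make_phase_cells`: unit-amplitude phantom with super-Gaussian phase
  bumps (default 8 cells, 5–15 µm, amplitude ≤ 1 rad — weak-phase regime)
  at seeded random positions; bit-reproducible by seed. It emulates the
  smooth phase relief of transparent cells; it does **not** emulate
  absorption, scattering, internal granularity or noise, so passing tests
  demonstrate the phase-gradient contrast mechanism, not performance on
  real micrographs.
* `phase_contrast_intensity`: exact first-order x-derivative (no aperture),
  rescaled by k₀² so a linear ramp φ = αx yields exactly α²; with a finite
  aperture the law holds in the slowly-varying limit.

## Verification strategy

Every closed form the analysis rests on is tested against an independent
route: TMM vs Fresnel/Airy (1e−10), energy conservation (1e−9), Jones
product vs the sin 2φ form (1e−12), the quartic identity
½ sin2φ·θ⁴ = uₓ³u_y + uₓu_y³ (1e−9), Taylor round trips (1e−6), the
a/b/c/d coefficient relations on pure synthetic responses (0.1 %), the
phase-gradient law (1e−6), and ideal-OTF differentiation vs high-order
finite differences (< 1 % L2). The n-peak edge law is verified end to end
for orders 1–4 with pure-coefficient responses (the operating points of an
ideal chip) and for orders 1–2 with the full transfer-matrix chip.

## Limitations

* **Stand-in indices.** With constant n = 2.02/1.46 the θ²-dominant band
  (601.5–694.5 nm) contains the nominal 643 nm operating point, but the
  complex ΔC₂(λ) never passes through zero, so no wavelength is purely
  θ⁴-dominant: the quartic share peaks at ≈ 0.27 near 624 nm, *below* the
  quadratic regime as expected, but third-/fourth-order differentiation by
  the TMM chip itself is out of reach without the real films' dispersion
  data. The quartic mechanism is exercised through pure-ΔC₄ responses
  instead.
* **Coherence.** Perfectly coherent, monochromatic scalar imaging; real
  measurements with a 2 nm-bandwidth source and an extended out-of-focus
  illumination spot average over angles and wavelengths, which suppresses
  the aperture ringing and interference fill-in discussed above.
* **One offset per simulation.** An experimental frame in which different
  image regions see different illumination angles (hence different
  differentiation orders simultaneously) is modeled as separate runs.
* No vectorial high-NA imaging, no camera/noise model, no partially
  coherent pupil integration, no anisotropic or magnetic layers, no guided-
  mode analysis.
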
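# planarchip

Simulation of a planar all-dielectric multilayer "photonic chip" that acts as
a **multi-order analog spatial differentiator**: placed between crossed
polarizers in an ordinary transmission microscope, the same 40-layer
Si₃N₄/SiO₂ stack performs first-, second-, third- or fourth-order spatial
differentiation of an optical image, depending only on the illumination
wavelength and angle. The package is aimed at computational-optics and
microscopy researchers who want to explore such nonlocal (angle-dependent)
flat optics numerically: it reproduces the device's k-space transfer
functions, its back-focal-plane maps, and the edge-enhanced images of
amplitude and phase (cell-like) specimens.

## The model

Image formation is linear in the plane-wave basis. For an input field with
angular spectrum A(kₓ, k_y),

    E_out(x, y) = ∬ t(kₓ, k_y) A(kₓ, k_y) e^{i(kₓx + k_y y)} dkₓ dk_y ,

so the device is fully characterized by its optical transfer function
t(kₓ, k_y). For a stratified dielectric stack between a vertical polarizer
and a horizontal analyzer, Jones calculus gives the scalar OTF

    t(kₓ, k_y) = ½ sin(2φ) · (t_p − t_s) ,      φ = arctan(kₓ/k_y),

with t_s, t_p the s/p amplitude transmissions from the transfer-matrix
method (TMM). Mirror symmetry makes t_p − t_s even in the polar angle θ:

    t_p − t_s = Σₙ ΔC₂ₙ θ^{2n},     θ = arcsin(k_r/k₀) ≈ k_r/k₀.

When one term dominates, the OTF reduces to pure power laws along specific
k-space cuts — and a power-law OTF **is** a spatial differentiator:

| dominant term | radial cut (fixed φ)                 | horizontal cut (fixed k_y = k_y0)  |
|---------------|--------------------------------------|------------------------------------|
| ΔC₂ θ²        | t = a k_r²,  a = ΔC₂ sin2φ / 2k₀²    | t = b kₓ,  b = ΔC₂ k_y0 / k₀²      |
| ΔC₄ θ⁴        | t = c k_r⁴,  c = ΔC₄ sin2φ / 2k₀⁴    | t = d kₓ³, d = ΔC₄ k_y0 / k₀⁴      |

An n-th order differentiator renders each step edge of an object as exactly
n intensity peaks, and converts a pure phase object E = e^{iφ(x,y)} into an
intensity image |∂φ/∂x|² — phase-gradient contrast without any dark-field or
DIC optics.

## Worked example

```python
import numpy as np
from planarchip import (default_chip, find_operating_wavelengths,
                        select_operating_wavelength, smallest_resolved_width)

chip = default_chip()          # 40 layers: Si3N4 56 nm / SiO2 80 nm on glass
table = find_operating_wavelengths(chip, np.arange(600, 700.1, 0.5))
lam2 = select_operating_wavelength(table, 2)
print(lam2)                    # 601.5  — strongest theta^2-dominant wavelength

smallest, detail = smallest_resolved_width(chip, [4.0, 3.0, 2.0],
                                           wavelength_nm=lam2, na=0.45)
print(detail)                  # {4.0: True, 3.0: True, 2.0: True}
print(smallest)                # 2.0  — um, both edges of every bar resolved
```

`601.5` is the wavelength (with the package's default constant refractive
indices) where the quadratic term of t_p − t_s is strongest while still
carrying ≥ 90 % of the angular response — the chip there acts as a
second-order differentiator. Imaging three-bar test elements through that
OTF at NA 0.45 resolves both edges of each bar down to 2 µm width
(inter-ridge dip ≥ 20 %).

The `examples/` scripts walk through each capability and print what they
compute: `01_band_diagram.py` (TMM transmission maps and the stopband),
`02_crossed_otf_and_bfp.py` (OTF, back-focal-plane image, power-law fits,
k-space region classification), `03_operating_wavelengths.py` (wavelength
scan and selection rules), `04_edge_enhanced_imaging.py` (the n-peak edge
law for orders 1–4 and the resolution test), `05_phase_objects.py`
(cell phantoms, the phase-gradient law, a spiral phase plate's seam).

A thin CLI mirrors the pipeline:
`planarchip band-diagram | otf | find-wavelengths | simulate-image | fixtures`
(YAML config via `--config`, products under `--out`; exit codes 0/2/3 for
success / config error / physics-precondition violation).

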
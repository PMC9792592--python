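# 40-layer alternating Si3N4/SiO2 differentiator chip on a glass coverslip.
# Units: layer thickness d_nm in nanometres; indices are dimensionless constants
# (stand-ins for the PECVD films; replace with dispersion tables [[lam_nm, n_re, n_im], ...] if known).
superstrate: air
substrate: glass
materials:
  air: 1.0
  glass: 1.52
  Si3N4: 2.02
  SiO2: 1.46
layers:
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
- material: Si3N4
  d_nm: 56
- material: SiO2
  d_nm: 80
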